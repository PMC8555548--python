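# polyterm

Tools for studying how T-rich sequence motifs (TRSM) relate to RNA
polymerase II pausing and alternative polyadenylation (APA), built for
transcriptomics analysts who have a genome, gene models, a polyadenylation
site (PAS) catalog, peak summits from a pause-site experiment (for example
NET-seq processed with MACS2), and replicate read counts from mutant and
control conditions.

The package implements four connected analyses:

1. **TRSM scanning** (`polyterm.trsm`) — a sliding 12 bp window calls a
   biased sequence when it holds ≥ 9 copies of one base (75%); after a hit
   the scan jumps past the window so one run is counted once. Rates are
   reported per feature class (introns, internal exons, terminal exons,
   5 kb downstream regions) as hits/kb and the fraction of features with a
   hit.
2. **Pause-peak post-processing** (`polyterm.peaks`) — unstranded summits
   are expanded to 80 bp, assigned strand by majority of overlapping reads
   (ties unassigned), filtered against internal (not terminal) exons and
   sequencing adaptors; base composition and 3′-half 5-mer frequencies are
   compared with length-matched random genomic controls (default 5 draws of
   5000 regions), reported as z = (obs − mean)/sd.
3. **Readthrough quantification** (`polyterm.readthrough`) — for each PAS,
   readthrough is

   ```
   readthrough = downstream reads / upstream reads      (275 bp windows)
   ```

   PAS closer than 275 bp are collapsed to the most used site; records are
   classified no_readthrough / low_expression / analyzable; mutant and
   control triplicates are compared with a two-tailed t-test at α = 0.05
   with no multiplicity correction (the test is conservative at n = 3 and
   neighbouring PAS are interdependent). Exon skipping is scored as
   spanning junctions / FPKM and tested the same way.
4. **Motif–phenotype correlation** (`polyterm.motifstats`) — in a window
   from 200 bases upstream of the nearest 3′ splice site to 200 bases
   downstream of the PAS (exon boundaries ± 200 for exons), each of the
   1024 5-mers gets an overlap-corrected frequency: a chain of r mutually
   overlapping instances counts 1 + 0.2·(r − 1) events, so a run of six
   identical bases counts 1.2. Per motif, Spearman's ρ between frequency
   and log2 fold change is reported with an asymptotic two-sided p-value.

A seeded synthetic-data generator (`polyterm.synth`) produces a genome,
annotation, PAS catalog, summits, counts and expression tables with planted
TRSM, planted peak strands, and a planted motif→readthrough effect
(mutant readthrough = WT × exp(β · TTTTT content + noise) for ~10% of PAS,
baseline readthrough ≈ 0.5), so every stage can be scored against ground
truth.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/03_readthrough.py` prints:

```
401 catalog PAS -> 401 after collapsing sites closer than 275 bp
categories: {'analyzable': 318, 'low_expression': 45, 'no_readthrough': 38}
318 PAS tested; 40 significantly altered (12.6%)
planted affected PAS recovered: 100% of 30 testable
```

318 PAS survive the expression and minimum-coverage filters; 12.6% are
flagged at α = 0.05 (the generator plants effects at 10% of PAS, plus the
test's ~4–5% false-positive rate on the rest), and every planted effect
that reaches the test is recovered. `examples/04_motif_correlation.py`
then shows TTTTT as the most negatively correlated 5-mer (ρ = −0.22,
p = 1.8 × 10⁻⁵), recovering the planted driver motif.

The same pipeline is available from the shell:

```bash
polyterm synth --seed 1 --out data/
polyterm features --gtf data/annotation.gtf --fasta data/genome.fa --out feats/
polyterm readthrough --pas data/pas.bed --counts data/counts.tsv \
    --expression data/expression.tsv --wt WT1,WT2,WT3 --mut MUT1,MUT2,MUT3 \
    --out rt/
polyterm run-all --seed 1 --out results/   # everything at once
```

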