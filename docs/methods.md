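# Methods

## Coordinates and orientation

All intervals are 0-based half-open on named sequences; GTF/GFF input
(1-based inclusive) is converted at the file boundary. Every sequence
handed to an analysis is in transcript orientation: minus-strand intervals
are reverse-complemented on extraction, so a T-rich template element reads
as T-rich regardless of strand.

## Feature decomposition

Genes are decomposed per transcript: the last exon in transcript
orientation is terminal, all others internal, and introns are the
inter-exon gaps. Features are unioned per gene; an exon that is terminal
in one transcript and internal in another is assigned terminal (the
analyses focus on terminal-exon behaviour, so the conservative class wins)
and flagged. One downstream region per gene starts at the gene's 3′-most
transcript end and extends 5000 bases in the direction of transcription,
truncated at sequence ends and dropped below 12 bases (the scanner needs
one full window). Finally, any feature overlapping a feature of a
*different* gene — on either strand — is removed from all classes,
symmetrically, so a downstream region never double-counts a neighbouring
gene's exonic composition. Within one gene the partition rule itself
prevents overlap.

## Biased-window scan

A window of `window = 12` bases qualifies when it holds at least
`min_count = 9` copies of the scanned base (9/12 = 75%). Scanning is left
to right; on a hit the scan resumes at the first base after the qualifying
window, so a single run yields one hit per 12 bases rather than one per
start position. An alternative skip mode (`skip_mode="run"`) resumes after
the maximal run of the scanned base; the two differ only inside runs
longer than 12 bases. Ambiguity codes never count toward any base.
Rates: `hits_per_kb = total hits / total feature kilobases`;
`fraction_with_hit` is the share of features with ≥ 1 hit. On a uniform
random genome the scan has a non-trivial background (a 12-window holds
≥ 9 of one base with probability ≈ 4 × 10⁻⁴ per position, ≈ 0.25 hits/kb
after greedy non-overlap), so planted-density recovery is always assessed
against a zero-density generation, not against zero.

## Peak post-processing

Summits are expanded to `width = 80` bases centred on the summit (clipped
and flagged at sequence edges). Strand is assigned by majority over reads
overlapping the region by ≥ 1 base; a tie leaves the region unassigned.
Regions overlapping any internal exon by ≥ 1 base, or containing a
configured adaptor on either strand, are removed with the reason logged.
k-mer quantification uses the 3′ half of each region. Controls are
independent draws of length-matched regions sampled uniformly from the
genome on a random strand, redrawn when they contain N; the per-motif mean
and SD over draws give z = (observed − mean)/sd. No p-value is attached to
z — the enrichment display is observed-versus-control. The control SD
reflects the sampling noise of a control draw, so meaningful calibration
requires `control_size` comparable to the number of observed regions.

## Readthrough and differential testing

For a PAS at base p on the + strand the upstream window is [p−275, p) and
the downstream window [p+1, p+276) (mirrored on −). A read counts in a
window when it overlaps it by ≥ 1 base; a read straddling the cleavage
site counts in both, a deliberate, stated convention so counts are
reproducible. Readthrough is down/up, defined only when up ≥ `min_up = 10`
(the data do not define a ratio on a near-empty upstream window); it is
invariant to per-sample scaling, so no depth normalization is applied.

PAS within 275 bp of one another (transitive clusters on one
seqname/strand) are collapsed to the maximal-usage site, usage defaulting
to mean WT upstream reads, ties going to the 5′-most site. Clustering is
per strand because sites on opposite strands belong to different genes'
3′ ends.

Records are classified in fixed precedence order: `no_readthrough` (zero
downstream signal in every WT sample), `low_expression`
(FPKM < 1, configurable), else `analyzable`. Analyzable records are tested
with a pooled-variance two-tailed t-test (Welch by flag), mutant versus
control triplicates, α = 0.05, no multiplicity correction. Degenerate
records (both groups constant) get p = 1 when equal, p = 0 flagged when
different. Fold change is reported on the natural scale; log2 is used for
PCA (log2(x + 10⁻³)) and correlation. The PCA summary centres the
sample × PAS matrix (columns with undefined entries dropped) and reports
scores on the first two components.

## Overlap-corrected motif counting and correlation

Raw occurrence counting is browser-style: every start position matches, so
five consecutive T's contain two TTTT hits. For frequencies this
overweights runs, so occurrences of one motif are grouped into maximal
chains in which each instance overlaps the previous one (successive starts
< k apart); a chain of r instances counts 1 + w·(r − 1) events with
w = 0.2, hence a run of six identical bases counts 1.2 and a run of length
L counts 1 + 0.2·(L − k). The linear chain weight is the minimal model
consistent with that anchor value and is exposed as a parameter.

Analysis windows span from 200 bases upstream of the PAS's nearest
upstream 3′ splice site (intron 3′ end in transcript orientation) to 200
bases downstream of the cleavage base; PAS of single-exon genes have no
such splice site and are excluded with a count. Exon windows use the exon
boundaries ± 200. Subregions (upstream flank, body, downstream flank) can
be analyzed separately.

Per motif, the corrected count divided by subregion length is paired with
log2 fold change and Spearman's ρ computed by vectorized rank transform +
Pearson, with asymptotic t p-values (two-sided); the log is monotone, so
it changes only the reported effect scale, not the ranks. Significance is
uncorrected at α = 0.05, matching the t-test policy; a Benjamini–Hochberg
column can be added by the caller. The reported `normalized_freq` is the
per-motif mean frequency divided by the sum over all 1024 motifs — a
relative-abundance axis. Motifs absent from every record are flagged with
undefined ρ. AT-content profiles report the A/T fraction per position
within ± 75 bases of the cleavage site; cross-analysis agreement
(exons versus PAS) is the Pearson r between the two per-motif ρ vectors.

## Synthetic data: what it emulates, and what it does not

The generator builds ~200 genes (2–6 exons, exons 100–300 bp, introns
200–1200 bp) on 4 chromosomes and both strands, spaced so 5 kb downstream
regions do not collide, on a uniform background. It plants, per feature
class, 12-base T runs at configurable densities (defaults: introns 1.0/kb,
downstream 0.8, terminal exons 0.4, internal exons 0.05 — T-rich elements
concentrated in non-coding sequence); 1–3 PAS per gene at and downstream
of the transcript end; pause summits mostly in terminal exons (20% in
internal exons to exercise the exclusion filter) with a 6-base T run
planted on the 3′ flank of 80% and reads at 90% strand purity.

Readthrough: WT baseline is lognormal with median 0.5; 10% of PAS carry
zero WT downstream signal and 10% of genes fall below the expression
filter. For a planted 10% of PAS, 2–5 six-base T runs are inserted within
150 bases upstream of the cleavage site and mutant readthrough is
WT × exp(β·c + ε), where c is the planted corrected TTTTT content
(1.2 per run), β = −0.6 and ε ~ N(0, 0.1). Window counts are negative
binomial with mean 200 (upstream) and 200 × readthrough (downstream),
dispersion 0.02 (replicate CV ≈ 15%), three replicates per group. β and
the dispersion were fixed together by a standard power calculation so that
the weakest planted effect (two runs, fc ≈ 0.24) is detectable by a 3-vs-3
t-test at these depths — the generator is meant to emulate a study in
which the planted biology is recoverable, and sensitivity is scored over
planted PAS that survive the pipeline's own filters, since filtered
records never reach the test. Exon skipping mirrors the same effect model
with Poisson junction counts.

What passing on this data does **not** show: real genomes are not uniform
(repeats, isochores, codon bias), real coverage is not uniform within
windows, PAS usage interacts across a gene, and real replicate noise has
structure beyond a single NB dispersion. Recovery here validates the
machinery — coordinate handling, counting conventions, test calibration —
not biological effect sizes.

## Numerical and policy choices

- t-test flavour: pooled variance by default (classic triplicate
  comparison); Welch via `equal_var=False`.
- Spearman p-values: asymptotic t approximation (exact permutation p is
  impractical at 1024 motifs × hundreds of records and differs negligibly
  at n ≥ 30).
- Tie-breaks are always 5′-most (collapse) or deterministic sorts; no
  analysis depends on dict iteration order.
- Control draws, generator output and correlation tables are bit-identical
  under a fixed seed.
- Default problem sizes (200 genes, ~400 PAS, 300 peaks, 5 × 1000 peak
  controls in the bundled examples) keep a full pipeline run in seconds
  while leaving ≥ 300 records for stable rank statistics.

## Known limitations

- The readthrough statistic has no between-sample normalization beyond its
  ratio form; strongly unbalanced libraries should be depth-checked first.
- `no_readthrough` classification keys on raw zero downstream counts and
  is depth-sensitive at very low coverage.
- The overlap-correction weight (0.2) is anchored at a single point
  (r = 2); chains mixing different motifs are corrected per motif
  independently.
- GFF3 input must carry exon `Parent` attributes resolvable to
  transcripts; fusion or trans-spliced models are out of scope.
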