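"""Self-contained synthetic dataset with planted ground truth.

Generates a multi-gene genome (both strands), a GTF annotation, a PAS
catalog with one to three sites per gene, triplicate stranded window counts
in which mutant readthrough is a monotone function of planted T-run content
plus noise, pause-peak summits with T-runs planted on the 3' flank, and
junction/expression tables — everything the pipeline consumes, with the
planted truth serialized alongside so recovery can be scored.

Defaults emulate the analyzed study conditions: ~50% baseline readthrough,
~10% of PAS affected in the mutant, triplicates per group, and read depths
at which a window ratio is stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, derive_features
from .intervals import GenomicInterval, Genome, reverse_complement
from .readthrough import PasSite

T_RUN = "T" * 12          # planted biased window (transcript orientation)
EFFECT_RUN = "T" * 6      # planted motif carrier near affected PAS


@dataclass
class SynthConfig:
    """All knobs of the generator; the seed fixes every draw."""

    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 4
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (200, 1200)
    intergenic: tuple[int, int] = (6500, 9000)
    downstream_len: int = 5000
    # planted 12-base T runs per kilobase, per feature class
    trsm_density: dict = field(default_factory=lambda: {
        "introns": 1.0, "internal_exons": 0.05,
        "terminal_exons": 0.4, "downstream_regions": 0.8})
    pas_per_gene: tuple[int, int] = (1, 3)
    pas_spacing: tuple[int, int] = (400, 1200)
    # baseline WT readthrough ~ lognormal centred near 0.5
    baseline_readthrough: float = 0.5
    baseline_sigma: float = 0.35
    no_readthrough_fraction: float = 0.10
    low_expression_fraction: float = 0.10
    affected_fraction: float = 0.10
    effect_beta: float = -0.6        # per planted corrected TTTTT event
    effect_runs: tuple[int, int] = (2, 5)
    noise_sd: float = 0.10
    replicates: int = 3
    depth: float = 200.0             # mean reads per upstream window
    nb_dispersion: float = 0.02
    # peaks: pause-like summits near gene 3' ends; a fraction falls in
    # internal exons to exercise the exclusion filter
    n_peaks: int = 300
    peak_internal_fraction: float = 0.2
    peak_planted_fraction: float = 0.8
    peak_reads: int = 30
    peak_strand_purity: float = 0.9


@dataclass
class GroundTruth:
    planted_trsm: list = field(default_factory=list)   # (class, chrom, start, end, strand)
    affected_pas: dict = field(default_factory=dict)   # pas_id -> {"effect", "n_runs"}
    pas_baseline: dict = field(default_factory=dict)   # pas_id -> WT readthrough
    pas_category: dict = field(default_factory=dict)   # planted category
    affected_exons: dict = field(default_factory=dict)
    peak_strand: dict = field(default_factory=dict)    # peak_id -> strand
    peak_planted: dict = field(default_factory=dict)   # peak_id -> bool
    effect_beta: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class SynthDataset:
    config: SynthConfig
    genome: Genome
    models: dict[str, GeneModel]
    pas_sites: list[PasSite]
    pas_gene: dict[str, str]
    counts: pd.DataFrame            # pas_id, sample, up, down
    wt_samples: list[str]
    mutant_samples: list[str]
    expression: dict[str, float]    # gene_id -> FPKM
    junctions: pd.DataFrame         # exon_id, gene_id, sample, junctions
    summits: list[tuple[str, int]]
    peak_reads: pd.DataFrame
    truth: GroundTruth


def generate(config: SynthConfig | None = None) -> SynthDataset:
    """Build the full synthetic dataset from one seeded configuration."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    chrom_seqs, models = _make_genes(config, rng)
    truth = GroundTruth(effect_beta=config.effect_beta)

    seq_lengths = {c: len(s) for c, s in chrom_seqs.items()}
    features = derive_features(models, seq_lengths,
                               downstream_len=config.downstream_len)
    _plant_trsm(config, rng, chrom_seqs, features, truth)
    pas_sites, pas_gene = _make_pas(config, rng, models, seq_lengths)
    _plant_effects(config, rng, chrom_seqs, pas_sites, truth)
    counts, wt_s, mut_s, expression = _make_counts(
        config, rng, pas_sites, pas_gene, truth)
    junctions = _make_junctions(config, rng, features, expression,
                                chrom_seqs, truth)
    summits, peak_reads = _make_peaks(config, rng, chrom_seqs, models, truth)

    genome = Genome({c: s.tobytes().decode() for c, s in chrom_seqs.items()})
    return SynthDataset(config, genome, models, pas_sites, pas_gene, counts,
                        wt_s, mut_s, expression, junctions, summits,
                        peak_reads, truth)


def _rand_seq(rng, n) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, n)].copy()


def _make_genes(config, rng):
    chrom_arrays: dict[str, np.ndarray] = {}
    models: dict[str, GeneModel] = {}
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(*config.intergenic))
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            gid = f"G{gi:04d}"
            strand = "+" if rng.integers(2) else "-"
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exons = []
            for e in range(n_exons):
                elen = int(rng.integers(*config.exon_len))
                exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
                pos += elen
                if e < n_exons - 1:
                    pos += int(rng.integers(*config.intron_len))
            # leave room for downstream region + PAS before the next gene
            pos += config.downstream_len + int(rng.integers(*config.intergenic))
            ordered = exons if strand == "+" else exons[::-1]
            models[gid] = GeneModel(gid, chrom, strand,
                                    {f"{gid}.t1": ordered})
            gi += 1
        chrom_arrays[chrom] = _rand_seq(rng, pos + 100)
    return chrom_arrays, models


def _plant(chrom_seqs, chrom, start, seq_tx, strand):
    """Write a transcript-orientation motif into the reference strand."""
    ref = seq_tx if strand != "-" else reverse_complement(seq_tx)
    arr = chrom_seqs[chrom]
    arr[start:start + len(ref)] = np.frombuffer(ref.encode(), dtype="S1")


def _plant_trsm(config, rng, chrom_seqs, features, truth):
    L = len(T_RUN)
    for cls, density in config.trsm_density.items():
        for _gid, iv in features.iter_class(cls):
            if len(iv) < L:
                continue
            n = rng.poisson(density * len(iv) / 1000.0)
            taken: list[tuple[int, int]] = []
            for _ in range(n):
                for _attempt in range(20):
                    s = int(rng.integers(iv.start, iv.end - L + 1))
                    if all(s + L <= a or s >= b for a, b in taken):
                        taken.append((s, s + L))
                        _plant(chrom_seqs, iv.seqname, s, T_RUN, iv.strand)
                        truth.planted_trsm.append(
                            (cls, iv.seqname, s, s + L, iv.strand))
                        break


def _make_pas(config, rng, models, seq_lengths):
    sites, pas_gene = [], {}
    for gid, model in models.items():
        exons = model.transcripts[f"{gid}.t1"]
        last = exons[-1]
        n_pas = int(rng.integers(config.pas_per_gene[0],
                                 config.pas_per_gene[1] + 1))
        if model.strand == "-":
            pos = last.start  # transcript 3' end (leftmost base just off exon)
            step = -1
        else:
            pos = last.end - 1
            step = 1
        for j in range(n_pas):
            if j > 0:
                pos += step * int(rng.integers(*config.pas_spacing))
            if not (0 <= pos < seq_lengths[model.seqname]):
                break
            pid = f"{gid}.pas{j}"
            sites.append(PasSite(pid, GenomicInterval(
                model.seqname, pos, pos + 1, model.strand), gene_id=gid))
            pas_gene[pid] = gid
    return sites, pas_gene


def _plant_effects(config, rng, chrom_seqs, pas_sites, truth):
    n_aff = int(round(config.affected_fraction * len(pas_sites)))
    order = rng.permutation(len(pas_sites))
    affected = [pas_sites[i] for i in order[:n_aff]]
    L = len(EFFECT_RUN)
    for site in affected:
        n_runs = int(rng.integers(config.effect_runs[0],
                                  config.effect_runs[1] + 1))
        iv = site.site
        planted = 0
        taken: list[tuple[int, int]] = []
        for _ in range(n_runs):
            # within 150 bases upstream of the cleavage site
            for _attempt in range(30):
                off = int(rng.integers(10, 150 - L))
                s = (iv.start + off + 1 if iv.strand == "-"
                     else iv.start - off - L)
                if s < 0 or s + L > len(chrom_seqs[iv.seqname]):
                    continue
                if all(s + L <= a or s >= b for a, b in taken):
                    taken.append((s, s + L))
                    _plant(chrom_seqs, iv.seqname, s, EFFECT_RUN, iv.strand)
                    planted += 1
                    break
        content = planted * 1.2  # corrected TTTTT events per planted run
        effect = config.effect_beta * content + rng.normal(0, config.noise_sd)
        truth.affected_pas[site.pas_id] = {
            "effect": float(effect), "n_runs": planted}


def _nb_draw(rng, mean, dispersion, size=None):
    """Negative binomial with var = m + a*m^2; Poisson when a -> 0."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _make_counts(config, rng, pas_sites, pas_gene, truth):
    wt_s = [f"WT{i+1}" for i in range(config.replicates)]
    mut_s = [f"MUT{i+1}" for i in range(config.replicates)]
    # per-gene expression; a planted fraction falls below the FPKM filter
    expression = {}
    genes = sorted(set(pas_gene.values()))
    low = set(rng.choice(genes,
                         int(round(config.low_expression_fraction * len(genes))),
                         replace=False))
    for g in genes:
        expression[g] = (float(rng.uniform(0.05, 0.5)) if g in low
                         else float(rng.lognormal(np.log(8.0), 1.0)))
    rows = []
    for site in pas_sites:
        pid = site.pas_id
        if rng.random() < config.no_readthrough_fraction \
                and pid not in truth.affected_pas:
            wt_rt = 0.0
            truth.pas_category[pid] = "no_readthrough"
        else:
            wt_rt = float(rng.lognormal(np.log(config.baseline_readthrough),
                                        config.baseline_sigma))
            truth.pas_category[pid] = (
                "low_expression" if pas_gene[pid] in low else "analyzable")
        truth.pas_baseline[pid] = wt_rt
        mut_rt = wt_rt
        if pid in truth.affected_pas:
            mut_rt = wt_rt * float(np.exp(truth.affected_pas[pid]["effect"]))
        for sample, rt in [(s, wt_rt) for s in wt_s] + \
                          [(s, mut_rt) for s in mut_s]:
            up = int(_nb_draw(rng, config.depth, config.nb_dispersion))
            down = int(_nb_draw(rng, config.depth * rt, config.nb_dispersion))
            rows.append((pid, sample, up, down))
    counts = pd.DataFrame(rows, columns=["pas_id", "sample", "up", "down"])
    return counts, wt_s, mut_s, expression


def _make_junctions(config, rng, features, expression, chrom_seqs, truth):
    wt_s = [f"WT{i+1}" for i in range(config.replicates)]
    mut_s = [f"MUT{i+1}" for i in range(config.replicates)]
    rows = []
    exon_items = [(gid, i, iv) for gid in sorted(features.internal_exons)
                  for i, iv in enumerate(features.internal_exons[gid])]
    n_aff = int(round(config.affected_fraction * len(exon_items)))
    aff_idx = set(rng.choice(len(exon_items), n_aff, replace=False).tolist()) \
        if exon_items else set()
    for j, (gid, i, iv) in enumerate(exon_items):
        exon_id = f"{gid}.ex{i}"
        fpkm = expression.get(gid, 1.0)
        base_skip = float(rng.lognormal(np.log(0.5), 0.5))
        mut_skip = base_skip
        if j in aff_idx:
            n_runs = int(rng.integers(config.effect_runs[0],
                                      config.effect_runs[1] + 1))
            for r in range(n_runs):
                s = int(rng.integers(iv.start, max(iv.start + 1,
                                                   iv.end - len(EFFECT_RUN))))
                _plant(chrom_seqs, iv.seqname, s, EFFECT_RUN, iv.strand)
            effect = config.effect_beta * n_runs * 1.2 \
                + rng.normal(0, config.noise_sd)
            mut_skip = base_skip * float(np.exp(effect))
            truth.affected_exons[exon_id] = {"effect": float(effect),
                                             "n_runs": n_runs}
        for sample, s in [(x, base_skip) for x in wt_s] + \
                         [(x, mut_skip) for x in mut_s]:
            rows.append((exon_id, gid, sample,
                         int(rng.poisson(s * fpkm))))
    return pd.DataFrame(rows,
                        columns=["exon_id", "gene_id", "sample", "junctions"])


def _make_peaks(config, rng, chrom_seqs, models, truth):
    gene_ids = sorted(models)
    summits, read_rows = [], []
    for p in range(config.n_peaks):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        model = models[gid]
        exons = model.transcripts[f"{gid}.t1"]
        if len(exons) > 1 and rng.random() < config.peak_internal_fraction:
            exon = exons[int(rng.integers(len(exons) - 1))]
        else:
            exon = exons[-1]  # pause sites cluster at the terminal exon
        if len(exon) < 20:
            continue
        summit = int(rng.integers(exon.start + 10, exon.end - 10))
        chrom, strand = model.seqname, model.strand
        pid = f"peak{p:04d}"
        summits.append((chrom, summit))
        truth.peak_strand[pid] = strand
        planted = bool(rng.random() < config.peak_planted_fraction)
        truth.peak_planted[pid] = planted
        if planted:
            # 3' half of the 80-base region, transcript orientation
            off = int(rng.integers(5, 35 - len(EFFECT_RUN)))
            s = summit + off if strand == "+" else summit - off - len(EFFECT_RUN)
            if 0 <= s and s + len(EFFECT_RUN) <= len(chrom_seqs[chrom]):
                _plant(chrom_seqs, chrom, s, EFFECT_RUN, strand)
        for _ in range(config.peak_reads):
            rs = summit + int(rng.integers(-60, 21))
            rs = max(0, rs)
            read_strand = strand if rng.random() < config.peak_strand_purity \
                else ("-" if strand == "+" else "+")
            read_rows.append((chrom, rs, rs + 40, read_strand))
    reads = pd.DataFrame(read_rows,
                         columns=["seqname", "start", "end", "strand"])
    return summits, reads


def simulate_null_counts(n_pas: int, replicates: int = 3,
                         depth: float = 200.0, dispersion: float = 0.05,
                         baseline: float = 0.5, sigma: float = 0.35,
                         seed: int | np.random.Generator = 0) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Window counts for PAS with no group effect (both groups identical).

    Used for type-I-error calibration of the differential test.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    wt_s = [f"WT{i+1}" for i in range(replicates)]
    mut_s = [f"MUT{i+1}" for i in range(replicates)]
    rows = []
    for i in range(n_pas):
        rt = float(rng.lognormal(np.log(baseline), sigma))
        for sample in wt_s + mut_s:
            up = int(_nb_draw(rng, depth, dispersion))
            down = int(_nb_draw(rng, depth * rt, dispersion))
            rows.append((f"pas{i:05d}", sample, up, down))
    return (pd.DataFrame(rows, columns=["pas_id", "sample", "up", "down"]),
            wt_s, mut_s)


def write_dataset(ds: SynthDataset, outdir) -> dict[str, Path]:
    """Serialize the dataset: FASTA, GTF, PAS/summit BED, TSVs, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name in ds.genome.names:
            fh.write(f">{name}\n")
            seq = ds.genome.fetch(name, 0, ds.genome.length(name))
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["fasta"] = fasta

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gid, model in sorted(ds.models.items()):
            for tid, exons in model.transcripts.items():
                span = (min(e.start for e in exons),
                        max(e.end for e in exons))
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(f"{model.seqname}\tsynth\ttranscript\t{span[0]+1}\t"
                         f"{span[1]}\t.\t{model.strand}\t.\t{attrs}\n")
                for iv in sorted(exons, key=lambda e: e.start):
                    fh.write(f"{iv.seqname}\tsynth\texon\t{iv.start+1}\t"
                             f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n")
    paths["gtf"] = gtf

    pas_bed = outdir / "pas.bed"
    with open(pas_bed, "w") as fh:
        for s in ds.pas_sites:
            iv = s.site
            fh.write(f"{iv.seqname}\t{iv.start}\t{iv.end}\t{s.pas_id}\t0\t"
                     f"{iv.strand}\n")
    paths["pas"] = pas_bed

    summit_bed = outdir / "summits.bed"
    with open(summit_bed, "w") as fh:
        for i, (chrom, pos) in enumerate(ds.summits):
            fh.write(f"{chrom}\t{pos}\t{pos+1}\tpeak{i:04d}\t0\n")
    paths["summits"] = summit_bed

    for name, df in [("counts", ds.counts), ("junctions", ds.junctions),
                     ("peak_reads", ds.peak_reads)]:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    expr = outdir / "expression.tsv"
    pd.Series(ds.expression, name="fpkm").rename_axis("gene_id") \
        .to_csv(expr, sep="\t")
    paths["expression"] = expr

    tj = outdir / "truth.json"
    tj.write_text(ds.truth.to_json())
    paths["truth"] = tj
    return paths
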