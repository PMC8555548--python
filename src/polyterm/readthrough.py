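"""PAS readthrough quantification and differential testing.

Readthrough at a polyadenylation site (PAS) is the number of reads in a
fixed window downstream of the cleavage site divided by the number in the
abutting upstream window, both in transcript orientation.  Nearby PAS are
collapsed to the most highly used site, low-expression and no-readthrough
records are filtered, and mutant-versus-control triplicates are compared
with an uncorrected two-tailed t-test (the test is conservative at n = 3 and
readthrough values are strongly interdependent, so no multiplicity
correction is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .coverage import ReadIndex
from .intervals import GenomicInterval

DEFAULT_WINDOW = 275
DEFAULT_MIN_UP = 10
DEFAULT_FPKM_MIN = 1.0


@dataclass
class PasSite:
    """One cleavage site (length-1 interval) from a PAS catalog."""

    pas_id: str
    site: GenomicInterval  # length 1
    gene_id: str | None = None
    score: float | None = None  # catalog usage score, if any


def load_pas_bed(path) -> list[PasSite]:
    """Read a PolyASite-style BED (chrom, start, end, name, score, strand).

    Multi-base records are reduced to their strand-aware 3' base, the
    cleavage position.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}"
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand == "-" else end - 1
            sites.append(PasSite(
                name, GenomicInterval(chrom, pos, pos + 1, strand),
                score=score))
    return sites


def collapse_pas(sites: list[PasSite], usage: dict[str, float],
                 min_spacing: int = DEFAULT_WINDOW) -> list[PasSite]:
    """Keep the most used PAS within each cluster of nearby sites.

    Sites on one seqname and strand whose consecutive gaps are below
    ``min_spacing`` form one (transitive) cluster; only the cluster's
    maximal-usage site survives, ties broken by the 5'-most position.
    Missing usage counts as 0.
    """
    retained: list[PasSite] = []
    keyed: dict[tuple[str, str], list[PasSite]] = {}
    for s in sites:
        keyed.setdefault((s.site.seqname, s.site.strand), []).append(s)
    for (_, strand), group in keyed.items():
        group = sorted(group, key=lambda s: s.site.start)
        cluster: list[PasSite] = []
        prev = None
        for s in group + [None]:
            if s is not None and (prev is None
                                  or s.site.start - prev < min_spacing):
                cluster.append(s)
            else:
                if cluster:
                    retained.append(_best_in_cluster(cluster, usage, strand))
                cluster = [s] if s is not None else []
            if s is not None:
                prev = s.site.start
    return sorted(retained, key=lambda s: (s.site.seqname, s.site.start))


def _best_in_cluster(cluster, usage, strand):
    def sort_key(s):
        # maximal usage first; tie -> 5'-most (left on +, right on -)
        pos = s.site.start if strand != "-" else -s.site.start
        return (-usage.get(s.pas_id, 0.0), pos)
    return min(cluster, key=sort_key)


def pas_windows(site: GenomicInterval, window: int = DEFAULT_WINDOW,
                seq_len: int | None = None):
    """Upstream/downstream windows abutting a PAS, transcript orientation.

    Returns (upstream, downstream, truncated); windows are clipped at
    sequence edges and at position 0.
    """
    pos = site.start
    if site.strand == "-":
        up_lo, up_hi = pos + 1, pos + 1 + window
        dn_lo, dn_hi = pos - window, pos
    else:
        up_lo, up_hi = pos - window, pos
        dn_lo, dn_hi = pos + 1, pos + 1 + window
    truncated = False
    out = []
    for lo, hi in ((up_lo, up_hi), (dn_lo, dn_hi)):
        clo = max(0, lo)
        chi = min(seq_len, hi) if seq_len is not None else hi
        if (clo, chi) != (lo, hi):
            truncated = True
        out.append(GenomicInterval(site.seqname, clo, chi, site.strand)
                   if chi > clo else None)
    return out[0], out[1], truncated


def count_windows(sites: list[PasSite],
                  sample_reads: dict[str, pd.DataFrame],
                  seq_lengths: dict[str, int] | None = None,
                  window: int = DEFAULT_WINDOW,
                  stranded: bool = False) -> pd.DataFrame:
    """Reads overlapping each PAS's flanking windows, per sample.

    Returns a long table (pas_id, sample, up, down, truncated); a read
    counts in a window when it overlaps it by >= 1 base, so a read
    straddling the PAS contributes to both windows.
    """
    indexes = {s: ReadIndex(df) for s, df in sample_reads.items()}
    rows = []
    for site in sites:
        seqlen = (seq_lengths or {}).get(site.site.seqname)
        up, dn, trunc = pas_windows(site.site, window, seqlen)
        for sample, idx in indexes.items():
            strand = site.site.strand if stranded else None
            u = idx.count(up.seqname, up.start, up.end, strand) if up else 0
            d = idx.count(dn.seqname, dn.start, dn.end, strand) if dn else 0
            rows.append((site.pas_id, sample, u, d, trunc))
    return pd.DataFrame(rows,
                        columns=["pas_id", "sample", "up", "down", "truncated"])


def compute_readthrough(up: int, down: int,
                        min_up: int = DEFAULT_MIN_UP) -> float | None:
    """down/up when the upstream count supports a ratio; else None."""
    if up >= max(min_up, 1):
        return down / up
    return None


def readthrough_table(counts: pd.DataFrame,
                      min_up: int = DEFAULT_MIN_UP) -> pd.DataFrame:
    """Wide per-PAS readthrough matrix (rows = pas_id, cols = samples).

    Entries where the upstream count is below ``min_up`` are NaN.
    """
    counts = counts.copy()
    counts["readthrough"] = [
        np.nan if (v := compute_readthrough(u, d, min_up)) is None else v
        for u, d in zip(counts["up"], counts["down"])]
    return counts.pivot(index="pas_id", columns="sample",
                        values="readthrough")


def classify_pas(rt: pd.DataFrame, wt_samples: list[str],
                 expression: dict[str, float],
                 fpkm_min: float = DEFAULT_FPKM_MIN,
                 wt_down: pd.DataFrame | None = None) -> pd.Series:
    """Label each PAS no_readthrough / low_expression / analyzable.

    Precedence is fixed: a PAS with zero downstream signal in every WT
    sample is no_readthrough even when it also fails the expression filter.
    ``wt_down`` (pas_id x sample downstream counts) decides the
    no-readthrough test when given; otherwise WT readthrough values are
    used.
    """
    labels = {}
    for pas_id, row in rt.iterrows():
        if wt_down is not None and pas_id in wt_down.index:
            no_rt = (wt_down.loc[pas_id, wt_samples].fillna(0) == 0).all()
        else:
            wt_vals = row[wt_samples]
            no_rt = (wt_vals.fillna(0) == 0).all()
        if no_rt:
            labels[pas_id] = "no_readthrough"
        elif expression.get(pas_id, 0.0) < fpkm_min:
            labels[pas_id] = "low_expression"
        else:
            labels[pas_id] = "analyzable"
    return pd.Series(labels, name="category")


def differential(values: pd.DataFrame, mutant_samples: list[str],
                 control_samples: list[str], alpha: float = 0.05,
                 equal_var: bool = True) -> pd.DataFrame:
    """Two-tailed t-test of per-record mutant vs control values.

    ``values`` is a record x sample matrix (readthrough or skipping
    scores).  Records with a NaN in any required replicate are dropped.
    Degenerate cases: both groups constant and equal -> p = 1; both
    constant but different -> p = 0, flagged.
    """
    if len(mutant_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = values[mutant_samples + control_samples].dropna()
    mut = sub[mutant_samples].to_numpy(float)
    ctl = sub[control_samples].to_numpy(float)
    mut_mean = mut.mean(axis=1)
    ctl_mean = ctl.mean(axis=1)
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant records are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(mut, ctl, axis=1, equal_var=equal_var)
        fold = mut_mean / ctl_mean
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.zeros(len(sub), dtype=bool)
    zero_var = (mut.std(axis=1) == 0) & (ctl.std(axis=1) == 0)
    same = np.isclose(mut_mean, ctl_mean)
    p[zero_var & same] = 1.0
    p[zero_var & ~same] = 0.0
    degenerate[zero_var & ~same] = True
    out = pd.DataFrame({
        "mutant_mean": mut_mean,
        "control_mean": ctl_mean,
        "fold_change": fold,
        "log2_fold_change": np.log2(fold),
        "p_value": p,
        "significant": p < alpha,
        "degenerate": degenerate,
    }, index=sub.index)
    return out


def skipping_score(junctions: int, fpkm: float) -> float | None:
    """Spanning-junction count normalized by expression; None when FPKM <= 0."""
    if fpkm <= 0:
        return None
    return junctions / fpkm


def skipping_table(junctions: pd.DataFrame,
                   fpkm: dict[str, float]) -> pd.DataFrame:
    """Exon x sample skipping scores from junction counts and gene FPKM.

    ``junctions`` is long (exon_id, gene_id, sample, junctions); exons of
    genes with FPKM <= 0 are excluded.
    """
    rows = []
    for (exon_id, gene_id), grp in junctions.groupby(["exon_id", "gene_id"]):
        f = fpkm.get(gene_id, 0.0)
        if f <= 0:
            continue
        for _, r in grp.iterrows():
            rows.append((exon_id, r["sample"], r["junctions"] / f))
    if not rows:
        return pd.DataFrame()
    return (pd.DataFrame(rows, columns=["exon_id", "sample", "skipping"])
            .pivot(index="exon_id", columns="sample", values="skipping"))


def pca_summary(rt: pd.DataFrame) -> pd.DataFrame:
    """Sample scores on the first two principal components.

    Rows of ``rt`` are samples, columns PAS; columns with any undefined
    entry are dropped, the matrix is centred and log2-transformed
    (log2(x + eps)) before decomposition.
    """
    if rt.shape[0] < 3:
        raise ValueError("need >= 3 samples for a PCA summary")
    mat = rt.dropna(axis=1).to_numpy(float)
    mat = np.log2(mat + 1e-3)
    n_comp = min(2, *mat.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(mat - mat.mean(axis=0))
    out = pd.DataFrame(scores, index=rt.index,
                       columns=[f"PC{i+1}" for i in range(n_comp)])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out
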