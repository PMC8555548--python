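"""Motif-frequency / phenotype correlation with overlap correction.

For every 5-mer, the per-record corrected frequency in an analysis window is
paired with the record's fold change in readthrough (PAS) or skipping
(exons), and a Spearman rank correlation computed over records.  Overlapping
instances of one motif are down-weighted: a chain of r instances in which
each instance overlaps the next contributes 1 + w*(r - 1) events (w = 0.2 by
default, so a run of six identical bases scores 1.2 for its 5-mer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureSet
from .intervals import Genome, GenomicInterval, extract_sequence
from .peaks import all_kmers
from .readthrough import PasSite

DEFAULT_K = 5
DEFAULT_FLANK = 200
DEFAULT_OVERLAP_WEIGHT = 0.2
SUBREGIONS = ("upstream", "body", "downstream", "whole")


def count_overlapping_motif(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) start positions matching *motif*.

    This is the browser-style convention in which a run of five thymidines
    holds two TTTT hits.
    """
    if not motif:
        raise ValueError("empty motif")
    count = 0
    pos = seq.find(motif)
    while pos != -1:
        count += 1
        pos = seq.find(motif, pos + 1)
    return count


def corrected_kmer_counts(seq: str, k: int = DEFAULT_K,
                          overlap_weight: float = DEFAULT_OVERLAP_WEIGHT
                          ) -> dict[str, float]:
    """Overlap-corrected k-mer event counts for one sequence.

    Occurrences of a motif are grouped into maximal chains of consecutive
    mutually overlapping instances (successive start positions < k apart);
    a chain of r instances counts 1 + overlap_weight*(r - 1) events, so a
    run of k + 1 identical bases counts 1 + overlap_weight.  Motifs with
    non-ACGT characters are ignored.  Only motifs that occur are returned.
    """
    if len(seq) < k:
        return {}
    seq = seq.upper()
    events: dict[str, float] = {}
    last_pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        motif = seq[i:i + k]
        if any(c not in "ACGT" for c in motif):
            continue
        prev = last_pos.get(motif)
        if prev is not None and i - prev < k:
            events[motif] += overlap_weight  # extends the current chain
        else:
            events[motif] = events.get(motif, 0.0) + 1.0
        last_pos[motif] = i
    return events


@dataclass
class AnalysisWindow:
    """Genomic window around a PAS or exon, with subregion boundaries."""

    record_id: str
    region: GenomicInterval
    upstream: GenomicInterval | None
    body: GenomicInterval
    downstream: GenomicInterval | None

    def subregion(self, name: str) -> GenomicInterval | None:
        if name == "whole":
            return self.region
        if name not in SUBREGIONS:
            raise KeyError(f"unknown subregion {name!r}")
        return getattr(self, name)


def _flanked(body: GenomicInterval, flank: int, seqlen: int,
             record_id: str) -> AnalysisWindow:
    lo = max(0, body.start - flank)
    hi = min(seqlen, body.end + flank)
    left = GenomicInterval(body.seqname, lo, body.start,
                           body.strand) if lo < body.start else None
    right = GenomicInterval(body.seqname, body.end, hi,
                            body.strand) if hi > body.end else None
    if body.strand == "-":
        upstream, downstream = right, left
    else:
        upstream, downstream = left, right
    region = GenomicInterval(body.seqname, lo, hi, body.strand)
    return AnalysisWindow(record_id, region, upstream, body, downstream)


def build_pas_windows(sites: list[PasSite], features: FeatureSet,
                      seq_lengths: dict[str, int],
                      flank: int = DEFAULT_FLANK,
                      pas_gene: dict[str, str] | None = None
                      ) -> tuple[list[AnalysisWindow], int]:
    """Windows from the closest upstream 3' splice site to past the PAS.

    The body runs from the nearest upstream 3' SS (an intron's 3' end in
    transcript orientation) to the cleavage base; ``flank`` bases are added
    on both sides.  PAS of single-exon genes, which have no upstream splice
    site, are excluded; their count is returned alongside the windows.
    """
    # acceptor positions (intron 3' ends in transcript orientation)
    acceptors: dict[tuple[str, str], list[int]] = {}
    for _gid, iv in features.iter_class("introns"):
        pos = iv.start if iv.strand == "-" else iv.end
        acceptors.setdefault((iv.seqname, iv.strand), []).append(pos)
    for key in acceptors:
        acceptors[key] = sorted(acceptors[key])

    windows, n_excluded = [], 0
    for site in sites:
        iv = site.site
        cands = acceptors.get((iv.seqname, iv.strand), [])
        idx = np.searchsorted(cands, iv.start)
        if iv.strand == "-":
            # upstream = higher coordinates on the minus strand
            if idx == len(cands):
                n_excluded += 1
                continue
            ss = cands[idx]
            body = GenomicInterval(iv.seqname, iv.start, ss, "-")
        else:
            if idx == 0:
                n_excluded += 1
                continue
            ss = cands[idx - 1]
            body = GenomicInterval(iv.seqname, ss, iv.end, "+")
        windows.append(_flanked(body, flank, seq_lengths[iv.seqname],
                                site.pas_id))
    return windows, n_excluded


def build_exon_windows(exons: dict[str, GenomicInterval],
                       seq_lengths: dict[str, int],
                       flank: int = DEFAULT_FLANK) -> list[AnalysisWindow]:
    """Windows using exon boundaries as reference points, with flanks."""
    return [_flanked(iv, flank, seq_lengths[iv.seqname], exon_id)
            for exon_id, iv in exons.items()]


def _spearman_columns(freqs: np.ndarray, y: np.ndarray):
    """Spearman rho and asymptotic two-sided p for each column vs y."""
    n = len(y)
    rx = stats.rankdata(freqs, axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return rho, p


def motif_correlation(windows: list[AnalysisWindow],
                      fold_changes: dict[str, float],
                      genome: Genome,
                      subregion: str = "whole",
                      k: int = DEFAULT_K,
                      overlap_weight: float = DEFAULT_OVERLAP_WEIGHT,
                      alpha: float = 0.05,
                      log_scale: bool = True) -> pd.DataFrame:
    """Spearman correlation of per-record motif frequency with fold change.

    Frequencies are overlap-corrected event counts divided by subregion
    length; fold changes enter as log2 (a monotone map, so the rank
    statistic is unchanged — only the reported effect scale differs).
    Significance is uncorrected at ``alpha``, mirroring the t-test policy.
    Motifs absent from every record have undefined rho and are flagged.
    """
    if subregion not in SUBREGIONS:
        raise KeyError(f"unknown subregion {subregion!r}")
    def _usable(fc):
        return np.isfinite(fc) and (fc > 0 or not log_scale)

    recs = [w for w in windows
            if _usable(fold_changes.get(w.record_id, np.nan))
            and w.subregion(subregion) is not None]
    if len(recs) < 3:
        raise ValueError("need >= 3 records with defined fold change")
    motifs = all_kmers(k)
    col = {m: j for j, m in enumerate(motifs)}
    freqs = np.zeros((len(recs), len(motifs)))
    y = np.empty(len(recs))
    for i, w in enumerate(recs):
        iv = w.subregion(subregion)
        seq = extract_sequence(iv, genome)
        length = len(seq)
        for motif, events in corrected_kmer_counts(
                seq, k, overlap_weight).items():
            freqs[i, col[motif]] = events / length
        fc = fold_changes[w.record_id]
        y[i] = np.log2(fc) if log_scale else fc

    rho, p = _spearman_columns(freqs, y)
    absent = freqs.sum(axis=0) == 0
    rho[absent] = np.nan
    p[absent] = np.nan
    mean_freq = freqs.mean(axis=0)
    total = mean_freq.sum()
    out = pd.DataFrame({
        "motif": motifs,
        "n_records": len(recs),
        "normalized_freq": mean_freq / total if total > 0 else mean_freq,
        "spearman_rho": rho,
        "p_value": p,
        "significant": p < alpha,
        "absent": absent,
    })
    return out


def at_content_profile(pas_groups: dict[str, list[PasSite]],
                       genome: Genome,
                       half_window: int = 75) -> pd.DataFrame:
    """Per-position A/T fraction around the PAS, per group.

    Positions run -half_window .. +half_window in transcript orientation,
    0 being the cleavage base; members truncated by a sequence edge are
    excluded from the affected positions' denominators.
    """
    positions = np.arange(-half_window, half_window + 1)
    data = {"position": positions}
    for name, sites in pas_groups.items():
        at = np.zeros(len(positions))
        n = np.zeros(len(positions))
        for site in sites:
            iv = site.site
            lo = iv.start - half_window
            hi = iv.start + half_window + 1
            clo, chi = max(0, lo), min(genome.length(iv.seqname), hi)
            seq = genome.fetch(iv.seqname, clo, chi)
            seq = "N" * (clo - lo) + seq + "N" * (hi - chi)
            if iv.strand == "-":
                from .intervals import reverse_complement
                seq = reverse_complement(seq)
            for j, base in enumerate(seq):
                if base in "ACGT":
                    n[j] += 1
                    if base in "AT":
                        at[j] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            data[name] = at / n
    return pd.DataFrame(data)


def compare_correlations(rho_exons: pd.Series,
                         rho_pas: pd.Series) -> tuple[float, pd.DataFrame]:
    """Pearson r between per-motif Spearman coefficients of exons and PAS.

    Both inputs are indexed by motif over the same universe; motifs with an
    undefined coefficient on either side are dropped.
    """
    joined = pd.DataFrame({"exons": rho_exons, "pas": rho_pas}).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 motifs with both coefficients defined")
    r, _p = stats.pearsonr(joined["exons"], joined["pas"])
    return float(r), joined
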