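"""Pause-peak summit post-processing and flank motif enrichment.

Peak callers emit unstranded single-base summits; here each summit is
expanded to a fixed-width region, assigned a strand by majority vote of
overlapping reads, filtered against internal exons and sequencing adaptors,
and its sequence composition and 3'-half k-mer content compared with
length-matched random genomic controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import ReadIndex
from .intervals import Genome, GenomicInterval, extract_sequence, reverse_complement

DEFAULT_WIDTH = 80  # twice the average called peak width


@dataclass
class PeakRegion:
    interval: GenomicInterval
    summit: int
    plus_reads: int
    minus_reads: int
    truncated: bool = False

    @property
    def strand(self) -> str:
        return self.interval.strand


def load_summits(path) -> list[tuple[str, int]]:
    """Read a MACS2 summit BED (chrom, 0-based summit, summit+1, ...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1])))
    return out


def expand_and_strand(summits: list[tuple[str, int]], reads: pd.DataFrame,
                      seq_lengths: dict[str, int],
                      width: int = DEFAULT_WIDTH) -> list[PeakRegion]:
    """Expand summits to ``width`` and assign strand by read majority.

    The region is centred on the summit (clipped at sequence edges, with the
    truncation recorded); reads overlapping it by >= 1 base are counted per
    strand and the majority strand assigned — a tie leaves the region
    unassigned.
    """
    index = ReadIndex(reads)
    regions = []
    for seqname, summit in summits:
        seqlen = seq_lengths[seqname]
        start = max(0, summit - width // 2)
        end = min(seqlen, summit + (width + 1) // 2)
        truncated = (end - start) < width
        plus = index.count(seqname, start, end, "+")
        minus = index.count(seqname, start, end, "-")
        strand = "+" if plus > minus else "-" if minus > plus else "."
        regions.append(PeakRegion(
            GenomicInterval(seqname, start, end, strand),
            summit, plus, minus, truncated))
    return regions


def filter_regions(regions: list[PeakRegion],
                   internal_exons: list[GenomicInterval],
                   adaptor_seqs: list[str],
                   genome: Genome) -> tuple[list[PeakRegion], pd.DataFrame]:
    """Drop regions touching internal exons or containing an adaptor.

    A region is removed iff it overlaps any internal (not terminal) exon by
    >= 1 base, or its sequence contains any adaptor as an exact substring on
    either strand.  Returns the retained regions and a log of removals.
    """
    from intervaltree import IntervalTree
    trees: dict[str, IntervalTree] = {}
    for iv in internal_exons:
        trees.setdefault(iv.seqname, IntervalTree()).addi(iv.start, iv.end)
    adaptors = [a.upper() for a in adaptor_seqs]
    adaptors += [reverse_complement(a) for a in adaptors]

    kept, removed = [], []
    for region in regions:
        iv = region.interval
        reason = None
        tree = trees.get(iv.seqname)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            reason = "internal_exon"
        elif adaptors:
            seq = genome.fetch(iv.seqname, iv.start, iv.end)
            if any(a in seq for a in adaptors):
                reason = "adaptor"
        if reason is None:
            kept.append(region)
        else:
            removed.append((iv.seqname, iv.start, iv.end, reason))
    logdf = pd.DataFrame(removed,
                         columns=["seqname", "start", "end", "reason"])
    return kept, logdf


def composition_profile(regions: list[PeakRegion], genome: Genome,
                        flank: int = 0) -> pd.DataFrame:
    """Per-position base frequencies across strand-assigned regions.

    Regions are aligned on the summit in transcript orientation; columns
    cover the region width plus ``flank`` bases each side.  Positions a
    truncated region cannot supply are excluded from that column's
    denominator, so every column's four frequencies sum to 1 where any base
    was counted.
    """
    assigned = [r for r in regions if r.strand in "+-"]
    if not assigned:
        raise ValueError("no strand-assigned regions")
    width = max(len(r.interval) for r in assigned)
    ncol = width + 2 * flank
    counts = np.zeros((4, ncol), dtype=float)
    base_row = {b: i for i, b in enumerate("ACGT")}
    for r in assigned:
        iv = r.interval
        start = iv.start - flank
        end = iv.end + flank
        lo = max(0, start)
        hi = min(genome.length(iv.seqname), end)
        seq = genome.fetch(iv.seqname, lo, hi)
        pad_left, pad_right = lo - start, end - hi
        seq = "N" * pad_left + seq + "N" * pad_right
        if iv.strand == "-":
            seq = reverse_complement(seq)
        for pos, base in enumerate(seq):
            row = base_row.get(base)
            if row is not None:
                counts[row, pos] += 1
    colsum = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / colsum
    df = pd.DataFrame(freqs.T, columns=list("ACGT"))
    df.insert(0, "position", np.arange(ncol) - flank)
    df["n_counted"] = colsum
    return df


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def _kmer_freqs(seqs: list[str], k: int) -> pd.Series:
    """Raw (overlap-counted) k-mer frequencies pooled over sequences."""
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] = counts.get(seq[i:i + k], 0) + 1
            total += 1
    motifs = all_kmers(k)
    vals = np.array([counts.get(m, 0) for m in motifs], dtype=float)
    return pd.Series(vals / total if total else vals, index=motifs)


def three_prime_half(seq: str) -> str:
    return seq[len(seq) // 2:]


def flank_kmer_enrichment(regions: list[PeakRegion], genome: Genome,
                          k: int = 5, n_controls: int = 5,
                          control_size: int = 5000,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """k-mer frequencies on region 3' halves versus random genomic controls.

    Controls are ``n_controls`` independent draws of ``control_size``
    length-matched regions sampled uniformly from the genome (either strand,
    N-containing draws redrawn); the per-motif control mean and SD across
    draws yield a z score for the observed frequency.
    """
    assigned = [r for r in regions if r.strand in "+-"]
    if not assigned:
        raise ValueError("need at least one strand-assigned region")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fragments = [three_prime_half(extract_sequence(r.interval, genome))
                 for r in assigned]
    observed = _kmer_freqs(fragments, k)

    lengths = np.array([len(f) for f in fragments])
    names = genome.names
    sizes = np.array([genome.length(n) for n in names], dtype=float)
    weights = sizes / sizes.sum()
    control_cols = []
    for _ in range(n_controls):
        seqs = []
        frag_lens = rng.choice(lengths, size=control_size, replace=True)
        for flen in frag_lens:
            for _attempt in range(100):
                ci = rng.choice(len(names), p=weights)
                name = names[ci]
                if genome.length(name) < flen:
                    continue
                start = int(rng.integers(0, genome.length(name) - flen + 1))
                seq = genome.fetch(name, start, start + int(flen))
                if "N" in seq:
                    continue
                if rng.integers(2):
                    seq = reverse_complement(seq)
                seqs.append(seq)
                break
            else:
                raise RuntimeError("could not draw an N-free control region")
        control_cols.append(_kmer_freqs(seqs, k))
    controls = pd.concat(control_cols, axis=1)
    out = pd.DataFrame({
        "motif": observed.index,
        "observed_freq": observed.to_numpy(),
        "control_mean": controls.mean(axis=1).to_numpy(),
        "control_sd": controls.std(axis=1, ddof=1).to_numpy(),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        out["z"] = (out.observed_freq - out.control_mean) / out.control_sd
    return out
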