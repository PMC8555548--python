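"""Sliding-window scan for short single-base-biased sequences.

A biased window (TRSM when the base is T) is a fixed-length window containing
at least ``min_count`` copies of one base.  The scan moves left to right and,
on a hit, jumps past the qualifying window so one biased run is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FEATURE_CLASSES, FeatureSet
from .intervals import Genome, extract_sequence

DEFAULT_WINDOW = 12
DEFAULT_MIN_COUNT = 9  # 9/12 = 75% of a single base


@dataclass(frozen=True)
class BiasedWindowHit:
    """One non-overlapping biased window, in sequence-local coordinates."""

    start: int
    end: int
    base: str
    count_in_window: int


def scan_biased_windows(seq: str, base: str,
                        window: int = DEFAULT_WINDOW,
                        min_count: int = DEFAULT_MIN_COUNT,
                        skip_mode: str = "window") -> list[BiasedWindowHit]:
    """Scan *seq* for windows holding >= ``min_count`` copies of *base*.

    When a window qualifies a hit is recorded and scanning resumes after it
    (``skip_mode='window'``) or after the maximal run of *base* extending
    beyond it (``skip_mode='run'``), so overlapping windows of one run are
    never double counted.  Characters other than A/C/G/T never count toward
    any base.
    """
    if window < 1 or not (1 <= min_count <= window):
        raise ValueError("need window >= 1 and 1 <= min_count <= window")
    if skip_mode not in ("window", "run"):
        raise ValueError(f"unknown skip_mode {skip_mode!r}")
    base = base.upper()
    if base not in "ACGT":
        return []  # ambiguity codes never count as the enriched base
    n = len(seq)
    if n < window:
        return []
    match = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
    # prefix sums give O(1) per-window counts
    csum = np.concatenate([[0], np.cumsum(match)])
    hits: list[BiasedWindowHit] = []
    i = 0
    while i <= n - window:
        count = int(csum[i + window] - csum[i])
        if count >= min_count:
            hits.append(BiasedWindowHit(i, i + window, base, count))
            i += window
            if skip_mode == "run":
                while i < n and match[i]:
                    i += 1
        else:
            i += 1
    return hits


def summarize_by_feature(features: FeatureSet, genome: Genome,
                         bases: str = "ACGT",
                         window: int = DEFAULT_WINDOW,
                         min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Per (feature class x base) hit rates: hits/kb and presence fraction.

    Returns a table with columns feature_class, base, n_features, total_kb,
    hits, hits_per_kb, fraction_with_hit; rates are NaN for empty classes.
    """
    rows = []
    for cls in FEATURE_CLASSES:
        seqs = [extract_sequence(iv, genome)
                for _gid, iv in features.iter_class(cls)]
        total_kb = sum(len(s) for s in seqs) / 1000.0
        for base in bases:
            counts = [len(scan_biased_windows(s, base, window, min_count))
                      for s in seqs]
            n = len(counts)
            total = sum(counts)
            rows.append({
                "feature_class": cls,
                "base": base,
                "n_features": n,
                "total_kb": total_kb,
                "hits": total,
                "hits_per_kb": total / total_kb if total_kb > 0 else float("nan"),
                "fraction_with_hit":
                    sum(c > 0 for c in counts) / n if n else float("nan"),
            })
    return pd.DataFrame(rows)


def positional_profile(features: FeatureSet, feature_class: str,
                       genome: Genome, base: str, bins: int,
                       window: int = DEFAULT_WINDOW,
                       min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Hit density along the relative coordinate [0, 1] of a feature class.

    Each hit's midpoint is mapped to its feature-relative position in
    transcript orientation and aggregated into ``bins`` bins; the rate is
    hits per kilobase of sequence falling in each bin.  Features shorter
    than the scan window are excluded (their count is reported).
    """
    if bins < 2:
        raise ValueError("need bins >= 2")
    hit_counts = np.zeros(bins)
    kb_per_bin = 0.0
    n_used = n_short = 0
    for _gid, iv in features.iter_class(feature_class):
        if len(iv) < window:
            n_short += 1
            continue
        n_used += 1
        seq = extract_sequence(iv, genome)
        kb_per_bin += len(seq) / 1000.0 / bins
        for hit in scan_biased_windows(seq, base, window, min_count):
            rel = ((hit.start + hit.end) / 2) / len(seq)
            hit_counts[min(int(rel * bins), bins - 1)] += 1
    df = pd.DataFrame({
        "bin": np.arange(bins),
        "rel_start": np.arange(bins) / bins,
        "hits": hit_counts,
        "hits_per_kb": hit_counts / kb_per_bin if kb_per_bin > 0
                       else np.full(bins, np.nan),
    })
    df.attrs["n_features_used"] = n_used
    df.attrs["n_features_too_short"] = n_short
    return df
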