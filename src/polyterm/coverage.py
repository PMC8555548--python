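"""Stranded read intervals and fast overlap counting.

Reads are held as plain tables (seqname, start, end, strand) — loaded from a
TSV or a SAM/BAM file — and indexed per chromosome/strand with sorted
endpoint arrays, so counting reads that overlap a query window by >= 1 base
is two binary searches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

READ_COLUMNS = ["seqname", "start", "end", "strand"]


def load_reads_table(path) -> pd.DataFrame:
    """Read a stranded-interval TSV with columns seqname,start,end,strand."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reads table missing columns {missing}")
    return df[READ_COLUMNS + [c for c in df.columns if c not in READ_COLUMNS]]


def load_reads_sam(path) -> pd.DataFrame:
    """Load mapped reads from SAM/BAM into the interval table format."""
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append((aln.reference_name, aln.reference_start,
                         aln.reference_end, "-" if aln.is_reverse else "+"))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


class ReadIndex:
    """Overlap-count index over a stranded read table."""

    def __init__(self, reads: pd.DataFrame):
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (seqname, strand), grp in reads.groupby(["seqname", "strand"]):
            self._idx[(seqname, strand)] = (
                np.sort(grp["start"].to_numpy()),
                np.sort(grp["end"].to_numpy()))

    def count(self, seqname: str, start: int, end: int,
              strand: str | None = None) -> int:
        """Number of reads overlapping [start, end) by at least one base."""
        strands = [strand] if strand else ["+", "-", "."]
        total = 0
        for s in strands:
            if (seqname, s) not in self._idx:
                continue
            starts, ends = self._idx[(seqname, s)]
            n = len(starts)
            # overlap <=> read.start < end and read.end > start; the two
            # excluded sets (fully left, fully right) are disjoint
            n_right = n - int(np.searchsorted(starts, end, side="left"))
            n_left = int(np.searchsorted(ends, start, side="right"))
            total += n - n_right - n_left
        return int(total)
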