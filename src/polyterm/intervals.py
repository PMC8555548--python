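"""Stranded genomic intervals and sequence access.

All coordinates are 0-based half-open; ``strand`` is ``+``, ``-`` or ``.``
(unassigned).  Sequences extracted from a minus-strand interval are
reverse-complemented, so every downstream analysis sees transcript-orientation
sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pyfaidx

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded 0-based half-open region on a named sequence."""

    seqname: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seqname}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.seqname == other.seqname
                and self.start < other.end and other.start < self.end)

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.seqname, self.start + offset,
                               self.end + offset, self.strand)


class Genome:
    """Random access to genome sequence, from a FASTA file or a dict.

    Wraps :class:`pyfaidx.Fasta` when given a path; an in-memory
    ``{name: sequence}`` mapping is accepted directly so synthetic genomes
    need not touch disk.
    """

    def __init__(self, source):
        if isinstance(source, (str, os.PathLike)):
            self._fasta = pyfaidx.Fasta(str(source), as_raw=True,
                                        sequence_always_upper=True)
            self._dict = None
        elif isinstance(source, dict):
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}
        else:
            raise TypeError("Genome expects a FASTA path or a dict of strings")

    @property
    def names(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def __contains__(self, name: str) -> bool:
        return name in (self._dict if self._dict is not None else self._fasta)

    def length(self, name: str) -> int:
        if self._dict is not None:
            return len(self._dict[name])
        return len(self._fasta[name])

    def lengths(self) -> dict[str, int]:
        return {n: self.length(n) for n in self.names}

    def fetch(self, name: str, start: int, end: int) -> str:
        """Plus-strand sequence of [start, end); bounds are checked."""
        if name not in self:
            raise KeyError(f"unknown sequence {name!r}")
        if start < 0 or end > self.length(name):
            raise ValueError(
                f"interval {name}:{start}-{end} outside sequence bounds "
                f"(length {self.length(name)})")
        if self._dict is not None:
            return self._dict[name][start:end]
        return str(self._fasta[name][start:end]).upper()


def extract_sequence(interval: GenomicInterval, genome: Genome) -> str:
    """Transcript-orientation sequence of *interval*.

    Minus-strand intervals return the reverse complement so that T-rich
    template features read as T-rich in the returned string.
    """
    seq = genome.fetch(interval.seqname, interval.start, interval.end)
    if interval.strand == "-":
        return reverse_complement(seq)
    return seq
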