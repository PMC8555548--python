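"""Gene-model parsing and feature decomposition.

Genes are decomposed into the four feature classes analyzed throughout the
package: introns, internal exons, terminal exons and fixed-length regions
downstream of the transcript 3' end.  Input is GTF or GFF3 (1-based inclusive
coordinates at the file boundary; 0-based half-open internally).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .intervals import Genome, GenomicInterval

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("introns", "internal_exons", "terminal_exons",
                   "downstream_regions")


@dataclass
class GeneModel:
    """One gene: ordered exon structures of its transcripts.

    Exons within each transcript are stored 5'->3' in transcript
    orientation (i.e. right-to-left genomic order on the minus strand).
    """

    gene_id: str
    seqname: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    expression: float | None = None


@dataclass
class FeatureSet:
    """Per-gene feature intervals for the four analyzed classes."""

    introns: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    internal_exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    terminal_exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    downstream_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    # exons terminal in one transcript but internal in another
    ambiguous_terminal: set[tuple[str, GenomicInterval]] = field(default_factory=set)
    # features dropped because they overlap a different gene's features
    filtered_out: list[tuple[str, str, GenomicInterval]] = field(default_factory=list)

    def by_class(self, name: str) -> dict[str, list[GenomicInterval]]:
        if name not in FEATURE_CLASSES:
            raise KeyError(f"unknown feature class {name!r}")
        return getattr(self, name)

    def iter_class(self, name: str):
        for gene_id, ivs in self.by_class(name).items():
            for iv in ivs:
                yield gene_id, iv

    def n_features(self, name: str) -> int:
        return sum(len(v) for v in self.by_class(name).values())


def load_gene_models(annotation_source) -> dict[str, GeneModel]:
    """Parse a GTF or GFF3 file into one :class:`GeneModel` per gene.

    Malformed records raise ``ValueError`` naming the line number; records
    with an unknown strand symbol are skipped with a warning.  Only ``exon``
    records (plus transcript/mRNA records, to resolve GFF3 parentage) are
    consumed.
    """
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    tx_seq: dict[str, str] = {}

    with open(annotation_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates")
            if end1 < start1 or start1 < 1:
                raise ValueError(
                    f"line {lineno}: invalid coordinates {start1}-{end1}")
            strand = fields[6]
            if strand not in ("+", "-"):
                warnings.warn(f"line {lineno}: unknown strand "
                              f"{strand!r}, record skipped")
                continue
            ftype = fields[2].lower()
            if ftype not in ("exon", "transcript", "mrna"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"line {lineno}: unparseable attributes "
                                 f"({exc})") from None
            attrs = feat.attributes
            if ftype in ("transcript", "mrna"):
                tid = _first(attrs, "transcript_id") or feat.id
                gid = _first(attrs, "gene_id") or _first(attrs, "Parent")
                if tid and gid:
                    tx_gene[tid] = gid
                continue
            tid = _first(attrs, "transcript_id") or _first(attrs, "Parent")
            if tid is None:
                raise ValueError(
                    f"line {lineno}: exon without transcript_id/Parent")
            gid = _first(attrs, "gene_id")
            if gid is not None:
                tx_gene[tid] = gid
            iv = GenomicInterval(fields[0], start1 - 1, end1, strand)
            tx_exons.setdefault(tid, []).append(iv)
            tx_strand[tid] = strand
            tx_seq[tid] = fields[0]

    models: dict[str, GeneModel] = {}
    for tid, exons in tx_exons.items():
        gid = tx_gene.get(tid, tid)
        strand = tx_strand[tid]
        exons = sorted(exons, key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {tid}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}")
        if strand == "-":
            exons = exons[::-1]  # 5'->3' transcript orientation
        model = models.setdefault(
            gid, GeneModel(gid, tx_seq[tid], strand))
        model.transcripts[tid] = exons
    return models


def _first(attrs, key):
    vals = attrs.get(key)
    if vals:
        return vals[0]
    return None


def derive_features(models: dict[str, GeneModel],
                    seq_lengths: dict[str, int],
                    downstream_len: int = 5000,
                    min_downstream: int = 12) -> FeatureSet:
    """Decompose gene models into the four feature classes.

    Per transcript, the last exon in transcript orientation is terminal and
    all others internal; introns are the inter-exon gaps.  Features are
    unioned per gene; an exon terminal in one transcript and internal in
    another is assigned terminal and flagged.  One downstream region per
    gene starts at the gene's 3'-most transcript end and extends
    ``downstream_len`` bases in the direction of transcription (truncated at
    sequence ends; dropped when shorter than ``min_downstream``).  Finally
    any feature overlapping a feature of a *different* gene (either strand)
    is removed from all sets, symmetrically.
    """
    fs = FeatureSet()
    for gid, model in models.items():
        terminal: set[GenomicInterval] = set()
        internal: set[GenomicInterval] = set()
        introns: set[GenomicInterval] = set()
        for exons in model.transcripts.values():
            if not exons:
                continue
            terminal.add(exons[-1])
            internal.update(exons[:-1])
            genomic = sorted(exons, key=lambda iv: iv.start)
            for a, b in zip(genomic, genomic[1:]):
                introns.add(GenomicInterval(
                    a.seqname, a.end, b.start, model.strand))
        for iv in terminal & internal:
            fs.ambiguous_terminal.add((gid, iv))
        internal -= terminal  # terminal status wins
        fs.terminal_exons[gid] = sorted(terminal)
        fs.internal_exons[gid] = sorted(internal)
        fs.introns[gid] = sorted(introns)

        seqlen = seq_lengths[model.seqname]
        ends = [exons[-1] for exons in model.transcripts.values() if exons]
        if ends:
            if model.strand == "-":
                three_prime = min(iv.start for iv in ends)
                ds_start, ds_end = max(0, three_prime - downstream_len), three_prime
            else:
                three_prime = max(iv.end for iv in ends)
                ds_start, ds_end = three_prime, min(seqlen, three_prime + downstream_len)
            if ds_end - ds_start >= min_downstream:
                fs.downstream_regions[gid] = [GenomicInterval(
                    model.seqname, ds_start, ds_end, model.strand)]
            else:
                fs.downstream_regions[gid] = []

    _filter_cross_gene_overlaps(fs)
    return fs


def _filter_cross_gene_overlaps(fs: FeatureSet) -> None:
    trees: dict[str, IntervalTree] = {}
    entries = []
    for cls in FEATURE_CLASSES:
        for gid, iv in fs.iter_class(cls):
            entries.append((gid, cls, iv))
            trees.setdefault(iv.seqname, IntervalTree()).addi(
                iv.start, iv.end, gid)
    doomed = []
    for gid, cls, iv in entries:
        hits = trees[iv.seqname].overlap(iv.start, iv.end)
        if any(h.data != gid for h in hits):
            doomed.append((gid, cls, iv))
    for gid, cls, iv in doomed:
        fs.by_class(cls)[gid].remove(iv)
        fs.filtered_out.append((gid, cls, iv))
    if doomed:
        log.info("overlap filter removed %d features", len(doomed))


def write_feature_beds(fs: FeatureSet, outdir) -> dict[str, Path]:
    """Write one 6-column BED per feature class (name = gene|class|ordinal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cls in FEATURE_CLASSES:
        path = outdir / f"{cls}.bed"
        with open(path, "w") as fh:
            for gid, ivs in sorted(fs.by_class(cls).items()):
                for i, iv in enumerate(ivs):
                    fh.write(f"{iv.seqname}\t{iv.start}\t{iv.end}\t"
                             f"{gid}|{cls}|{i}\t0\t{iv.strand}\n")
        paths[cls] = path
    return paths


def read_feature_bed(path) -> dict[str, list[GenomicInterval]]:
    """Read a feature BED written by :func:`write_feature_beds`."""
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            gid = name.split("|")[0]
            out.setdefault(gid, []).append(
                GenomicInterval(chrom, int(start), int(end), strand.strip()))
    return out
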