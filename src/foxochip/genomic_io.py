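"""Readers and writers for the genomic formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open.  Conversions to the
1-based inclusive conventions of GFF3 and fixed-step wiggle happen only on
read/write, so downstream modules never see mixed conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "Peak",
    "ReadAlignment",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "read_peaks",
    "write_peaks",
    "read_reads",
    "write_reads",
    "validate_chromosomes",
]


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


@dataclass
class GenomeSequence:
    """An in-memory reference genome: uppercase DNA over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name!r} contains non-DNA characters {bad}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the subsequence [start, end) of ``chrom`` (0-based half-open)."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(f"window [{start},{end}) outside {chrom} (length {len(seq)})")
        return seq[start:end]


@dataclass(frozen=True)
class GeneModel:
    """A gene: its TSS (strand-aware), exon structure and coding status.

    ``tss`` is the first transcribed base: the leftmost exon start on the
    plus strand, the rightmost exon end minus one on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        if not exons or any(e <= s for s, e in exons):
            raise ValueError(f"gene {self.gene_id}: empty or inverted exon")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expected = exons[0][0] if self.strand == "+" else exons[-1][1] - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with strand/exons "
                f"(expected {expected})"
            )

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak with its summit (base of maximal enrichment)."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    height: float
    pvalue: float = 1.0
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside [{self.start},{self.end})"
            )
        if self.height < 0:
            raise ValueError(f"peak {self.peak_id}: negative height")


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A uniquely mapped single-end read."""

    chrom: str
    start: int
    end: int
    strand: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read on {self.chrom}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError("read strand must be + or -")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str) -> GenomeSequence:
    seqs = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in seqs:
            raise ParseError(f"duplicate chromosome name {record.id!r} in {path}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise ParseError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk -> 0-based half-open in memory)


def read_annotation(path: str) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file into gene models.

    Exons are attached to their gene via the ``Parent`` (or ``gene_id``)
    attribute; a gene feature without exons gets a single exon spanning it.
    Feature types other than gene/exon/mRNA are ignored.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: invalid interval {start1}-{end1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                biotype = attrs.get("biotype", attrs.get("gene_biotype", "protein_coding"))
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "coding": biotype == "protein_coding",
                }
            elif ftype == "mRNA":
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append((start, end))

    models = []
    for gid, info in genes.items():
        gene_exons = list(exons.get(gid, []))
        # exons may be attached to an mRNA child instead of the gene itself
        for tid, parent in mrna_parent.items():
            if parent == gid:
                gene_exons.extend(exons.get(tid, []))
        if not gene_exons:
            gene_exons = [(info["start"], info["end"])]
        gene_exons = sorted(set(gene_exons))
        tss = gene_exons[0][0] if info["strand"] == "+" else gene_exons[-1][1] - 1
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                tss=tss,
                exons=tuple(gene_exons),
                coding=info["coding"],
            )
        )
    return models


def write_annotation(genes: list[GeneModel], path: str, source: str = "foxochip") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            biotype = "protein_coding" if g.coding else "ncRNA"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={biotype}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


# ---------------------------------------------------------------------------
# narrowPeak / BED peaks (native 0-based half-open)


def read_peaks(path: str, condition: str = "") -> list[Peak]:
    """Parse a narrowPeak (10-column) or BED+summit file.

    narrowPeak column 10 is the summit offset from the interval start; an
    offset of -1 means no summit was called and the interval midpoint
    (rounded down) is used.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                height = float(fields[6])
                pvalue = 10 ** -float(fields[7]) if len(fields) > 7 and fields[7] != "-1" else 1.0
                offset = int(fields[9]) if len(fields) > 9 else -1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(
                Peak(
                    peak_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    height=height,
                    pvalue=min(max(pvalue, 0.0), 1.0) or 1.0,
                    condition=condition,
                )
            )
    return peaks


def write_peaks(peaks: list[Peak], path: str) -> None:
    import math

    with open(path, "w") as fh:
        for p in peaks:
            mlog10p = -math.log10(p.pvalue) if p.pvalue > 0 else 999.0
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                f"{p.height:g}\t{mlog10p:g}\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# Reads: BED6 (native) or SAM text (via pysam)


def read_reads(path: str, sample: str = "") -> list[ReadAlignment]:
    """Parse read alignments from BED6 or SAM text.

    SAM records that are unmapped or secondary/supplementary are skipped
    (the pipeline consumes uniquely mapped primary reads only); the skip
    count is logged.
    """
    if path.endswith(".sam"):
        return _read_sam(path, sample)
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires a strand in column 6")
            if fields[5] not in "+-":
                raise ParseError(f"{path}:{lineno}: invalid strand {fields[5]!r}")
            reads.append(
                ReadAlignment(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    sample=sample,
                )
            )
    return reads


def _read_sam(path: str, sample: str) -> list[ReadAlignment]:
    import pysam

    reads = []
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            reads.append(
                ReadAlignment(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    sample=sample,
                )
            )
    if skipped:
        logger.info("skipped %d unmapped/secondary SAM records in %s", skipped, path)
    return reads


def write_reads(reads: list[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------


def validate_chromosomes(genome: GenomeSequence, *collections) -> None:
    """Raise if any gene/peak/read names a chromosome absent from the genome."""
    known = set(genome.chrom_names)
    offenders = sorted(
        {item.chrom for coll in collections for item in coll if item.chrom not in known}
    )
    if offenders:
        raise ValueError(f"chromosome names not in genome: {offenders}")
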