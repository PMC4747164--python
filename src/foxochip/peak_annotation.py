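"""Peak-to-gene assignment by closest TSS, promoter windows and distance bands.

Distances are measured summit-to-TSS and signed in transcription
orientation: negative means the summit lies upstream of the TSS.  A peak is
"in the promoter window" when it falls within 2.5 kb upstream to 300 bp
downstream of the assigned TSS, the window used throughout the downstream
binding/expression integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .genomic_io import GeneModel, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationConfig",
    "PeakAssignment",
    "GeneBinding",
    "ConditionComparison",
    "band_for_distance",
    "assign_peaks",
    "band_and_count",
    "compare_conditions",
]


@dataclass
class AnnotationConfig:
    upstream_window: int = 2500
    downstream_window: int = 300
    band_width: int = 500
    proximal_cutoff: int = 500

    def __post_init__(self) -> None:
        if min(self.upstream_window, self.downstream_window,
               self.band_width, self.proximal_cutoff) <= 0:
            raise ValueError("all annotation windows must be positive")


@dataclass(frozen=True)
class PeakAssignment:
    peak_id: str
    gene_id: str | None
    signed_distance: int | None  # negative = upstream of TSS
    band: str | None
    in_promoter_window: bool


@dataclass(frozen=True)
class GeneBinding:
    """Per-gene binding summary: closest peak and proximal peak count."""

    gene_id: str
    closest_distance: int
    band: str
    n_proximal: int  # peaks with |distance| <= proximal_cutoff
    n_in_window: int


@dataclass
class ConditionComparison:
    common: list[tuple[str, str]]
    exclusive_a: list[str]
    exclusive_b: list[str]
    summit_shifts: list[int]


def band_for_distance(signed_distance: int, band_width: int = 500) -> str:
    """Label the |distance| band, e.g. -250 -> ``0-0.5 kb``."""
    lo = (abs(signed_distance) // band_width) * band_width
    return f"{lo / 1000:g}-{(lo + band_width) / 1000:g} kb"


def assign_peaks(
    peaks: list[Peak], genes: list[GeneModel], config: AnnotationConfig | None = None
) -> list[PeakAssignment]:
    """Assign each peak summit to the gene with the closest TSS.

    Ties on distance are broken lexicographically by gene id (logged).  A
    peak on a chromosome without genes gets a null assignment and is
    flagged via ``gene_id=None``.
    """
    config = config or AnnotationConfig()
    if not genes:
        raise ValueError("no genes to assign to")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs]), gs)

    out = []
    n_ties = 0
    for p in peaks:
        if p.chrom not in index:
            out.append(PeakAssignment(p.peak_id, None, None, None, False))
            continue
        tss_arr, gs = index[p.chrom]
        dmin = int(np.min(np.abs(tss_arr - p.summit)))
        # all genes whose TSS attains the minimum distance; tie -> min gene_id
        hits = [g for g, t in zip(gs, tss_arr) if abs(int(t) - p.summit) == dmin]
        if len(hits) > 1:
            n_ties += 1
        gene = min(hits, key=lambda g: g.gene_id)
        sign = 1 if gene.strand == "+" else -1
        d = (p.summit - gene.tss) * sign
        in_window = -config.upstream_window <= d <= config.downstream_window
        out.append(
            PeakAssignment(p.peak_id, gene.gene_id, d, band_for_distance(d, config.band_width),
                           in_window)
        )
    if n_ties:
        logger.info("broke %d equidistant-TSS ties lexicographically", n_ties)
    return out


def band_and_count(
    assignments: list[PeakAssignment], config: AnnotationConfig | None = None
) -> dict[str, GeneBinding]:
    """Summarize assignments per gene: closest band and proximal peak count."""
    config = config or AnnotationConfig()
    per_gene: dict[str, list[PeakAssignment]] = {}
    for a in assignments:
        if a.gene_id is not None:
            per_gene.setdefault(a.gene_id, []).append(a)
    out = {}
    for gid, items in per_gene.items():
        closest = min(items, key=lambda a: abs(a.signed_distance))
        out[gid] = GeneBinding(
            gene_id=gid,
            closest_distance=closest.signed_distance,
            band=band_for_distance(closest.signed_distance, config.band_width),
            n_proximal=sum(1 for a in items if abs(a.signed_distance) <= config.proximal_cutoff),
            n_in_window=sum(1 for a in items if a.in_promoter_window),
        )
    return out


def compare_conditions(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    strand_by_peak: dict[str, str] | None = None,
) -> ConditionComparison:
    """Pair peaks across two conditions by interval overlap.

    Peaks are paired when their intervals intersect by at least 1 bp,
    greedily by maximal overlap with each peak used at most once.  Summit
    shifts for common pairs are ``summit_b - summit_a``; when
    ``strand_by_peak`` provides the assigned gene's strand for the peak in
    A, the shift is signed in transcription orientation.
    """
    candidates = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= 1:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    common, shifts = [], []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = peaks_a[i], peaks_b[j]
        shift = b.summit - a.summit
        if strand_by_peak and strand_by_peak.get(a.peak_id) == "-":
            shift = -shift
        common.append((a.peak_id, b.peak_id))
        shifts.append(shift)
    return ConditionComparison(
        common=common,
        exclusive_a=[p.peak_id for i, p in enumerate(peaks_a) if i not in used_a],
        exclusive_b=[p.peak_id for i, p in enumerate(peaks_b) if i not in used_b],
        summit_shifts=shifts,
    )
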