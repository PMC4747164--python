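"""Binding-by-expression integration statistics.

The central quantity is the representation score

    R = (n_DDEG / n_DEG) / (n_bound_expressed / n_expressed)

the enrichment of factor-bound genes among differentially expressed genes
relative to the bound fraction of all expressed genes; overlap significance
is the upper-tail hypergeometric probability.  Distance-stratified fold
changes and per-class summit profiles reproduce the promoter-proximity and
prior-occupancy analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coverage_profiles import SummitMatrix
from .expression import DeResult
from .peak_annotation import AnnotationConfig, PeakAssignment, band_for_distance

__all__ = [
    "OverlapResult",
    "StratifiedFoldChange",
    "representation_score",
    "hypergeom_overlap",
    "overlap_result",
    "stratified_fold_change",
    "profiles_by_class",
    "paired_wilcoxon",
]


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    p_hypergeom: float
    representation: float


@dataclass
class StratifiedFoldChange:
    """band (or peak-count group) -> (n genes, mean fold change, SD)."""

    groups: dict[str, tuple[int, float | None, float | None]]


def representation_score(
    n_ddeg: int, n_deg: int, n_bound_expressed: int, n_expressed: int
) -> float:
    """Fold enrichment of bound genes among the differentially expressed."""
    if n_deg <= 0 or n_expressed <= 0 or n_bound_expressed <= 0:
        raise ValueError("n_deg, n_expressed and n_bound_expressed must be positive")
    return (n_ddeg / n_deg) / (n_bound_expressed / n_expressed)


def hypergeom_overlap(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, n_a, n_b)."""
    if not (0 <= n_a <= universe and 0 <= n_b <= universe):
        raise ValueError("set sizes exceed the universe")
    if overlap > min(n_a, n_b) or overlap < max(0, n_a + n_b - universe):
        raise ValueError("overlap inconsistent with set sizes")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def overlap_result(n_a: int, n_b: int, overlap: int, universe: int) -> OverlapResult:
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        overlap=overlap,
        universe=universe,
        p_hypergeom=hypergeom_overlap(n_a, n_b, overlap, universe),
        representation=(overlap / n_a) / (n_b / universe) if n_a and n_b else math.nan,
    )


def stratified_fold_change(
    assignments: list[PeakAssignment],
    de_results: list[DeResult],
    config: AnnotationConfig | None = None,
    de_class: str = "activated",
    by: str = "band",
) -> StratifiedFoldChange:
    """Mean and SD of linear fold change, stratified by summit-TSS distance
    band (``by='band'``) or by proximal peak count 1 vs >=2
    (``by='peak_count'``)."""
    config = config or AnnotationConfig()
    de_by_gene = {r.gene_id: r for r in de_results}
    per_gene: dict[str, list[PeakAssignment]] = {}
    for a in assignments:
        if a.gene_id is not None and a.in_promoter_window:
            per_gene.setdefault(a.gene_id, []).append(a)

    groups: dict[str, list[float]] = {}
    for gid, items in per_gene.items():
        r = de_by_gene.get(gid)
        if r is None or r.de_class != de_class or not np.isfinite(r.fold_change):
            continue
        if by == "band":
            closest = min(items, key=lambda a: abs(a.signed_distance))
            key = band_for_distance(closest.signed_distance, config.band_width)
        elif by == "peak_count":
            n_prox = sum(1 for a in items if abs(a.signed_distance) <= config.proximal_cutoff)
            if n_prox == 0:
                continue
            key = "single" if n_prox == 1 else "multiple"
        else:
            raise ValueError(f"unknown stratifier {by!r}")
        groups.setdefault(key, []).append(r.fold_change)

    out = {}
    for key, folds in sorted(groups.items()):
        arr = np.asarray(folds)
        out[key] = (arr.size, float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else None)
    return StratifiedFoldChange(groups=out)


def profiles_by_class(
    matrix: SummitMatrix,
    gene_of_peak: dict[str, str],
    class_of_gene: dict[str, str],
) -> dict:
    """Mean summit profile per expression class plus pairwise Mann-Whitney
    tests on the centre-bin values.

    Classes with fewer than two members get an undefined-p flag (None).
    """
    center = matrix.matrix.shape[1] // 2
    by_class: dict[str, list[np.ndarray]] = {}
    for pid, row in zip(matrix.peak_ids, matrix.matrix):
        cls = class_of_gene.get(gene_of_peak.get(pid, ""), None)
        if cls is not None:
            by_class.setdefault(cls, []).append(row)

    profiles = {
        cls: np.vstack(rows).mean(axis=0) for cls, rows in by_class.items()
    }
    pvalues: dict[tuple[str, str], float | None] = {}
    classes = sorted(by_class)
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            xa = np.vstack(by_class[a])[:, center]
            xb = np.vstack(by_class[b])[:, center]
            if xa.size < 2 or xb.size < 2:
                pvalues[(a, b)] = None
                continue
            method = "exact" if max(xa.size, xb.size) <= 20 else "asymptotic"
            pvalues[(a, b)] = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)[1]
            )
    return {"profiles": profiles, "mannwhitney_p": pvalues,
            "n_per_class": {c: len(v) for c, v in by_class.items()}}


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-gene values across
    two conditions; 1.0 when every pair is tied."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(x == y):
        return 1.0
    return float(stats.wilcoxon(x, y, zero_method="wilcox")[1])
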