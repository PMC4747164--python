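"""RPKM quantification and beta-binomial differential expression.

The two-group test treats each replicate's gene count as a binomial draw
from that library's total and allows extra-binomial (beta) variance between
replicates, in the spirit of the SAGE-era weighted proportions test: each
group's proportion estimate is a library-size-weighted mean, its variance
the larger of the empirical between-replicate variance and the binomial
floor, and the two groups are compared with a t statistic under
Satterthwaite degrees of freedom.  With one replicate per group the
between-replicate term vanishes and the statistic reduces exactly to the
unpooled two-proportion z-test.

Genes are called DAF-16-dependently activated when they are up in the
low-IIS mutant relative to wild type AND up relative to the factor-null
double mutant, both at the fold-change and p-value cut-offs; repressed
mirrors this with reciprocal fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CONDITIONS, NULL_CONDITION

__all__ = [
    "CountTable",
    "DeConfig",
    "DeResult",
    "compute_rpkm",
    "baggerley_test",
    "classify_genes",
]


@dataclass
class CountTable:
    """Gene x sample integer counts plus the metadata RPKM needs."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    condition_of: dict[str, str]  # sample -> condition
    exon_length: pd.Series  # per-gene exon-model length, bp
    totals: pd.Series | None = None  # per-sample total mapped reads

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        if self.totals is None:
            self.totals = colsums
        else:
            self.totals = self.totals.reindex(self.counts.columns)
            if self.totals.isna().any() or (self.totals < colsums).any():
                raise ValueError("per-sample totals missing or smaller than column sums")
        self.exon_length = self.exon_length.reindex(self.counts.index)
        if self.exon_length.isna().any() or (self.exon_length < 1).any():
            raise ValueError("every gene needs an exon length >= 1 bp")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass
class DeConfig:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")


@dataclass
class DeResult:
    gene_id: str
    rpkm: dict[str, float]  # condition -> mean RPKM
    fold_change: float  # daf-2 vs WT
    p_primary: float  # daf-2 vs WT
    p_dependence: float  # daf-2 vs daf-16;daf-2
    expressed: bool
    de_class: str  # activated | repressed | unchanged


def compute_rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads."""
    if (table.totals <= 0).any():
        raise ValueError("zero total mapped reads")
    return table.counts * 1e9 / np.outer(table.exon_length.values, table.totals.values)


def baggerley_test(
    counts_a: np.ndarray,
    totals_a: np.ndarray,
    counts_b: np.ndarray,
    totals_b: np.ndarray,
) -> np.ndarray:
    """Two-sided beta-binomial proportions test, vectorized over genes.

    ``counts_*`` are (genes, replicates) arrays; ``totals_*`` the library
    totals per replicate.  Returns one p-value per gene; genes with zero
    counts in every replicate of both groups get p = 1.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    totals_a = np.asarray(totals_a, dtype=float)
    totals_b = np.asarray(totals_b, dtype=float)

    p_a, v_a, k_a = _group_moments(counts_a, totals_a)
    p_b, v_b, k_b = _group_moments(counts_b, totals_b)

    diff = p_a - p_b
    var = v_a + v_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(var)
        if k_a > 1 or k_b > 1:
            denom = np.zeros_like(var)
            if k_a > 1:
                denom += v_a**2 / (k_a - 1)
            if k_b > 1:
                denom += v_b**2 / (k_b - 1)
            df = np.where(denom > 0, var**2 / np.where(denom > 0, denom, 1.0), np.inf)
            df = np.maximum(df, 1.0)
            pvals = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(t))
    # zero variance: identical proportions -> 1, otherwise an extreme call
    pvals = np.where(var == 0, np.where(diff == 0, 1.0, 0.0), pvals)
    return np.minimum(np.nan_to_num(pvals, nan=1.0), 1.0)


def _group_moments(x: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted proportion, its variance, and replicate count for one group.

    With replicates the variance of the library-size-weighted mean is
    estimated from the replicate spread itself, which already contains the
    within-replicate binomial part on top of any between-replicate (beta)
    variance; with a single library only the binomial part is estimable.
    """
    k = x.shape[1]
    w = n / n.sum()
    p_i = x / n
    p_hat = p_i @ w
    if k == 1:
        v_binom = p_hat * (1 - p_hat) * np.sum(w**2 / n)
        return p_hat, v_binom, k
    wsq = np.sum(w**2)
    spread = ((p_i - p_hat[:, None]) ** 2) @ w
    v_emp = wsq * spread / (1.0 - wsq)
    return p_hat, v_emp, k


def classify_genes(table: CountTable, config: DeConfig | None = None) -> list[DeResult]:
    """Classify genes as activated / repressed / unchanged in a
    factor-dependent manner.

    Activated requires fold >= threshold and p <= threshold in BOTH the
    primary contrast (daf-2 vs WT) and the dependence contrast (daf-2 vs
    daf-16;daf-2); repressed mirrors with reciprocal folds.  A gene is
    "expressed" when its mean RPKM is positive in both the daf-2 and the
    daf-16;daf-2 condition.
    """
    config = config or DeConfig()
    missing = [c for c in CONDITIONS if not table.samples_for(c)]
    if missing:
        raise ValueError(f"conditions missing from the table: {missing}")

    rpkm = compute_rpkm(table)
    mean_rpkm = {
        cond: rpkm[table.samples_for(cond)].mean(axis=1) for cond in CONDITIONS
    }

    def _contrast(cond_a: str, cond_b: str) -> tuple[np.ndarray, np.ndarray]:
        sa, sb = table.samples_for(cond_a), table.samples_for(cond_b)
        p = baggerley_test(
            table.counts[sa].values, table.totals[sa].values,
            table.counts[sb].values, table.totals[sb].values,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mean_rpkm[cond_a].values / mean_rpkm[cond_b].values
        return fc, p

    fc_primary, p_primary = _contrast("daf-2", "WT")
    fc_dep, p_dependence = _contrast("daf-2", NULL_CONDITION)
    if config.bh_correction:
        p_primary = _bh(p_primary)
        p_dependence = _bh(p_dependence)

    fct, pt = config.fc_threshold, config.p_threshold
    expressed = (mean_rpkm["daf-2"].values > 0) & (mean_rpkm[NULL_CONDITION].values > 0)

    results = []
    for i, gid in enumerate(table.counts.index):
        up = fc_primary[i] >= fct and p_primary[i] <= pt and fc_dep[i] >= fct \
            and p_dependence[i] <= pt
        down = fc_primary[i] <= 1 / fct and p_primary[i] <= pt and fc_dep[i] <= 1 / fct \
            and p_dependence[i] <= pt
        results.append(
            DeResult(
                gene_id=gid,
                rpkm={c: float(mean_rpkm[c].iloc[i]) for c in CONDITIONS},
                fold_change=float(fc_primary[i]),
                p_primary=float(p_primary[i]),
                p_dependence=float(p_dependence[i]),
                expressed=bool(expressed[i]),
                de_class="activated" if up else ("repressed" if down else "unchanged"),
            )
        )
    return results


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def results_frame(results: list[DeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id, "fold_change": r.fold_change,
               "p_primary": r.p_primary, "p_dependence": r.p_dependence,
               "expressed": r.expressed, "de_class": r.de_class}
        row.update({f"rpkm_{c}": v for c, v in r.rpkm.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
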