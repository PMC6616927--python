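"""Weighted-index trade-off analysis between nutritional and organoleptic quality.

The seven NQ and seven OQ indicators are aggregated into two synthetic
indexes by expert importance weights (absolute weights summing to 1 within
each index); the indexes are re-standardized over the population so that the
trade-off targets (NQ, OQ) = (2, 2) and (-2, -2) read as "two standard
deviations better/worse than the population mean" on both axes.  The package
then reports the Pearson correlation between the two indexes, selects the k
animals nearest each target in the (NQ, OQ) plane, and contrasts the best and
worst sets trait-by-trait with two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightScheme",
    "default_weights",
    "quality_index",
    "pearson_corr_test",
    "select_profiles",
    "compare_traits",
    "TradeoffResult",
    "run_tradeoff",
]


@dataclass
class WeightScheme:
    """Expert importance weights on the standardized NQ and OQ indicators."""

    nq: dict[str, float]
    oq: dict[str, float]

    def validate(self, tol: float = 1e-9) -> None:
        for label, w in (("NQ", self.nq), ("OQ", self.oq)):
            total = sum(abs(v) for v in w.values())
            if abs(total - 1.0) > tol:
                raise ValueError(f"{label} weights have sum(|w|) = {total}, expected 1")

    def weights(self, which: str) -> dict[str, float]:
        if which == "NQ":
            return self.nq
        if which == "OQ":
            return self.oq
        raise ValueError("which must be 'NQ' or 'OQ'")


def default_weights() -> WeightScheme:
    """The expert weight set used throughout the trade-off analysis."""
    return WeightScheme(
        nq={
            "lipid content": -0.15,
            "long FA": 0.05,
            "C16:0/C18:0": -0.15,
            "n-6/n-3": -0.25,
            "PUFA/MUFA": 0.25,
            "CLA": 0.10,
            "trans FA": -0.05,
        },
        oq={
            "tenderness": 0.425,
            "juiciness": 0.150,
            "flavor intensity": 0.175,
            "bitter": -0.025,
            "rancid fish": -0.125,
            "fatty vs metal": -0.050,
            "blood acid": -0.050,
        },
    )


def quality_index(
    values: pd.DataFrame,
    weights: WeightScheme,
    which: str,
    restandardize: bool = True,
) -> pd.Series:
    """Weighted linear aggregation of standardized indicators into one index."""
    w = weights.weights(which)
    missing = [k for k in w if k not in values.columns]
    if missing:
        raise ValueError(f"missing indicator(s) for {which} index: {missing}")
    idx = sum(coef * values[name] for name, coef in w.items())
    idx.name = which
    if restandardize:
        sd = idx.std(ddof=1)
        if sd > 0:
            idx = (idx - idx.mean()) / sd
    return idx


def pearson_corr_test(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_profiles(
    nq: pd.Series, oq: pd.Series, target: tuple[float, float], k: int = 30
) -> list:
    """The k animals nearest the target in the (NQ, OQ) plane (ties by id)."""
    if k > len(nq):
        raise ValueError(f"k={k} exceeds population size {len(nq)}")
    d = np.hypot(nq.to_numpy() - target[0], oq.to_numpy() - target[1])
    order = np.lexsort((np.asarray(nq.index), d))
    return [nq.index[i] for i in order[:k]]


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return "ns"


def compare_traits(best: pd.DataFrame, worst: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of every indicator.

    Uses the exact null distribution when both groups have at most 12
    observations and the combined sample is tie-free; the tie-corrected
    normal approximation otherwise.
    """
    if best.empty or worst.empty:
        raise ValueError("both groups must be nonempty")
    rows = []
    for col in best.columns:
        b = best[col].to_numpy(float)
        w = worst[col].to_numpy(float)
        combined = np.concatenate([b, w])
        if np.all(combined == combined[0]):
            warnings.warn(f"constant combined sample for {col!r}: p set to 1")
            stat, p = float(len(b) * len(w) / 2), 1.0
        else:
            no_ties = len(np.unique(combined)) == len(combined)
            method = "exact" if (len(b) <= 12 and len(w) <= 12 and no_ties) else "asymptotic"
            res = stats.mannwhitneyu(b, w, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "indicator": col,
                "median_best": float(np.median(b)),
                "median_worst": float(np.median(w)),
                "W": stat,
                "p": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TradeoffResult:
    indexes: pd.DataFrame  # animal, NQ, OQ, is_best, is_worst
    r: float
    p: float
    best_ids: list
    worst_ids: list
    comparison: pd.DataFrame
    targets: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 2.0), (-2.0, -2.0))
    k: int = 30
    extras: dict = field(default_factory=dict)


def run_tradeoff(
    values: pd.DataFrame,
    weights: WeightScheme | None = None,
    k: int = 30,
    targets: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 2.0), (-2.0, -2.0)),
    restandardize: bool = True,
) -> TradeoffResult:
    """Indexes, correlation, best/worst selection and trait comparison in one call."""
    weights = weights or default_weights()
    weights.validate()
    nq = quality_index(values, weights, "NQ", restandardize=restandardize)
    oq = quality_index(values, weights, "OQ", restandardize=restandardize)
    r, p = pearson_corr_test(nq, oq)
    best = select_profiles(nq, oq, targets[0], k=k)
    worst_pool_nq = nq.drop(index=best)
    worst_pool_oq = oq.drop(index=best)
    worst = select_profiles(worst_pool_nq, worst_pool_oq, targets[1], k=k)
    idx = pd.DataFrame({"NQ": nq, "OQ": oq})
    idx["is_best"] = idx.index.isin(best)
    idx["is_worst"] = idx.index.isin(worst)
    comparison = compare_traits(values.loc[best], values.loc[worst])
    return TradeoffResult(
        indexes=idx, r=r, p=p, best_ids=best, worst_ids=worst,
        comparison=comparison, targets=targets, k=k,
    )
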