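"""Model-driven generation of virtual animals.

With only ~30 real animals, the fitted models are exercised on a virtual
population instead: one parameter-of-interest group is chosen as *anchor*,
its indicator values are drawn from the grid {-2.0, -1.9, ..., 2.0} (each
standardized anchor coordinate may range over 0 +/- 2 sigma with step 0.1),
and implausible anchor combinations are rejected with a pairwise realism
filter — for every ordered pair (u, v) of anchor indicators a simple linear
regression v ~ u is fit on the real standardized data, and a candidate is
accepted only if each coordinate lies inside the 95% prediction interval of
its regression on every other coordinate.

All non-anchor indicators start at 0 (the standardized mean) and are then
updated in ``rounds`` successive passes: in each pass every non-anchor
indicator is re-predicted by its model from the current state, visiting the
indicators in a freshly drawn random order per round (one order per round,
shared by the whole population so the update is a well-defined population
map).  The maximum absolute change in the final round is recorded as a
convergence diagnostic; for linear models the procedure is a fixed-point
iteration whose limit solves the induced linear system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pretreat import IndicatorTable

GRID = np.round(np.arange(-20, 21) / 10.0, 1)  # -2.0 .. 2.0 step 0.1

__all__ = ["GRID", "RealismModel", "VirtualPopulation", "fit_pairwise_bounds",
           "sample_anchor", "sample_anchors", "generate_population"]


@dataclass
class _PairFit:
    slope: float
    intercept: float
    resid_sd: float
    x_mean: float
    sxx: float
    n: int


@dataclass
class RealismModel:
    """Pairwise-regression realism filter over the anchor indicators."""

    variables: list[str]
    pairs: dict[tuple[str, str], _PairFit]  # (u, v): regression of v on u
    level: float = 0.95
    interval: str = "prediction"  # or "mean"

    def half_width(self, pair: _PairFit, u0: float) -> float:
        alpha = 1.0 - self.level
        t = stats.t.ppf(1.0 - alpha / 2.0, pair.n - 2)
        lever = 1.0 / pair.n + (u0 - pair.x_mean) ** 2 / pair.sxx
        extra = 1.0 if self.interval == "prediction" else 0.0
        return float(t * pair.resid_sd * np.sqrt(extra + lever))

    def accepts(self, candidate: dict[str, float] | pd.Series) -> bool:
        for (u, v), pair in self.pairs.items():
            u0, v0 = float(candidate[u]), float(candidate[v])
            mid = pair.intercept + pair.slope * u0
            if abs(v0 - mid) > self.half_width(pair, u0):
                return False
        return True


def fit_pairwise_bounds(
    anchors: pd.DataFrame, level: float = 0.95, interval: str = "prediction"
) -> RealismModel:
    """OLS of every ordered pair of anchor indicators on the real animals.

    On standardized data the intercept is ~0 and the slope is the Pearson
    correlation.  With a single anchor indicator the model is empty and the
    filter vacuously accepts.
    """
    if anchors.shape[0] < 3:
        raise ValueError("need at least 3 animals to fit pairwise bounds")
    if interval not in ("prediction", "mean"):
        raise ValueError("interval must be 'prediction' or 'mean'")
    cols = list(anchors.columns)
    pairs: dict[tuple[str, str], _PairFit] = {}
    n = anchors.shape[0]
    for u in cols:
        for v in cols:
            if u == v:
                continue
            x = anchors[u].to_numpy(float)
            y = anchors[v].to_numpy(float)
            xm = float(x.mean())
            sxx = float(np.sum((x - xm) ** 2))
            slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
            intercept = float(y.mean() - slope * xm)
            resid = y - (intercept + slope * x)
            resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
            pairs[(u, v)] = _PairFit(slope, intercept, resid_sd, xm, sxx, n)
    return RealismModel(cols, pairs, level=level, interval=interval)


def _candidate_mask(realism: RealismModel, cand: pd.DataFrame) -> np.ndarray:
    ok = np.ones(len(cand), dtype=bool)
    alpha = 1.0 - realism.level
    extra = 1.0 if realism.interval == "prediction" else 0.0
    for (u, v), pair in realism.pairs.items():
        t = stats.t.ppf(1.0 - alpha / 2.0, pair.n - 2)
        u0 = cand[u].to_numpy()
        v0 = cand[v].to_numpy()
        hw = t * pair.resid_sd * np.sqrt(extra + 1.0 / pair.n + (u0 - pair.x_mean) ** 2 / pair.sxx)
        ok &= np.abs(v0 - (pair.intercept + pair.slope * u0)) <= hw
    return ok


def sample_anchors(
    realism: RealismModel,
    names: list[str],
    n: int,
    rng: np.random.Generator,
    max_draws: int = 100_000,
) -> pd.DataFrame:
    """Rejection-sample n anchor vectors from the 41-point grid per coordinate."""
    out: list[pd.DataFrame] = []
    got = 0
    drawn = 0
    chunk = max(256, 2 * n)
    while got < n:
        if drawn >= max_draws * n:
            raise RuntimeError(
                "anchor rejection sampling exhausted its retry cap; "
                "consider a wider interval level"
            )
        m = min(chunk, max_draws * n - drawn)
        cand = pd.DataFrame(
            GRID[rng.integers(0, len(GRID), size=(m, len(names)))], columns=names
        )
        drawn += m
        mask = _candidate_mask(realism, cand) if realism.pairs else np.ones(m, bool)
        keep = cand[mask]
        out.append(keep)
        got += len(keep)
    return pd.concat(out, ignore_index=True).iloc[:n].reset_index(drop=True)


def sample_anchor(
    realism: RealismModel, seed: int | np.random.Generator = 0, names: list[str] | None = None
) -> pd.Series:
    """A single realism-filtered anchor vector (see :func:`sample_anchors`)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = names if names is not None else realism.variables
    return sample_anchors(realism, names, 1, rng).iloc[0]


@dataclass
class VirtualPopulation:
    values: pd.DataFrame  # n x 24 standardized indicator matrix
    anchor_group: str
    anchor_names: list[str]
    rounds: int
    max_last_change: np.ndarray  # per-animal max |change| in the final round
    round_orders: list[list[str]]
    seed: int

    @property
    def n(self) -> int:
        return len(self.values)


def generate_population(
    models: dict[str, object],
    data: IndicatorTable,
    anchor_group: str = "CP",
    n: int = 500,
    rounds: int = 10,
    seed: int = 0,
    level: float = 0.95,
    interval: str = "prediction",
    realism: RealismModel | None = None,
) -> VirtualPopulation:
    """Generate ``n`` virtual animals from the fitted models.

    ``models`` must contain one object per non-anchor indicator exposing
    ``predictors`` (names) and ``predict(ndarray)``.  The realism filter is
    fitted on the real standardized anchor indicators unless supplied.
    """
    anchor_names = data.group_indicators(anchor_group)
    if not anchor_names:
        raise ValueError(f"no indicators in anchor group {anchor_group!r}")
    non_anchor = [c for c in data.indicator_names if c not in anchor_names]
    missing = [c for c in non_anchor if c not in models]
    if missing:
        raise ValueError(f"missing models for non-anchor indicators: {missing}")

    rng = np.random.default_rng(seed)
    if realism is None:
        realism = fit_pairwise_bounds(data.values[anchor_names], level=level, interval=interval)
    anchors = sample_anchors(realism, anchor_names, n, rng)

    values = pd.DataFrame(
        0.0, index=pd.RangeIndex(n, name="animal"), columns=data.indicator_names
    )
    values[anchor_names] = anchors.to_numpy()

    round_orders: list[list[str]] = []
    max_change = np.zeros(n)
    for r in range(rounds):
        order = [non_anchor[i] for i in rng.permutation(len(non_anchor))]
        round_orders.append(order)
        if r == rounds - 1:
            max_change[:] = 0.0
        for name in order:
            m = models[name]
            pred = np.asarray(m.predict(values[list(m.predictors)].to_numpy()), float)
            if r == rounds - 1:
                max_change = np.maximum(max_change, np.abs(pred - values[name].to_numpy()))
            values[name] = pred

    bad = ~np.isfinite(values.to_numpy()).all(axis=1)
    if bad.any():
        import warnings

        warnings.warn(f"{int(bad.sum())} animal(s) produced non-finite values; resampled")
        if seed > 2**30:
            raise RuntimeError("resampling failed to produce finite animals")
        repl = generate_population(
            models, data, anchor_group, n=int(bad.sum()), rounds=rounds,
            seed=seed + 1, level=level, interval=interval, realism=realism,
        )
        values.loc[bad, :] = repl.values.to_numpy()
        max_change[bad] = repl.max_last_change

    return VirtualPopulation(
        values=values,
        anchor_group=anchor_group,
        anchor_names=anchor_names,
        rounds=rounds,
        max_last_change=max_change,
        round_orders=round_orders,
        seed=seed,
    )
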