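"""Champion-model selection per indicator.

Every one of the 24 indicators is modeled from the indicators of the *other
three* parameter-of-interest groups (21 candidate predictors for AP responses,
17 otherwise).  Five regression families compete — ordinary linear regression
(lm), ridge, random forest (rf), partial least squares (plsr) and sliced
inverse regression (sir) — over repeated random 2/3-1/3 train/test splits
(identical splits across families); the champion is the family with the
lowest *median* test mean-squared error.  Predictors are then screened by
permutation importance against a standard-normal random probe, the champion
family is refit on all animals with the retained predictors, and model
quality is reported as the apparent adjusted R-squared together with a
bootstrap optimism-corrected adjusted R-squared (Harrell's correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold

from .pretreat import IndicatorTable

FAMILIES = ("lm", "ridge", "rf", "plsr", "sir")
PROBE = "__probe__"

__all__ = [
    "FAMILIES",
    "ModelTask",
    "FamilyScores",
    "FittedModel",
    "ModelQuality",
    "make_tasks",
    "compare_families",
    "importance",
    "select_predictors",
    "fit_model",
    "apparent_adj_r2",
    "corrected_adj_r2",
    "select_and_fit_all",
]


@dataclass
class ModelTask:
    response: str
    candidates: list[str]


def make_tasks(data: IndicatorTable) -> list[ModelTask]:
    """One task per indicator; candidates span exactly the other three groups."""
    tasks = []
    for name in data.indicator_names:
        g = data.group_map[name]
        cands = [c for c in data.indicator_names if data.group_map[c] != g]
        tasks.append(ModelTask(name, cands))
    return tasks


class _OLS:
    """Least-squares linear fit via pseudoinverse (tolerates singular designs)."""

    def __init__(self):
        self.coef_ = None
        self.intercept_ = 0.0

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        A = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            warnings.warn("singular design: fitting by least-squares pseudoinverse")
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_


class _SIR:
    """Sliced inverse regression: first EDR direction + univariate linear link.

    The response is cut into ``n_slices`` quantile slices; the leading
    generalized eigenvector of the between-slice covariance of X against
    cov(X) gives the direction, and a simple linear fit on the projection
    provides the predictor.
    """

    def __init__(self, n_slices: int = 5):
        self.n_slices = n_slices
        self.direction_ = None

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        Sigma = Xc.T @ Xc / n + 1e-8 * np.eye(p)
        order = np.argsort(y, kind="stable")
        slices = np.array_split(order, min(self.n_slices, n))
        M = np.zeros((p, p))
        for idx in slices:
            if len(idx) == 0:
                continue
            m = Xc[idx].mean(axis=0)
            M += (len(idx) / n) * np.outer(m, m)
        vals, vecs = linalg.eigh(M, Sigma)
        beta = vecs[:, -1]
        self.direction_ = beta / np.linalg.norm(beta)
        t = Xc @ self.direction_
        self._link = _OLS().fit(t[:, None], y)
        return self

    def predict(self, X):
        t = (np.asarray(X, float) - self.mean_) @ self.direction_
        return self._link.predict(t[:, None])


class _PLS:
    """PLS regression with the component count chosen by inner 5-fold CV.

    Per fold a single max-component model is fit; the coefficient vectors of
    every truncated component count come from the leading columns of the
    rotation/loading matrices, so the CV costs one PLS fit per fold.
    """

    def __init__(self, max_components: int = 10, seed: int = 0):
        self.max_components = max_components
        self.seed = seed

    @staticmethod
    def _fold_errors(Xtr, ytr, Xte, yte, cmax):
        m = PLSRegression(n_components=cmax, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xtr, ytr)
        errs = np.empty(cmax)
        for c in range(1, cmax + 1):
            B = m.x_rotations_[:, :c] @ m.y_loadings_[:, :c].T
            pred = (Xte - m._x_mean) @ B.ravel() + m.intercept_
            errs[c - 1] = np.mean((pred - yte) ** 2)
        return errs

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        cmax = max(1, min(self.max_components, p, n - 2))
        if cmax == 1:
            best = 1
        else:
            kf = KFold(n_splits=min(5, n), shuffle=True, random_state=self.seed)
            errs = np.zeros(cmax)
            for tr, te in kf.split(X):
                cc = max(1, min(cmax, len(tr) - 1, p))
                errs[:cc] += self._fold_errors(X[tr], y[tr], X[te], y[te], cc)
                if cc < cmax:
                    errs[cc:] += errs[cc - 1]
            best = int(np.argmin(errs)) + 1
        self._m = PLSRegression(n_components=best, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._m.fit(X, y)
        self.n_components_ = best
        return self

    def predict(self, X):
        return self._m.predict(np.asarray(X, float)).ravel()


def _fit_family(family: str, X, y, seed: int, rf_trees: int = 500):
    if family == "lm":
        return _OLS().fit(X, y)
    if family == "ridge":
        # penalty by efficient leave-one-out CV over a log-spaced grid
        m = RidgeCV(alphas=np.logspace(-3, 3, 25))
        return m.fit(X, y)
    if family == "rf":
        m = RandomForestRegressor(n_estimators=rf_trees, random_state=seed, n_jobs=1)
        return m.fit(X, y)
    if family == "plsr":
        return _PLS(seed=seed).fit(X, y)
    if family == "sir":
        return _SIR().fit(X, y)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class FamilyScores:
    mse: pd.DataFrame  # splits x families (NaN where a fit failed)
    champion: str
    splits: list[tuple[np.ndarray, np.ndarray]]


def _make_splits(n: int, n_splits: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(n / 3)))
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return splits


def compare_families(
    task: ModelTask,
    data: IndicatorTable,
    n_splits: int = 50,
    seed: int = 0,
    rf_trees: int = 500,
    families: tuple[str, ...] = FAMILIES,
) -> FamilyScores:
    """Race the regression families over shared 2/3-1/3 train/test splits.

    Champion = lowest median test MSE; a family failing on more than 20% of
    the splits is disqualified.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    # canonical candidate order -> champion invariant to how candidates are listed
    cand = [c for c in data.indicator_names if c in set(task.candidates)]
    X = data.values[cand].to_numpy()
    y = data.values[task.response].to_numpy()
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 animals")
    splits = _make_splits(n, n_splits, seed)
    mse = pd.DataFrame(np.nan, index=range(n_splits), columns=list(families))
    for s, (tr, te) in enumerate(splits):
        for fam in families:
            try:
                m = _fit_family(fam, X[tr], y[tr], seed=seed + s, rf_trees=rf_trees)
                pred = m.predict(X[te])
                mse.loc[s, fam] = float(np.mean((pred - y[te]) ** 2))
            except Exception as exc:  # noqa: BLE001 - a failed fit is data, not a bug
                warnings.warn(f"{fam} failed on split {s}: {exc}")
    medians = mse.median()
    ok = mse.notna().mean() >= 0.8
    if not ok.any():
        raise RuntimeError("every family was disqualified")
    best = float(medians[ok].min())
    # numerically indistinguishable medians tie-break to the earlier (simpler) family
    champion = next(
        f for f in medians.index if ok[f] and medians[f] <= best * (1 + 1e-9) + 1e-12
    )
    return FamilyScores(mse=mse, champion=str(champion), splits=splits)


def importance(
    task: ModelTask,
    data: IndicatorTable,
    family: str,
    n_splits: int = 50,
    seed: int = 0,
    rf_trees: int = 500,
    add_probe: bool = True,
) -> pd.Series:
    """Permutation importance of each candidate (plus a random probe column).

    For each train/test split the family is refit and each candidate's test
    column is permuted once (one seeded permutation per split, shared across
    columns); importance = mean increase in test MSE.  The probe is a
    standard-normal column processed identically, providing the selection
    threshold.
    """
    rng = np.random.default_rng(seed)
    cols = [c for c in data.indicator_names if c in set(task.candidates)]
    Xdf = data.values[cols].copy()
    if add_probe:
        Xdf[PROBE] = rng.standard_normal(len(Xdf))
        cols = cols + [PROBE]
    X = Xdf.to_numpy()
    y = data.values[task.response].to_numpy()
    splits = _make_splits(len(y), n_splits, seed)
    deltas = np.zeros((len(splits), len(cols)))
    for s, (tr, te) in enumerate(splits):
        m = _fit_family(family, X[tr], y[tr], seed=seed + s, rf_trees=rf_trees)
        base = float(np.mean((m.predict(X[te]) - y[te]) ** 2))
        perm = rng.permutation(len(te))
        # stack the per-column permuted copies into one predict call
        stack = np.repeat(X[te][None, :, :], len(cols), axis=0)
        for j in range(len(cols)):
            stack[j, :, j] = stack[j, perm, j]
        preds = m.predict(stack.reshape(-1, len(cols))).reshape(len(cols), len(te))
        deltas[s] = np.mean((preds - y[te]) ** 2, axis=1) - base
    return pd.Series(deltas.mean(axis=0), index=cols)


def select_predictors(importances: pd.Series, probe_importance: float | None = None) -> list[str]:
    """Keep candidates whose importance beats the probe's; never empty."""
    imps = importances.drop(PROBE, errors="ignore")
    if probe_importance is None:
        if PROBE not in importances.index:
            raise ValueError("no probe importance available")
        probe_importance = float(importances[PROBE])
    kept = [c for c in imps.index if imps[c] > probe_importance]
    if not kept:
        kept = [imps.idxmax()]
    return kept


@dataclass
class FittedModel:
    """A final per-indicator model: family, retained predictors, fitted state."""

    response: str
    family: str
    predictors: list[str]
    estimator: object
    seed: int

    def predict(self, X) -> np.ndarray:
        """Predict from an array/frame whose columns are ``self.predictors``."""
        if isinstance(X, pd.DataFrame):
            X = X[self.predictors].to_numpy()
        return np.asarray(self.estimator.predict(np.asarray(X, float)), float)

    def predict_full(self, df: pd.DataFrame) -> np.ndarray:
        """Predict from a frame holding (at least) all predictor columns."""
        return self.predict(df[self.predictors].to_numpy())


def fit_model(
    task: ModelTask,
    data: IndicatorTable,
    family: str,
    subset: list[str],
    seed: int = 0,
    rf_trees: int = 500,
) -> FittedModel:
    """Refit the champion family on all animals with the selected predictors."""
    if not subset:
        raise ValueError("predictor subset must be nonempty")
    X = data.values[subset].to_numpy()
    y = data.values[task.response].to_numpy()
    est = _fit_family(family, X, y, seed=seed, rf_trees=rf_trees)
    return FittedModel(task.response, family, list(subset), est, seed)


def _adj_r2(y: np.ndarray, pred: np.ndarray, p: int) -> float:
    n = len(y)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def apparent_adj_r2(model: FittedModel, data: IndicatorTable) -> float:
    """Adjusted R^2 on the training animals, penalized by the predictor count."""
    y = data.values[model.response].to_numpy()
    p = len(model.predictors)
    if len(y) <= p + 1:
        raise ValueError(f"n={len(y)} too small for p={p} predictors")
    pred = model.predict(data.values[model.predictors].to_numpy())
    return _adj_r2(y, pred, p)


@dataclass
class ModelQuality:
    adjR2_apparent: float
    adjR2_corrected: float
    B: int


def corrected_adj_r2(
    task: ModelTask,
    data: IndicatorTable,
    family: str,
    subset: list[str],
    B: int = 100,
    seed: int = 0,
    rf_trees: int = 500,
) -> ModelQuality:
    """Bootstrap optimism-corrected adjusted R^2 (Harrell's internal validation).

    For each of B bootstrap resamples the family is refit (same predictors);
    optimism_b = adjR2(refit, on the resample) - adjR2(refit, on the original
    data); corrected = apparent - mean optimism.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X = data.values[subset].to_numpy()
    y = data.values[task.response].to_numpy()
    n, p = X.shape
    apparent = _adj_r2(y, _fit_family(family, X, y, seed=seed, rf_trees=rf_trees).predict(X), p)
    rng = np.random.default_rng(seed)
    optimism = np.empty(B)
    for b in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            if np.std(y[idx]) > 1e-12:
                break
            warnings.warn("degenerate bootstrap resample redrawn (zero-variance response)")
        m = _fit_family(family, X[idx], y[idx], seed=seed + 1 + b, rf_trees=rf_trees)
        boot = _adj_r2(y[idx], m.predict(X[idx]), p)
        orig = _adj_r2(y, m.predict(X), p)
        optimism[b] = boot - orig
    return ModelQuality(apparent, apparent - float(np.mean(optimism)), B)


@dataclass
class ModelReport:
    models: dict[str, FittedModel]
    quality: pd.DataFrame  # indicator, family, adjR2_apparent, adjR2_corrected, n_selected
    scores: dict[str, FamilyScores] = field(repr=False, default=None)


def select_and_fit_all(
    data: IndicatorTable,
    n_splits: int = 50,
    B: int = 100,
    seed: int = 0,
    rf_trees: int = 500,
    compute_quality: bool = True,
) -> ModelReport:
    """Run the full selection for every indicator: race, screen, refit, validate."""
    models: dict[str, FittedModel] = {}
    rows = []
    scores: dict[str, FamilyScores] = {}
    for t, task in enumerate(make_tasks(data)):
        s = seed + 1000 * t
        fs = compare_families(task, data, n_splits=n_splits, seed=s, rf_trees=rf_trees)
        scores[task.response] = fs
        imps = importance(task, data, fs.champion, n_splits=n_splits, seed=s, rf_trees=rf_trees)
        subset = select_predictors(imps)
        model = fit_model(task, data, fs.champion, subset, seed=s, rf_trees=rf_trees)
        models[task.response] = model
        row = {
            "indicator": task.response,
            "family": fs.champion,
            "n_selected": len(subset),
            "adjR2_apparent": apparent_adj_r2(model, data),
        }
        if compute_quality:
            q = corrected_adj_r2(task, data, fs.champion, subset, B=B, seed=s, rf_trees=rf_trees)
            row["adjR2_corrected"] = q.adjR2_corrected
        rows.append(row)
    return ModelReport(models=models, quality=pd.DataFrame(rows), scores=scores)
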