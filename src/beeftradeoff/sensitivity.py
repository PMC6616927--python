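"""Variance-based sensitivity analysis of the fitted models.

Each predictor's influence in a fitted model is quantified by its first-order
Sobol index ``Si = Var(E[f | X_i]) / Var(f)``, estimated by the pick-freeze
(Saltelli) scheme with two independent base matrices of iid standard-normal
inputs — consistent with the standardized scale of the indicators.  The
indices live in [0, 1]; negative Monte-Carlo estimates are clipped to 0 (and
logged), and their sum is reported as-is: for models with interactions it is
legitimately below 1.

A complementary one-at-a-time (OAT) view sweeps a single predictor over
``0 +/- 2 sigma`` (the grid [-2, 2], all other predictors held at their mean
0) and records the model prediction, exposing slopes and non-linearities that
a small Si can hide when interactions are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelsel import FittedModel

__all__ = [
    "SensitivityResult",
    "ProfileCurve",
    "first_order_si",
    "oat_profile",
    "sensitivity_table",
]


@dataclass
class SensitivityResult:
    response: str
    si: pd.Series  # predictor -> Si in [0, 1]
    sum_si: float
    n_base: int
    seed: int
    clipped: list[str]


@dataclass
class ProfileCurve:
    response: str
    predictor: str
    grid: np.ndarray
    prediction: np.ndarray


def first_order_si(model: FittedModel, n_base: int = 10_000, seed: int = 0) -> SensitivityResult:
    """First-order Sobol indices of a fitted model under independent N(0,1) inputs.

    Pick-freeze estimator: with base matrices A, B and AB_i (= A with column i
    taken from B), ``Si ~= mean(f(B) * (f(AB_i) - f(A))) / Var(f)``.
    """
    if n_base < 1000:
        raise ValueError("n_base must be >= 1000")
    p = len(model.predictors)
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_base, p))
    B = rng.standard_normal((n_base, p))
    fA = model.predict(A)
    fB = model.predict(B)
    var = float(np.var(np.concatenate([fA, fB]), ddof=1))
    if var < 1e-12:
        warnings.warn("model output is (numerically) constant: all Si set to 0")
        si = pd.Series(0.0, index=model.predictors)
        return SensitivityResult(model.response, si, 0.0, n_base, seed, [])
    values = {}
    clipped = []
    for i, name in enumerate(model.predictors):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        est = float(np.mean(fB * (model.predict(ABi) - fA))) / var
        if est < 0.0 or est > 1.0:
            clipped.append(name)
            warnings.warn(f"Si estimate for {name!r} clipped from {est:.4f} into [0, 1]")
            est = min(1.0, max(0.0, est))
        values[name] = est
    si = pd.Series(values)
    return SensitivityResult(model.response, si, float(si.sum()), n_base, seed, clipped)


def oat_profile(model: FittedModel, predictor: str, n_grid: int = 41) -> ProfileCurve:
    """Model prediction as one predictor sweeps [-2, 2] with the others at 0."""
    if predictor not in model.predictors:
        raise ValueError(f"{predictor!r} is not a predictor of the {model.response!r} model")
    grid = np.linspace(-2.0, 2.0, n_grid)
    X = np.zeros((n_grid, len(model.predictors)))
    X[:, model.predictors.index(predictor)] = grid
    return ProfileCurve(model.response, predictor, grid, model.predict(X))


def sensitivity_table(models: dict[str, FittedModel], n_base: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Long-format Si table (model, predictor, Si) across all fitted models."""
    rows = []
    for i, (name, model) in enumerate(models.items()):
        res = first_order_si(model, n_base=n_base, seed=seed + i)
        for pred, si in res.si.items():
            rows.append({"model": name, "predictor": pred, "Si": si})
    return pd.DataFrame(rows)
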