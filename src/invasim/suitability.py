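"""Correlative component: presence-background suitability modelling.

The suitability engine is a penalized-logistic equivalent of the
maximum-entropy presence-background model: linear + quadratic (optionally
hinge) features of min-max-normalized predictors, presence-vs-background
labels, an L1 penalty weighted per feature by its standard deviation, and a
complementary log-log link mapping the linear predictor to a suitability in
[0, 1].  The engine sits behind a small contract (:class:`SuitabilityModel`)
so alternative engines can be plugged in.

Evaluation is by training AUC (the Mann-Whitney rank probability that a
presence outranks a background point) and variable selection by permutation
importance: the drop in training AUC when one predictor's values are
shuffled across the pooled training points, floored at zero and normalized
to percentages within each repetition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .landscape import Extent, Layer

DEFAULT_L1_PENALTY = 0.05
DEFAULT_BACKGROUND_N = 10_000


@dataclass
class PresenceBackground:
    """Design data for a presence-background fit.

    ``X`` rows hold predictor values at the presence points followed by the
    background points; ``y`` is 1 for presence, 0 for background.
    """

    variables: list[str]
    X: np.ndarray
    y: np.ndarray
    presence_points: np.ndarray  # (n_p, 2) lon/lat
    background_points: np.ndarray  # (n_b, 2) lon/lat

    @classmethod
    def from_layers(cls, presence_points, background_points,
                    predictors: dict[str, Layer]) -> "PresenceBackground":
        """Extract design rows by nearest-cell lookup; drops points that fall
        on masked cells of any predictor."""
        presence_points = np.atleast_2d(np.asarray(presence_points, dtype=float))
        background_points = np.atleast_2d(np.asarray(background_points, dtype=float))
        if background_points.shape[0] == 0:
            raise ValueError("background point set is empty")
        variables = list(predictors)

        def rows(points):
            cols = []
            valid = np.ones(points.shape[0], bool)
            for v in variables:
                vals, ok = predictors[v].sample(points[:, 0], points[:, 1])
                cols.append(vals)
                valid &= ok
            return np.column_stack(cols), valid

        Xp, okp = rows(presence_points)
        Xb, okb = rows(background_points)
        X = np.vstack([Xp[okp], Xb[okb]])
        y = np.concatenate([np.ones(okp.sum()), np.zeros(okb.sum())])
        return cls(variables, X, y, presence_points[okp], background_points[okb])


class SuitabilityModel(Protocol):
    """Contract every suitability engine satisfies."""

    variables: list[str]

    def predict_rows(self, X: np.ndarray) -> np.ndarray: ...
    def predict(self, predictors: dict[str, Layer]) -> Layer: ...


@dataclass
class FittedSuitabilityModel:
    """Penalized-logistic presence-background model (maxent equivalent)."""

    variables: list[str]
    feature_spec: list[tuple[str, str, float]]  # (variable, transform, knot)
    coefficients: np.ndarray
    intercept: float
    var_min: np.ndarray
    var_max: np.ndarray

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.var_max > self.var_min, self.var_max - self.var_min, 1.0)
        return (X - self.var_min) / span

    def _features(self, X: np.ndarray) -> np.ndarray:
        Z = self._normalize(X)
        cols = []
        var_idx = {v: j for j, v in enumerate(self.variables)}
        for var, transform, knot in self.feature_spec:
            z = Z[:, var_idx[var]]
            if transform == "linear":
                cols.append(z)
            elif transform == "quadratic":
                cols.append(z ** 2)
            elif transform == "hinge":
                cols.append(np.maximum(z - knot, 0.0))
            else:  # pragma: no cover - spec is built internally
                raise ValueError(f"unknown transform {transform!r}")
        return np.column_stack(cols)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self._features(X) @ self.coefficients + self.intercept

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for raw predictor rows (cloglog link)."""
        eta = self.linear_predictor(np.asarray(X, dtype=float))
        return 1.0 - np.exp(-np.exp(eta))

    def predict(self, predictors: dict[str, Layer]) -> Layer:
        """Per-cell suitability layer; masked where any predictor is masked."""
        missing = [v for v in self.variables if v not in predictors]
        if missing:
            raise ValueError(f"missing predictor layers: {missing}")
        first = predictors[self.variables[0]]
        grid = first.grid
        mask = np.zeros(grid.shape, bool)
        cols = []
        for v in self.variables:
            lyr = predictors[v]
            if lyr.grid != grid:
                raise ValueError(f"predictor {v} is on a different grid")
            mask |= lyr.mask
            cols.append(np.where(lyr.mask, 0.0, lyr.values).ravel())
        X = np.column_stack(cols)
        suit = self.predict_rows(X).reshape(grid.shape)
        suit = np.where(mask, np.nan, suit)
        return Layer(grid, suit, mask, "BCS", "emergent")


def sample_background(extent: Extent, predictors: dict[str, Layer] | list[Layer],
                      n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform background points (cell centres, with replacement) within extent.

    Cells masked in any predictor are excluded.
    """
    layers = list(predictors.values()) if isinstance(predictors, dict) else list(predictors)
    grid = layers[0].grid
    mask = np.zeros(grid.shape, bool)
    for lyr in layers:
        mask |= lyr.mask
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    inside = ((lat_c[:, None] >= extent.lat_min) & (lat_c[:, None] <= extent.lat_max)
              & (lon_c[None, :] >= extent.lon_min) & (lon_c[None, :] <= extent.lon_max))
    candidates = np.flatnonzero(inside & ~mask)
    if candidates.size == 0:
        raise ValueError("no unmasked cells within the extent")
    if n == 0:
        return np.empty((0, 2))
    draws = rng.choice(candidates, size=n, replace=True)
    r, c = np.divmod(draws, grid.n_cols)
    lon, lat = grid.center_of(r, c)
    return np.column_stack([lon, lat])


def fit_suitability(data: PresenceBackground, reg: float = DEFAULT_L1_PENALTY,
                    rng: np.random.Generator | None = None,
                    hinge: bool = False, n_hinge_knots: int = 4,
                    tol: float = 1e-4) -> FittedSuitabilityModel:
    """Fit the penalized-logistic presence-background model.

    The L1 penalty weight per feature is ``reg`` scaled by the feature's
    training standard deviation (implemented by column scaling), and the
    loss is per-sample so the fit is invariant to duplicating every row.
    """
    X, y = data.X, data.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 presence and 2 background points")
    var_min = X.min(axis=0)
    var_max = X.max(axis=0)
    degenerate = [v for v, lo, hi in zip(data.variables, var_min, var_max) if lo == hi]
    if degenerate:
        raise ValueError(f"degenerate predictors (zero variance): {degenerate}")

    spec: list[tuple[str, str, float]] = []
    for v in data.variables:
        spec.append((v, "linear", 0.0))
        spec.append((v, "quadratic", 0.0))
    if hinge:
        for v in data.variables:
            for q in np.linspace(0.2, 0.8, n_hinge_knots):
                spec.append((v, "hinge", float(q)))

    model = FittedSuitabilityModel(
        variables=list(data.variables),
        feature_spec=spec,
        coefficients=np.zeros(len(spec)),
        intercept=0.0,
        var_min=var_min,
        var_max=var_max,
    )
    F = model._features(X)
    sd = F.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Fs = F / sd

    # penalty scales with the presence count (the information-bearing class),
    # so the fit is invariant to duplicating every training row and the
    # regularization strength does not wash out under heavy presence/
    # background imbalance
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (reg * float((y == 1).sum())),
        solver="liblinear",
        random_state=0,
        intercept_scaling=100.0,
        tol=tol,
        max_iter=2000,
    )
    clf.fit(Fs, y)
    model.coefficients = clf.coef_[0] / sd
    model.intercept = float(clf.intercept_[0])
    return model


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 * P(equal)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(p.size), np.zeros(b.size)])
    s = np.concatenate([p, b])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def training_auc(model: SuitabilityModel, data: PresenceBackground) -> float:
    scores = model.predict_rows(data.X)
    return auc(scores[data.y == 1], scores[data.y == 0])


@dataclass
class ImportanceTable:
    """Per-variable permutation importances, percentages per repetition."""

    table: pd.DataFrame  # columns: variable, rep, importance_pct

    def mean_importance(self) -> pd.Series:
        return self.table.groupby("variable")["importance_pct"].mean()


def permutation_importance(model: SuitabilityModel, data: PresenceBackground,
                           reps: int = 50,
                           rng: np.random.Generator | None = None) -> ImportanceTable:
    """Drop in training AUC when each variable is shuffled, as percentages.

    One permutation is drawn per variable per repetition from ``rng`` in
    variable order; raw drops are floored at 0 and normalized to sum to 100
    within each repetition (uniform split if every drop is zero).
    """
    rng = np.random.default_rng() if rng is None else rng
    base = training_auc(model, data)
    k = len(data.variables)
    records = []
    for rep in range(reps):
        raw = np.empty(k)
        for j in range(k):
            Xp = data.X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            scores = model.predict_rows(Xp)
            raw[j] = base - auc(scores[data.y == 1], scores[data.y == 0])
        raw = np.maximum(raw, 0.0)
        total = raw.sum()
        pct = raw / total * 100.0 if total > 0 else np.full(k, 100.0 / k)
        for v, p in zip(data.variables, pct):
            records.append({"variable": v, "rep": rep, "importance_pct": p})
    return ImportanceTable(pd.DataFrame.from_records(records))


def select_variables(importance: ImportanceTable, k: int) -> list[str]:
    """Top-k variables by mean importance, descending; ties by name."""
    means = importance.mean_importance()
    if k > len(means):
        raise ValueError(f"k={k} exceeds the {len(means)} available variables")
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [v for v, _ in ranked[:k]]
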