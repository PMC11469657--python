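"""Probability-of-death models on a single severity score.

Three families, compared by stratified 5-fold cross-validated log loss:

* logistic — maximum-likelihood logistic regression of death on the
  oriented score (IRLS, deviance tolerance 1e-8, ridge fallback under
  complete separation);
* spline — penalised logistic regression on a linear tail-restricted
  (natural) cubic spline basis with three knots at the 10th/50th/90th
  percentiles, ridge weights 2 on the linear and 4 on the nonlinear
  coefficient (base strength 1/n), linear in the logit beyond the boundary
  knots;
* monotone — isotonic regression (pool-adjacent-violators) of the outcome
  on the oriented score, with linear interpolation between block centres
  for out-of-sample prediction, guaranteeing that worse scores never get
  lower predicted mortality.

All predictions are probabilities in [0, 1]; log loss clips at 1e-15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FittedRiskModel",
    "ModelComparison",
    "FAMILIES",
    "fit_logistic",
    "fit_spline",
    "fit_monotone",
    "pava",
    "log_loss",
    "cross_validate",
    "compare_models",
    "rcs_basis",
]

FAMILIES = ("logistic", "spline", "monotone")

_CLIP = 1e-15


@dataclass
class FittedRiskModel:
    family: str
    score: str
    params: dict
    _predict: Callable = field(repr=False)

    def predict(self, score_values) -> np.ndarray:
        p = np.clip(self._predict(np.asarray(score_values, dtype=float)), 0.0, 1.0)
        return p


@dataclass
class ModelComparison:
    """CV log-loss grid: one row per (score, family)."""

    losses: dict            # (score, family) -> mean CV log loss
    best_family: dict       # score -> family with the smallest loss
    folds: int
    seed: int


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log_loss(probabilities, outcomes) -> float:
    """Negative mean Bernoulli log-likelihood, probabilities clipped to
    [1e-15, 1 - 1e-15]."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _irls(X: np.ndarray, y: np.ndarray, penalty: Optional[np.ndarray] = None,
          tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """(Penalised) logistic IRLS.  ``penalty`` is a diagonal ridge vector
    (no penalty on the intercept by convention of the caller's basis)."""
    n, d = X.shape
    beta = np.zeros(d)
    pen = np.zeros(d) if penalty is None else np.asarray(penalty, dtype=float)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        zvec = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + np.diag(pen)
        beta_new = np.linalg.solve(A, XtW @ zvec)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if not np.all(np.isfinite(beta_new)):
            raise FloatingPointError("IRLS diverged")
        if abs(dev - dev_old) < tol:
            beta = beta_new
            break
        beta, dev_old = beta_new, dev
    return beta, dev


def _deviance(X, y, beta):
    mu = np.clip(_sigmoid(X @ beta), 1e-10, 1 - 1e-10)
    return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))


def _check_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("both outcome classes are required")


def fit_logistic(score_values, outcomes, score: str = "score") -> FittedRiskModel:
    """ML logistic regression of death on the oriented score.

    Complete separation (diverging coefficients) triggers a small ridge
    penalty (1e-4) with a warning instead of failing.
    """
    x = np.asarray(score_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    X = np.column_stack([np.ones_like(x), x])
    try:
        beta, dev = _irls(X, y)
        # a vanishing deviance with both classes present means the fit is
        # driving probabilities to 0/1: complete separation
        separated = dev < 1e-6 or np.abs(beta).max() > 1e6
    except (FloatingPointError, np.linalg.LinAlgError):
        separated = True
    if separated:
        warnings.warn(f"{score}: complete separation suspected; "
                      "refitting with a small ridge penalty")
        beta, _ = _irls(X, y, penalty=np.array([0.0, 1e-4]))
    b0, b1 = beta
    return FittedRiskModel(
        family="logistic", score=score,
        params={"intercept": float(b0), "slope": float(b1)},
        _predict=lambda s: _sigmoid(b0 + b1 * s),
    )


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis without intercept.

    For knots t_1 < ... < t_k the basis is x plus k-2 nonlinear terms that
    are cubic between the boundary knots and linear outside them.
    """
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    tk, tk1 = knots[-1], knots[-2]
    cols = [x]

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        tj = knots[j]
        term = (cube(x - tj)
                - cube(x - tk1) * (tk - tj) / (tk - tk1)
                + cube(x - tk) * (tk1 - tj) / (tk - tk1))
        cols.append(term)
    return np.column_stack(cols)


def fit_spline(score_values, outcomes, score: str = "score",
               penalty_linear: float = 2.0, penalty_nonlinear: float = 4.0,
               penalty_interaction: float = 10.0) -> FittedRiskModel:
    """Penalised natural-cubic-spline logistic regression, 3 knots at the
    10th/50th/90th percentiles of the oriented score.

    The ridge penalty has base strength 1/n scaled by ``penalty_linear`` on
    the linear coefficient and ``penalty_nonlinear`` on the nonlinear one.
    ``penalty_interaction`` is accepted for configurability but a
    single-predictor model has no interaction terms to apply it to.  Fewer
    than 3 distinct score values falls back to plain logistic regression.
    """
    x = np.asarray(score_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    ux = np.unique(x)
    if len(ux) < 3:
        warnings.warn(f"{score}: fewer than 3 distinct score values for "
                      "knot placement; falling back to logistic regression")
        model = fit_logistic(x, y, score=score)
        model.family = "spline"
        model.params["fallback"] = "logistic"
        return model
    knots = np.unique(np.percentile(x, [10, 50, 90]))
    if len(knots) < 3:
        # concentrated discrete scores: place knots on observed distinct values
        knots = np.unique(np.quantile(ux, [0.1, 0.5, 0.9], method="nearest"))
    base = 1.0 / len(x)
    B = rcs_basis(x, knots)
    X = np.column_stack([np.ones_like(x), B])
    pen = np.concatenate([[0.0], [penalty_linear * base],
                          np.full(B.shape[1] - 1, penalty_nonlinear * base)])
    try:
        beta, _ = _irls(X, y, penalty=pen)
    except (FloatingPointError, np.linalg.LinAlgError):
        warnings.warn(f"{score}: spline IRLS unstable; increasing ridge")
        beta, _ = _irls(X, y, penalty=np.maximum(pen, 1e-4))

    def predict(s):
        Xs = np.column_stack([np.ones_like(s), rcs_basis(s, knots)])
        return _sigmoid(Xs @ beta)

    return FittedRiskModel(
        family="spline", score=score,
        params={"knots": knots.tolist(), "coefficients": beta.tolist()},
        _predict=predict,
    )


def pava(y: np.ndarray, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Pool-adjacent-violators: weighted least-squares nondecreasing fit."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # blocks as (value, weight, count) merged while decreasing
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        cnt.append(1)
        while len(vals) > 1 and vals[-2] >= vals[-1]:
            wtot = wts[-2] + wts[-1]
            vals[-2] = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / wtot
            wts[-2] = wtot
            cnt[-2] += cnt[-1]
            vals.pop()
            wts.pop()
            cnt.pop()
    return np.repeat(vals, cnt)


def fit_monotone(score_values, outcomes, score: str = "score") -> FittedRiskModel:
    """Isotonic (monotone nondecreasing) fit of death on the oriented score.

    Outcomes at tied score values are pre-averaged, PAVA pools adjacent
    violators, and prediction interpolates linearly between block centres
    (weighted mean score of each block), clamping outside the observed
    range.
    """
    x = np.asarray(score_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ux, inverse, counts = np.unique(xs, return_inverse=True, return_counts=True)
    ymeans = np.bincount(inverse, weights=ys) / counts
    fitted = pava(ymeans, weights=counts.astype(float))
    # collapse equal-fitted runs into blocks with weighted-centre abscissae
    block_id = np.concatenate([[0], np.cumsum(np.diff(fitted) > 1e-12)])
    nb = block_id[-1] + 1
    bw = np.bincount(block_id, weights=counts.astype(float), minlength=nb)
    bx = np.bincount(block_id, weights=ux * counts, minlength=nb) / bw
    by = np.bincount(block_id, weights=fitted * counts, minlength=nb) / bw

    def predict(s):
        return np.interp(s, bx, by)

    return FittedRiskModel(
        family="monotone", score=score,
        params={"block_x": bx.tolist(), "block_p": by.tolist()},
        _predict=predict,
    )


_FITTERS = {"logistic": fit_logistic, "spline": fit_spline,
            "monotone": fit_monotone}


def cross_validate(family: str, score_values, outcomes, k: int = 5,
                   seed: int = 0, score: str = "score") -> float:
    """Mean held-out log loss over a stratified, seeded k-fold split."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(score_values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(x) < k:
        raise ValueError(f"need at least k={k} observations")
    _check_classes(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    losses = []
    for train, test in skf.split(x.reshape(-1, 1), y):
        model = _FITTERS[family](x[train], y[train], score=score)
        losses.append(log_loss(model.predict(x[test]), y[test]))
    return float(np.mean(losses))


def compare_models(risk_frame, outcomes, k: int = 5, seed: int = 0) -> ModelComparison:
    """6 scores x 3 families grid of mean CV log losses.

    ``risk_frame`` holds oriented risks (larger = worse), one column per
    score; the same fold split (derived from ``seed``) is reused across the
    grid so families are compared on identical folds.
    """
    losses = {}
    for name in risk_frame.columns:
        x = risk_frame[name].to_numpy(dtype=float)
        for family in FAMILIES:
            losses[(name, family)] = cross_validate(
                family, x, outcomes, k=k, seed=seed, score=name)
    best = {}
    for name in risk_frame.columns:
        best[name] = min(FAMILIES, key=lambda f: losses[(name, f)])
    return ModelComparison(losses=losses, best_family=best, folds=k, seed=seed)
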