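"""Partial least squares on field descriptors, with LOO CV and contours.

PLS1 via the NIPALS algorithm with mean-centering only (no column
autoscaling — the CoMFA convention, where a column's standard deviation
is physically meaningful). Component count is chosen by maximizing the
leave-one-out q²; contour fields use the StDev*Coeff convention
(per-column training standard deviation × model coefficient) thresholded
at distribution percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .activity import UndefinedStatisticError, f_statistic, loo_q2

__all__ = [
    "PLSModel",
    "CVResult",
    "ContourSet",
    "fit_pls",
    "loo_cv",
    "loo_predictions",
    "model_summary",
    "stdev_coeff_field",
    "contour_set",
    "y_scramble_q2",
]

_RANK_TOL = 1e-10


@dataclass
class PLSModel:
    """Centered PLS1 model: ŷ = y_mean + (x − x_means)·coef."""

    n_components: int
    x_means: np.ndarray
    y_mean: float
    coef: np.ndarray
    weights: np.ndarray  # W, columns = component weight vectors
    loadings: np.ndarray  # P
    y_loadings: np.ndarray  # q
    scores_norms: np.ndarray  # diagnostics: per-component score norms
    rank_reduced: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.y_mean + (X - self.x_means) @ self.coef


@dataclass
class CVResult:
    """Leave-one-out CV profile: (m, PRESS, q²) per component count."""

    per_component: List[Tuple[int, float, float]]
    chosen_m: int

    def q2(self, m: Optional[int] = None) -> float:
        m = self.chosen_m if m is None else m
        for mm, _, q in self.per_component:
            if mm == m:
                return q
        raise KeyError(f"no CV entry for m={m}")

    @property
    def chosen_q2(self) -> float:
        return self.q2(self.chosen_m)


def fit_pls(X: np.ndarray, y: np.ndarray, m: int) -> PLSModel:
    """Fit an m-component PLS1 model by NIPALS (centering only).

    If m exceeds the rank of the centered X, the component count is
    reduced automatically and the model is flagged. The fit is fully
    deterministic and invariant to training-row permutations.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if m < 1:
        raise ValueError("need at least one component")
    if n < m + 2:
        raise ValueError(f"need at least m+2 = {m + 2} training rows, got {n}")

    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_means
    f = y - y_mean
    scale0 = max(float(np.abs(E).max()), 1.0)

    W, P, Q, tnorms = [], [], [], []
    rank_reduced = False
    for _ in range(m):
        w = E.T @ f
        wn = np.linalg.norm(w)
        if wn <= _RANK_TOL * scale0:
            rank_reduced = True
            break
        w = w / wn
        t = E @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale0) ** 2:
            rank_reduced = True
            break
        p_load = (E.T @ t) / tt
        q_load = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q_load * t
        W.append(w)
        P.append(p_load)
        Q.append(q_load)
        tnorms.append(np.sqrt(tt))

    if not W:
        # y has no linear relation to X at all; the model is the mean
        return PLSModel(
            n_components=0,
            x_means=x_means,
            y_mean=y_mean,
            coef=np.zeros(p),
            weights=np.zeros((p, 0)),
            loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            scores_norms=np.zeros(0),
            rank_reduced=True,
        )

    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    # B = W (PᵀW)⁻¹ q  — regression coefficients in original X space
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return PLSModel(
        n_components=Wm.shape[1],
        x_means=x_means,
        y_mean=y_mean,
        coef=coef,
        weights=Wm,
        loadings=Pm,
        y_loadings=qv,
        scores_norms=np.array(tnorms),
        rank_reduced=rank_reduced,
    )


def loo_predictions(X: np.ndarray, y: np.ndarray, m: int) -> np.ndarray:
    """Leave-one-out predictions: refit (with re-centering) per left-out row."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_pls(X[keep], y[keep], m)
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def loo_cv(X: np.ndarray, y: np.ndarray, max_components: int = 10) -> CVResult:
    """LOO cross-validation over 1..max_components; q²-maximal m chosen.

    Ties in q² go to the smaller component count. Raises when y has no
    variance (q² undefined).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 4:
        raise ValueError("LOO needs at least 4 samples")
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("constant y; q² undefined")
    cap = min(max_components, n - 3)  # each LOO fold needs m+2 rows
    rows = []
    for m in range(1, cap + 1):
        preds = loo_predictions(X, y, m)
        press = float(np.sum((y - preds) ** 2))
        rows.append((m, press, loo_q2(y, preds)))
    best_q2 = max(q for _, _, q in rows)
    chosen = min(m for m, _, q in rows if q == best_q2)
    return CVResult(per_component=rows, chosen_m=chosen)


def model_summary(
    model: PLSModel, X: np.ndarray, y: np.ndarray, cv: Optional[CVResult] = None
) -> dict:
    """Training-set fit statistics plus cross-validation summary.

    Reports training r², SEP, the F statistic at (r², n, m), and — when a
    CVResult is given — q² at the chosen component count.
    """
    y = np.asarray(y, float).ravel()
    resid = y - model.predict(X)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("constant y; r² undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    n, m = len(y), max(model.n_components, 1)
    out = {
        "n_train": n,
        "n_components": model.n_components,
        "r2": r2,
        "sep": float(np.sqrt(np.sum(resid**2) / n)),
        "f_stat": f_statistic(min(r2, 1.0), n, m) if r2 < 1 else float("inf"),
        "rank_reduced": model.rank_reduced,
    }
    if cv is not None:
        out["q2"] = cv.chosen_q2
        out["chosen_m"] = cv.chosen_m
    return out


def stdev_coeff_field(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """StDev*Coeff contour values: column std (over training rows) × coef."""
    X = np.asarray(X, float)
    return X.std(axis=0, ddof=1) * model.coef


@dataclass
class ContourSet:
    """Favored/disfavored lattice points per (fragment label, field kind)."""

    favored: Dict[Tuple[str, str], List[Tuple[int, float]]]
    disfavored: Dict[Tuple[str, str], List[Tuple[int, float]]]
    thresholds: Dict[Tuple[str, str], Tuple[float, float]]
    flags: List[str] = field(default_factory=list)


def contour_set(
    values: np.ndarray,
    column_meta: Sequence[Tuple[str, str, int]],
    upper_pct: float = 80.0,
    lower_pct: float = 20.0,
) -> ContourSet:
    """Threshold StDev*Coeff values into favored / disfavored point sets.

    Per (fragment, field) block: points at or above the block's
    ``upper_pct`` percentile are favored (the "green"/"blue" contours),
    points at or below the ``lower_pct`` percentile disfavored
    ("yellow"/"red"). Degenerate all-equal blocks yield empty sets and a
    flag.
    """
    values = np.asarray(values, float)
    if len(values) != len(column_meta):
        raise ValueError("values and column metadata lengths differ")
    favored, disfavored, thresholds = {}, {}, {}
    flags: List[str] = []
    keys = []
    for label, kind, _ in column_meta:
        if (label, kind) not in keys:
            keys.append((label, kind))
    for key in keys:
        idx = [
            (i, meta[2])
            for i, meta in enumerate(column_meta)
            if (meta[0], meta[1]) == key
        ]
        block = values[[i for i, _ in idx]]
        lo = float(np.percentile(block, lower_pct))
        hi = float(np.percentile(block, upper_pct))
        thresholds[key] = (hi, lo)
        if np.ptp(block) == 0:
            favored[key], disfavored[key] = [], []
            flags.append(f"degenerate-block-{key[0]}-{key[1]}")
            continue
        favored[key] = [
            (lattice, float(v))
            for (_, lattice), v in zip(idx, block)
            if v >= hi and v > lo
        ]
        disfavored[key] = [
            (lattice, float(v))
            for (_, lattice), v in zip(idx, block)
            if v <= lo and v < hi
        ]
    return ContourSet(favored=favored, disfavored=disfavored, thresholds=thresholds, flags=flags)


def y_scramble_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 20,
    seed: int = 0,
    max_components: int = 10,
) -> np.ndarray:
    """q² under random permutations of y — a basic chance-correlation check."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float).ravel()
    out = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(len(y))
        out[i] = loo_cv(X, y[perm], max_components=max_components).chosen_q2
    return out
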