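"""Activity arithmetic and QSAR model-validation statistics.

Implements the IC50 → pIC50 conversion used for congeneric-series
cytotoxicity data (IC50 in μM, pIC50 on the molar scale), the censoring
policy for compounds inactive up to the highest tested concentration,
and the external-validation statistics used to judge a 3D-QSAR model:
PRESS, RMSEP, the predictive r² (r²pred), Roy's R²m (both axis
conventions), leave-one-out q², and the PLS F statistic.

Also provides loaders for the packaged activity tables of the
betulinic-acid / betulin HT29 series (37 compounds, 26 train / 11 test)
and the prospectively synthesized betulin 28-O-esters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "ValidationReport",
    "pic50_from_ic50",
    "residual",
    "press",
    "rmsep",
    "r2_pred",
    "r2_m",
    "pearson_r2",
    "r2_through_origin",
    "loo_q2",
    "f_statistic",
    "load_paper_tables",
    "load_cytotoxicity_panel",
    "load_activity_csv",
    "validation_report",
    "DEFAULT_CENSOR_PIC50",
]

#: pIC50 assigned to compounds censored at the assay ceiling (IC50 > 100 μM).
DEFAULT_CENSOR_PIC50 = 4.0


class UndefinedStatisticError(ZeroDivisionError):
    """A validation statistic is undefined (zero variance / zero SD)."""


@dataclass
class ActivityRecord:
    """One compound's activity bookkeeping within a congeneric series.

    ``ic50`` is in μM; ``exp_pic50``/``pred_pic50`` are −log10 of the molar
    IC50. ``censored`` marks activities printed as ">value" and mapped to a
    fixed policy pIC50. ``r1_label``/``r2_label`` carry the substituent
    shorthand; "figure-only" marks substituents published only as drawings.
    """

    compound_id: str
    role: Literal["train", "test"]
    r1_label: str = ""
    r2_label: str = ""
    ic50: Optional[float] = None
    censored: bool = False
    exp_pic50: float = math.nan
    pred_pic50: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")
        if not math.isfinite(self.exp_pic50):
            raise ValueError(f"exp_pic50 must be finite for {self.compound_id!r}")
        if self.ic50 is not None and not self.censored:
            implied = pic50_from_ic50(self.ic50)
            if abs(implied - self.exp_pic50) > 0.001:
                raise ValueError(
                    f"{self.compound_id!r}: exp_pic50 {self.exp_pic50} inconsistent "
                    f"with IC50 {self.ic50} μM (implies {implied:.3f})"
                )

    @property
    def residual(self) -> Optional[float]:
        if self.pred_pic50 is None:
            return None
        return residual(self.exp_pic50, self.pred_pic50)


@dataclass
class ValidationReport:
    """External/internal validation summary for one fitted QSAR model."""

    n_train: int
    n_test: int
    train_mean: float
    press: float
    sd: float
    r2_pred: float
    rmsep: float
    r2: float
    r2_zero_obs: float
    r2_zero_pred: float
    r2_m_obs: float
    r2_m_pred: float
    q2: Optional[float] = None
    f_stat: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Summary dict with statistics rounded for reporting."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def pic50_from_ic50(
    ic50: float,
    censored: bool = False,
    censor_value: float = DEFAULT_CENSOR_PIC50,
) -> float:
    """Convert an IC50 in μM to pIC50 = −log10(molar IC50).

    Censored measurements (reported only as exceeding the highest tested
    concentration, e.g. ">100 μM") are assigned the fixed policy value
    ``censor_value`` (default 4.0, the pIC50 of exactly 100 μM).
    """
    if censored:
        return censor_value
    if not (ic50 > 0):
        raise ValueError(f"IC50 must be positive, got {ic50!r}")
    return -math.log10(ic50 * 1e-6)


def residual(exp: float, pred: float) -> float:
    """Prediction residual, experimental − predicted (log units)."""
    if not (math.isfinite(exp) and math.isfinite(pred)):
        raise ValueError("residual requires finite experimental and predicted values")
    return exp - pred


def _as_pairs(pairs: Iterable[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one (experimental, predicted) pair is required")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (experimental, predicted) 2-tuples")
    return arr


def press(pairs: Iterable[tuple[float, float]]) -> float:
    """Predictive residual sum of squares, Σ(exp − pred)²."""
    arr = _as_pairs(pairs)
    return float(np.sum((arr[:, 0] - arr[:, 1]) ** 2))


def rmsep(pairs: Iterable[tuple[float, float]]) -> float:
    """Root mean square error of prediction, sqrt(PRESS / n)."""
    arr = _as_pairs(pairs)
    return float(np.sqrt(press(arr) / len(arr)))


def r2_pred(
    test_pairs: Iterable[tuple[float, float]],
    train_mean: float,
    sd_basis: Literal["observed", "predicted"] = "observed",
) -> float:
    """Predictive r² of an external test set, (SD − PRESS) / SD.

    SD is the sum of squared deviations of the test-set activities from the
    training-set mean — the naive "predict the training mean" null model.
    ``sd_basis`` selects whether the observed (default) or the predicted
    test activities enter SD; the observed convention is the one that
    reproduces published values for this statistic.
    """
    arr = _as_pairs(test_pairs)
    basis = arr[:, 0] if sd_basis == "observed" else arr[:, 1]
    sd = float(np.sum((basis - train_mean) ** 2))
    if sd <= 0:
        raise UndefinedStatisticError("SD is zero; r2_pred undefined")
    return (sd - press(arr)) / sd


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation (regression with intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def r2_through_origin(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the through-origin fit y = kx.

    k is the least-squares slope without intercept; the residual sum of
    squares is referenced to the mean of y (the convention used by Roy's
    R²m metric).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0 or np.all(x == 0):
        raise UndefinedStatisticError("degenerate data; r²0 undefined")
    k = float(np.sum(x * y) / np.sum(x * x))
    return 1.0 - float(np.sum((y - k * x) ** 2)) / denom


def r2_m(
    pairs: Iterable[tuple[float, float]],
    axis: Literal["observed", "predicted"] = "observed",
) -> float:
    """Roy's modified r², R²m = r²·(1 − sqrt(|r² − r²0|)).

    Penalizes test-set predictions whose through-origin fit (r²0) departs
    from the ordinary correlation (r²). ``axis`` chooses the abscissa of
    the through-origin regression: "observed" regresses predicted on
    observed, "predicted" the reverse. Both conventions circulate in the
    QSAR literature, so callers should report both.
    """
    arr = _as_pairs(pairs)
    if len(arr) < 3:
        raise ValueError("r2_m needs at least 3 pairs")
    obs, pred = arr[:, 0], arr[:, 1]
    x, y = (obs, pred) if axis == "observed" else (pred, obs)
    r2 = pearson_r2(x, y)
    r20 = r2_through_origin(x, y)
    return r2 * (1.0 - math.sqrt(abs(r2 - r20)))


def loo_q2(observed: Sequence[float], cv_predictions: Sequence[float]) -> float:
    """Cross-validated q² = 1 − Σ(y − ŷ_cv)² / Σ(y − ȳ)²."""
    y = np.asarray(observed, float)
    yhat = np.asarray(cv_predictions, float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("observed and cv_predictions must be equal-length, n ≥ 3")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("zero total sum of squares; q² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def f_statistic(r2: float, n: int, m: int) -> float:
    """PLS regression F ratio, (r²/m) / ((1−r²)/(n−m−1))."""
    if not (0 <= r2 <= 1):
        raise ValueError(f"r² must lie in [0, 1], got {r2}")
    if n <= m + 1:
        raise ValueError("need n > m + 1 residual degrees of freedom")
    if r2 == 1:
        return math.inf
    return (r2 / m) / ((1 - r2) / (n - m - 1))


# ---------------------------------------------------------------------------
# loaders


def _data_path(name: str):
    return resources.files("fragqsar.data").joinpath(name)


def load_paper_tables(path=None) -> list[ActivityRecord]:
    """Load the packaged HT29 activity tables as ActivityRecords.

    Returns the 37-compound training/test table (experimental and model
    predicted pIC50s) followed by the prospectively assayed betulin
    28-O-ester compounds with their IC50s. ``path`` may point at an
    alternative directory holding the same CSV files.
    """
    base = resources.files("fragqsar.data") if path is None else path
    records: list[ActivityRecord] = []

    t1 = pd.read_csv(str(base.joinpath("ht29_table1.csv")) if path is None else f"{path}/ht29_table1.csv")
    for i, row in t1.iterrows():
        try:
            records.append(
                ActivityRecord(
                    compound_id=str(row["compound_id"]),
                    role=str(row["role"]),
                    r1_label=str(row["r1_label"]),
                    r2_label=str(row["r2_label"]),
                    censored=bool(row["censored"]),
                    exp_pic50=float(row["exp_pic50"]),
                    pred_pic50=float(row["pred_pic50"]),
                )
            )
        except (ValueError, KeyError) as exc:  # pragma: no cover - fixture guard
            raise ValueError(f"malformed activity table row {i + 2}: {exc}") from exc

    t2 = pd.read_csv(str(base.joinpath("ht29_table2.csv")) if path is None else f"{path}/ht29_table2.csv")
    for i, row in t2.iterrows():
        if row.get("source") == "literature":
            continue
        pred = row.get("pred_pic50")
        records.append(
            ActivityRecord(
                compound_id=f"ester-{row['compound_id']}",
                role="test",
                ic50=float(row["ic50_uM"]),
                exp_pic50=float(row["exp_pic50"]),
                pred_pic50=None if pd.isna(pred) else float(pred),
            )
        )
    return records


def load_cytotoxicity_panel() -> pd.DataFrame:
    """IC50 panel of the synthesized esters across six tumor cell lines."""
    return pd.read_csv(str(_data_path("panel_table3.csv")))


def load_activity_csv(path) -> list[ActivityRecord]:
    """Read a user activity CSV (compound_id, role, ic50_uM and/or pic50).

    ``ic50_uM`` values may carry a ">" prefix marking censoring at that
    concentration; censored compounds receive the policy pIC50.
    """
    df = pd.read_csv(path)
    if "compound_id" not in df.columns or "role" not in df.columns:
        raise ValueError("activity CSV requires 'compound_id' and 'role' columns")
    records = []
    for i, row in df.iterrows():
        ic50 = None
        censored = False
        raw = row.get("ic50_uM")
        if raw is not None and not pd.isna(raw):
            s = str(raw).strip()
            if s.startswith(">"):
                censored = True
                ic50 = float(s[1:])
            else:
                ic50 = float(s)
        if "pic50" in df.columns and not pd.isna(row.get("pic50")):
            exp = float(row["pic50"])
        elif ic50 is not None:
            exp = pic50_from_ic50(ic50, censored=censored)
        else:
            raise ValueError(f"row {i + 2}: neither ic50_uM nor pic50 given")
        pred = row.get("pred_pic50")
        records.append(
            ActivityRecord(
                compound_id=str(row["compound_id"]),
                role=str(row["role"]),
                ic50=ic50,
                censored=censored,
                exp_pic50=exp,
                pred_pic50=None if pred is None or pd.isna(pred) else float(pred),
            )
        )
    return records


def validation_report(
    records: Sequence[ActivityRecord],
    sd_basis: Literal["observed", "predicted"] = "observed",
    q2: Optional[float] = None,
    r2_train: Optional[float] = None,
    n_components: Optional[int] = None,
) -> ValidationReport:
    """Compute the full external-validation report from activity records.

    Uses the train-role records for the training mean and the test-role
    records with predictions for PRESS/RMSEP/r²pred/R²m. Training r² and
    q², which need the fitted model, are passed through if supplied; the
    F statistic is derived from r2_train when both it and n_components
    are available.
    """
    train = [r for r in records if r.role == "train"]
    test = [r for r in records if r.role == "test" and r.pred_pic50 is not None]
    if not train or not test:
        raise ValueError("need non-empty train set and predicted test set")
    train_mean = float(np.mean([r.exp_pic50 for r in train]))
    pairs = [(r.exp_pic50, r.pred_pic50) for r in test]
    arr = np.asarray(pairs)
    obs, pred = arr[:, 0], arr[:, 1]
    sd = float(np.sum((obs - train_mean) ** 2))
    f_stat = None
    if r2_train is not None and n_components is not None:
        f_stat = f_statistic(r2_train, len(train), n_components)
    return ValidationReport(
        n_train=len(train),
        n_test=len(test),
        train_mean=train_mean,
        press=press(pairs),
        sd=sd,
        r2_pred=r2_pred(pairs, train_mean, sd_basis=sd_basis),
        rmsep=rmsep(pairs),
        r2=pearson_r2(obs, pred),
        r2_zero_obs=r2_through_origin(obs, pred),
        r2_zero_pred=r2_through_origin(pred, obs),
        r2_m_obs=r2_m(pairs, axis="observed"),
        r2_m_pred=r2_m(pairs, axis="predicted"),
        q2=q2,
        f_stat=f_stat,
    )
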