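"""Evaluation battery for aging-clock predictions.

Accuracy metrics (MedAE, MAE, RMSE, R², Pearson's r), case/control
age-acceleration testing with a permuted-label negative control,
sex-stratified error tables by age bracket, a BMI ordinary-least-squares
model, and CpG-panel overlap counting.

Conventions: the signed error is ``predicted - true`` (positive means the
epigenome is predicted "older"); cohort comparisons use the two-sided
Mann-Whitney U test, with exact enumeration of the U null at cohort sizes
of eight or below and the tie-corrected normal approximation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PredictionSet",
    "EvalReport",
    "CohortComparison",
    "compute_metrics",
    "mann_whitney",
    "compare_cohorts",
    "stratified_errors",
    "bmi_effect",
    "clock_overlap",
    "DEFAULT_AGE_BRACKETS",
]

DEFAULT_AGE_BRACKETS = [(20.0, 45.0), (45.0, 55.0), (55.0, 65.0), (65.0, 75.0)]


@dataclass
class PredictionSet:
    """True/predicted ages joined with sample metadata.

    ``frame`` has one row per sample with at least ``sample_id``,
    ``true_age`` and ``predicted_age``; metadata columns (sex, cohort,
    study_id, bmi) are carried when available.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "true_age", "predicted_age"}
        if not need <= set(self.frame.columns):
            raise ValidationError(f"PredictionSet needs columns {sorted(need)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in PredictionSet")
        both = self.frame[["true_age", "predicted_age"]].to_numpy(float)
        if not np.all(np.isfinite(both)):
            raise ValidationError("true/predicted ages must be finite")

    @classmethod
    def from_predictions(cls, preds: pd.Series, meta: pd.DataFrame) -> "PredictionSet":
        df = meta.rename(columns={"age": "true_age"}).copy()
        df = df.merge(
            preds.rename("predicted_age"), left_on="sample_id", right_index=True
        )
        return cls(df)

    @property
    def signed_error(self) -> np.ndarray:
        return (self.frame["predicted_age"] - self.frame["true_age"]).to_numpy(float)


@dataclass
class EvalReport:
    """One prediction run's metric set (errors in years)."""

    medae: float
    mae: float
    rmse: float
    r_squared: float | None
    pearson_r: float | None
    n: int
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortComparison:
    mean_error_control: float
    mean_error_case: float
    p_value: float
    p_value_permuted: float
    n_control: int
    n_case: int

    def to_dict(self) -> dict:
        return asdict(self)


def _metrics(true: np.ndarray, pred: np.ndarray) -> dict:
    from sklearn.metrics import (
        mean_absolute_error,
        median_absolute_error,
        mean_squared_error,
        r2_score,
    )

    out = {
        "medae": float(median_absolute_error(true, pred)),
        "mae": float(mean_absolute_error(true, pred)),
        "rmse": float(np.sqrt(mean_squared_error(true, pred))),
        "n": len(true),
    }
    if len(true) < 2 or np.ptp(true) == 0 or np.ptp(pred) == 0:
        # Pearson's r and R^2 are undefined for a single pair or a
        # zero-variance vector (cf. a single-sample verification study)
        if len(true) >= 2 and np.ptp(pred) == 0:
            warnings.warn("zero-variance predictions; correlation undefined", stacklevel=3)
        out["r_squared"] = None if len(true) < 2 else float(r2_score(true, pred))
        out["pearson_r"] = None
    else:
        out["r_squared"] = float(r2_score(true, pred))
        out["pearson_r"] = float(stats.pearsonr(true, pred).statistic)
    return out


def compute_metrics(preds: PredictionSet, by: list[str] | None = None) -> EvalReport:
    """MedAE/MAE/RMSE/R²/Pearson-r for a prediction set.

    ``by`` adds subgroup breakdowns keyed by the given metadata columns
    (e.g. ``["cohort"]`` or ``["sex"]``).
    """
    df = preds.frame
    if len(df) == 0:
        raise ValidationError("empty PredictionSet")
    true = df["true_age"].to_numpy(float)
    pred = df["predicted_age"].to_numpy(float)
    base = _metrics(true, pred)
    subgroups: dict = {}
    for col in by or []:
        for value, sub in df.groupby(col):
            subgroups[f"{col}={value}"] = _metrics(
                sub["true_age"].to_numpy(float), sub["predicted_age"].to_numpy(float)
            )
    return EvalReport(**base, subgroups=subgroups)


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided MW p by full enumeration of label assignments (small n)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = 0
    extreme = 0
    mu = n * m / 2
    d_obs = abs(u_obs - mu)
    for combo in combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            extreme += 1
    return extreme / total


def mann_whitney(x, y) -> float:
    """Two-sided MW U p-value; exact enumeration when both groups <= 8."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if len(x) <= 8 and len(y) <= 8:
        return float(_exact_mw_p(x, y))
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def compare_cohorts(
    preds: PredictionSet, n_permutations: int = 25, seed: int = 0
) -> CohortComparison:
    """Case-vs-control comparison of signed prediction errors.

    The MW test compares ``predicted - true`` between the cohorts; a
    seeded label permutation repeated ``n_permutations`` times gives the
    negative-control p-value (median across repetitions), which should be
    non-significant when the test is calibrated.
    """
    df = preds.frame
    if "cohort" not in df.columns:
        raise ValidationError("PredictionSet lacks a 'cohort' column")
    err = preds.signed_error
    is_case = (df["cohort"] == "case").to_numpy()
    case, ctrl = err[is_case], err[~is_case]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValidationError("both cohorts must be non-empty")
    p = mann_whitney(case, ctrl)
    rng = np.random.default_rng(seed)
    perm_ps = []
    for _ in range(n_permutations):
        lab = rng.permutation(is_case)
        perm_ps.append(mann_whitney(err[lab], err[~lab]))
    return CohortComparison(
        mean_error_control=float(ctrl.mean()),
        mean_error_case=float(case.mean()),
        p_value=p,
        p_value_permuted=float(np.median(perm_ps)),
        n_control=len(ctrl),
        n_case=len(case),
    )


def stratified_errors(
    preds: PredictionSet, age_brackets: list[tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Mean signed/absolute error by sex within (lo, hi] age brackets,
    with a male-vs-female MW p-value per bracket.

    Returns a tidy table: bracket, sex, n, mean_error, mean_abs_error,
    p_value_mw (bracket-level, repeated on both sex rows; NaN when either
    sex is absent or the bracket is empty).
    """
    brackets = age_brackets if age_brackets is not None else DEFAULT_AGE_BRACKETS
    for (lo1, hi1), (lo2, hi2) in zip(brackets, brackets[1:]):
        if lo2 < hi1:
            raise ValidationError("age brackets must be non-overlapping and ordered")
    df = preds.frame.copy()
    if "sex" not in df.columns:
        raise ValidationError("PredictionSet lacks a 'sex' column")
    df["error"] = df["predicted_age"] - df["true_age"]
    rows = []
    for lo, hi in brackets:
        sub = df[(df["true_age"] > lo) & (df["true_age"] <= hi)]
        by_sex = {s: g["error"].to_numpy() for s, g in sub.groupby("sex")}
        if "male" in by_sex and "female" in by_sex:
            p = mann_whitney(by_sex["male"], by_sex["female"])
        else:
            p = np.nan  # single-sex bracket: comparison skipped
        for sex in ("male", "female"):
            e = by_sex.get(sex, np.array([]))
            rows.append(
                {
                    "bracket": f"({lo:g}, {hi:g}]",
                    "sex": sex,
                    "n": len(e),
                    "mean_error": float(e.mean()) if len(e) else np.nan,
                    "mean_abs_error": float(np.abs(e).mean()) if len(e) else np.nan,
                    "p_value_mw": p,
                }
            )
    return pd.DataFrame(rows)


def bmi_effect(preds: PredictionSet):
    """OLS of ``Prediction ~ Actual_Age + Is_Male + BMI``.

    Continuous variables (prediction, age, BMI) are z-scored; the male
    indicator stays 0/1.  Samples without BMI are dropped (count logged as
    a warning).  Returns a statsmodels regression results object whose
    params/pvalues are indexed by const/Actual_Age/Is_Male/BMI.
    """
    import statsmodels.api as sm

    df = preds.frame
    for col in ("bmi", "sex"):
        if col not in df.columns:
            raise ValidationError(f"PredictionSet lacks a '{col}' column")
    n0 = len(df)
    df = df.dropna(subset=["bmi"])
    if n0 - len(df):
        warnings.warn(f"dropped {n0 - len(df)} sample(s) without BMI", stacklevel=2)
    if len(df) < 10:
        raise ValidationError("need >= 10 samples with BMI")

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValidationError("constant regressor makes the design singular")
        return (v - v.mean()) / sd

    X = pd.DataFrame(
        {
            "Actual_Age": z(df["true_age"]),
            "Is_Male": (df["sex"] == "male").astype(float).to_numpy(),
            "BMI": z(df["bmi"]),
        }
    )
    y = z(df["predicted_age"])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model


def clock_overlap(set_a, set_b) -> tuple[int, int, int]:
    """(|A|, |B|, |A ∩ B|) for two CpG panels; duplicates collapse with a
    warning."""
    a, b = list(set_a), list(set_b)
    sa, sb = set(a), set(b)
    if len(sa) != len(a) or len(sb) != len(b):
        warnings.warn("duplicate probe IDs collapsed before overlap", stacklevel=2)
    return len(sa), len(sb), len(sa & sb)
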