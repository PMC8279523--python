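"""Horvath-protocol linear aging clocks.

A linear clock is a weighted sum of CpG beta values plus an intercept.
Following the 353-CpG clock convention, the regression target is a
log-linear transform of age: logarithmic below the adult age (20 years),
linear above it.  Predictions made in transformed space are mapped back to
years with the piecewise inverse

    age = 21 * exp(p) - 1    if p <= 0
    age = 21 * p + 20        if p >  0

which is continuous at p = 0 (both branches give 20 years).  De-novo
clocks are fitted with an elastic net whose penalty strength is chosen by
internal cross-validation at a fixed L1/L2 mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import DegenerateTargetError, HarmonizationError, ValidationError
from .meth_io import BetaMatrix

__all__ = [
    "AgeTransformParams",
    "LinearClock",
    "forward_transform",
    "inverse_transform",
    "predict_linear",
    "fit_elastic_net",
    "elastic_net_cv_predictions",
]


@dataclass(frozen=True)
class AgeTransformParams:
    """The transform's single knob: the adult age (years) where the map
    switches from logarithmic to linear."""

    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.adult_age <= 0:
            raise ValidationError("adult_age must be > 0")


def forward_transform(age, params: AgeTransformParams = AgeTransformParams()):
    """Map age (years) into the clock's regression space.

    ``log((age+1)/(adult+1))`` below the adult age, ``(age-adult)/(adult+1)``
    above; continuous and strictly increasing.  Accepts scalars or arrays.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValidationError("age must be >= 0")
    adult = params.adult_age
    out = np.where(
        a <= adult,
        np.log((a + 1.0) / (adult + 1.0)),
        (a - adult) / (adult + 1.0),
    )
    return out.item() if np.isscalar(age) or np.ndim(age) == 0 else out


def inverse_transform(prediction, params: AgeTransformParams = AgeTransformParams()):
    """Map a transformed-space prediction back to years.

    Exponential branch for p <= 0, linear branch for p > 0; output >= -1.
    """
    p = np.asarray(prediction, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValidationError("prediction must be finite")
    adult = params.adult_age
    out = np.where(
        p <= 0,
        (adult + 1.0) * np.exp(p) - 1.0,
        (adult + 1.0) * p + adult,
    )
    return out.item() if np.isscalar(prediction) or np.ndim(prediction) == 0 else out


@dataclass
class LinearClock:
    """Probe weights + intercept; ``uses_transform`` marks clocks whose raw
    output lives in transformed-age space."""

    weights: dict[str, float]
    intercept: float
    uses_transform: bool = True
    transform_params: AgeTransformParams = field(default_factory=AgeTransformParams)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("clock weights must be non-empty")
        vals = np.fromiter(self.weights.values(), dtype=float)
        if not (np.all(np.isfinite(vals)) and np.isfinite(self.intercept)):
            raise ValidationError("clock coefficients must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)


def predict_linear(
    clock: LinearClock, matrix: BetaMatrix, raw: bool = False
) -> pd.Series:
    """Predict age (years) for every sample in the matrix.

    ``raw=True`` returns the linear combination without the inverse
    transform (debugging aid for transformed-space clocks).
    """
    missing = [p for p in clock.probe_ids if p not in matrix.values.index]
    if missing:
        raise HarmonizationError(
            f"clock probe(s) absent from matrix: {missing[:10]}; "
            "harmonize the matrix to the clock panel first"
        )
    sub = matrix.values.loc[clock.probe_ids]
    if sub.isna().to_numpy().any():
        raise ValidationError("matrix has missing entries at clock probes; impute first")
    w = np.array([clock.weights[p] for p in clock.probe_ids])
    lin = clock.intercept + w @ sub.to_numpy(dtype=float)
    if clock.uses_transform and not raw:
        lin = inverse_transform(lin, clock.transform_params)
    return pd.Series(lin, index=matrix.sample_ids, name="predicted_age")


def fit_elastic_net(
    matrix: BetaMatrix,
    meta: pd.DataFrame,
    params: AgeTransformParams = AgeTransformParams(),
    penalty_mix: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    n_alphas: int = 50,
) -> LinearClock:
    """Fit a de-novo elastic-net clock on forward-transformed ages.

    The penalty strength is chosen by ``cv_folds``-fold internal CV
    minimizing squared error in transformed-age space at the fixed
    ``penalty_mix`` (L1 proportion).  Only probes with nonzero weight are
    retained.  Inputs are z-scored before fitting (glmnet's behavior, and
    what gives the elastic net its grouping effect across correlated
    CpGs); the returned weights are mapped back to the beta scale.  Pass
    ``standardize=False`` to fit on raw beta fractions.
    """
    ages = meta.set_index("sample_id").loc[matrix.sample_ids, "age"].to_numpy(float)
    if len(ages) < 2 * cv_folds:
        raise ValidationError(
            f"need >= {2 * cv_folds} samples for {cv_folds}-fold internal CV"
        )
    if np.ptp(ages) == 0:
        raise DegenerateTargetError("all ages identical; cannot fit an age regression")
    X = matrix.to_feature_array()
    if np.isnan(X).any():
        raise ValidationError("matrix has missing entries; impute before fitting")
    y = forward_transform(ages, params)

    scale = np.ones(X.shape[1])
    center = np.zeros(X.shape[1])
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - center) / scale

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=penalty_mix,
        alphas=n_alphas,  # int: length of the automatic alpha path
        cv=cv,
        max_iter=50_000,
        random_state=seed,
    )
    model.fit(X, y)

    coefs = model.coef_ / scale
    intercept = float(model.intercept_ - np.sum(model.coef_ * center / scale))
    probes = matrix.probe_ids
    weights = {p: float(c) for p, c in zip(probes, coefs) if c != 0.0}
    if not weights:
        # fully-shrunk solution: keep the single largest-path coefficient is
        # meaningless; surface it instead
        raise DegenerateTargetError(
            "elastic net shrank every coefficient to zero; data carry no age signal"
        )
    return LinearClock(
        weights=weights,
        intercept=intercept,
        uses_transform=True,
        transform_params=params,
    )


def elastic_net_cv_predictions(
    matrix: BetaMatrix,
    meta: pd.DataFrame,
    fold_assignment: np.ndarray,
    params: AgeTransformParams = AgeTransformParams(),
    penalty_mix: float = 0.5,
    seed: int = 0,
    **fit_kwargs,
) -> pd.Series:
    """Out-of-fold elastic-net predictions under a supplied fold assignment.

    Each fold's clock is fitted (with its own internal penalty CV) on the
    training portion only, then applied to the held-out samples; useful
    for like-for-like comparison with other clock families on the same
    folds.
    """
    sample_ids = matrix.sample_ids
    oof = pd.Series(np.nan, index=sample_ids, name="predicted_age")
    meta_indexed = meta.set_index("sample_id").loc[sample_ids].reset_index()
    for f in np.unique(fold_assignment):
        tr = fold_assignment != f
        va = ~tr
        tr_matrix = BetaMatrix(matrix.values.loc[:, tr])
        clock = fit_elastic_net(
            tr_matrix, meta_indexed[tr], params=params, penalty_mix=penalty_mix,
            seed=seed, **fit_kwargs,
        )
        va_matrix = BetaMatrix(matrix.values.loc[:, va])
        oof[va] = predict_linear(clock, va_matrix).to_numpy()
    return oof
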