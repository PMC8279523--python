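"""Synthetic methylation cohorts with the structure aging clocks assume.

The generator emulates a pooled multi-study blood-methylation collection:
beta-valued probes, a minority of CpGs drifting with age (linearly or with
exponential saturation), additive per-study batch offsets, case cohorts
whose probes are driven by an accelerated biological age, an optional
BMI-driven shift, and recorded ages that are integer-valued for a fraction
of samples (~17% in real GEO collections).

It deliberately does *not* simulate IDAT intensities, Infinium I/II probe
chemistry, or cell-composition heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .meth_io import BetaMatrix, write_beta_matrix, write_sample_meta

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort", "truncate_ages"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort.

    ``age_effect_scale`` is the typical beta-fraction change per 50 years
    for an informative probe; each probe's own effect is drawn as
    ``sign * U(0.5, 1.5) * age_effect_scale``.  ``case_acceleration_years``
    shifts the *biological* age that drives case samples' probe values,
    not their recorded age.  ``bmi_effect_years_per_sd`` shifts biological
    age per standard deviation of BMI.
    """

    n_samples: int = 400
    n_probes: int = 1000
    n_linear_probes: int = 30
    n_saturating_probes: int = 0
    age_range: tuple[float, float] = (20.0, 75.0)
    beta_noise_sd: float = 0.02
    age_effect_scale: float = 0.15
    integer_age_fraction: float = 0.17
    n_studies: int = 4
    study_offset_sd: float = 0.01
    case_fraction: float = 0.0
    case_acceleration_years: float = 0.0
    bmi_effect_years_per_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        if self.n_linear_probes < 0 or self.n_saturating_probes < 0:
            raise ConfigurationError("informative probe counts must be >= 0")
        if self.n_linear_probes + self.n_saturating_probes > self.n_probes:
            raise ConfigurationError(
                "n_linear_probes + n_saturating_probes exceeds n_probes"
            )
        lo, hi = self.age_range
        if lo < 0 or lo >= hi:
            raise ConfigurationError("age_range must satisfy 0 <= min < max")
        for name in ("integer_age_fraction", "case_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("beta_noise_sd", "study_offset_sd", "age_effect_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    betas: BetaMatrix
    meta: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_beta_matrix(self.betas, out / "betas.tsv")
        write_sample_meta(self.meta, out / "meta.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort; identical config (incl. seed) gives identical output.

    Informative probes respond to *biological* age:
    ``bio_age = chron_age + case_acceleration_years*is_case + bmi_effect*z(BMI)``.
    Linear probes follow ``b0 + s*(bio_age - age_mid)/50``; saturating
    probes follow ``b0 + s*(1 - exp(-bio_age/tau))`` with tau ~ U(10, 30)
    years.  Everything is clipped to [0, 1] after noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    lo, hi = config.age_range
    age_mid = 0.5 * (lo + hi)

    ages = rng.uniform(lo, hi, size=n)
    sex = rng.choice(["male", "female"], size=n)
    is_case = rng.random(n) < config.case_fraction
    study = rng.integers(0, config.n_studies, size=n)
    bmi = np.clip(rng.normal(26.0, 4.0, size=n), 15.0, None)

    bio_age = ages + config.case_acceleration_years * is_case
    if config.bmi_effect_years_per_sd != 0.0:
        z_bmi = (bmi - bmi.mean()) / bmi.std()
        bio_age = bio_age + config.bmi_effect_years_per_sd * z_bmi

    probes = _probe_ids(p)
    n_inf = config.n_linear_probes + config.n_saturating_probes
    informative = rng.choice(p, size=n_inf, replace=False)
    linear_idx = informative[: config.n_linear_probes]
    sat_idx = informative[config.n_linear_probes :]

    # Baselines: bimodal (hypo/hyper-methylated peaks) for background probes;
    # informative probes start mid-range so drift survives clipping.
    peak = rng.random(p) < 0.5
    b0 = np.where(
        peak, rng.normal(0.10, 0.05, size=p), rng.normal(0.85, 0.05, size=p)
    )
    b0[informative] = rng.uniform(0.25, 0.60, size=n_inf)
    b0 = np.clip(b0, 0.01, 0.99)

    effect = np.zeros(p)
    signs = rng.choice([-1.0, 1.0], size=n_inf)
    effect[informative] = signs * rng.uniform(0.5, 1.5, size=n_inf) * config.age_effect_scale
    tau = np.zeros(p)
    tau[sat_idx] = rng.uniform(10.0, 30.0, size=len(sat_idx))

    betas = np.tile(b0[:, None], (1, n))
    if len(linear_idx):
        betas[linear_idx] += np.outer(effect[linear_idx], (bio_age - age_mid) / 50.0)
    if len(sat_idx):
        sat_curve = 1.0 - np.exp(-bio_age[None, :] / tau[sat_idx, None])
        betas[sat_idx] += effect[sat_idx, None] * sat_curve

    offsets = rng.normal(0.0, config.study_offset_sd, size=(p, config.n_studies))
    betas += offsets[:, study]
    if config.beta_noise_sd > 0:
        betas += rng.normal(0.0, config.beta_noise_sd, size=(p, n))
    betas = np.clip(betas, 0.0, 1.0)

    samples = _sample_ids(n)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "age": ages,
            "age_is_integer": False,
            "sex": sex,
            "cohort": np.where(is_case, "case", "control"),
            "study_id": [f"STUDY{j:02d}" for j in study],
            "bmi": np.round(bmi, 2),
        }
    )
    trunc_seed = int(rng.integers(0, 2**31 - 1))
    meta = truncate_ages(meta, config.integer_age_fraction, trunc_seed)

    truth = {
        "linear_probes": [probes[i] for i in linear_idx],
        "saturating_probes": [probes[i] for i in sat_idx],
        "effect_per_probe": {probes[i]: float(effect[i]) for i in informative},
        "tau_per_probe": {probes[i]: float(tau[i]) for i in sat_idx},
        "baseline_per_probe": {probes[i]: float(b0[i]) for i in informative},
        "biological_age": {s: float(a) for s, a in zip(samples, bio_age)},
        "config": asdict(config),
    }
    matrix = BetaMatrix(pd.DataFrame(betas, index=probes, columns=samples))
    return SyntheticCohort(betas=matrix, meta=meta, truth=truth)


def truncate_ages(meta: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Floor the recorded age of a seeded random subset of samples.

    Emulates metadata recorded in whole years: a ``round(fraction * N)``
    subset gets ``age -> floor(age)`` and ``age_is_integer = True``; the
    rest are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    if (meta["age"] < 0).any():
        raise ValidationError("ages must be >= 0")
    out = meta.copy()
    n = len(out)
    k = int(round(fraction * n))
    if k == 0:
        return out
    idx = np.random.default_rng(seed).choice(n, size=k, replace=False)
    pos = out.columns.get_loc("age")
    out.iloc[idx, pos] = np.floor(out.iloc[idx, pos].astype(float))
    out.iloc[idx, out.columns.get_loc("age_is_integer")] = True
    return out
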