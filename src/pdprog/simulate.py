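"""Synthetic longitudinal PD cohorts with the structure the analysis assumes.

The generator draws, per patient, a latent progression subtype (slow/fast), a
latent time shift delta ~ N(0, sigma_delta^2), and per-outcome random
intercepts/slopes from a bivariate normal.  On the normalized (0-1,
higher-is-worse) scale the latent trajectory of outcome k is linear,

    v_ijk = b_k + beta_age,k * (age_i - 62) + beta_sex,k * sex_i
            + gamma_k(subtype_i) * (t_ij + delta_i)
            + a0_ik + a1_ik * t_ij + eps_ijk ,

after which values are mapped back to the raw scale of the outcome (with
direction flip for higher-is-better scales), clipped to the theoretical range
and, for ordinal scales, rounded to integers.  Visit schedules are irregular
(jittered), entries are deleted at a configurable missingness rate, and
subtype-linked mortality can be generated on top.

By default the subtype affects only the slopes (minor baseline differences,
large progression-speed differences); an optional baseline offset flag adds
subtype differences at baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    LongitudinalCohort,
    OutcomeSpec,
    SurvivalTable,
    default_outcome_specs,
    rng_from_seed,
)


@dataclass
class OutcomeGenParams:
    """Generating parameters for one outcome, on the normalized scale."""

    baseline_mean: float          # normalized units at t=0 for the mean patient
    slope_slow: float             # normalized units / year, slow subtype
    slope_fast: float             # normalized units / year, fast subtype
    intercept_sd: float = 0.05    # random-intercept SD
    slope_sd: float = 0.004       # random-slope SD (within subtype)
    intercept_slope_corr: float = 0.3
    resid_sd: float = 0.025       # residual SD
    beta_age: float = 0.0015      # per year of age at diagnosis (centred at 62)
    beta_sex: float = 0.01        # sex = 1 effect
    baseline_offset_fast: float = 0.0  # optional subtype baseline difference


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults emulate an early-PD observational cohort: a 25% fast-progressing
    subtype separated from the slow subtype in progression speed (slope
    standardized mean difference around 4 within-outcome), a latent time-shift
    SD of 3 years, roughly annual visits over ~5 years of follow-up, and 10%
    completely-at-random missingness.
    """

    n_patients: int = 200
    fraction_fast: float = 0.25
    specs: dict[str, OutcomeSpec] = field(default_factory=default_outcome_specs)
    outcome_params: dict[str, OutcomeGenParams] = field(default_factory=dict)
    sigma_delta: float = 3.0            # years
    visit_interval: float = 1.0         # mean years between visits
    visit_jitter_sd: float = 0.1        # years
    n_visits: int = 6
    missing_rate: float = 0.10
    age_mean: float = 62.0
    age_sd: float = 9.0
    fraction_female: float = 0.35
    clip: bool = True
    round_ordinal: bool = True
    # survival: exponential (or Weibull) with subtype-dependent hazard
    hazard_baseline: float = 0.03       # events / year, slow subtype
    log_hr_fast: float = np.log(3.4)
    weibull_shape: float = 1.0          # 1.0 = exponential
    censor_horizon: float = 12.0        # years of administrative censoring
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_fast <= 1.0:
            raise ValueError("fraction_fast must lie in [0, 1]")
        if self.n_visits < 1 and self.n_patients > 0:
            raise ValueError("degenerate visit schedule: need >= 1 visit")
        if self.sigma_delta < 0 or self.visit_jitter_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not self.outcome_params:
            self.outcome_params = default_outcome_gen_params()
        unknown = set(self.outcome_params) - set(self.specs)
        if unknown:
            raise ValueError(f"outcome_params for unspecified outcomes: {sorted(unknown)}")


def default_outcome_gen_params() -> dict[str, OutcomeGenParams]:
    """Per-outcome generating parameters for the seven-outcome PD battery.

    Normalized slopes around 1-2 %/year (slow) vs 2.5-5 %/year (fast) mirror
    clinically plausible progression (e.g. ~2 UPDRS-III points/year on a
    132-point scale for a slow progressor).  Baseline severities emulate a
    mid-stage cohort, keeping trajectories away from the scale boundaries so
    that range clipping stays rare in the calibration fixtures.
    """
    return {
        "updrs1": OutcomeGenParams(0.20, 0.014, 0.032),
        "updrs2": OutcomeGenParams(0.20, 0.015, 0.034),
        "updrs3": OutcomeGenParams(0.25, 0.016, 0.036),
        "updrs4": OutcomeGenParams(0.15, 0.010, 0.026, intercept_sd=0.04),
        "pigd":   OutcomeGenParams(0.18, 0.013, 0.030, intercept_sd=0.04),
        "moca":   OutcomeGenParams(0.18, 0.008, 0.022),
        "scopa":  OutcomeGenParams(0.22, 0.012, 0.028),
    }


def _normalized_to_raw(v: np.ndarray, spec: OutcomeSpec) -> np.ndarray:
    if spec.higher_is_worse:
        return spec.theoretical_min + spec.range * v
    return spec.theoretical_min + spec.range * (1.0 - v)


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> LongitudinalCohort:
    """Draw a synthetic cohort; ground truth is recorded per patient.

    The clipping rate (fraction of measurements clipped to the theoretical
    range) is stored in ``cohort.metadata["clip_rate"]`` so calibration tests
    can require it to stay small.
    """
    rng = rng_from_seed(cfg.seed if seed is None else seed)
    outcomes = sorted(cfg.outcome_params)
    n, K = cfg.n_patients, len(outcomes)

    subtype = (rng.random(n) < cfg.fraction_fast).astype(int)  # 1 = fast
    delta = rng.normal(0.0, cfg.sigma_delta, size=n)
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    sex = (rng.random(n) < cfg.fraction_female).astype(int)

    # per-outcome bivariate random effects (independent across outcomes)
    a0 = np.empty((n, K))
    a1 = np.empty((n, K))
    for k, name in enumerate(outcomes):
        p = cfg.outcome_params[name]
        cov = np.array(
            [[p.intercept_sd**2, p.intercept_slope_corr * p.intercept_sd * p.slope_sd],
             [p.intercept_slope_corr * p.intercept_sd * p.slope_sd, p.slope_sd**2]]
        )
        re = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        a0[:, k], a1[:, k] = re[:, 0], re[:, 1]

    rows = []
    n_clipped = 0
    n_total = 0
    for i in range(n):
        t = cfg.visit_interval * np.arange(cfg.n_visits) + np.concatenate(
            [[0.0], rng.normal(0.0, cfg.visit_jitter_sd, size=max(cfg.n_visits - 1, 0))]
        )
        t = np.maximum.accumulate(np.maximum(t, 0.0))  # keep visits ordered, >= 0
        for k, name in enumerate(outcomes):
            p = cfg.outcome_params[name]
            spec = cfg.specs[name]
            gamma = p.slope_fast if subtype[i] else p.slope_slow
            base = p.baseline_mean + (p.baseline_offset_fast if subtype[i] else 0.0)
            v = (
                base
                + p.beta_age * (age[i] - cfg.age_mean)
                + p.beta_sex * sex[i]
                + gamma * (t + delta[i])
                + a0[i, k]
                + a1[i, k] * t
                + rng.normal(0.0, p.resid_sd, size=len(t))
            )
            raw = _normalized_to_raw(v, spec)
            if cfg.clip:
                clipped = np.clip(raw, spec.theoretical_min, spec.theoretical_max)
                n_clipped += int(np.sum(clipped != raw))
                raw = clipped
            n_total += len(raw)
            if cfg.round_ordinal and spec.scale_type in ("ordinal", "binary"):
                raw = np.round(raw)
            miss = rng.random(len(t)) < cfg.missing_rate
            for j in range(len(t)):
                if not miss[j]:
                    rows.append((f"p{i:04d}", j, float(t[j]), name, float(raw[j])))

    measurements = pd.DataFrame(rows, columns=["patient_id", "visit", "time_years", "outcome", "value"])
    pid = [f"p{i:04d}" for i in range(n)]
    covariates = pd.DataFrame(
        {"patient_id": pid, "age_at_diagnosis": age, "sex": sex}
    )
    gt = pd.DataFrame({"patient_id": pid, "true_subtype": subtype, "true_delta": delta})
    for k, name in enumerate(outcomes):
        gt[f"a0_{name}"] = a0[:, k]
        gt[f"a1_{name}"] = a1[:, k]

    # drop patients that lost all but <2 visits to missingness
    nvis = measurements.groupby("patient_id")["visit"].nunique()
    keep = set(nvis.index[nvis >= 2])
    measurements = measurements[measurements["patient_id"].isin(keep)].reset_index(drop=True)
    covariates = covariates[covariates["patient_id"].isin(keep)].reset_index(drop=True)
    gt = gt[gt["patient_id"].isin(keep)].reset_index(drop=True)

    cohort = LongitudinalCohort(measurements, covariates, dict(cfg.specs), ground_truth=gt)
    cohort.metadata["clip_rate"] = n_clipped / max(n_total, 1)
    cohort.metadata["generator"] = {"fraction_fast": cfg.fraction_fast, "n_patients": n}
    return cohort


def generate_survival(
    cohort: LongitudinalCohort, cfg: GeneratorConfig, seed: int | None = None
) -> SurvivalTable:
    """Event times from a Weibull (shape 1 = exponential) hazard, multiplied by
    exp(log-HR) for the fast subtype; administrative censoring at the horizon."""
    if cohort.ground_truth is None:
        raise ValueError("generate_survival requires ground truth (synthetic cohort)")
    if cfg.hazard_baseline <= 0:
        raise ValueError("baseline hazard must be positive")
    if cfg.censor_horizon <= 0:
        raise ValueError("degenerate censoring horizon: all observations censored at 0")
    rng = rng_from_seed(cfg.seed if seed is None else seed)
    gt = cohort.ground_truth.merge(cohort.covariates, on="patient_id")
    lam = cfg.hazard_baseline * np.exp(cfg.log_hr_fast * gt["true_subtype"].to_numpy())
    u = rng.random(len(gt))
    # Weibull PH: S(t) = exp(-lam * t^shape)
    t_event = (-np.log(u) / lam) ** (1.0 / cfg.weibull_shape)
    event = (t_event <= cfg.censor_horizon).astype(int)
    time = np.minimum(t_event, cfg.censor_horizon)
    time = np.maximum(time, 1e-9)
    df = pd.DataFrame(
        {
            "patient_id": gt["patient_id"],
            "time_years": time,
            "event": event,
            "subtype": gt["true_subtype"].to_numpy(),
            "age_at_diagnosis": gt["age_at_diagnosis"].to_numpy(),
            "sex": gt["sex"].to_numpy(),
        }
    )
    return SurvivalTable(df)


# ---------------------------------------------------------------------------
# Named fixtures

_FIXTURE_SEEDS = {"well_separated": 96241, "overlapping": 96242, "null_one_subtype": 96243}


def fixture_config(name: str) -> GeneratorConfig:
    """Generator configuration behind each named fixture."""
    if name == "well_separated":
        return GeneratorConfig(n_patients=200, fraction_fast=0.25, seed=_FIXTURE_SEEDS[name])
    if name == "overlapping":
        params = default_outcome_gen_params()
        for p in params.values():  # shrink the subtype slope gap to ~1 within-SD
            mid = 0.5 * (p.slope_slow + p.slope_fast)
            p.slope_slow = mid - 0.5 * p.slope_sd
            p.slope_fast = mid + 0.5 * p.slope_sd
        return GeneratorConfig(
            n_patients=200, fraction_fast=0.25, outcome_params=params, seed=_FIXTURE_SEEDS[name]
        )
    if name == "null_one_subtype":
        return GeneratorConfig(n_patients=200, fraction_fast=0.0, seed=_FIXTURE_SEEDS[name])
    raise KeyError(f"unknown fixture {name!r}")


def make_fixture(name: str) -> LongitudinalCohort:
    """Named, seeded cohort presets.

    - ``well_separated``: two subtypes, slope SMD ~4 per outcome (ground-truth
      slope separation >= 2 within-subtype SDs).
    - ``overlapping``: subtype slope gap shrunk to ~1 within-subtype SD.
    - ``null_one_subtype``: fraction_fast = 0, a single generative class.
    - ``tiny_worked``: 8 patients x 3 visits x 2 outcomes, noiseless, with
      hand-computable expected intermediates (see :func:`tiny_worked_truth`).
    """
    if name == "tiny_worked":
        return _tiny_worked_cohort()
    return generate_cohort(fixture_config(name))


def _tiny_worked_cohort() -> LongitudinalCohort:
    """Deterministic 8-patient, 2-outcome, 3-visit cohort.

    No noise, no random effects.  Normalized trajectories are exactly
    v = b_k + gamma_k * (t + delta_i) with gamma = (0.02, 0.04) for the slow
    (patients 0-5) and fast (patients 6-7) subtype respectively, b = (0.1, 0.2)
    and delta alternating (-1, 0, +1, ...) years; visits at t = 0, 1, 2.
    Outcomes: 'a' on [0, 100] higher-is-worse, 'b' on [0, 50] higher-is-better
    (so stored raw values of 'b' are inverted).
    """
    specs = {
        "a": OutcomeSpec("a", 0, 100, True, "continuous", "motor"),
        "b": OutcomeSpec("b", 0, 50, False, "continuous", "cognition"),
    }
    deltas = [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0, -1.0, 0.0]
    subtype = [0, 0, 0, 0, 0, 0, 1, 1]
    gammas = {0: {"a": 0.02, "b": 0.01}, 1: {"a": 0.05, "b": 0.03}}
    base = {"a": 0.10, "b": 0.20}
    rows = []
    for i in range(8):
        for j, t in enumerate([0.0, 1.0, 2.0]):
            for name, spec in specs.items():
                v = base[name] + gammas[subtype[i]][name] * (t + deltas[i])
                rows.append((f"p{i:04d}", j, t, name, float(_normalized_to_raw(np.array(v), spec))))
    measurements = pd.DataFrame(rows, columns=["patient_id", "visit", "time_years", "outcome", "value"])
    covariates = pd.DataFrame(
        {"patient_id": [f"p{i:04d}" for i in range(8)],
         "age_at_diagnosis": [62.0] * 8, "sex": [0] * 8}
    )
    gt = pd.DataFrame(
        {"patient_id": [f"p{i:04d}" for i in range(8)],
         "true_subtype": subtype, "true_delta": deltas}
    )
    return LongitudinalCohort(measurements, covariates, specs, ground_truth=gt)


def tiny_worked_truth() -> dict:
    """Hand-computed generating quantities for the tiny_worked fixture."""
    return {
        "gamma_normalized": {"slow": {"a": 0.02, "b": 0.01}, "fast": {"a": 0.05, "b": 0.03}},
        "baseline_normalized": {"a": 0.10, "b": 0.20},
        "delta": [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0, -1.0, 0.0],
        "subtype": [0, 0, 0, 0, 0, 0, 1, 1],
        "visits": [0.0, 1.0, 2.0],
    }
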