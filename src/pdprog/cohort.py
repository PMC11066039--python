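"""Shared data model for longitudinal Parkinson's-disease cohorts.

The universal input of the pipeline is a long-format table of repeated
clinical-outcome measurements (one row per patient / visit / outcome) together
with per-patient covariates (age at clinical diagnosis, sex) and a registry of
outcome specifications (theoretical score range, direction, scale type, symptom
domain).  Time is measured in years since clinical diagnosis throughout; the
visit index is ordinal bookkeeping only.

Missing outcomes at a visit are represented by absent rows (sparse long
format), never by sentinel values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pdprog")

MEASUREMENT_COLUMNS = ["patient_id", "visit", "time_years", "outcome", "value"]
COVARIATE_COLUMNS = ["patient_id", "age_at_diagnosis", "sex"]

#: on-disk dialect: comma-separated, UTF-8, '.' decimal, "NA" for missing
NA_TOKEN = "NA"


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Specification of one clinical outcome scale.

    Parameters
    ----------
    name : str
        Outcome identifier as used in the measurement table.
    theoretical_min, theoretical_max : float
        Theoretical range of the score (not the observed range).
    higher_is_worse : bool
        Direction of the scale.  Scales where high values mean *less* severe
        symptoms (e.g. MoCA) are inverted during normalization so that, after
        normalization, higher always means worse.
    scale_type : {"continuous", "ordinal", "binary"}
        Drives the choice of progression model during characterization.
    symptom_domain : str
        Clinical domain used to group outcomes for the meta-analysis.
    """

    name: str
    theoretical_min: float
    theoretical_max: float
    higher_is_worse: bool
    scale_type: str = "continuous"
    symptom_domain: str = "other"

    def __post_init__(self) -> None:
        if not self.theoretical_min < self.theoretical_max:
            raise SchemaError(
                f"outcome {self.name!r}: theoretical_min must be < theoretical_max"
            )
        if self.scale_type not in ("continuous", "ordinal", "binary"):
            raise SchemaError(
                f"outcome {self.name!r}: unknown scale_type {self.scale_type!r}"
            )

    @property
    def range(self) -> float:
        return self.theoretical_max - self.theoretical_min


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """The seven-outcome PD battery used for model fitting and clustering.

    Analogues of MDS-UPDRS parts I-IV, the postural-instability/gait-difficulty
    (PIGD) sub-score, MoCA (inverted: higher is better) and SCOPA-AUT, with
    their theoretical ranges.
    """
    specs = [
        OutcomeSpec("updrs1", 0, 52, True, "ordinal", "non_motor"),
        OutcomeSpec("updrs2", 0, 52, True, "ordinal", "motor"),
        OutcomeSpec("updrs3", 0, 132, True, "ordinal", "motor"),
        OutcomeSpec("updrs4", 0, 24, True, "ordinal", "motor_complications"),
        OutcomeSpec("pigd", 0, 4, True, "continuous", "axial"),
        OutcomeSpec("moca", 0, 30, False, "ordinal", "cognition"),
        OutcomeSpec("scopa", 0, 69, True, "ordinal", "autonomic"),
    ]
    return {s.name: s for s in specs}


@dataclass
class LongitudinalCohort:
    """Long-format repeated outcome measurements plus per-patient covariates.

    ``measurements`` has columns patient_id, visit, time_years, outcome, value;
    ``covariates`` has columns patient_id, age_at_diagnosis, sex (0/1 coded,
    with the mapping recorded in ``metadata``).  ``ground_truth`` is present
    only for synthetic cohorts and carries the generating subtype, latent time
    shift and random effects per patient.
    """

    measurements: pd.DataFrame
    covariates: pd.DataFrame
    specs: dict[str, OutcomeSpec]
    ground_truth: pd.DataFrame | None = None
    metadata: dict = field(default_factory=lambda: {"sex_coding": {"male": 0, "female": 1}})

    @property
    def patients(self) -> np.ndarray:
        return np.asarray(sorted(self.covariates["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.measurements["outcome"].unique())

    def subset(self, patient_ids) -> "LongitudinalCohort":
        ids = set(patient_ids)
        gt = None
        if self.ground_truth is not None:
            gt = self.ground_truth[self.ground_truth["patient_id"].isin(ids)].reset_index(drop=True)
        return LongitudinalCohort(
            measurements=self.measurements[self.measurements["patient_id"].isin(ids)].reset_index(drop=True),
            covariates=self.covariates[self.covariates["patient_id"].isin(ids)].reset_index(drop=True),
            specs=self.specs,
            ground_truth=gt,
            metadata=dict(self.metadata),
        )


@dataclass
class SurvivalTable:
    """Per-patient survival data on the common disease timescale.

    One row per patient: time_years (strictly positive, measured on the common
    timescale from its shifted origin), event (1 = death observed, 0 =
    censored), and covariates subtype, age_at_diagnosis, sex.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "time_years", "event", "subtype", "age_at_diagnosis", "sex"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"survival table missing columns {sorted(missing)}")
        if (self.data["time_years"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")


def validate_cohort(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame,
    specs: dict[str, OutcomeSpec],
    ground_truth: pd.DataFrame | None = None,
) -> tuple[LongitudinalCohort, pd.DataFrame]:
    """Validate raw frames into a :class:`LongitudinalCohort`.

    Rows violating the outcome range, referencing an unknown outcome, or
    duplicating a (patient, visit, outcome) key are rejected; patients left
    with fewer than two distinct visits are excluded (the inclusion criterion
    requires longitudinal information).  Returns the cohort and a diagnostics
    frame with one row per rejected row / excluded patient.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise SchemaError(f"measurement table missing columns {sorted(missing)}")
    missing = set(COVARIATE_COLUMNS) - set(covariates.columns)
    if missing:
        raise SchemaError(f"covariate table missing columns {sorted(missing)}")

    m = measurements.copy()
    problems: list[dict] = []

    unknown = ~m["outcome"].isin(specs)
    for idx in m.index[unknown]:
        problems.append({"kind": "unknown_outcome", "patient_id": m.at[idx, "patient_id"],
                         "detail": str(m.at[idx, "outcome"])})
    m = m[~unknown]

    lo = m["outcome"].map(lambda o: specs[o].theoretical_min)
    hi = m["outcome"].map(lambda o: specs[o].theoretical_max)
    bad = m["value"].notna() & ((m["value"] < lo) | (m["value"] > hi))
    for idx in m.index[bad]:
        problems.append({"kind": "out_of_range", "patient_id": m.at[idx, "patient_id"],
                         "detail": f"{m.at[idx, 'outcome']}={m.at[idx, 'value']}"})
    m = m[~bad]
    m = m[m["value"].notna()]

    dup = m.duplicated(subset=["patient_id", "visit", "outcome"], keep="first")
    for idx in m.index[dup]:
        problems.append({"kind": "duplicate", "patient_id": m.at[idx, "patient_id"],
                         "detail": f"visit={m.at[idx, 'visit']} outcome={m.at[idx, 'outcome']}"})
    m = m[~dup]

    # inclusion criterion: at least two distinct visits per patient
    nvisits = m.groupby("patient_id")["visit"].nunique()
    keep = set(nvisits.index[nvisits >= 2])
    dropped = sorted(set(m["patient_id"]) - keep)
    for pid in dropped:
        problems.append({"kind": "lt_two_visits", "patient_id": pid, "detail": ""})
    if dropped:
        warnings.warn(f"excluded {len(dropped)} patient(s) with < 2 visits", stacklevel=2)
    m = m[m["patient_id"].isin(keep)]

    cov = covariates[covariates["patient_id"].isin(keep)].reset_index(drop=True)
    no_cov = keep - set(cov["patient_id"])
    if no_cov:
        raise SchemaError(f"patients without covariate rows: {sorted(no_cov)[:5]} ...")
    gt = None
    if ground_truth is not None:
        gt = ground_truth[ground_truth["patient_id"].isin(keep)].reset_index(drop=True)

    cohort = LongitudinalCohort(
        measurements=m.reset_index(drop=True),
        covariates=cov,
        specs=specs,
        ground_truth=gt,
    )
    diagnostics = pd.DataFrame(problems, columns=["kind", "patient_id", "detail"])
    return cohort, diagnostics


def read_cohort(path, specs: dict[str, OutcomeSpec]) -> LongitudinalCohort:
    """Read a cohort directory of CSVs (measurements.csv, covariates.csv,
    optionally ground_truth.csv) and validate it."""
    path = Path(path)
    meas = pd.read_csv(path / "measurements.csv", na_values=[NA_TOKEN])
    cov = pd.read_csv(path / "covariates.csv", na_values=[NA_TOKEN])
    gt_path = path / "ground_truth.csv"
    gt = pd.read_csv(gt_path, na_values=[NA_TOKEN]) if gt_path.exists() else None
    cohort, diagnostics = validate_cohort(meas, cov, specs, gt)
    if len(diagnostics):
        logger.info("read_cohort: rejected %d row(s)/patient(s)", len(diagnostics))
    return cohort


def read_outcome_specs(path) -> dict[str, OutcomeSpec]:
    df = pd.read_csv(path)
    required = {"name", "min", "max", "higher_is_worse", "scale_type", "domain"}
    if not required <= set(df.columns):
        raise SchemaError(f"spec table missing columns {sorted(required - set(df.columns))}")
    return {
        r["name"]: OutcomeSpec(r["name"], r["min"], r["max"],
                               bool(r["higher_is_worse"]), r["scale_type"], r["domain"])
        for _, r in df.iterrows()
    }


def write_outcome_specs(specs: dict[str, OutcomeSpec], path) -> None:
    rows = [
        {"name": s.name, "min": s.theoretical_min, "max": s.theoretical_max,
         "higher_is_worse": s.higher_is_worse, "scale_type": s.scale_type,
         "domain": s.symptom_domain}
        for s in specs.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=NA_TOKEN)


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.measurements.to_csv(path / "measurements.csv", index=False, na_rep=NA_TOKEN)
    cohort.covariates.to_csv(path / "covariates.csv", index=False, na_rep=NA_TOKEN)
    write_outcome_specs(cohort.specs, path / "outcome_specs.csv")
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(path / "ground_truth.csv", index=False, na_rep=NA_TOKEN)
    with open(path / "metadata.json", "w") as fh:
        json.dump(cohort.metadata, fh, indent=1)


def write_results(obj, path) -> None:
    """Serialize any pipeline product to ``path``.

    DataFrames go to a single CSV; dataclass products go to a directory of
    flat tables plus a JSON metadata sidecar via their own ``to_dir`` method;
    plain dicts go to JSON.  Round-trip reads reproduce the object bit-exactly
    for integer/string fields and to full stored precision for floats (floats
    are written with repr-level precision).
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.17g")
    elif hasattr(obj, "to_dir"):
        obj.to_dir(path)
    elif isinstance(obj, LongitudinalCohort):
        write_cohort(obj, path)
    elif isinstance(obj, SurvivalTable):
        obj.data.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.17g")
    elif dataclasses.is_dataclass(obj):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(obj), fh, indent=1, default=_json_default)
    elif isinstance(obj, dict):
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=_json_default)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Uniform seeding contract: every randomized operation accepts a seed."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    rng = rng_from_seed(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
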