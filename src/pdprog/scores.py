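"""Outcome normalization and standardized progression scores.

Outcomes are min-max normalized on their *theoretical* range and
direction-aligned (higher-is-better scales such as MoCA are inverted), so that
after normalization every outcome lies in [0, 1] and higher means worse.

From a fitted LTJMM, model-predicted trajectories are evaluated on a regular
grid of the common disease timescale and converted into *outcome progression
scores*: the predicted value at common time t minus the predicted value at the
common-timescale origin, divided by the cross-patient standard deviation of
the predicted value at the origin.  Scores are therefore 0 at the origin by
construction and are measured in SD-at-origin units; under the linear model
they are exactly linear in t with slope (gamma_k + a1_ik) / sd0_k.

Because the scores are functions of the *fitted model*, trajectories are
evaluated on the full grid by default; an alternative mode masks grid points
outside each patient's observed common-timescale window (the clustering stage
has its own imputation mechanism for such masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import NA_TOKEN, OutcomeSpec, SchemaError


def normalize_outcome(values, spec: OutcomeSpec) -> np.ndarray:
    """Min-max normalize onto [0, 1] with direction alignment.

    v' = (v - min) / (max - min); if higher is better, v' <- 1 - v'.
    Invertible via :func:`denormalize_outcome`.  Values outside the
    theoretical range raise (validation happens upstream).
    """
    if spec.range <= 0:
        raise SchemaError(f"outcome {spec.name!r}: degenerate range")
    v = np.asarray(values, float)
    finite = np.isfinite(v)
    if np.any((v[finite] < spec.theoretical_min) | (v[finite] > spec.theoretical_max)):
        raise ValueError(f"value outside theoretical range of {spec.name!r}")
    out = (v - spec.theoretical_min) / spec.range
    if not spec.higher_is_worse:
        out = 1.0 - out
    return out


def denormalize_outcome(values, spec: OutcomeSpec) -> np.ndarray:
    v = np.asarray(values, float)
    if not spec.higher_is_worse:
        v = 1.0 - v
    return spec.theoretical_min + spec.range * v


@dataclass
class ProgressionScoreTensor:
    """Patients x grid-timepoints x outcomes array of progression scores.

    ``values[i, g, k]`` is patient i's score for outcome k at common-timescale
    grid point g (SD-at-origin units); ``mask`` is True where the score is
    defined.  ``sd0`` holds the per-outcome cross-patient SD of the predicted
    value at the origin (sample SD, n-1 denominator).
    """

    values: np.ndarray
    mask: np.ndarray
    grid: np.ndarray
    patients: list[str]
    outcomes: list[str]
    sd0: np.ndarray
    dropped_outcomes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.values.shape == self.mask.shape
        assert self.values.shape == (len(self.patients), len(self.grid), len(self.outcomes))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subset(self, indices) -> "ProgressionScoreTensor":
        indices = np.asarray(indices)
        return ProgressionScoreTensor(
            values=self.values[indices], mask=self.mask[indices], grid=self.grid,
            patients=[self.patients[i] for i in indices], outcomes=self.outcomes,
            sd0=self.sd0, dropped_outcomes=list(self.dropped_outcomes),
        )

    # -- serialization: one wide CSV per outcome plus a mask CSV ------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cols = [f"t{g:g}" for g in self.grid]
        for k, name in enumerate(self.outcomes):
            vals = np.where(self.mask[:, :, k], self.values[:, :, k], np.nan)
            df = pd.DataFrame(vals, columns=cols)
            df.insert(0, "patient_id", self.patients)
            df.to_csv(path / f"scores_{name}.csv", index=False, na_rep=NA_TOKEN,
                      float_format="%.17g")
        import json

        with open(path / "scores.json", "w") as fh:
            json.dump(
                {"grid": self.grid.tolist(), "outcomes": self.outcomes,
                 "sd0": self.sd0.tolist(), "dropped_outcomes": self.dropped_outcomes},
                fh, indent=1,
            )

    @classmethod
    def from_dir(cls, path) -> "ProgressionScoreTensor":
        import json

        path = Path(path)
        with open(path / "scores.json") as fh:
            meta = json.load(fh)
        grid = np.asarray(meta["grid"], float)
        outcomes = meta["outcomes"]
        frames = [pd.read_csv(path / f"scores_{o}.csv", na_values=[NA_TOKEN]) for o in outcomes]
        patients = list(frames[0]["patient_id"])
        values = np.stack([f.iloc[:, 1:].to_numpy(float) for f in frames], axis=2)
        mask = np.isfinite(values)
        values = np.nan_to_num(values)
        return cls(values=values, mask=mask, grid=grid, patients=patients,
                   outcomes=outcomes, sd0=np.asarray(meta["sd0"], float),
                   dropped_outcomes=meta.get("dropped_outcomes", []))


def compute_progression_scores(
    fit,
    t_max: float = 8.0,
    step: float = 1.0,
    measurements: pd.DataFrame | None = None,
    extrapolate: bool = True,
) -> ProgressionScoreTensor:
    """Evaluate LTJMM-predicted trajectories on a common-timescale grid and
    standardize them into progression scores.

    For each patient and outcome the model prediction at common time s is
    y-hat(s) = x'beta + gamma s + a0 + a1 (s - delta) (observed time
    t = s - delta), and

        score(s) = (y-hat(s) - y-hat(0)) / sd0_k ,

    with sd0_k the sample SD across patients of y-hat(0).  Outcomes with
    sd0_k = 0 are dropped with a warning.  Because the scores are built from
    *model-predicted* trajectories, they are evaluated on the full grid by
    default; passing ``extrapolate=False`` together with ``measurements``
    (the cohort's long table) instead masks grid points outside a patient's
    observed window [min t + delta, max t + delta], for sensitivity analysis.
    Requires at least 2 patients.
    """
    import warnings

    p = fit.params
    n, K = len(p.patients), len(p.outcomes)
    if n < 2:
        raise ValueError("progression scores need >= 2 patients (cross-patient SD)")
    grid = np.arange(0.0, t_max + 0.5 * step, step)
    # predicted value at common time s: observed time is s - delta_i
    s = grid[None, :]                                   # (1, G)
    t_obs = s - p.delta[:, None]                        # (n, G)
    yhat = np.empty((n, len(grid), K))
    for k in range(K):
        fixed = fit.X @ p.beta[k]                       # (n,)
        yhat[:, :, k] = (
            fixed[:, None] + p.gamma[k] * s + p.alpha0[:, k][:, None]
            + p.alpha1[:, k][:, None] * t_obs
        )
    y0 = yhat[:, 0, :]                                  # (n, K) value at origin
    sd0 = np.std(y0, axis=0, ddof=1)
    keep = sd0 > 0
    dropped = [p.outcomes[k] for k in range(K) if not keep[k]]
    if dropped:
        warnings.warn(f"dropping outcomes with zero SD at origin: {dropped}", stacklevel=2)
    scores = (yhat - y0[:, None, :]) / np.where(sd0 > 0, sd0, 1.0)

    mask = np.ones_like(scores, dtype=bool)
    if measurements is not None and not extrapolate:
        window = measurements.groupby("patient_id")["time_years"].agg(["min", "max"])
        pidx = {pid: i for i, pid in enumerate(p.patients)}
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
        for pid, row in window.iterrows():
            if pid in pidx:
                i = pidx[pid]
                lo[i] = row["min"] + p.delta[i]
                hi[i] = row["max"] + p.delta[i]
        inside = (s >= lo[:, None]) & (s <= hi[:, None])   # (n, G)
        mask = np.broadcast_to(inside[:, :, None], scores.shape).copy()

    return ProgressionScoreTensor(
        values=scores[:, :, keep], mask=mask[:, :, keep], grid=grid,
        patients=list(p.patients), outcomes=[o for o, k in zip(p.outcomes, keep) if k],
        sd0=sd0[keep], dropped_outcomes=dropped,
    )


def slope_features(scores: ProgressionScoreTensor) -> np.ndarray:
    """Per-patient per-outcome score slope, the sufficient statistic of the
    linear model: least-squares slope of score against grid time over the
    unmasked grid points (patients with < 2 unmasked points fall back to the
    all-point fit)."""
    n, G, K = scores.values.shape
    out = np.zeros((n, K))
    t = scores.grid
    for i in range(n):
        for k in range(K):
            m = scores.mask[i, :, k]
            tt = t[m] if m.sum() >= 2 else t
            vv = scores.values[i, m, k] if m.sum() >= 2 else scores.values[i, :, k]
            tc = tt - tt.mean()
            denom = np.sum(tc**2)
            out[i, k] = np.sum(tc * vv) / denom if denom > 0 else 0.0
    return out
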