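"""Shared fixtures: the expensive cohort fits are computed once per session."""

import numpy as np
import pytest

import pdprog as pp


@pytest.fixture(scope="session")
def well_separated():
    return pp.make_fixture("well_separated")


@pytest.fixture(scope="session")
def well_separated_fit(well_separated):
    return pp.fit_ltjmm(well_separated)


@pytest.fixture(scope="session")
def well_separated_scores(well_separated_fit):
    return pp.compute_progression_scores(well_separated_fit)


@pytest.fixture(scope="session")
def well_separated_truth(well_separated, well_separated_fit):
    gt = well_separated.ground_truth.set_index("patient_id")
    gt = gt.loc[well_separated_fit.params.patients]
    return gt


@pytest.fixture(scope="session")
def null_cohort():
    return pp.make_fixture("null_one_subtype")


@pytest.fixture(scope="session")
def null_scores(null_cohort):
    return pp.compute_progression_scores(pp.fit_ltjmm(null_cohort))


@pytest.fixture(scope="session")
def tiny_worked():
    return pp.make_fixture("tiny_worked")


def make_score_tensor(values, mask=None, grid=None, outcomes=None):
    """Wrap a raw (n, T, K) array into a ProgressionScoreTensor for tests."""
    values = np.asarray(values, float)
    n, T, K = values.shape
    return pp.ProgressionScoreTensor(
        values=values,
        mask=np.ones_like(values, bool) if mask is None else mask,
        grid=np.arange(T, dtype=float) if grid is None else np.asarray(grid, float),
        patients=[f"p{i:04d}" for i in range(n)],
        outcomes=[f"o{k}" for k in range(K)] if outcomes is None else list(outcomes),
        sd0=np.ones(K),
    )
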