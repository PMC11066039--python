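"""Subtype characterization: mixed-model coefficients, SMDs, meta-analysis,
baseline associations, survival, ANCOVA, multiplicity control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import pdprog as pp
from pdprog.characterize import (ModelError, _pool, adjusted_comparison,
                                 baseline_association, bh_adjust, cox_ph,
                                 fit_outcome_progression, meta_analyze_domain,
                                 progression_coefficients, smd)
from pdprog.cluster import SubtypeAssignment
from pdprog.simulate import fixture_config, generate_cohort


def _long(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time", "value"])


# ---------------------------------------------------------------------------
# progression models


def test_noiseless_common_slope_coefficients():
    rows = [(f"p{i}", t, 0.1 + 0.03 * t) for i in range(15) for t in range(4)]
    co = fit_outcome_progression(_long(rows))
    np.testing.assert_allclose(co["coefficient"], 0.03, atol=1e-6)


def test_blup_coefficients_are_shrunk():
    """Sample variance of BLUP-based per-patient coefficients does not exceed
    the generating slope variance."""
    rng = np.random.default_rng(0)
    true_sd = 0.05
    rows = []
    for i in range(60):
        s = 0.1 + rng.normal(0, true_sd)
        for t in range(4):
            rows.append((f"p{i:02d}", t, s * t + rng.normal(0, 0.15)))
    co = fit_outcome_progression(_long(rows))
    assert co["coefficient"].var(ddof=1) <= true_sd**2 * 1.05


@pytest.mark.parametrize("family", ["binary", "ordinal"])
def test_glmm_recovers_slope_direction_and_magnitude(family):
    rng = np.random.default_rng(1)
    rows = []
    true_slope = 0.5
    cuts = np.array([0.0, 1.5, 3.0])
    for i in range(50):
        u0, u1 = rng.normal(0, 0.5), rng.normal(0, 0.15)
        for t in range(5):
            eta = -0.5 + true_slope * t + u0 + u1 * t
            if family == "binary":
                y = float(rng.random() < expit(eta))
            else:
                y = int(np.sum(rng.random() > expit(cuts - eta)))
            rows.append((f"p{i:02d}", t, y))
    co = fit_outcome_progression(_long(rows), family)
    assert co["coefficient"].mean() == pytest.approx(true_slope, abs=0.2)


def test_ordinal_with_many_levels_falls_back_to_linear():
    rng = np.random.default_rng(2)
    rows = [(f"p{i}", t, float(rng.integers(0, 40)) ) for i in range(10) for t in range(3)]
    co = fit_outcome_progression(_long(rows), "ordinal")  # runs via linear path
    assert len(co) == 10


def test_inclusion_filters_exclude_sparse_outcome(well_separated_fit):
    """An outcome observed in only 4 patients is excluded (minimum 5 per
    subtype, 30 total)."""
    c = pp.make_fixture("well_separated")
    delta = pp.common_timescale(well_separated_fit)
    gt = c.ground_truth.set_index("patient_id").loc[well_separated_fit.params.patients]
    labels = gt["true_subtype"].to_numpy()
    asg = SubtypeAssignment(patients=list(well_separated_fit.params.patients),
                            labels=labels, probabilities=np.eye(2)[labels],
                            semantic_map={0: "slow", 1: "fast"})
    keep = c.measurements["patient_id"].isin(set(list(c.patients[:4])))
    sparse = c.measurements.copy()
    sparse = pd.concat([
        sparse[sparse["outcome"] != "scopa"],
        sparse[(sparse["outcome"] == "scopa") & keep],
    ])
    c_sparse = pp.LongitudinalCohort(sparse.reset_index(drop=True), c.covariates, c.specs,
                                     c.ground_truth)
    assert progression_coefficients(c_sparse, delta, asg, "scopa") is None
    assert progression_coefficients(c_sparse, delta, asg, "updrs3") is not None


# ---------------------------------------------------------------------------
# SMD


def test_smd_examples():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 40)
    g, v = smd(x, x)
    assert g == 0.0 and v > 0
    g2, _ = smd(np.zeros(50) + rng.normal(0, 1, 50), 1 + rng.normal(0, 1, 50))
    assert g2 == pytest.approx(-1.0, abs=0.35)
    with pytest.raises(ModelError):
        smd([1.0], [1.0, 2.0])
    with pytest.raises(ModelError):
        smd([1.0, 1.0], [1.0, 1.0])


def test_smd_unbiased_at_true_effect():
    """Hedges correction: mean estimate over 1000 replicates within 3 MC SEs
    of the generating d = -0.8."""
    rng = np.random.default_rng(4)
    ests = []
    for _ in range(1000):
        slow = rng.normal(0.0, 1.0, 50)
        fast = rng.normal(0.8, 1.0, 50)
        ests.append(smd(slow, fast)[0])
    ests = np.asarray(ests)
    mcse = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - (-0.8)) < 3 * mcse


# ---------------------------------------------------------------------------
# meta-analysis


def test_single_effect_passthrough():
    eff = pd.DataFrame({"domain": ["d"], "outcome": ["o"], "cohort": ["c1"],
                        "estimate": [0.4], "variance": [0.01]})
    de = meta_analyze_domain(eff)
    assert de.estimate == pytest.approx(0.4)
    assert "single_effect" in de.flags
    assert de.ci_low <= de.estimate <= de.ci_high


def test_equal_effects_zero_heterogeneity():
    eff = pd.DataFrame({"domain": ["d"] * 4, "outcome": list("abcd"),
                        "cohort": ["c1", "c1", "c2", "c2"],
                        "estimate": [0.3] * 4, "variance": [0.02] * 4})
    de = meta_analyze_domain(eff)
    assert de.estimate == pytest.approx(0.3)
    assert de.tau2_cohort == pytest.approx(0.0, abs=1e-5)


def test_ci_coverage_with_between_cohort_heterogeneity():
    """Two-level simulation with known tau^2: 95% CI coverage of the true
    overall effect lies in [0.90, 0.99] over 500 replicates."""
    rng = np.random.default_rng(5)
    tau, mu_true = 0.2, -0.5
    covered = 0
    reps = 500
    for _ in range(reps):
        cohort_means = mu_true + rng.normal(0, tau, 3)
        y = cohort_means[:, None] + rng.normal(0, 0.2, (3, 4))
        eff = pd.DataFrame({
            "domain": "d", "outcome": [f"o{j}" for _ in range(3) for j in range(4)],
            "cohort": np.repeat(["c1", "c2", "c3"], 4),
            "estimate": y.ravel(), "variance": 0.04,
        })
        de = meta_analyze_domain(eff)
        covered += de.ci_low <= mu_true <= de.ci_high
    assert 0.90 <= covered / reps <= 0.99


def test_bh_examples():
    padj, lvl = bh_adjust([0.01, 0.04], alpha=0.05)
    np.testing.assert_allclose(padj, [0.02, 0.04])
    assert lvl == pytest.approx(0.95)
    padj2, _ = bh_adjust([0.2, 0.2, 0.2])
    np.testing.assert_allclose(padj2, [0.2, 0.2, 0.2])   # all equal -> unchanged
    empty, lvl0 = bh_adjust([])
    assert empty.size == 0 and lvl0 == 0.95
    padj3, _ = bh_adjust(np.linspace(0.001, 0.9, 10))
    assert np.all(np.diff(padj3[np.argsort(np.linspace(0.001, 0.9, 10))]) >= 0)
    assert np.all(padj3 <= 1.0)


# ---------------------------------------------------------------------------
# baseline association


def _assignment_from_truth(cohort, fit):
    gt = cohort.ground_truth.set_index("patient_id").loc[fit.params.patients]
    labels = gt["true_subtype"].to_numpy()
    return SubtypeAssignment(patients=list(fit.params.patients), labels=labels,
                             probabilities=np.eye(2)[labels],
                             semantic_map={0: "slow", 1: "fast"})


def test_baseline_association_null_and_signal():
    cfg = fixture_config("well_separated")
    cfg.n_patients = 150
    # subtype affects baseline severity of updrs3 only
    cfg.outcome_params["updrs3"].baseline_offset_fast = 0.15
    c = generate_cohort(cfg, seed=31)
    fit = pp.fit_ltjmm(c)
    asg = _assignment_from_truth(c, fit)
    delta = pp.common_timescale(fit)
    with_signal = baseline_association(c, "updrs3", asg, delta)
    # more severe baseline associates with fast: negative by the convention
    assert with_signal["estimate"] < 0
    assert with_signal["p"] < 0.05
    null = baseline_association(c, "moca", asg, delta)
    assert null["p"] > 0.001  # no generating baseline difference

    single = SubtypeAssignment(patients=asg.patients,
                               labels=np.zeros(len(asg.patients), int),
                               probabilities=np.ones((len(asg.patients), 1)))
    with pytest.raises(ModelError):
        baseline_association(c, "updrs3", single, delta)


def test_baseline_association_recovers_known_log_odds():
    """Direct logistic recovery: baseline value drawn so the generating
    log-odds coefficient is 1; mean estimate over 300 replicates within 3 MC
    SEs (sign flipped by the reporting convention)."""
    rng = np.random.default_rng(6)
    specs = {"x": pp.OutcomeSpec("x", 0, 1, True)}
    ests = []
    for _ in range(300):
        x = rng.random(300)
        y = (rng.random(300) < expit(-0.5 + 1.0 * x)).astype(int)
        meas = pd.DataFrame({"patient_id": [f"p{i}" for i in range(300)],
                             "visit": 0, "time_years": 0.0, "outcome": "x", "value": x})
        extra = meas.assign(visit=1, time_years=1.0)
        cohort = pp.LongitudinalCohort(pd.concat([meas, extra]),
                                       pd.DataFrame({"patient_id": meas["patient_id"],
                                                     "age_at_diagnosis": 60.0, "sex": 0}),
                                       specs)
        asg = SubtypeAssignment(patients=list(meas["patient_id"]), labels=y,
                                probabilities=np.eye(2)[y],
                                semantic_map={0: "slow", 1: "fast"})
        delta = pd.DataFrame({"patient_id": meas["patient_id"], "delta": 0.0})
        res = baseline_association(cohort, "x", asg, delta, adjust_duration=False)
        ests.append(-res["estimate"])   # undo the sign convention
    ests = np.asarray(ests)
    mcse = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - 1.0) < 3 * mcse


# ---------------------------------------------------------------------------
# survival


def test_cox_identical_groups_hr_near_one():
    rng = np.random.default_rng(7)
    n = 400
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "time_years": rng.exponential(5, n) + 1e-3,
        "event": 1,
        "subtype": rng.integers(0, 2, n),
        "age_at_diagnosis": rng.normal(62, 8, n),
        "sex": rng.integers(0, 2, n),
    })
    res = cox_ph(pp.SurvivalTable(df)).set_index("covariate")
    assert res.loc["subtype", "hr_ci_low"] <= 1.0 <= res.loc["subtype", "hr_ci_high"]


def test_cox_no_events_rejected():
    df = pd.DataFrame({"patient_id": ["a", "b"], "time_years": [1.0, 2.0],
                       "event": [0, 0], "subtype": [0, 1],
                       "age_at_diagnosis": [60.0, 61.0], "sex": [0, 1]})
    with pytest.raises(ModelError):
        cox_ph(pp.SurvivalTable(df))


# ---------------------------------------------------------------------------
# ANCOVA


def test_adjusted_comparison_controls_for_confounding_covariate():
    """Groups that differ only through the covariate: the adjusted group
    effect rejects at about the nominal rate."""
    rng = np.random.default_rng(8)
    rejections = 0
    reps = 200
    for _ in range(reps):
        n = 200
        dur = np.concatenate([rng.normal(2, 1, n // 2), rng.normal(4, 1, n // 2)])
        value = 2.0 * dur + rng.normal(0, 1, n)          # value driven by duration only
        labels = np.repeat([0, 1], n // 2)
        asg = SubtypeAssignment(patients=[f"p{i}" for i in range(n)], labels=labels,
                                probabilities=np.eye(2)[labels],
                                semantic_map={0: "slow", 1: "fast"})
        df = pd.DataFrame({"patient_id": asg.patients, "value": value, "duration": dur})
        rejections += adjusted_comparison(df, asg)["p"] < 0.05
    assert rejections / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_adjusted_comparison_degenerate_inputs():
    labels = np.array([0, 0, 1, 1])
    asg = SubtypeAssignment(patients=list("abcd"), labels=labels,
                            probabilities=np.eye(2)[labels],
                            semantic_map={0: "slow", 1: "fast"})
    df = pd.DataFrame({"patient_id": list("abcd"), "value": 1.0, "duration": [1, 2, 3, 4]})
    with pytest.raises(ModelError):
        adjusted_comparison(df, asg)


# ---------------------------------------------------------------------------
# end-to-end characterization signs


def test_characterization_sign_coherence(well_separated, well_separated_fit):
    """Every domain whose generating slopes favour the fast subtype pools to
    a negative SMD (fast progresses faster -> slow minus fast < 0)."""
    asg = _assignment_from_truth(well_separated, well_separated_fit)
    delta = pp.common_timescale(well_separated_fit)
    table = pp.characterize_progression({"sim": (well_separated, delta, asg)})
    assert len(table) > 0
    assert (table["estimate"] < 0).all()
    assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
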