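"""Subtype prediction, enrichment curves and trial sample-size machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pdprog as pp
from pdprog.simulate import fixture_config, generate_cohort
from pdprog.trial import (TrialDesign, VarianceComponents, build_features,
                          default_trial_components, edland_sample_size,
                          enrichment_curve, mixture_components,
                          nested_cv_predict, power_from_n,
                          predict_probabilities, sample_size_vs_enrichment,
                          simulate_trial_power)


# ---------------------------------------------------------------------------
# features


def _cohort(n=60, seed=1):
    cfg = fixture_config("well_separated")
    cfg.n_patients = n
    return generate_cohort(cfg, seed=seed)


def test_baseline_features_shape():
    c = _cohort()
    f = build_features(c, "baseline")
    predictor_cols = [col for col in f.columns if col.endswith("_bl")]
    assert len(predictor_cols) == 6          # UPDRS I-III, PIGD, MoCA, SCOPA analogues
    assert {"age_at_diagnosis", "sex"} <= set(f.columns)
    assert "updrs4_bl" not in f.columns      # excluded from the predictor set


def test_plus1y_mode_doubles_predictors_and_applies_window():
    c = _cohort()
    f = build_features(c, "baseline_plus_1y")
    cols_1y = [col for col in f.columns if col.endswith("_1y")]
    assert len(cols_1y) == 6
    # a patient whose only follow-up is outside [0.5, 1.5] years is excluded
    m = pd.DataFrame({
        "patient_id": ["a"] * 4, "visit": [0, 0, 1, 1],
        "time_years": [0.0, 0.0, 1.6, 1.6],
        "outcome": ["updrs1", "moca", "updrs1", "moca"],
        "value": [5.0, 28.0, 7.0, 27.0],
    })
    cov = pd.DataFrame({"patient_id": ["a"], "age_at_diagnosis": [60.0], "sex": [0]})
    c2 = pp.LongitudinalCohort(m, cov, pp.default_outcome_specs())
    assert len(build_features(c2, "baseline_plus_1y")) == 0
    assert len(build_features(c2, "baseline")) == 1


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        build_features(_cohort(n=5), "weekly")


# ---------------------------------------------------------------------------
# nested CV


def _gauss_features(n, auc, n_noise=4, prevalence=0.3, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    d = np.sqrt(2) * stats.norm.ppf(auc)
    X = rng.normal(0, 1, (n, 1 + n_noise))
    X[:, 0] += d * y
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(1 + n_noise)]), y


def test_chance_level_auc_on_independent_labels():
    feats, y = _gauss_features(400, auc=0.75, seed=1)
    rng = np.random.default_rng(2)
    res = nested_cv_predict(feats, rng.permutation(y),
                            outer_repeats=3, inner_repeats=1, seed=3)
    assert 0.45 <= res["mean_auc"] <= 0.55


def test_perfectly_separable_auc():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 30)
    X = pd.DataFrame({"f0": y * 10.0 + rng.normal(0, 0.01, 60)})
    res = nested_cv_predict(X, y, outer_repeats=2, inner_repeats=1, seed=5)
    assert res["mean_auc"] >= 0.99


def test_nested_cv_contracts():
    feats, y = _gauss_features(30, auc=0.7)
    with pytest.raises(ValueError):
        nested_cv_predict(feats, np.zeros(30, int), seed=0)
    with pytest.raises(ValueError):
        nested_cv_predict(feats.iloc[:20], y[:20], seed=0)


def test_transfer_auc_close_to_in_cohort():
    """A predictor trained on cohort A applied to a matched-process cohort B
    scores within 0.1 of B's in-cohort AUC."""
    from sklearn.metrics import roc_auc_score

    feats_a, y_a = _gauss_features(400, auc=0.80, seed=6)
    feats_b, y_b = _gauss_features(400, auc=0.80, seed=7)
    res_a = nested_cv_predict(feats_a, y_a, outer_repeats=3, inner_repeats=1, seed=8)
    res_b = nested_cv_predict(feats_b, y_b, outer_repeats=3, inner_repeats=1, seed=9)
    auc_transfer = roc_auc_score(y_b, predict_probabilities(res_a, feats_b))
    assert abs(auc_transfer - res_b["mean_auc"]) <= 0.1


# ---------------------------------------------------------------------------
# enrichment curve


def test_enrichment_curve_endpoints_and_perfect_classifier():
    y = np.repeat([1, 0], [30, 70])
    perfect = y.astype(float)
    cur = enrichment_curve(perfect, y)
    first = cur.iloc[0]
    assert first["fraction_eligible"] == 1.0
    assert first["fraction_fast_among_selected"] == pytest.approx(0.3)
    at_half = cur[cur["threshold"] == 0.5].iloc[0]
    assert at_half["fraction_fast_among_selected"] == 1.0
    assert at_half["fraction_eligible"] == pytest.approx(0.3)
    assert (np.diff(cur["fraction_eligible"]) <= 1e-12).all()


def test_enrichment_flat_under_random_probabilities():
    rng = np.random.default_rng(10)
    n = 10000
    y = (rng.random(n) < 0.25).astype(int)
    probs = rng.random(n)
    cur = enrichment_curve(probs, y)
    keep = cur[cur["fraction_eligible"] >= 0.10]
    assert np.all(np.abs(keep["fraction_fast_among_selected"] - 0.25) <= 0.02)


def test_enrichment_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        enrichment_curve(np.array([0.5, 1.2]), np.array([0, 1]))


# ---------------------------------------------------------------------------
# Edland closed form


def test_edland_formula_scaling():
    d = TrialDesign()
    vc = VarianceComponents(mean_slope=3.0, slope_sd_between_subjects=2.5, residual_sd=5.0)
    n1 = edland_sample_size(d, vc).n_per_arm
    d2 = TrialDesign(effect=0.6)                 # Delta doubled -> n quartered
    n2 = edland_sample_size(d2, vc).n_per_arm
    assert abs(n1 / 4 - n2) <= 1.0
    # halving both variance contributions halves n (pre-ceiling)
    sxx = d.sxx
    vc_half = VarianceComponents(3.0, vc.slope_sd_between_subjects / np.sqrt(2),
                                 vc.residual_sd / np.sqrt(2))
    n3 = edland_sample_size(d, vc_half).n_per_arm
    assert abs(n1 / 2 - n3) <= 1.0
    assert edland_sample_size(d, vc).achieved_power_closed_form >= d.target_power


def test_edland_degenerate_designs():
    vc = VarianceComponents(3.0, 2.5, 5.0)
    with pytest.raises(ValueError):
        TrialDesign(visit_times=(0.0,))
    with pytest.raises(ValueError):
        edland_sample_size(TrialDesign(), VarianceComponents(0.0, 2.5, 5.0))
    zero_spread = TrialDesign(visit_times=(1.0, 1.0))
    with pytest.raises(ValueError):
        edland_sample_size(zero_spread, vc)


def test_mixture_components_collapse_at_endpoints():
    comp = default_trial_components()
    at0 = mixture_components(comp["slow"], comp["fast"], 0.0)
    at1 = mixture_components(comp["slow"], comp["fast"], 1.0)
    assert at0 == comp["slow"]
    assert at1 == comp["fast"]


def test_sample_size_vs_enrichment_monotone():
    comp = default_trial_components()
    tab = sample_size_vs_enrichment(TrialDesign(), comp["slow"], comp["fast"])
    assert (np.diff(tab["total_n"]) <= 0).all()
    pure_fast = tab[tab["fraction_fast"] == 1.0]["total_n"].iloc[0]
    prevalence = tab.iloc[(tab["fraction_fast"] - comp["fraction_fast"]).abs().argmin()]
    assert pure_fast < prevalence["total_n"]


# ---------------------------------------------------------------------------
# trial simulator


def test_trial_simulator_type_i_error_near_alpha():
    d = TrialDesign()
    vc = mixture_components(**{
        "vc_slow": default_trial_components()["slow"],
        "vc_fast": default_trial_components()["fast"],
        "fraction_fast": 0.25,
    })
    rate = simulate_trial_power(d, vc, n_per_arm=200, reps=1000, effect=0.0, seed=1)
    assert rate == pytest.approx(d.alpha, abs=0.03)


def test_trial_simulator_full_effect_power_one():
    d = TrialDesign()
    vc = VarianceComponents(mean_slope=5.0, slope_sd_between_subjects=0.1, residual_sd=0.1)
    power = simulate_trial_power(d, vc, n_per_arm=20, reps=200, effect=1.0, seed=2)
    assert power >= 0.99


def test_closed_form_matches_monte_carlo_across_grid():
    """|analytic - Monte Carlo| power within 3 points across a grid of
    effect sizes and variance settings."""
    d0 = TrialDesign()
    for effect in (0.2, 0.3, 0.5):
        for sd_s, sd_e in ((1.5, 4.0), (2.5, 5.0)):
            d = TrialDesign(effect=effect)
            vc = VarianceComponents(3.0, sd_s, sd_e)
            n = edland_sample_size(d, vc).n_per_arm
            analytic = power_from_n(d, vc, n)
            mc = simulate_trial_power(d, vc, n, reps=600, seed=hash((effect, sd_s)) % 2**31)
            assert abs(analytic - mc) <= 0.035 + 2 * np.sqrt(mc * (1 - mc) / 600)


def test_plus1y_auc_beats_baseline_on_informative_fixture():
    """Follow-up adds slope information: baseline+1y AUC >= baseline AUC on
    average over seeds (subtypes differ in slopes, not baselines)."""
    diffs = []
    for seed in range(4):
        cfg = fixture_config("well_separated")
        cfg.n_patients = 150
        cfg.missing_rate = 0.0
        c = generate_cohort(cfg, seed=100 + seed)
        truth = c.ground_truth.set_index("patient_id")["true_subtype"]
        f_bl = build_features(c, "baseline")
        f_1y = build_features(c, "baseline_plus_1y")
        y_bl = truth.loc[f_bl["patient_id"]].to_numpy()
        y_1y = truth.loc[f_1y["patient_id"]].to_numpy()
        a_bl = nested_cv_predict(f_bl, y_bl, outer_repeats=2, inner_repeats=1,
                                 seed=seed)["mean_auc"]
        a_1y = nested_cv_predict(f_1y, y_1y, outer_repeats=2, inner_repeats=1,
                                 seed=seed)["mean_auc"]
        diffs.append(a_1y - a_bl)
    assert np.mean(diffs) >= 0.0
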