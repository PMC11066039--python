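"""Statistical characterization of progression subtypes.

Per subtype and outcome, progression is modeled on the common disease
timescale with a mixed-effects model matched to the scale type (linear for
continuous scores, mixed-effects logistic for binary items, cumulative-logit
for ordinal items; both GLMMs use a per-patient Laplace approximation).
Per-patient progression coefficients (fixed slope + random-slope BLUP) are
compared between subtypes as Hedges-corrected standardized mean differences
(SMDs), pooled per symptom domain by a three-level random-effects
meta-analysis (outcomes within cohorts, then across cohorts), and corrected
for multiple testing across domains with the Benjamini-Hochberg procedure.

Sign convention (progression): SMD = (slow - fast) / pooled SD, so a faster
fast subtype gives a *negative* SMD.  Baseline associations report the
logistic coefficient oriented the same way: negative values mean more severe
baseline symptoms associate with the fast subtype.

Survival differences are quantified by a Cox proportional-hazards model
(subtype, age, sex; common disease timescale as time variable), and
single-visit cross-sectional measurements (digital gait style) by an ANCOVA
controlling for common-timescale disease duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import LongitudinalCohort, SurvivalTable
from .scores import normalize_outcome

logger = logging.getLogger("pdprog")

MIN_PATIENTS_TOTAL = 30
MIN_PATIENTS_PER_SUBTYPE = 5
MAX_ORDINAL_LEVELS = 10


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Per-patient progression coefficients


def fit_outcome_progression(df: pd.DataFrame, scale_type: str = "continuous") -> pd.DataFrame:
    """Per-patient progression coefficients for one outcome within one subtype.

    ``df`` needs columns patient_id, time (common timescale, years) and value
    (normalized, direction-aligned).  Continuous: linear mixed model with
    random intercept + slope; per-patient coefficient = fixed slope + slope
    BLUP.  Binary: mixed-effects logistic (Laplace).  Ordinal: cumulative
    logit mixed model (Laplace); ordinal outcomes with more than
    ``MAX_ORDINAL_LEVELS`` observed levels fall back to the linear model.
    Patients need >= 2 measurements.

    Returns a frame (patient_id, coefficient).
    """
    counts = df.groupby("patient_id")["value"].size()
    keep = counts.index[counts >= 2]
    df = df[df["patient_id"].isin(keep)]
    if df["patient_id"].nunique() < 2:
        raise ModelError("need >= 2 patients with >= 2 measurements")
    if scale_type == "ordinal" and df["value"].nunique() > MAX_ORDINAL_LEVELS:
        scale_type = "continuous"
    if scale_type == "continuous":
        return _linear_mixed_coefficients(df)
    if scale_type == "binary":
        return _glmm_coefficients(df, family="binomial")
    if scale_type == "ordinal":
        return _glmm_coefficients(df, family="cumlogit")
    raise ValueError(f"unknown scale_type {scale_type!r}")


def _linear_mixed_coefficients(df: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.formula.api as smf

    data = df.rename(columns={"time": "t"})[["patient_id", "t", "value"]].copy()
    if np.allclose(data["value"].var(), 0.0):
        # degenerate: identical trajectories; slope from pooled OLS
        slope = np.polyfit(data["t"], data["value"], 1)[0]
        pats = sorted(data["patient_id"].unique())
        return pd.DataFrame({"patient_id": pats, "coefficient": slope})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("value ~ t", data, groups=data["patient_id"], re_formula="~t")
        try:
            fit = md.fit(reml=True, method="lbfgs")
        except Exception:
            fit = md.fit(reml=False)
    slope = fit.fe_params["t"]
    rows = []
    re = fit.random_effects
    for pid in sorted(data["patient_id"].unique()):
        b = re.get(pid, None)
        b_t = float(b.get("t", 0.0)) if b is not None else 0.0
        rows.append({"patient_id": pid, "coefficient": float(slope) + b_t})
    return pd.DataFrame(rows)


# ---- generic 2-D Laplace GLMM (binary / cumulative-logit) -----------------


def _cumlogit_eta_terms(y_codes, cut, eta):
    """log-likelihood, d/deta and d2/deta2 of the cumulative-logit likelihood."""
    L = len(cut) + 1
    hi = np.where(y_codes < L - 1, cut[np.minimum(y_codes, L - 2)] - eta, np.inf)
    lo = np.where(y_codes > 0, cut[np.maximum(y_codes - 1, 0)] - eta, -np.inf)
    Fhi, Flo = special.expit(hi), special.expit(lo)
    fhi = np.where(np.isfinite(hi), Fhi * (1 - Fhi), 0.0)
    flo = np.where(np.isfinite(lo), Flo * (1 - Flo), 0.0)
    dfhi = np.where(np.isfinite(hi), fhi * (1 - 2 * Fhi), 0.0)
    dflo = np.where(np.isfinite(lo), flo * (1 - 2 * Flo), 0.0)
    P = np.maximum(Fhi - Flo, 1e-12)
    ll = np.log(P)
    g = -(fhi - flo) / P                              # d ll / d eta
    h = (dfhi - dflo) / P - ((fhi - flo) / P) ** 2    # d2 ll / d eta2
    return ll, g, h


def _binom_eta_terms(y, eta):
    p = special.expit(eta)
    ll = y * eta - np.log1p(np.exp(np.clip(eta, -30, 30)))
    g = y - p
    h = -p * (1 - p)
    return ll, g, h


def _glmm_laplace_nll(theta, groups, family, n_cut):
    """Negative Laplace marginal log-likelihood.

    theta = [slope, (cutpoints increments | intercept), log sd0, log sd1,
    atanh(rho)].  Random effects per patient: (u0, u1) on the linear
    predictor eta = fixed + u0 + u1 * t.
    """
    slope = theta[0]
    if family == "cumlogit":
        raw = theta[1: 1 + n_cut]
        cut = np.cumsum(np.concatenate([[raw[0]], np.exp(raw[1:])])) if n_cut > 1 else raw
        fixed_intercept = 0.0
        rest = theta[1 + n_cut:]
    else:
        fixed_intercept = theta[1]
        cut = None
        rest = theta[2:]
    sd0, sd1 = np.exp(rest[0]), np.exp(rest[1])
    rho = np.tanh(rest[2])
    Sigma = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
    try:
        Sinv = np.linalg.inv(Sigma)
        logdetS = np.log(np.linalg.det(Sigma))
    except np.linalg.LinAlgError:
        return 1e10
    total = 0.0
    modes = {}
    for pid, (t, y) in groups.items():
        u = np.zeros(2)
        Zu = np.column_stack([np.ones(len(t)), t])
        for _ in range(50):
            eta = fixed_intercept + slope * t + Zu @ u
            if family == "binomial":
                ll, g, h = _binom_eta_terms(y, eta)
            else:
                ll, g, h = _cumlogit_eta_terms(y, cut, eta)
            grad = Zu.T @ g - Sinv @ u
            H = (Zu * h[:, None]).T @ Zu - Sinv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad * 0.01
            u_new = u - step
            if np.max(np.abs(u_new - u)) < 1e-8:
                u = u_new
                break
            u = np.clip(u_new, -20, 20)
        eta = fixed_intercept + slope * t + Zu @ u
        if family == "binomial":
            ll, g, h = _binom_eta_terms(y, eta)
        else:
            ll, g, h = _cumlogit_eta_terms(y, cut, eta)
        H = (Zu * h[:, None]).T @ Zu - Sinv
        sign, logdetH = np.linalg.slogdet(-H)
        if sign <= 0:
            return 1e10
        joint = np.sum(ll) - 0.5 * u @ Sinv @ u - 0.5 * logdetS - np.log(2 * np.pi)
        total += joint + np.log(2 * np.pi) - 0.5 * logdetH
        modes[pid] = u.copy()
    _glmm_laplace_nll.last_modes = modes
    return -total


def _glmm_coefficients(df: pd.DataFrame, family: str) -> pd.DataFrame:
    groups = {}
    if family == "cumlogit":
        levels = np.sort(df["value"].unique())
        codes = {v: i for i, v in enumerate(levels)}
        n_cut = len(levels) - 1
        if n_cut < 1:
            raise ModelError("ordinal outcome with a single observed level")
    else:
        vals = set(df["value"].unique())
        if not vals <= {0, 1} and not vals <= {0.0, 1.0}:
            # normalized binary values are 0/1 already by construction
            df = df.assign(value=(df["value"] > 0.5).astype(float))
        n_cut = 0
    for pid, g in df.groupby("patient_id"):
        t = g["time"].to_numpy(float)
        if family == "cumlogit":
            y = np.array([codes[v] for v in g["value"]])
        else:
            y = g["value"].to_numpy(float)
        groups[pid] = (t, y)

    if family == "cumlogit":
        # init cutpoints from marginal frequencies
        freq = np.array([(df["value"] == v).mean() for v in levels])
        cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
        c0 = special.logit(cum)
        raw0 = np.concatenate([[c0[0]], np.log(np.maximum(np.diff(c0), 1e-3))]) if n_cut > 1 else c0
        theta0 = np.concatenate([[0.0], raw0, [np.log(0.5), np.log(0.1), 0.0]])
    else:
        p0 = np.clip(df["value"].mean(), 1e-3, 1 - 1e-3)
        theta0 = np.array([0.0, special.logit(p0), np.log(0.5), np.log(0.1), 0.0])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            _glmm_laplace_nll, theta0, args=(groups, family, n_cut),
            method="L-BFGS-B", options={"maxiter": 200},
        )
    _glmm_laplace_nll(res.x, groups, family, n_cut)  # refresh modes at optimum
    modes = _glmm_laplace_nll.last_modes
    slope = res.x[0]
    rows = [{"patient_id": pid, "coefficient": float(slope + modes[pid][1])}
            for pid in sorted(groups)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subtype comparison machinery


def progression_coefficients(
    cohort: LongitudinalCohort,
    delta: pd.DataFrame,
    assignment,
    outcome: str,
) -> pd.DataFrame | None:
    """Apply inclusion filters and fit one progression model per subtype.

    Filters: >= 30 patients with the outcome in total, >= 5 per subtype,
    >= 2 measurements per patient.  Returns (patient_id, subtype,
    coefficient) or None when the outcome is excluded (reason logged).
    """
    spec = cohort.specs[outcome]
    m = cohort.measurements[cohort.measurements["outcome"] == outcome]
    dmap = dict(zip(delta["patient_id"], delta["delta"]))
    lab = dict(zip(assignment.patients, assignment.semantic_labels()
                   if assignment.semantic_map else assignment.labels.astype(str)))
    df = pd.DataFrame({
        "patient_id": m["patient_id"],
        "time": m["time_years"] + m["patient_id"].map(dmap),
        "value": normalize_outcome(m["value"].to_numpy(float), spec),
    })
    df["subtype"] = df["patient_id"].map(lab)
    df = df.dropna(subset=["subtype", "time"])
    counts = df.groupby("patient_id").size()
    df = df[df["patient_id"].isin(counts.index[counts >= 2])]
    n_total = df["patient_id"].nunique()
    if n_total < MIN_PATIENTS_TOTAL:
        logger.info("outcome %s excluded: %d < %d patients", outcome, n_total, MIN_PATIENTS_TOTAL)
        return None
    per = df.groupby("subtype")["patient_id"].nunique()
    if len(per) < 2 or per.min() < MIN_PATIENTS_PER_SUBTYPE:
        logger.info("outcome %s excluded: < %d patients in a subtype", outcome,
                    MIN_PATIENTS_PER_SUBTYPE)
        return None
    # resolve the ordinal->linear fallback once on the whole outcome, so both
    # subtypes are modeled on the same scale (coefficients must be comparable)
    scale = spec.scale_type
    if scale == "ordinal" and df["value"].nunique() > MAX_ORDINAL_LEVELS:
        scale = "continuous"
    out = []
    for st, g in df.groupby("subtype"):
        coefs = fit_outcome_progression(g[["patient_id", "time", "value"]], scale)
        coefs["subtype"] = st
        out.append(coefs)
    return pd.concat(out, ignore_index=True)


def smd(slow: np.ndarray, fast: np.ndarray) -> tuple[float, float]:
    """Hedges-corrected standardized mean difference (slow - fast)/pooled SD
    with its variance; negative when the fast group progresses faster.
    Raises on groups of size < 2 or zero pooled SD.
    """
    slow, fast = np.asarray(slow, float), np.asarray(fast, float)
    n1, n2 = len(slow), len(fast)
    if n1 < 2 or n2 < 2:
        raise ModelError("both groups need >= 2 observations")
    s2 = ((n1 - 1) * slow.var(ddof=1) + (n2 - 1) * fast.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ModelError("zero pooled SD: SMD undefined")
    d = (slow.mean() - fast.mean()) / np.sqrt(s2)
    df_ = n1 + n2 - 2
    J = 1.0 - 3.0 / (4.0 * df_ - 1.0)
    g = J * d
    var = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(g), float(var)


# ---------------------------------------------------------------------------
# Random-effects meta-analysis (three-level: outcomes within cohorts)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML between-effect heterogeneity, DerSimonian-Laird fallback."""
    k = len(y)
    if k < 2:
        return 0.0

    def nll(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                      + np.sum(w * (y - mu) ** 2))

    hi = max(10.0 * np.var(y), 1e-6)
    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded")
    if res.success:
        return float(res.x)
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - (k - 1)) / c)) if c > 0 else 0.0


def _pool(y: np.ndarray, v: np.ndarray, hksj: bool = False) -> dict:
    """Random-effects pooling; HKSJ t-based CI/p at the top level."""
    y, v = np.asarray(y, float), np.asarray(v, float)
    k = len(y)
    if k == 1:
        se = np.sqrt(v[0])
        z = y[0] / se if se > 0 else np.inf
        return {"estimate": float(y[0]), "se": float(se), "tau2": 0.0, "k": 1,
                "ci_low": float(y[0] - 1.96 * se), "ci_high": float(y[0] + 1.96 * se),
                "p": float(2 * stats.norm.sf(abs(z))), "single_effect": True}
    tau2 = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    if hksj:
        q = float(np.sum(w * (y - mu) ** 2) / ((k - 1) * np.sum(w)))
        se = np.sqrt(max(q, 1e-12))
        tcrit = stats.t.ppf(0.975, k - 1)
        p = float(2 * stats.t.sf(abs(mu / se), k - 1))
        ci = (mu - tcrit * se, mu + tcrit * se)
    else:
        se = float(np.sqrt(1.0 / np.sum(w)))
        p = float(2 * stats.norm.sf(abs(mu / se)))
        ci = (mu - 1.96 * se, mu + 1.96 * se)
    return {"estimate": mu, "se": float(se), "tau2": float(tau2), "k": k,
            "ci_low": float(ci[0]), "ci_high": float(ci[1]), "p": p,
            "single_effect": False}


@dataclass
class DomainEffect:
    """Pooled subtype effect for one symptom domain."""

    domain: str
    per_outcome: pd.DataFrame          # estimate, variance, cohort, outcome, n
    cohort_level: pd.DataFrame         # one pooled row per cohort
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float | None = None
    tau2_cohort: float = 0.0
    flags: list[str] = field(default_factory=list)


def meta_analyze_domain(effects: pd.DataFrame, hksj: bool = True) -> DomainEffect:
    """Three-level random-effects pooling of per-outcome effects for one
    domain: first an overall estimate per cohort across its outcomes, then an
    overall estimate across cohorts.  REML heterogeneity with DL fallback;
    t-based (HKSJ) CI and p at the cohort level by default."""
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    domain = effects["domain"].iloc[0] if "domain" in effects else "domain"
    cohort_rows = []
    for cohort_name, g in effects.groupby("cohort"):
        pooled = _pool(g["estimate"].to_numpy(), g["variance"].to_numpy(), hksj=False)
        cohort_rows.append({"cohort": cohort_name, **{k: pooled[k] for k in
                            ("estimate", "se", "tau2", "k", "ci_low", "ci_high", "p")}})
    cohort_level = pd.DataFrame(cohort_rows)
    top = _pool(cohort_level["estimate"].to_numpy(), cohort_level["se"].to_numpy() ** 2,
                hksj=hksj and len(cohort_level) > 1)
    flags = []
    if len(effects) == 1:
        flags.append("single_effect")
    return DomainEffect(
        domain=domain, per_outcome=effects.reset_index(drop=True),
        cohort_level=cohort_level,
        estimate=top["estimate"], se=top["se"], ci_low=top["ci_low"],
        ci_high=top["ci_high"], p_raw=top["p"], tau2_cohort=top["tau2"], flags=flags,
    )


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)
    plus the matched CI level: CIs are re-computed at 1 - p*_max where p*_max
    is the largest BH-rejected raw threshold (1 - alpha when nothing is
    rejected)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), 1.0 - alpha
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    m = len(p)
    if reject.any():
        r_max = int(reject.sum())  # largest rejected rank under step-up
        ci_level = 1.0 - alpha * r_max / m
    else:
        ci_level = 1.0 - alpha
    return p_adj, float(ci_level)


# ---------------------------------------------------------------------------
# Baseline associations, survival, cross-sectional comparisons


def baseline_association(
    cohort: LongitudinalCohort,
    outcome: str,
    assignment,
    delta: pd.DataFrame,
    adjust_duration: bool = True,
    ridge_on_separation: float = 1.0,
) -> dict:
    """Logistic association of a baseline outcome value with the subtype.

    Model: P(fast) ~ baseline value (+ disease duration on the common
    timescale as covariate).  The reported estimate is sign-flipped so that
    *negative* values mean more severe baseline symptoms associate with the
    fast subtype.  On complete separation the fit is ridge-stabilized and
    flagged.  Set ``adjust_duration=False`` for the unadjusted variant.
    """
    import statsmodels.api as sm

    spec = cohort.specs[outcome]
    m = cohort.measurements[cohort.measurements["outcome"] == outcome]
    base = m.loc[m.groupby("patient_id")["time_years"].idxmin()]
    dmap = dict(zip(delta["patient_id"], delta["delta"]))
    if assignment.semantic_map is not None:
        lab = {p: 1.0 if s == "fast" else 0.0
               for p, s in zip(assignment.patients, assignment.semantic_labels())}
    else:
        lab = {p: float(l) for p, l in zip(assignment.patients, assignment.labels)}
    y = base["patient_id"].map(lab)
    if y.nunique() < 2:
        raise ModelError("both subtypes must be present")
    x_val = normalize_outcome(base["value"].to_numpy(float), spec)
    X = [np.ones(len(base)), x_val]
    if adjust_duration:
        X.append(base["time_years"].to_numpy() + base["patient_id"].map(dmap).to_numpy())
    X = np.column_stack(X)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y.to_numpy(), X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)) or np.abs(fit.params[1]) > 50:
                raise np.linalg.LinAlgError
            coef, se = fit.params[1], fit.bse[1]
        except Exception:
            flagged = True
            coef, se = _ridge_logit(y.to_numpy(), X, ridge_on_separation)
    z = coef / se
    return {
        "outcome": outcome,
        "estimate": -float(coef),       # negative = severity associates with fast
        "se": float(se),
        "ci_low": -float(coef + 1.96 * se),
        "ci_high": -float(coef - 1.96 * se),
        "p": float(2 * stats.norm.sf(abs(z))),
        "separation_flag": flagged,
        "n": int(len(base)),
    }


def _ridge_logit(y, X, lam):
    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.log1p(np.exp(np.clip(eta, -30, 30)))) \
            + 0.5 * lam * np.sum(b[1:] ** 2)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    p = special.expit(X @ res.x)
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X + lam * np.diag([0.0] + [1.0] * (X.shape[1] - 1))
    cov = np.linalg.inv(H)
    return float(res.x[1]), float(np.sqrt(cov[1, 1]))


def cox_ph(survival: SurvivalTable) -> pd.DataFrame:
    """Cox proportional hazards on the common timescale with subtype, age and
    sex as covariates (Efron ties).  Returns HR, CI and p per covariate."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = survival.data[["time_years", "event", "subtype", "age_at_diagnosis", "sex"]].copy()
    if df["event"].sum() == 0:
        raise ModelError("no events: Cox model undefined")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time_years", event_col="event")
        except ConvergenceError as exc:
            raise ModelError(f"Cox fit failed (monotone likelihood?): {exc}") from exc
    out = cph.summary.reset_index().rename(columns={"covariate": "covariate"})
    return pd.DataFrame({
        "covariate": out["covariate"],
        "coef": out["coef"],
        "hr": np.exp(out["coef"]),
        "hr_ci_low": np.exp(out["coef lower 95%"]),
        "hr_ci_high": np.exp(out["coef upper 95%"]),
        "p": out["p"],
    })


def adjusted_comparison(values: pd.DataFrame, assignment, covariate: str = "duration") -> dict:
    """ANCOVA for single-visit measurements: value ~ subtype + covariate;
    F-test p-value for the subtype term.

    ``values`` needs columns patient_id, value and the covariate column
    (typically common-timescale disease duration).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    lab = dict(zip(assignment.patients,
                   assignment.semantic_labels() if assignment.semantic_map
                   else assignment.labels.astype(str)))
    df = values.copy()
    df["group"] = df["patient_id"].map(lab)
    df = df.dropna(subset=["group", "value", covariate])
    if df["group"].nunique() < 2 or df.groupby("group").size().min() < 2:
        raise ModelError("need >= 2 patients in each group")
    if np.allclose(df["value"].var(), 0.0):
        raise ModelError("constant values: comparison degenerate")
    flags = []
    if np.allclose(df[covariate].var(), 0.0):
        flags.append("collinear_covariate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(f"value ~ C(group) + {covariate}", data=df).fit()
        an = sm.stats.anova_lm(fit, typ=2)
    group_terms = [ix for ix in an.index if "group" in ix]
    effect = [c for c in fit.params.index if "group" in c]
    return {
        "p": float(an.loc[group_terms[0], "PR(>F)"]),
        "effect": float(fit.params[effect[0]]) if effect else np.nan,
        "flags": flags,
        "n": int(len(df)),
    }


# ---------------------------------------------------------------------------
# Cohort-level convenience wrapper


def characterize_progression(
    cohorts: dict[str, tuple[LongitudinalCohort, pd.DataFrame, object]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full progression characterization across cohorts.

    ``cohorts`` maps cohort name -> (cohort, delta frame, assignment with
    semantic labels).  Per cohort and outcome the per-patient progression
    coefficients are computed (inclusion filters applied), turned into
    slow-vs-fast SMDs, pooled per symptom domain by the three-level
    meta-analysis and BH-corrected across domains.  Returns a tidy frame with
    one row per domain.
    """
    effects = []
    for name, (cohort, delta, assignment) in cohorts.items():
        for outcome in cohort.outcomes:
            spec = cohort.specs[outcome]
            coefs = progression_coefficients(cohort, delta, assignment, outcome)
            if coefs is None:
                continue
            slow = coefs.loc[coefs["subtype"] == "slow", "coefficient"].to_numpy()
            fast = coefs.loc[coefs["subtype"] == "fast", "coefficient"].to_numpy()
            try:
                est, var = smd(slow, fast)
            except ModelError:
                continue
            effects.append({"domain": spec.symptom_domain, "outcome": outcome,
                            "cohort": name, "estimate": est, "variance": var,
                            "n": len(slow) + len(fast)})
    if not effects:
        return pd.DataFrame()
    eff = pd.DataFrame(effects)
    rows = []
    domain_effects = []
    for domain, g in eff.groupby("domain"):
        de = meta_analyze_domain(g)
        domain_effects.append(de)
    p_adj, ci_level = bh_adjust([de.p_raw for de in domain_effects], alpha=alpha)
    for de, pa in zip(domain_effects, p_adj):
        de.p_adjusted = float(pa)
        rows.append({"domain": de.domain, "estimate": de.estimate, "se": de.se,
                     "ci_low": de.ci_low, "ci_high": de.ci_high,
                     "p_raw": de.p_raw, "p_adj": de.p_adjusted,
                     "n_outcomes": len(de.per_outcome), "ci_level": ci_level})
    return pd.DataFrame(rows).sort_values("domain").reset_index(drop=True)
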