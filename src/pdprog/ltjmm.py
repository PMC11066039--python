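"""Latent-time joint mixed-effects model (LTJMM) of disease progression.

K clinical outcomes progress linearly and jointly; patient i is shifted along
the disease timescale by a latent shift delta_i shared across all outcomes:

    y_ijk = x_i' beta_k + gamma_k (t_ijk + delta_i) + a0_ik + a1_ik t_ijk + e_ijk

with delta_i ~ N(0, sigma_delta^2), (a0_ik, a1_ik) ~ N(0, Sigma_alpha_k)
independently across outcomes, and e_ijk ~ N(0, sigma_eps_k^2).  Covariates
x_i are (1, age at diagnosis centred, sex).  All outcomes are min-max
normalized on their theoretical range and direction-aligned before fitting,
so gamma_k is in normalized units per year.

Identifiability: the model is invariant to a global time translation
(delta -> delta + c absorbed by intercepts), so delta estimates are centred to
mean zero after every update, with the shift gamma_k * c absorbed into the
per-outcome intercepts.  delta is identified through its shared effect
gamma_k * delta_i across outcomes; with a single outcome it is confounded
with the random intercept (a warning is raised).

Two inference backends are provided:

- ``map``: expectation-maximization on the marginal posterior.  The E-step is
  exact - per patient, the joint posterior of (delta_i, a0_i., a1_i.) is
  Gaussian and computed in closed form - and the M-step updates fixed effects
  and variance components in closed form.  The reported objective is the exact
  marginal log-posterior, which is non-decreasing over iterations.
- ``mcmc``: a Gibbs sampler; every full conditional is conjugate (Gaussian
  blocks for fixed effects and latents, inverse-gamma / inverse-Wishart for
  variances).  Convergence is gated at R-hat < 1.05 (computed with arviz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LongitudinalCohort, OutcomeSpec, rng_from_seed, spawn_seeds
from .scores import normalize_outcome

logger = logging.getLogger("pdprog")


class FitError(RuntimeError):
    """Model fitting failed (singular design, no data, ...)."""


@dataclass
class LTJMMParams:
    """Point estimates of all LTJMM parameters.

    Shapes: beta (K, p) with column 0 the intercept; gamma (K,); delta (n,);
    alpha0/alpha1 (n, K); Sigma_alpha (K, 2, 2); sigma_eps (K,).
    """

    outcomes: list[str]
    patients: list[str]
    covariate_names: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray
    Sigma_alpha: np.ndarray
    sigma_delta: float
    sigma_eps: np.ndarray


@dataclass
class LTJMMFit:
    """Fitted LTJMM: parameters, diagnostics and the data fingerprint needed
    for prediction (covariate matrix, normalization specs)."""

    params: LTJMMParams
    specs: dict[str, OutcomeSpec]
    X: np.ndarray                      # (n, p) covariate matrix used in the fit
    age_center: float
    backend: str
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    draws: dict | None = None          # posterior draws (mcmc backend)

    @property
    def patient_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.params.patients)}

    # -- serialization ------------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        p = self.params
        fixed = pd.DataFrame(p.beta, columns=p.covariate_names)
        fixed.insert(0, "outcome", p.outcomes)
        fixed["gamma"] = p.gamma
        fixed["sigma_eps"] = p.sigma_eps
        fixed.to_csv(path / "fixed_effects.csv", index=False, float_format="%.17g")
        pe = {"patient_id": p.patients, "delta": p.delta}
        for k, name in enumerate(p.outcomes):
            pe[f"alpha0_{name}"] = p.alpha0[:, k]
            pe[f"alpha1_{name}"] = p.alpha1[:, k]
        pd.DataFrame(pe).to_csv(path / "patient_effects.csv", index=False, float_format="%.17g")
        rows = []
        for k, name in enumerate(p.outcomes):
            S = p.Sigma_alpha[k]
            rows.append({"outcome": name, "var_a0": S[0, 0], "cov_a01": S[0, 1], "var_a1": S[1, 1]})
        vdf = pd.DataFrame(rows)
        vdf["sigma_delta"] = p.sigma_delta
        vdf.to_csv(path / "variances.csv", index=False, float_format="%.17g")
        import json

        meta = {
            "backend": self.backend,
            "converged": bool(self.converged),
            "age_center": self.age_center,
            "objective_trace": [float(v) for v in self.objective_trace],
            "diagnostics": {k: (float(v) if np.isscalar(v) else v) for k, v in self.diagnostics.items()},
            "covariate_names": p.covariate_names,
        }
        with open(path / "fit.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savetxt(path / "covariates_X.csv", self.X, delimiter=",", fmt="%.17g")

    @classmethod
    def from_dir(cls, path, specs: dict[str, OutcomeSpec]) -> "LTJMMFit":
        import json

        path = Path(path)
        fixed = pd.read_csv(path / "fixed_effects.csv")
        pe = pd.read_csv(path / "patient_effects.csv")
        vdf = pd.read_csv(path / "variances.csv")
        with open(path / "fit.json") as fh:
            meta = json.load(fh)
        outcomes = list(fixed["outcome"])
        covnames = meta["covariate_names"]
        params = LTJMMParams(
            outcomes=outcomes,
            patients=list(pe["patient_id"]),
            covariate_names=covnames,
            beta=fixed[covnames].to_numpy(),
            gamma=fixed["gamma"].to_numpy(),
            delta=pe["delta"].to_numpy(),
            alpha0=np.column_stack([pe[f"alpha0_{o}"] for o in outcomes]),
            alpha1=np.column_stack([pe[f"alpha1_{o}"] for o in outcomes]),
            Sigma_alpha=np.array(
                [[[r["var_a0"], r["cov_a01"]], [r["cov_a01"], r["var_a1"]]] for _, r in vdf.iterrows()]
            ),
            sigma_delta=float(vdf["sigma_delta"].iloc[0]),
            sigma_eps=fixed["sigma_eps"].to_numpy(),
        )
        X = np.loadtxt(path / "covariates_X.csv", delimiter=",", ndmin=2)
        return cls(
            params=params, specs=specs, X=X, age_center=meta["age_center"],
            backend=meta["backend"], converged=meta["converged"],
            objective_trace=meta["objective_trace"], diagnostics=meta["diagnostics"],
        )


# ---------------------------------------------------------------------------


@dataclass
class _Design:
    """Normalized long-format data in index form."""

    patients: list[str]
    outcomes: list[str]
    X: np.ndarray          # (n, p)
    age_center: float
    obs_i: np.ndarray      # patient index per row
    obs_k: np.ndarray      # outcome index per row
    obs_t: np.ndarray
    obs_y: np.ndarray      # normalized, direction-aligned
    rows_of_patient: list[np.ndarray]


def _build_design(cohort: LongitudinalCohort, specs: dict[str, OutcomeSpec]) -> _Design:
    m = cohort.measurements
    patients = sorted(cohort.covariates["patient_id"])
    outcomes = sorted(m["outcome"].unique())
    pidx = {p: i for i, p in enumerate(patients)}
    kidx = {o: k for k, o in enumerate(outcomes)}
    cov = cohort.covariates.set_index("patient_id").loc[patients]
    age_center = float(cov["age_at_diagnosis"].mean())
    X = np.column_stack(
        [np.ones(len(patients)), cov["age_at_diagnosis"].to_numpy() - age_center, cov["sex"].to_numpy()]
    )
    obs_i = m["patient_id"].map(pidx).to_numpy()
    obs_k = m["outcome"].map(kidx).to_numpy()
    obs_t = m["time_years"].to_numpy(float)
    y = np.empty(len(m))
    vals = m["value"].to_numpy(float)
    for o, k in kidx.items():
        sel = obs_k == k
        y[sel] = normalize_outcome(vals[sel], specs[o])
    order = np.argsort(obs_i, kind="stable")
    obs_i, obs_k, obs_t, y = obs_i[order], obs_k[order], obs_t[order], y[order]
    rows_of_patient = [np.flatnonzero(obs_i == i) for i in range(len(patients))]
    return _Design(patients, outcomes, X, age_center, obs_i, obs_k, obs_t, y, rows_of_patient)


@dataclass
class InferenceConfig:
    """Inference settings for :func:`fit_ltjmm`.

    MAP: ``max_iter`` EM iterations, convergence when the marginal
    log-posterior improves by less than ``tol`` (relative).  MCMC: ``chains``
    Gibbs chains of ``iterations`` draws with ``warmup`` discarded.
    ``fix_sigma_delta`` pins sigma_delta (0 disables the latent shift and the
    model reduces to independent per-outcome linear mixed models);
    ``fix_variances`` skips all variance-component updates.
    """

    backend: str = "map"
    max_iter: int = 200
    tol: float = 1e-8
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int | None = None
    prior_fixed_sd: float = 5.0
    prior_eps: tuple[float, float] = (1.5, 1e-5)     # inverse-gamma (a, b) on sigma_eps^2
    prior_delta: tuple[float, float] = (1.5, 0.5)    # inverse-gamma on sigma_delta^2
    prior_alpha_nu: float = 3.0
    prior_alpha_psi: float = 1e-6                    # inverse-Wishart scale (times I)
    fix_sigma_delta: float | None = None
    fix_variances: bool = False
    init_sigma_delta: float = 1.0
    init_alpha_sd: tuple[float, float] = (0.1, 0.032)  # intercept / slope SD


def fit_ltjmm(
    cohort: LongitudinalCohort,
    specs: dict[str, OutcomeSpec] | None = None,
    inference: InferenceConfig | None = None,
) -> LTJMMFit:
    """Fit the LTJMM to a cohort (outcomes normalized internally).

    Raises :class:`FitError` on a singular design; warns when only one outcome
    is present and sigma_delta is free (delta confounded with the random
    intercept).
    """
    specs = specs if specs is not None else cohort.specs
    inf = inference or InferenceConfig()
    if cohort.n_patients == 0 or len(cohort.measurements) == 0:
        raise FitError("empty cohort")
    d = _build_design(cohort, specs)
    if len(d.outcomes) == 1 and inf.fix_sigma_delta is None:
        warnings.warn(
            "single outcome with free sigma_delta: the latent time shift is "
            "confounded with the random intercept", stacklevel=2
        )
    if inf.backend == "map":
        return _fit_map(d, specs, inf)
    if inf.backend == "mcmc":
        return _fit_mcmc(d, specs, inf)
    raise ValueError(f"unknown backend {inf.backend!r}")


def _init_fixed(d: _Design, ridge: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    K, p = len(d.outcomes), d.X.shape[1]
    beta = np.zeros((K, p))
    gamma = np.zeros(K)
    sigma_eps = np.ones(K) * 0.1
    for k in range(K):
        sel = d.obs_k == k
        G = np.column_stack([d.X[d.obs_i[sel]], d.obs_t[sel]])
        A = G.T @ G + ridge * np.eye(p + 1)
        try:
            coef = np.linalg.solve(A, G.T @ d.obs_y[sel])
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError("singular design in initialization") from exc
        beta[k] = coef[:p]
        gamma[k] = coef[p]
        resid = d.obs_y[sel] - G @ coef
        sigma_eps[k] = max(np.std(resid) * 0.7, 1e-4)
    return beta, gamma, sigma_eps


def _estep(d, beta, gamma, delta_free, sigma_eps, Sigma_alpha, sigma_delta2, prior_fixed_sd):
    """Exact per-patient joint Gaussian posterior of (delta_i, a0_i., a1_i.).

    Returns posterior means m (n, L), selected covariance entries, and the
    marginal log-likelihood (including the latent integrals).
    """
    n, K = d.X.shape[0], len(d.outcomes)
    L = (1 if delta_free else 0) + 2 * K
    off = 1 if delta_free else 0
    Sig_inv = np.zeros((L, L))
    logdet_Su = 0.0
    if delta_free:
        Sig_inv[0, 0] = 1.0 / sigma_delta2
        logdet_Su += np.log(sigma_delta2)
    Sa_inv = np.empty((K, 2, 2))
    for k in range(K):
        Sa_inv[k] = np.linalg.inv(Sigma_alpha[k])
        Sig_inv[off + 2 * k: off + 2 * k + 2, off + 2 * k: off + 2 * k + 2] = Sa_inv[k]
        logdet_Su += np.log(np.linalg.det(Sigma_alpha[k]))

    m = np.zeros((n, L))
    Vd = np.zeros(n)
    Va = np.zeros((n, K, 2, 2))
    Cda = np.zeros((n, K, 2))
    loglik = 0.0
    w_k = 1.0 / sigma_eps**2
    for i in range(n):
        rows = d.rows_of_patient[i]
        kk, tt, yy = d.obs_k[rows], d.obs_t[rows], d.obs_y[rows]
        F = (d.X[i] @ beta[kk].T) + gamma[kk] * tt
        r = yy - F
        w = w_k[kk]
        ni = len(rows)
        Z = np.zeros((ni, L))
        if delta_free:
            Z[:, 0] = gamma[kk]
        rowsel = np.arange(ni)
        Z[rowsel, off + 2 * kk] = 1.0
        Z[rowsel, off + 2 * kk + 1] = tt
        ZW = Z * w[:, None]
        P = Z.T @ ZW + Sig_inv
        rhs = ZW.T @ r
        try:
            cP = np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise FitError("non-positive-definite posterior precision") from exc
        mi = np.linalg.solve(P, rhs)
        Vi = np.linalg.inv(P)
        m[i] = mi
        if delta_free:
            Vd[i] = Vi[0, 0]
        for k in range(K):
            blk = slice(off + 2 * k, off + 2 * k + 2)
            Va[i, k] = Vi[blk, blk]
            if delta_free:
                Cda[i, k] = Vi[0, blk]
        logdetP = 2.0 * np.sum(np.log(np.diag(cP)))
        quad = r @ (w * r) - rhs @ mi
        loglik += -0.5 * (quad + logdet_Su + logdetP - np.sum(np.log(w)) + ni * np.log(2 * np.pi))
    # weak Gaussian prior on fixed effects
    loglik += -0.5 * (np.sum(beta**2) + np.sum(gamma**2)) / prior_fixed_sd**2
    return m, Vd, Va, Cda, loglik


def _variance_log_prior(sigma_eps, Sigma_alpha, sigma_delta2, delta_free, inf) -> float:
    """Log prior of the variance components (the M-step maximizes the
    penalized surrogate, so the reported objective must include these terms
    for monotonicity)."""
    a_e, b_e = inf.prior_eps
    a_d, b_d = inf.prior_delta
    lp = float(np.sum(-(a_e + 1.0) * np.log(sigma_eps**2) - b_e / sigma_eps**2))
    if delta_free and inf.fix_sigma_delta is None:
        lp += -(a_d + 1.0) * np.log(sigma_delta2) - b_d / sigma_delta2
    for S in Sigma_alpha:
        Sinv = np.linalg.inv(S)
        lp += -0.5 * (inf.prior_alpha_nu + 3.0) * np.log(np.linalg.det(S)) \
            - 0.5 * inf.prior_alpha_psi * np.trace(Sinv)
    return lp


def _fit_map(d: _Design, specs, inf: InferenceConfig) -> LTJMMFit:
    n, K, p = d.X.shape[0], len(d.outcomes), d.X.shape[1]
    ridge = 1.0 / inf.prior_fixed_sd**2
    beta, gamma, sigma_eps = _init_fixed(d, ridge)
    a0, a1 = inf.init_alpha_sd
    Sigma_alpha = np.tile(np.array([[a0**2, 0.0], [0.0, a1**2]]), (K, 1, 1))
    delta_free = inf.fix_sigma_delta != 0.0
    sigma_delta2 = (
        inf.fix_sigma_delta**2 if inf.fix_sigma_delta else inf.init_sigma_delta**2
    )
    if not delta_free:
        sigma_delta2 = 1.0  # unused

    a_e, b_e = inf.prior_eps
    a_d, b_d = inf.prior_delta
    nu0, psi0 = inf.prior_alpha_nu, inf.prior_alpha_psi
    off = 1 if delta_free else 0

    trace: list[float] = []
    converged = False
    for it in range(inf.max_iter):
        m, Vd, Va, Cda, loglik = _estep(
            d, beta, gamma, delta_free, sigma_eps, Sigma_alpha, sigma_delta2, inf.prior_fixed_sd
        )
        if not inf.fix_variances:
            loglik += _variance_log_prior(sigma_eps, Sigma_alpha, sigma_delta2, delta_free, inf)
        trace.append(loglik)
        if it > 1 and abs(trace[-1] - trace[-2]) < inf.tol * (1.0 + abs(trace[-2])):
            converged = True
            break

        delta_hat = m[:, 0] if delta_free else np.zeros(n)
        alpha0 = m[:, off::2]
        alpha1 = m[:, off + 1::2]

        # M-step: fixed effects per outcome, with posterior-variance corrections
        for k in range(K):
            sel = d.obs_k == k
            ii, tt, yy = d.obs_i[sel], d.obs_t[sel], d.obs_y[sel]
            dd = tt + delta_hat[ii]
            wk = yy - alpha0[ii, k] - alpha1[ii, k] * tt
            G = np.column_stack([d.X[ii], dd])
            A = G.T @ G + ridge * np.eye(p + 1)
            A[p, p] += np.sum(Vd[ii])
            rhs = G.T @ wk
            rhs[p] -= np.sum(Cda[ii, k, 0] + tt * Cda[ii, k, 1])
            try:
                coef = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError as exc:
                raise FitError("singular design") from exc
            beta[k], gamma[k] = coef[:p], coef[p]

        if not inf.fix_variances:
            # residual variances
            for k in range(K):
                sel = d.obs_k == k
                ii, tt, yy = d.obs_i[sel], d.obs_t[sel], d.obs_y[sel]
                pred = d.X[ii] @ beta[k] + gamma[k] * (tt + delta_hat[ii]) \
                    + alpha0[ii, k] + alpha1[ii, k] * tt
                e2 = (yy - pred) ** 2
                var = (
                    gamma[k] ** 2 * Vd[ii]
                    + Va[ii, k, 0, 0] + tt**2 * Va[ii, k, 1, 1] + 2 * tt * Va[ii, k, 0, 1]
                    + 2 * gamma[k] * (Cda[ii, k, 0] + tt * Cda[ii, k, 1])
                )
                mk = sel.sum()
                sigma_eps[k] = np.sqrt((2 * b_e + np.sum(e2 + var)) / (2 * a_e + mk + 2))
                sigma_eps[k] = max(sigma_eps[k], 1e-5)
            # random-effect covariances
            for k in range(K):
                a = np.column_stack([alpha0[:, k], alpha1[:, k]])
                S = a.T @ a + Va[:, k].sum(axis=0)
                Sigma_alpha[k] = (psi0 * np.eye(2) + S) / (nu0 + n + 3)
                Sigma_alpha[k][0, 0] = max(Sigma_alpha[k][0, 0], 1e-8)
                Sigma_alpha[k][1, 1] = max(Sigma_alpha[k][1, 1], 1e-8)
            # latent-shift variance
            if delta_free and inf.fix_sigma_delta is None:
                sigma_delta2 = (2 * b_d + np.sum(delta_hat**2 + Vd)) / (2 * a_d + n + 2)
                sigma_delta2 = max(sigma_delta2, 1e-8)

        # identifiability: centre delta, absorb into intercepts
        if delta_free:
            c = float(np.mean(m[:, 0]))
            m[:, 0] -= c
            beta[:, 0] += gamma * c

    if delta_free:
        # the final E-step is not followed by a centring pass; centre here
        c = float(np.mean(m[:, 0]))
        m[:, 0] -= c
        beta[:, 0] += gamma * c
    delta_hat = m[:, 0] if delta_free else np.zeros(n)
    params = LTJMMParams(
        outcomes=d.outcomes, patients=d.patients,
        covariate_names=["intercept", "age_c", "sex"],
        beta=beta, gamma=gamma, delta=delta_hat,
        alpha0=m[:, off::2].copy(), alpha1=m[:, off + 1::2].copy(),
        Sigma_alpha=Sigma_alpha,
        sigma_delta=float(np.sqrt(sigma_delta2)) if delta_free else float(inf.fix_sigma_delta or 0.0),
        sigma_eps=sigma_eps,
    )
    return LTJMMFit(
        params=params, specs=dict(specs), X=d.X, age_center=d.age_center,
        backend="map", converged=converged, objective_trace=trace,
        diagnostics={"n_iter": len(trace)},
    )


# ---------------------------------------------------------------------------
# Gibbs sampler (MCMC backend)


def _fit_mcmc(d: _Design, specs, inf: InferenceConfig) -> LTJMMFit:
    import arviz as az

    n, K, p = d.X.shape[0], len(d.outcomes), d.X.shape[1]
    seeds = spawn_seeds(inf.seed, inf.chains)
    keep = inf.iterations - inf.warmup
    if keep <= 1:
        raise ValueError("need iterations > warmup + 1")
    gam_draws = np.empty((inf.chains, keep, K))
    sde_draws = np.empty((inf.chains, keep, K))
    sdd_draws = np.empty((inf.chains, keep))
    beta_draws = np.empty((inf.chains, keep, K, p))
    delta_draws = np.empty((inf.chains, keep, n))
    alpha0_draws = np.empty((inf.chains, keep, n, K))
    alpha1_draws = np.empty((inf.chains, keep, n, K))
    Sig_draws = np.empty((inf.chains, keep, K, 2, 2))

    for c, chain_seed in enumerate(seeds):
        rng = rng_from_seed(chain_seed)
        ridge = 1.0 / inf.prior_fixed_sd**2
        beta, gamma, sigma_eps = _init_fixed(d, ridge)
        a0, a1 = inf.init_alpha_sd
        Sigma_alpha = np.tile(np.array([[a0**2, 0.0], [0.0, a1**2]]), (K, 1, 1))
        sigma_delta2 = inf.init_sigma_delta**2
        delta_free = inf.fix_sigma_delta != 0.0
        off = 1 if delta_free else 0
        a_e, b_e = inf.prior_eps
        a_d, b_d = inf.prior_delta
        nu0, psi0 = inf.prior_alpha_nu, inf.prior_alpha_psi

        for it in range(inf.iterations):
            # latent block: joint (delta_i, alpha_i.) per patient
            u = np.zeros((n, (1 if delta_free else 0) + 2 * K))
            w_k = 1.0 / sigma_eps**2
            Sig_inv = np.zeros((u.shape[1], u.shape[1]))
            if delta_free:
                Sig_inv[0, 0] = 1.0 / sigma_delta2
            for k in range(K):
                Sig_inv[off + 2 * k: off + 2 * k + 2, off + 2 * k: off + 2 * k + 2] = \
                    np.linalg.inv(Sigma_alpha[k])
            for i in range(n):
                rows = d.rows_of_patient[i]
                kk, tt, yy = d.obs_k[rows], d.obs_t[rows], d.obs_y[rows]
                F = (d.X[i] @ beta[kk].T) + gamma[kk] * tt
                r = yy - F
                w = w_k[kk]
                ni = len(rows)
                Z = np.zeros((ni, u.shape[1]))
                if delta_free:
                    Z[:, 0] = gamma[kk]
                rowsel = np.arange(ni)
                Z[rowsel, off + 2 * kk] = 1.0
                Z[rowsel, off + 2 * kk + 1] = tt
                ZW = Z * w[:, None]
                P = Z.T @ ZW + Sig_inv
                rhs = ZW.T @ r
                cP = np.linalg.cholesky(P)
                mu = np.linalg.solve(P, rhs)
                z = rng.standard_normal(u.shape[1])
                u[i] = mu + np.linalg.solve(cP.T, z)
            delta = u[:, 0] if delta_free else np.zeros(n)
            alpha0 = u[:, off::2]
            alpha1 = u[:, off + 1::2]
            # centre delta (identifiability), absorb into intercepts
            if delta_free:
                cshift = float(delta.mean())
                delta = delta - cshift
                beta[:, 0] += gamma * cshift

            # fixed effects per outcome
            for k in range(K):
                sel = d.obs_k == k
                ii, tt, yy = d.obs_i[sel], d.obs_t[sel], d.obs_y[sel]
                dd = tt + delta[ii]
                wk2 = yy - alpha0[ii, k] - alpha1[ii, k] * tt
                G = np.column_stack([d.X[ii], dd])
                prec = G.T @ G / sigma_eps[k] ** 2 + ridge * np.eye(p + 1)
                mu = np.linalg.solve(prec, G.T @ wk2 / sigma_eps[k] ** 2)
                cp = np.linalg.cholesky(prec)
                coef = mu + np.linalg.solve(cp.T, rng.standard_normal(p + 1))
                beta[k], gamma[k] = coef[:p], coef[p]

            # variances
            for k in range(K):
                sel = d.obs_k == k
                ii, tt, yy = d.obs_i[sel], d.obs_t[sel], d.obs_y[sel]
                pred = d.X[ii] @ beta[k] + gamma[k] * (tt + delta[ii]) \
                    + alpha0[ii, k] + alpha1[ii, k] * tt
                sse = float(np.sum((yy - pred) ** 2))
                sigma_eps[k] = np.sqrt(
                    1.0 / rng.gamma(a_e + sel.sum() / 2.0, 1.0 / (b_e + sse / 2.0))
                )
                a = np.column_stack([alpha0[:, k], alpha1[:, k]])
                S = psi0 * np.eye(2) + a.T @ a
                Sigma_alpha[k] = stats.invwishart.rvs(df=nu0 + n, scale=S, random_state=rng)
            if delta_free and inf.fix_sigma_delta is None:
                sigma_delta2 = 1.0 / rng.gamma(
                    a_d + n / 2.0, 1.0 / (b_d + float(np.sum(delta**2)) / 2.0)
                )

            if it >= inf.warmup:
                j = it - inf.warmup
                gam_draws[c, j] = gamma
                sde_draws[c, j] = sigma_eps
                sdd_draws[c, j] = np.sqrt(sigma_delta2)
                beta_draws[c, j] = beta
                delta_draws[c, j] = delta
                alpha0_draws[c, j] = alpha0
                alpha1_draws[c, j] = alpha1
                Sig_draws[c, j] = Sigma_alpha

    rhats = {}
    for k, name in enumerate(d.outcomes):
        rhats[f"gamma_{name}"] = float(az.rhat(gam_draws[:, :, k]))
        rhats[f"sigma_eps_{name}"] = float(az.rhat(sde_draws[:, :, k]))
    rhats["sigma_delta"] = float(az.rhat(sdd_draws))
    max_rhat = float(np.nanmax(list(rhats.values())))
    converged = bool(max_rhat < 1.05)
    if not converged:
        warnings.warn(f"MCMC not converged: max R-hat = {max_rhat:.3f}", stacklevel=2)

    Sigma_alpha_mean = Sig_draws.mean(axis=(0, 1))
    params = LTJMMParams(
        outcomes=d.outcomes, patients=d.patients,
        covariate_names=["intercept", "age_c", "sex"],
        beta=beta_draws.mean(axis=(0, 1)),
        gamma=gam_draws.mean(axis=(0, 1)),
        delta=delta_draws.mean(axis=(0, 1)),
        alpha0=alpha0_draws.mean(axis=(0, 1)),
        alpha1=alpha1_draws.mean(axis=(0, 1)),
        Sigma_alpha=Sigma_alpha_mean,
        sigma_delta=float(sdd_draws.mean()),
        sigma_eps=sde_draws.mean(axis=(0, 1)),
    )
    draws = {"gamma": gam_draws, "sigma_eps": sde_draws, "sigma_delta": sdd_draws}
    return LTJMMFit(
        params=params, specs=dict(specs), X=d.X, age_center=d.age_center,
        backend="mcmc", converged=converged,
        diagnostics={"rhat_max": max_rhat, **rhats}, draws=draws,
    )


# ---------------------------------------------------------------------------
# Prediction and downstream views


def predict_outcomes(fit: LTJMMFit, patient_id: str, times) -> pd.DataFrame:
    """Predicted normalized outcomes y-hat for one patient at observed-scale
    times: y-hat = x'beta + gamma (t + delta-hat) + a0-hat + a1-hat t.

    Deterministic given the fit.  Returns a frame indexed by time with one
    column per outcome.
    """
    p = fit.params
    try:
        i = fit.patient_index[patient_id]
    except KeyError:
        raise KeyError(f"unknown patient {patient_id!r}") from None
    times = np.atleast_1d(np.asarray(times, float))
    out = {}
    for k, name in enumerate(p.outcomes):
        out[name] = (
            fit.X[i] @ p.beta[k]
            + p.gamma[k] * (times + p.delta[i])
            + p.alpha0[i, k]
            + p.alpha1[i, k] * times
        )
    return pd.DataFrame(out, index=pd.Index(times, name="time_years"))


def common_timescale(fit: LTJMMFit, force: bool = False) -> pd.DataFrame:
    """Per-patient monotone affine map t -> t + delta-hat onto the common
    disease timescale.  Population mean shift is zero by construction.

    Refuses on an unconverged fit unless ``force``.
    """
    if not fit.converged and not force:
        raise FitError("fit not converged; pass force=True to use it anyway")
    p = fit.params
    return pd.DataFrame({"patient_id": p.patients, "delta": p.delta})


def heldout_last_visit_r2(
    cohort: LongitudinalCohort,
    specs: dict[str, OutcomeSpec] | None = None,
    inference: InferenceConfig | None = None,
) -> dict:
    """Held-out validation: refit with every patient's last visit excluded and
    report pooled R^2 of the predictions for those excluded measurements.

    R^2 = 1 - SSE/SST over all excluded measurements pooled across outcomes on
    the normalized scale, with SST taken about the per-outcome training mean
    (so predicting the training mean gives R^2 = 0 by construction).  Patients
    that would retain fewer than 2 visits are not excluded (counted in
    ``n_skipped``).
    """
    specs = specs if specs is not None else cohort.specs
    m = cohort.measurements
    held_parts = []
    train_parts = []
    n_skipped = 0
    for pid, g in m.groupby("patient_id"):
        visits = sorted(g["visit"].unique(), key=lambda v: g.loc[g["visit"] == v, "time_years"].iloc[0])
        if len(visits) < 3:
            n_skipped += 1
            train_parts.append(g)
            continue
        last = visits[-1]
        held_parts.append(g[g["visit"] == last])
        train_parts.append(g[g["visit"] != last])
    if not held_parts:
        raise FitError("no excludable visits: every patient has < 3 visits")
    train = pd.concat(train_parts).reset_index(drop=True)
    held = pd.concat(held_parts).reset_index(drop=True)
    train_cohort = LongitudinalCohort(train, cohort.covariates, dict(specs))
    fit = fit_ltjmm(train_cohort, specs, inference)

    train_means = {}
    for o in fit.params.outcomes:
        vals = normalize_outcome(train.loc[train["outcome"] == o, "value"].to_numpy(float), specs[o])
        train_means[o] = float(np.mean(vals))
    sse = 0.0
    sst = 0.0
    n_held = 0
    for (pid, o), g in held.groupby(["patient_id", "outcome"]):
        if o not in fit.params.outcomes or pid not in fit.patient_index:
            continue
        yhat = predict_outcomes(fit, pid, g["time_years"].to_numpy())[o].to_numpy()
        yobs = normalize_outcome(g["value"].to_numpy(float), specs[o])
        sse += float(np.sum((yobs - yhat) ** 2))
        sst += float(np.sum((yobs - train_means[o]) ** 2))
        n_held += len(g)
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return {"r2": r2, "n_held_out": n_held, "n_skipped": n_skipped, "fit": fit}
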