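"""Recurrent variational autoencoder with Gaussian-mixture latent (VaDER style).

Multivariate progression-score trajectories (patients x timepoints x outcomes)
are encoded by a single-layer tanh recurrence into a Gaussian posterior
q(z|x) = N(mu_z, diag(sigma_z^2)); the latent prior is a k-component diagonal
Gaussian mixture, so cluster responsibilities fall out of the latent space;
a second recurrence decodes z back into a trajectory.  Missing entries pass
through a trainable imputation layer before encoding (observed entries are
untouched) and are excluded from the reconstruction loss, so irregular or
masked series need no pre-imputation.

The implementation is a compact, dependency-free numpy one: forward pass and
hand-derived backpropagation-through-time, optimized with Adam.  Gradients are
verified against numerical differentiation in the test suite.  Training
follows the usual variational-deep-embedding recipe: a reconstruction-only
pretraining phase, mixture initialization by a Gaussian mixture fit on the
pretrained latent means, then joint training of network and mixture (network
by gradient, mixture by closed-form weighted updates).  Responsibilities are
treated as constants within each gradient step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .cohort import rng_from_seed

LEARNING_RATE_GRID = (0.0001, 0.001, 0.01, 0.1)
BATCH_SIZE_GRID = (16, 32, 64)
HIDDEN_NODES_GRID = (1, 2, 4, 8, 16, 32, 64)


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class VaderHyperparams:
    """Hyperparameters; defaults drawn from the search grid."""

    learning_rate: float = 0.01
    batch_size: int = 32
    hidden_nodes: int = 8          # hidden size = latent dimension
    k: int = 2
    epochs: int = 50
    pretrain_epochs: int = 50
    kl_weight: float = 1.0
    mixture_damping: float = 0.1   # step size of the per-epoch mixture update
    seed: int | None = None


def _init_weights(T: int, K: int, H: int, rng: np.random.Generator) -> dict:
    def glorot(shape):
        s = np.sqrt(2.0 / sum(shape))
        return rng.normal(0.0, s, size=shape)

    return {
        "imp": np.zeros((T, K)),
        "Wxh": glorot((K, H)), "Whh": glorot((H, H)), "bh": np.zeros(H),
        "Wmu": glorot((H, H)), "bmu": np.zeros(H),
        "Wlv": glorot((H, H)), "blv": np.full(H, -2.0),
        "Wzg": glorot((H, H)), "bzg": np.zeros(H),
        "Wgg": glorot((H, H)), "bg": np.zeros(H),
        "Wout": glorot((H, K)), "bout": np.zeros(K),
    }


def _log_gauss_mix(z: np.ndarray, log_pi: np.ndarray, mu_c: np.ndarray,
                   lv_c: np.ndarray) -> np.ndarray:
    """Per-sample per-component log pi_c + log N(z; mu_c, exp(lv_c))."""
    # z (B, L); mu_c, lv_c (k, L)
    diff2 = (z[:, None, :] - mu_c[None]) ** 2
    ll = -0.5 * np.sum(np.log(2 * np.pi) + lv_c[None] + diff2 / np.exp(lv_c)[None], axis=2)
    return log_pi[None] + ll


def _responsibilities(z, pi, mu_c, lv_c):
    logits = _log_gauss_mix(z, np.log(pi), mu_c, lv_c)
    logits -= logits.max(axis=1, keepdims=True)
    g = np.exp(logits)
    return g / g.sum(axis=1, keepdims=True)


def loss_and_grads(w: dict, X: np.ndarray, M: np.ndarray, eps: np.ndarray,
                   mixture: tuple | None, kl_weight: float) -> tuple[float, dict, dict]:
    """One forward/backward pass on a batch.

    X, M: (B, T, K) values and observation mask; eps: (B, L) reparametrization
    noise; mixture: (pi, mu_c, lv_c) or None for reconstruction-only.
    Returns (mean loss, gradients keyed like ``w``, auxiliaries).
    """
    B, T, K = X.shape
    H = w["Wxh"].shape[1]
    Xt = np.where(M, X, w["imp"][None])

    hs = np.zeros((B, T + 1, H))
    for t in range(T):
        hs[:, t + 1] = np.tanh(Xt[:, t] @ w["Wxh"] + hs[:, t] @ w["Whh"] + w["bh"])
    hT = hs[:, T]
    mu = hT @ w["Wmu"] + w["bmu"]
    lv = np.clip(hT @ w["Wlv"] + w["blv"], -10.0, 10.0)
    sd = np.exp(0.5 * lv)
    z = mu + sd * eps

    g = np.zeros((B, T, H))
    g[:, 0] = np.tanh(z @ w["Wzg"] + w["bzg"])
    for t in range(1, T):
        g[:, t] = np.tanh(g[:, t - 1] @ w["Wgg"] + w["bg"])
    Xhat = g @ w["Wout"] + w["bout"]

    diff = (Xhat - X) * M
    recon = 0.5 * float(np.sum(diff**2)) / B

    kl = 0.0
    dmu_kl = np.zeros_like(mu)
    dlv_kl = np.zeros_like(lv)
    gamma = np.ones((B, 1))
    if mixture is not None and kl_weight > 0:
        pi, mu_c, lv_c = mixture
        gamma = _responsibilities(z, pi, mu_c, lv_c)          # treated as constant
        var_c = np.exp(lv_c)
        e_term = 0.5 * (
            lv_c[None] + (np.exp(lv)[:, None, :] + (mu[:, None, :] - mu_c[None]) ** 2) / var_c[None]
        ).sum(axis=2)                                          # (B, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(gamma > 0, gamma * (np.log(gamma) - np.log(pi)[None]), 0.0).sum(axis=1)
        kl_per = ent + (gamma * e_term).sum(axis=1) - 0.5 * np.sum(1.0 + lv, axis=1)
        kl = float(np.sum(kl_per)) / B
        inv_var = gamma @ (1.0 / var_c)                        # (B, L)
        dmu_kl = (inv_var * mu - gamma @ (mu_c / var_c)) / B
        dlv_kl = (0.5 * np.exp(lv) * inv_var - 0.5) / B

    loss = recon + kl_weight * kl
    if not np.isfinite(loss):
        raise TrainingError("non-finite training loss")

    # ---- backward ----
    grads = {k_: np.zeros_like(v) for k_, v in w.items()}
    dXhat = diff / B
    grads["Wout"] = np.einsum("bth,btk->hk", g, dXhat)
    grads["bout"] = dXhat.sum(axis=(0, 1))
    dg = dXhat @ w["Wout"].T
    for t in range(T - 1, 0, -1):
        da = dg[:, t] * (1.0 - g[:, t] ** 2)
        grads["Wgg"] += g[:, t - 1].T @ da
        grads["bg"] += da.sum(axis=0)
        dg[:, t - 1] += da @ w["Wgg"].T
    da0 = dg[:, 0] * (1.0 - g[:, 0] ** 2)
    grads["Wzg"] = z.T @ da0
    grads["bzg"] = da0.sum(axis=0)
    dz = da0 @ w["Wzg"].T

    dmu = dz + kl_weight * dmu_kl
    dlv = dz * (0.5 * sd * eps) + kl_weight * dlv_kl
    grads["Wmu"] = hT.T @ dmu
    grads["bmu"] = dmu.sum(axis=0)
    grads["Wlv"] = hT.T @ dlv
    grads["blv"] = dlv.sum(axis=0)
    dh = dmu @ w["Wmu"].T + dlv @ w["Wlv"].T
    dXt = np.zeros_like(Xt)
    for t in range(T - 1, -1, -1):
        da = dh * (1.0 - hs[:, t + 1] ** 2)
        grads["Wxh"] += Xt[:, t].T @ da
        grads["Whh"] += hs[:, t].T @ da
        grads["bh"] += da.sum(axis=0)
        dXt[:, t] = da @ w["Wxh"].T
        dh = da @ w["Whh"].T
    grads["imp"] = (dXt * (~M)).sum(axis=0)

    aux = {"recon": recon, "kl": kl, "mu": mu, "lv": lv, "z": z, "gamma": gamma}
    return loss, grads, aux


class _Adam:
    def __init__(self, shapes: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, w: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in w:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            w[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class VaderModel:
    """Trained model: network weights + latent Gaussian mixture."""

    hp: VaderHyperparams
    outcomes: list[str]
    grid: np.ndarray
    weights: dict = field(default_factory=dict)
    pi: np.ndarray | None = None
    mu_c: np.ndarray | None = None
    lv_c: np.ndarray | None = None
    loss_trace: list[float] = field(default_factory=list)

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, M: np.ndarray) -> "VaderModel":
        B, T, K = X.shape
        hp = self.hp
        if hp.k < 1:
            raise ValueError("k must be >= 1")
        if hp.k > B:
            raise ValueError(f"k={hp.k} exceeds number of patients ({B})")
        rng = rng_from_seed(hp.seed)
        H = hp.hidden_nodes
        self.weights = _init_weights(T, K, H, rng)
        opt = _Adam(self.weights, hp.learning_rate)

        def run_epochs(n_epochs: int, mixture_on: bool) -> None:
            for ep in range(n_epochs):
                # KL warm-up over the first half of the joint phase avoids
                # collapsing the mixture before the latent space is formed
                ramp = min(1.0, (ep + 1) / max(n_epochs // 2, 1)) if mixture_on else 0.0
                klw = hp.kl_weight * ramp
                order = rng.permutation(B)
                ep_loss = 0.0
                for s in range(0, B, hp.batch_size):
                    idx = order[s: s + hp.batch_size]
                    eps = rng.standard_normal((len(idx), H))
                    mix = (self.pi, self.mu_c, self.lv_c) if mixture_on else None
                    loss, grads, _ = loss_and_grads(
                        self.weights, X[idx], M[idx], eps, mix, klw
                    )
                    opt.step(self.weights, grads)
                    ep_loss += loss * len(idx)
                self.loss_trace.append(ep_loss / B)
                if mixture_on:
                    self._mixture_m_step(X, M, damping=hp.mixture_damping)

        run_epochs(hp.pretrain_epochs, mixture_on=False)
        self._init_mixture(X, M, rng)
        run_epochs(hp.epochs, mixture_on=True)
        # final mixture: re-estimated to convergence at the trained encoder
        self._init_mixture(X, M, rng)
        return self

    def _encode(self, X: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = self.weights
        B, T, K = X.shape
        Xt = np.where(M, X, w["imp"][None])
        h = np.zeros((B, w["Wxh"].shape[1]))
        for t in range(T):
            h = np.tanh(Xt[:, t] @ w["Wxh"] + h @ w["Whh"] + w["bh"])
        mu = h @ w["Wmu"] + w["bmu"]
        lv = np.clip(h @ w["Wlv"] + w["blv"], -10.0, 10.0)
        return mu, lv

    def _init_mixture(self, X, M, rng) -> None:
        mu, _ = self._encode(X, M)
        k = self.hp.k
        if k == 1:
            self.pi = np.ones(1)
            self.mu_c = mu.mean(axis=0, keepdims=True)
            self.lv_c = np.log(np.maximum(mu.var(axis=0, keepdims=True), 1e-4))
            return
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=1e-4,
            random_state=int(rng.integers(2**31 - 1)), n_init=3,
        ).fit(mu)
        self.pi = gm.weights_.copy()
        self.mu_c = gm.means_.copy()
        self.lv_c = np.log(np.maximum(gm.covariances_, 1e-4))

    def _mixture_m_step(self, X, M, damping: float = 1.0) -> None:
        """Damped closed-form update of (pi, mu_c, sigma_c) at the current
        encoder; damping < 1 moves the mixture a fraction of the way toward
        the EM target to keep it from collapsing early in joint training."""
        mu, lv = self._encode(X, M)
        gamma = _responsibilities(mu, self.pi, self.mu_c, self.lv_c)
        nk = gamma.sum(axis=0) + 1e-8
        pi_t = np.maximum(nk / nk.sum(), 1e-6)
        mu_t = (gamma.T @ mu) / nk[:, None]
        var = np.exp(lv)
        second = gamma.T @ (var + mu**2) / nk[:, None]
        lv_t = np.log(np.maximum(second - mu_t**2, 1e-4))
        self.pi = (1 - damping) * self.pi + damping * pi_t
        self.pi /= self.pi.sum()
        self.mu_c = (1 - damping) * self.mu_c + damping * mu_t
        self.lv_c = (1 - damping) * self.lv_c + damping * lv_t

    # -- inference ----------------------------------------------------------
    def responsibilities(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        """Posterior mixture responsibilities per patient (rows sum to 1),
        evaluated at the latent posterior mean."""
        if self.hp.k == 1 or self.pi is None:
            return np.ones((X.shape[0], 1))
        mu, _ = self._encode(X, M)
        return _responsibilities(mu, self.pi, self.mu_c, self.lv_c)

    def assign(self, X: np.ndarray, M: np.ndarray) -> np.ndarray:
        return np.argmax(self.responsibilities(X, M), axis=1)
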