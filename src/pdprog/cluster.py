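"""Progression-subtype discovery from progression-score tensors.

Clustering is done either by the VaDER-style recurrent variational
autoencoder (:mod:`pdprog.vader`) or by a deterministic lightweight
clusterer - a Gaussian mixture on per-patient score slopes, which is also the
test oracle (under the linear progression model the per-patient slope vector
is a sufficient statistic of the trajectory).

The number of subtypes is selected by the prediction-strength method
(Tibshirani & Walther): the data are split in half, a model fit on one half
assigns the other half, and the statistic is the minimum over test clusters
of the fraction of co-clustered pairs preserved under the train-half
assignment.  The fitted statistic is compared against a null distribution
obtained by replacing the train-half assignment with uniformly random labels
of the same cluster sizes; the chosen k is the smallest candidate whose
statistic significantly exceeds its null.

Final assignments are stabilized by consensus over repeated trainings: the
patients-by-patients co-assignment frequency matrix is cut at k groups by
average-linkage agglomeration of 1 - consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.mixture import GaussianMixture

from .cohort import SchemaError, rng_from_seed, spawn_seeds
from .scores import ProgressionScoreTensor, slope_features
from .vader import VaderHyperparams, VaderModel

logger = logging.getLogger("pdprog")


@dataclass
class SubtypeAssignment:
    """Per-patient cluster labels and responsibilities, with the consensus
    co-assignment matrix when derived from repeated runs and, for k=2, the
    slow/fast semantic map."""

    patients: list[str]
    labels: np.ndarray
    probabilities: np.ndarray                  # (n, k), rows sum to 1
    consensus_matrix: np.ndarray | None = None
    semantic_map: dict[int, str] | None = None

    def __post_init__(self) -> None:
        assert len(self.patients) == len(self.labels)
        np.testing.assert_allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6)

    @property
    def k(self) -> int:
        return self.probabilities.shape[1]

    def semantic_labels(self) -> np.ndarray:
        if self.semantic_map is None:
            raise ValueError("no semantic map; run label_subtypes first")
        return np.array([self.semantic_map[int(l)] for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patients, "label": self.labels.astype(int)})
        for c in range(self.k):
            df[f"prob_{c}"] = self.probabilities[:, c]
        if self.semantic_map is not None:
            df["subtype"] = self.semantic_labels()
        return df

    def to_dir(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path / "assignment.csv", index=False, float_format="%.17g")
        if self.consensus_matrix is not None:
            np.savetxt(path / "consensus.csv", self.consensus_matrix, delimiter=",", fmt="%.17g")

    @classmethod
    def from_dir(cls, path) -> "SubtypeAssignment":
        from pathlib import Path

        path = Path(path)
        df = pd.read_csv(path / "assignment.csv")
        probs = df[[c for c in df.columns if c.startswith("prob_")]].to_numpy()
        cons = None
        if (path / "consensus.csv").exists():
            cons = np.loadtxt(path / "consensus.csv", delimiter=",")
        sem = None
        if "subtype" in df.columns:
            sem = {int(l): s for l, s in zip(df["label"], df["subtype"])}
        return cls(list(df["patient_id"]), df["label"].to_numpy(), probs, cons, sem)


# ---------------------------------------------------------------------------
# Clusterers


class SlopeGMMClusterer:
    """Deterministic lightweight clusterer: Gaussian mixture on per-patient
    score-slope vectors.  Serves as the test oracle for the VaDER model and as
    a fast mode for model selection."""

    def __init__(self, k: int, seed: int | None = None):
        self.k = k
        self.seed = seed
        self.gm: GaussianMixture | None = None
        self.outcomes: list[str] | None = None
        self.grid: np.ndarray | None = None

    def fit(self, scores: ProgressionScoreTensor) -> "SlopeGMMClusterer":
        X = slope_features(scores)
        self.outcomes = list(scores.outcomes)
        self.grid = scores.grid.copy()
        self.gm = GaussianMixture(
            n_components=self.k, covariance_type="full", reg_covar=1e-6,
            random_state=self.seed, n_init=5,
        ).fit(X)
        return self

    def _check(self, scores: ProgressionScoreTensor) -> None:
        if list(scores.outcomes) != self.outcomes or not np.array_equal(scores.grid, self.grid):
            raise SchemaError("outcome set / grid mismatch between model and scores")

    def responsibilities(self, scores: ProgressionScoreTensor) -> np.ndarray:
        self._check(scores)
        return self.gm.predict_proba(slope_features(scores))

    def assign(self, scores: ProgressionScoreTensor) -> np.ndarray:
        return np.argmax(self.responsibilities(scores), axis=1)


class VaderClusterer:
    """VaDER model wrapped to the common clusterer interface."""

    def __init__(self, hp: VaderHyperparams):
        self.hp = hp
        self.model: VaderModel | None = None

    def fit(self, scores: ProgressionScoreTensor) -> "VaderClusterer":
        vals = np.where(scores.mask, scores.values, 0.0)
        self.model = VaderModel(
            hp=self.hp, outcomes=list(scores.outcomes), grid=scores.grid.copy()
        ).fit(vals, scores.mask)
        return self

    def _check(self, scores: ProgressionScoreTensor) -> None:
        if list(scores.outcomes) != self.model.outcomes or not np.array_equal(
            scores.grid, self.model.grid
        ):
            raise SchemaError("outcome set / grid mismatch between model and scores")

    def responsibilities(self, scores: ProgressionScoreTensor) -> np.ndarray:
        self._check(scores)
        vals = np.where(scores.mask, scores.values, 0.0)
        return self.model.responsibilities(vals, scores.mask)

    def assign(self, scores: ProgressionScoreTensor) -> np.ndarray:
        return np.argmax(self.responsibilities(scores), axis=1)


def make_clusterer(method: str, k: int, seed: int | None = None,
                   hp: VaderHyperparams | None = None):
    if method == "gmm":
        return SlopeGMMClusterer(k, seed)
    if method == "vader":
        hp = hp or VaderHyperparams()
        hp = VaderHyperparams(**{**hp.__dict__, "k": k, "seed": seed})
        return VaderClusterer(hp)
    raise ValueError(f"unknown clustering method {method!r}")


def train_vader(
    scores: ProgressionScoreTensor, hp: VaderHyperparams
) -> tuple[VaderClusterer, SubtypeAssignment]:
    """Train a single VaDER run and return the model plus its assignment."""
    if not np.all(np.isfinite(scores.values[scores.mask])):
        raise ValueError("scores must be finite on the observation mask")
    clusterer = VaderClusterer(hp).fit(scores)
    probs = clusterer.responsibilities(scores)
    return clusterer, SubtypeAssignment(
        patients=list(scores.patients), labels=np.argmax(probs, axis=1), probabilities=probs
    )


# ---------------------------------------------------------------------------
# Prediction strength and model selection


def _pairwise_strength(own_labels: np.ndarray, cross_labels: np.ndarray,
                       k: int | None = None) -> float:
    """Tibshirani-Walther statistic: min over own-clusters (size >= 2) of the
    fraction of same-cluster pairs also co-assigned by ``cross_labels``.
    An empty own-cluster (fewer than k distinct labels) scores 0."""
    if k is not None and len(np.unique(own_labels)) < k:
        return 0.0
    strengths = []
    for c in np.unique(own_labels):
        idx = np.flatnonzero(own_labels == c)
        if len(idx) < 2:
            continue
        sub = cross_labels[idx]
        same = (sub[:, None] == sub[None, :])
        n = len(idx)
        frac = (same.sum() - n) / (n * (n - 1))
        strengths.append(frac)
    if not strengths:
        return 0.0
    return float(min(strengths))


def prediction_strength(
    scores: ProgressionScoreTensor,
    k: int,
    method: str = "vader",
    hp: VaderHyperparams | None = None,
    n_splits: int = 1,
    n_null: int = 100,
    seed: int | None = None,
) -> dict:
    """Split-half prediction strength with a random-label null.

    For each random halving, a model is fit on each half; test-half patients
    get (a) their own model's labels and (b) the train-half model's labels,
    and the statistic is the preserved-co-membership minimum (both
    orientations averaged).  The null replaces the cross labels with uniformly
    random labels of the same cluster sizes.  Empty test clusters score 0 for
    that split (logged).  Returns statistic, null draws and the empirical
    exceedance p-value.
    """
    n = scores.n_patients
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} patients")
    if k == 1:
        return {"k": 1, "statistic": 1.0, "null": np.ones(n_null), "p_value": 1.0}
    rng = rng_from_seed(seed)
    split_stats = []
    null_draws = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half_a, half_b = perm[: n // 2], perm[n // 2:]
        both = []
        for train_idx, test_idx in ((half_a, half_b), (half_b, half_a)):
            train = scores.subset(train_idx)
            test = scores.subset(test_idx)
            m_train = make_clusterer(method, k, int(rng.integers(2**31 - 1)), hp).fit(train)
            m_test = make_clusterer(method, k, int(rng.integers(2**31 - 1)), hp).fit(test)
            own = m_test.assign(test)
            cross = m_train.assign(test)
            if len(np.unique(own)) < k:
                logger.info("prediction_strength: empty test cluster (k=%d), split scored 0", k)
            stat = _pairwise_strength(own, cross, k)
            both.append(stat)
            # null: random labels with the same sizes as the cross assignment
            for _ in range(int(np.ceil(n_null / (2 * n_splits)))):
                null_cross = rng.permutation(cross)
                null_draws.append(_pairwise_strength(own, null_cross, k))
        split_stats.append(np.mean(both))
    statistic = float(np.mean(split_stats))
    null = np.asarray(null_draws[:max(n_null, 1)])
    p = (1.0 + np.sum(null >= statistic)) / (len(null) + 1.0)
    return {"k": k, "statistic": statistic, "null": null, "p_value": float(p)}


@dataclass
class ModelSelectionReport:
    """Per-k prediction strength vs random-clustering null; ``chosen_k`` is
    the smallest k with a significant improvement, or None (no subtype
    structure)."""

    table: pd.DataFrame
    chosen_k: int | None
    alpha: float

    @property
    def no_structure(self) -> bool:
        return self.chosen_k is None


def select_k(
    scores: ProgressionScoreTensor,
    k_candidates=(2, 3, 4, 5),
    alpha: float = 0.05,
    method: str = "vader",
    hp: VaderHyperparams | None = None,
    n_splits: int = 1,
    n_null: int = 100,
    seed: int | None = None,
) -> ModelSelectionReport:
    """Choose the number of subtypes: smallest candidate k whose prediction
    strength significantly exceeds the random-clustering null."""
    rows = []
    chosen = None
    seeds = spawn_seeds(seed, len(k_candidates))
    for k, s in zip(k_candidates, seeds):
        res = prediction_strength(scores, k, method=method, hp=hp,
                                  n_splits=n_splits, n_null=n_null, seed=s)
        rows.append({"k": k, "statistic": res["statistic"],
                     "null_mean": float(np.mean(res["null"])),
                     "null_q95": float(np.quantile(res["null"], 0.95)),
                     "p_value": res["p_value"]})
        if chosen is None and res["p_value"] < alpha:
            chosen = k
    return ModelSelectionReport(table=pd.DataFrame(rows), chosen_k=chosen, alpha=alpha)


def hyperparameter_search(
    scores: ProgressionScoreTensor,
    n_samples: int = 24,
    k_range=(2, 3, 4, 5),
    epochs: int = 50,
    seed: int | None = None,
) -> tuple[VaderHyperparams, pd.DataFrame]:
    """Random search over the (learning rate, batch size, hidden nodes) grid,
    scored by prediction strength; duplicates are deduplicated before
    training.  Returns the best hyperparameters and the search trace."""
    from .vader import BATCH_SIZE_GRID, HIDDEN_NODES_GRID, LEARNING_RATE_GRID

    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = rng_from_seed(seed)
    seen = set()
    candidates = []
    max_unique = len(LEARNING_RATE_GRID) * len(BATCH_SIZE_GRID) * len(HIDDEN_NODES_GRID) * len(k_range)
    while len(candidates) < min(n_samples, max_unique):
        cand = (
            float(rng.choice(LEARNING_RATE_GRID)),
            int(rng.choice(BATCH_SIZE_GRID)),
            int(rng.choice(HIDDEN_NODES_GRID)),
            int(rng.choice(list(k_range))),
        )
        if cand not in seen:
            seen.add(cand)
            candidates.append(cand)
    rows = []
    best = None
    for lr, bs, hn, k in candidates:
        hp = VaderHyperparams(learning_rate=lr, batch_size=bs, hidden_nodes=hn,
                              k=k, epochs=epochs, seed=int(rng.integers(2**31 - 1)))
        try:
            res = prediction_strength(scores, k, method="vader", hp=hp,
                                      n_splits=1, n_null=20,
                                      seed=int(rng.integers(2**31 - 1)))
            stat = res["statistic"]
        except Exception as exc:  # diverged candidates score 0
            logger.info("candidate %s failed: %s", (lr, bs, hn, k), exc)
            stat = 0.0
        rows.append({"learning_rate": lr, "batch_size": bs, "hidden_nodes": hn,
                     "k": k, "prediction_strength": stat})
        if best is None or stat > best[0]:
            best = (stat, hp)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus, semantics, transfer


def consensus_cluster(runs: list[SubtypeAssignment], k: int | None = None) -> SubtypeAssignment:
    """Aggregate repeated stochastic runs into a final partition.

    The consensus matrix holds pairwise co-assignment frequencies (symmetric,
    unit diagonal); the final labels cut the average-linkage dendrogram of
    1 - consensus at k groups.  Invariant to label permutations within runs.
    Final per-patient 'probability' is the mean consensus with the members of
    the patient's final cluster.
    """
    if not runs:
        raise ValueError("no runs")
    patients = runs[0].patients
    for r in runs[1:]:
        if r.patients != patients:
            raise ValueError("runs must share an identical patient set")
    if k is None:
        k = runs[0].k
    n = len(patients)
    C = np.zeros((n, n))
    for r in runs:
        same = r.labels[:, None] == r.labels[None, :]
        C += same
    C /= len(runs)
    np.fill_diagonal(C, 1.0)
    agg = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
    labels = agg.fit_predict(1.0 - C)
    probs = np.zeros((n, k))
    for c in range(k):
        members = labels == c
        denom = max(members.sum(), 1)
        probs[:, c] = C[:, members].sum(axis=1) / denom
    probs /= probs.sum(axis=1, keepdims=True)
    return SubtypeAssignment(patients=list(patients), labels=labels,
                             probabilities=probs, consensus_matrix=C)


def label_subtypes(assignment: SubtypeAssignment, fit) -> dict[int, str]:
    """Name the k=2 clusters: the cluster with the larger mean per-patient
    composite slope (mean over outcomes of gamma_k + a1_ik, normalized scale)
    is 'fast'.  Ties break deterministically by cluster id (flagged)."""
    if assignment.k != 2:
        raise ValueError("semantic labelling requires exactly 2 clusters")
    p = fit.params
    pidx = {pid: i for i, pid in enumerate(p.patients)}
    rows = [pidx[pid] for pid in assignment.patients]
    slopes = (p.gamma[None, :] + p.alpha1[rows]).mean(axis=1)
    mean0 = slopes[assignment.labels == 0].mean()
    mean1 = slopes[assignment.labels == 1].mean()
    if mean0 == mean1:
        logger.warning("label_subtypes: exact tie; cluster 1 named fast by convention")
        semantic = {0: "slow", 1: "fast"}
    elif mean1 > mean0:
        semantic = {0: "slow", 1: "fast"}
    else:
        semantic = {0: "fast", 1: "slow"}
    assignment.semantic_map = semantic
    return semantic


def transfer_model(model, scores_b: ProgressionScoreTensor) -> SubtypeAssignment:
    """Assign cohort B's patients with a frozen model trained on cohort A
    (B's scores computed from B's own LTJMM fit); no retraining.  Outcome set
    and grid must match."""
    probs = model.responsibilities(scores_b)  # raises SchemaError on mismatch
    return SubtypeAssignment(
        patients=list(scores_b.patients), labels=np.argmax(probs, axis=1), probabilities=probs
    )
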