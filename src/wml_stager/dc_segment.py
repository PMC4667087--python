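"""Self-supervised discriminative clustering of multispectral voxel features.

Voxels inside the brain mask are treated as exchangeable points in a
robust-normalized intensity space (one dimension per pulse sequence).  A
coarse 4-group clustering generates high-confidence tissue seeds
automatically (no annotator), and a penalized K-means — many clusters, each
carrying a smoothed tissue-label distribution — partitions the feature space
into regions that are both compact and label-consistent.  Soft cluster
responsibilities under a Gaussian kernel then yield per-voxel tissue
membership probabilities, which is what makes sub-voxel (partial volume)
lesion quantification possible downstream.

The fitted objective is

    J = sum_v ||x_v - mu_c(v)||^2  +  lambda * sum_{v in seeds} (1 - P(label_v | c(v)))

where ``P(. | c)`` is the Laplace-smoothed (alpha=1) distribution of seed
labels in cluster ``c``.  With ``lambda = 0`` the fit reduces exactly to
Lloyd's K-means from the same initialization.

``K`` defaults to 4 (one cluster per tissue class): every cluster then
receives seeds and carries an informative label distribution.  With larger
``K`` the clusters covering partial-volume voxels typically contain no seeds,
so their Laplace-smoothed label distributions stay near-uniform and flatten
the membership calibration that sub-voxel lesion staging relies on; raise
``K`` only together with a seeding scheme that labels every mode of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .imaging_io import MultispectralVolume
from .phantom import TISSUES

logger = logging.getLogger(__name__)

#: Canonical per-channel intensity rank of each tissue (0 = darkest of the
#: four).  FLAIR: lesions brightest, CSF suppressed; T2: CSF brightest, WM
#: darkest; MT/T1-like: WM brightest, lesions below grey matter.
CANONICAL_RANKS = {
    "FLAIR": {"CSF": 0, "WM": 1, "GM": 2, "LESION": 3},
    "T2": {"WM": 0, "GM": 1, "LESION": 2, "CSF": 3},
    "MT": {"CSF": 0, "LESION": 1, "GM": 2, "WM": 3},
}


@dataclass
class FeatureMatrix:
    """Robust-normalized in-mask voxel intensities, one row per voxel."""

    X: np.ndarray
    voxel_indices: np.ndarray  # (N, 3) grid coordinates of each row
    channel_names: tuple
    grid_shape: tuple
    voxel_size_mm: tuple
    affine: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]


@dataclass
class SeedLabels:
    """Sparse self-generated tissue labels (a small, confident subset)."""

    rows: np.ndarray       # indices into FeatureMatrix rows
    labels: np.ndarray     # tissue codes, indices into TISSUES
    confidence_fraction: float
    degenerate: bool = False


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray            # (K, n_channels)
    cluster_tissue_dist: np.ndarray  # (K, 4) row-stochastic P(tissue | cluster)
    temperature: float               # tau for Gaussian-kernel responsibilities
    lambda_label: float
    objective_trace: list
    assignments: np.ndarray
    n_iter: int = 0
    converged: bool = True


@dataclass
class TissueProbabilityMap:
    """Per in-mask voxel probability vector over (CSF, GM, WM, LESION)."""

    probs: np.ndarray          # (N, 4)
    voxel_indices: np.ndarray  # (N, 3)
    grid_shape: tuple
    voxel_size_mm: tuple
    affine: np.ndarray
    tissues: tuple = TISSUES

    def to_volume(self, tissue: str) -> np.ndarray:
        """Scatter one tissue's probabilities back onto the grid (0 outside)."""
        vol = np.zeros(self.grid_shape)
        j = self.tissues.index(tissue)
        vol[tuple(self.voxel_indices.T)] = self.probs[:, j]
        return vol

    def hard_labels(self) -> np.ndarray:
        """Most probable tissue per voxel as an int grid; -1 outside mask."""
        vol = np.full(self.grid_shape, -1, dtype=np.int8)
        vol[tuple(self.voxel_indices.T)] = np.argmax(self.probs, axis=1)
        return vol

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m


def normalize_channels(msv: MultispectralVolume) -> FeatureMatrix:
    """Per-channel robust normalization of in-mask intensities.

    Each channel is centred on its in-mask median and scaled by
    1.4826 x MAD, making the features dimensionless and invariant to global
    intensity rescaling of any single channel.
    """
    mask = msv.brain_mask
    idx = np.argwhere(mask)
    cols = []
    for ch in msv.channels:
        vals = ch.data[mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"channel {ch.channel_name!r}: non-finite in-mask values")
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        if mad == 0:
            # degenerate (e.g. noiseless discrete intensities where one
            # tissue holds the majority): fall back to the standard deviation
            sd = float(vals.std())
            if sd == 0:
                raise ValueError(
                    f"channel {ch.channel_name!r} is constant in the mask; "
                    "cannot normalize"
                )
            logger.info(
                "channel %s: zero MAD, falling back to SD scaling",
                ch.channel_name,
            )
            mad = sd
        cols.append((vals - med) / mad)
    return FeatureMatrix(
        X=np.column_stack(cols),
        voxel_indices=idx,
        channel_names=msv.channel_names,
        grid_shape=msv.shape,
        voxel_size_mm=msv.voxel_size_mm,
        affine=msv.affine,
    )


def generate_seed_labels(
    features: FeatureMatrix,
    confidence_fraction: float = 0.10,
    seed: int = 0,
) -> SeedLabels:
    """Self-supervised seeds: coarse 4-means groups mapped to tissues by rank.

    The four groups' channel-mean intensity ranks are matched to the
    canonical per-channel tissue orderings (:data:`CANONICAL_RANKS`); within
    each group the ``confidence_fraction`` of voxels nearest its centre are
    labeled, the rest stay unlabeled.
    """
    if not 0 < confidence_fraction <= 0.25:
        raise ValueError("confidence_fraction must lie in (0, 0.25]")
    X = features.X
    km = KMeans(n_clusters=4, n_init=10, random_state=int(seed) % (2**31)).fit(X)
    means = km.cluster_centers_  # (4, n_channels)

    # observed rank of each group per channel (0 = darkest)
    order = np.argsort(means, axis=0)
    obs_rank = np.empty_like(order)
    for c in range(means.shape[1]):
        obs_rank[order[:, c], c] = np.arange(4)

    if any(
        np.array_equal(obs_rank[a], obs_rank[b])
        for a in range(4) for b in range(a + 1, 4)
    ):
        raise ValueError(
            "ambiguous signature match: two groups share an identical rank "
            "signature; try more clusters or different channels"
        )

    cost = np.zeros((4, 4))
    for g in range(4):
        for t_i, t in enumerate(TISSUES):
            for c_i, ch in enumerate(features.channel_names):
                canon = CANONICAL_RANKS.get(ch)
                if canon is None:
                    continue
                cost[g, t_i] += abs(int(obs_rank[g, c_i]) - canon[t])
    from scipy.optimize import linear_sum_assignment

    g_idx, t_idx = linear_sum_assignment(cost)
    group_tissue = dict(zip(g_idx.tolist(), t_idx.tolist()))

    rows, labels = [], []
    assign = km.labels_
    for g in range(4):
        members = np.flatnonzero(assign == g)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - means[g], axis=1)
        k = max(1, int(round(confidence_fraction * members.size)))
        chosen = members[np.argsort(d, kind="stable")[:k]]
        rows.append(chosen)
        labels.append(np.full(chosen.size, group_tissue[g], dtype=np.int64))
    rows = np.concatenate(rows)
    labels = np.concatenate(labels)
    degenerate = len(set(labels.tolist())) < 4
    if degenerate:
        logger.warning("seed labels degenerate: not every tissue has a seed")
    return SeedLabels(
        rows=rows, labels=labels,
        confidence_fraction=float(rows.size) / features.n_voxels,
        degenerate=degenerate,
    )


def _farthest_point_init(X, K, rng, centroids=None):
    """K-means++-style farthest-point seeding (deterministic given the RNG)."""
    if centroids is None:
        centroids = [X[int(rng.integers(X.shape[0]))]]
    else:
        centroids = [c for c in centroids]
    d2 = np.min(
        np.stack([np.sum((X - c) ** 2, axis=1) for c in centroids]), axis=0
    )
    while len(centroids) < K:
        nxt = int(np.argmax(d2))  # ties -> lowest index
        centroids.append(X[nxt])
        d2 = np.minimum(d2, np.sum((X - centroids[-1]) ** 2, axis=1))
    return np.array(centroids)


def _seed_informed_init(X, seeds: SeedLabels, K, rng):
    """Start the first four centroids at the per-tissue seed means.

    Initializing from the self-generated labels anchors one cluster per
    tissue and avoids the outlier-collapse that pure farthest-point seeding
    suffers on heavily imbalanced tissue sizes; extra clusters (K > 4) are
    added by farthest-point selection.
    """
    if seeds.rows.size == 0:
        return _farthest_point_init(X, K, rng)
    anchors = [
        X[seeds.rows[seeds.labels == t]].mean(axis=0)
        for t in range(len(TISSUES))
        if np.any(seeds.labels == t)
    ][:K]
    if K == len(anchors):
        return np.array(anchors)
    return _farthest_point_init(X, K, rng, centroids=anchors)


def _label_distributions(assign, seeds: SeedLabels, K):
    counts = np.ones((K, len(TISSUES)))  # Laplace alpha = 1
    np.add.at(counts, (assign[seeds.rows], seeds.labels), 1.0)
    return counts / counts.sum(axis=1, keepdims=True)


def _objective(X, assign, centroids, P, seeds, lambda_label):
    d2 = np.sum((X - centroids[assign]) ** 2, axis=1)
    obj = float(d2.sum())
    if lambda_label > 0 and seeds.rows.size:
        obj += lambda_label * float(
            np.sum(1.0 - P[assign[seeds.rows], seeds.labels])
        )
    return obj


def fit_discriminative_clustering(
    features: FeatureMatrix,
    seeds: SeedLabels,
    K: int = 4,
    lambda_label: float = 10.0,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> ClusterModel:
    """Alternating minimization of the penalized K-means objective.

    The assignment step moves each voxel to the cluster minimizing its summed
    contribution (squared distance plus, for seeds, the label penalty under
    the current cluster-label distributions); the update step recomputes
    centroids and Laplace-smoothed label distributions.  Iteration stops when
    fewer than ``tol`` of assignments change, when ``max_iter`` is reached,
    or when a sweep would increase the objective (the sweep is then rolled
    back, keeping the recorded trace non-increasing).  Empty clusters are
    re-seeded from the farthest voxel.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if lambda_label < 0:
        raise ValueError("lambda_label must be nonnegative")
    X = features.X
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    centroids = _seed_informed_init(X, seeds, K, rng)
    P = np.full((K, len(TISSUES)), 1.0 / len(TISSUES))
    assign = None
    trace = []
    converged = False
    state = None
    n_done = 0
    for it in range(max_iter):
        d2 = (
            np.sum(X**2, axis=1, keepdims=True)
            - 2.0 * X @ centroids.T
            + np.sum(centroids**2, axis=1)
        )
        cost = d2
        if lambda_label > 0 and seeds.rows.size:
            cost = d2.copy()
            cost[seeds.rows] += lambda_label * (1.0 - P[:, seeds.labels].T)
        new_assign = np.argmin(cost, axis=1)

        # re-seed empty clusters from the farthest voxel
        counts = np.bincount(new_assign, minlength=K)
        while (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            dist_own = np.sum((X - centroids[new_assign]) ** 2, axis=1)
            far = int(np.argmax(dist_own))
            logger.info("re-seeding empty cluster %d from voxel %d", empty, far)
            centroids[empty] = X[far]
            new_assign[far] = empty
            counts = np.bincount(new_assign, minlength=K)

        new_centroids = np.zeros_like(centroids)
        np.add.at(new_centroids, new_assign, X)
        new_centroids /= counts[:, None]
        new_P = _label_distributions(new_assign, seeds, K)
        obj = _objective(X, new_assign, new_centroids, new_P, seeds, lambda_label)
        if trace and obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
            logger.info(
                "objective would increase (%.6g -> %.6g); stopping at the "
                "previous sweep", trace[-1], obj,
            )
            converged = True
            break
        changed = 1.0 if assign is None else float(np.mean(new_assign != assign))
        assign, centroids, P = new_assign, new_centroids, new_P
        trace.append(obj)
        n_done = it + 1
        if changed < tol:
            converged = True
            break
    if not converged:
        logger.warning("discriminative clustering did not converge in %d iterations", max_iter)

    # RMS pairwise distance between points of a cluster: E||x-x'||^2 = 2 E||x-mu||^2
    d2_own = np.sum((X - centroids[assign]) ** 2, axis=1)
    tau = float(np.sqrt(2.0 * np.mean(d2_own)))
    return ClusterModel(
        K=K,
        centroids=centroids,
        cluster_tissue_dist=P,
        temperature=tau,
        lambda_label=lambda_label,
        objective_trace=trace,
        assignments=assign,
        n_iter=n_done,
        converged=converged,
    )


def tissue_probabilities(model: ClusterModel, features: FeatureMatrix) -> TissueProbabilityMap:
    """Soft tissue memberships from Gaussian-kernel cluster responsibilities.

    ``P(cluster c | x) ∝ exp(-||x - mu_c||^2 / (2 tau^2))`` and
    ``P(tissue t | x) = sum_c P(t | c) P(c | x)``; every output vector is
    normalized to sum to one.
    """
    tau = model.temperature
    if tau <= 0:
        raise ValueError("temperature must be positive")
    X = features.X
    d2 = (
        np.sum(X**2, axis=1, keepdims=True)
        - 2.0 * X @ model.centroids.T
        + np.sum(model.centroids**2, axis=1)
    )
    logits = -d2 / (2.0 * tau**2)
    log_resp = logits - logsumexp(logits, axis=1, keepdims=True)
    probs = np.exp(log_resp) @ model.cluster_tissue_dist
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return TissueProbabilityMap(
        probs=probs,
        voxel_indices=features.voxel_indices,
        grid_shape=features.grid_shape,
        voxel_size_mm=features.voxel_size_mm,
        affine=features.affine,
    )


def segment_volume(
    msv: MultispectralVolume,
    K: int = 4,
    lambda_label: float = 10.0,
    confidence_fraction: float = 0.10,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
):
    """Full segmentation: normalize, seed, cluster, and score memberships.

    Returns ``(tpm, model, seeds)``.
    """
    features = normalize_channels(msv)
    seeds = generate_seed_labels(features, confidence_fraction, seed=seed)
    model = fit_discriminative_clustering(
        features, seeds, K=K, lambda_label=lambda_label,
        max_iter=max_iter, tol=tol, seed=seed,
    )
    tpm = tissue_probabilities(model, features)
    return tpm, model, seeds


def seed_purity(seeds: SeedLabels, features: FeatureMatrix, truth_fractions: dict) -> float:
    """Fraction of seeds whose label matches the dominant true tissue."""
    idx = features.voxel_indices[seeds.rows]
    true_stack = np.stack(
        [truth_fractions[t][tuple(idx.T)] for t in TISSUES], axis=1
    )
    return float(np.mean(np.argmax(true_stack, axis=1) == seeds.labels))
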