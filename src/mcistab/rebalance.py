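"""Hybrid class rebalancing: centroid oversampling + medoid undersampling.

Class imbalance (e.g. 27 naMCI vs 115 CN) is addressed before training by a
combination of two clustering-based resamplers, both operating in 0-1 scaled
feature space with Euclidean distance:

- the minority class is grown iteratively: the current Ns minority points are
  clustered with K-means into max(1, floor(Ns/3)) clusters and the cluster
  centroids are appended as synthetic points; this repeats until the minority
  reaches 2/3 of the *original* majority size (overshoot is kept);
- the majority class is shrunk with K-medoids, whose cluster centres are
  actual data points, so every retained majority row is a real subject.

The final training set concatenates the oversampled minority and the
undersampled majority. By default the majority is undersampled to the final
minority size, yielding a balanced set; this target is configurable because
the stopping side of the trade-off is a genuinely open choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from ._seeding import child_seeds

ORIGINAL = "original"
CENTROID = "centroid"


@dataclass
class RebalancedSet:
    """Training set after oversampling + undersampling.

    ``provenance`` flags each row as ``"original"`` (an input row, bit-exact)
    or ``"centroid"`` (a synthetic K-means centroid of minority points).
    """

    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray
    minority_label: str
    majority_label: str
    minority_final: int
    majority_final: int

    @property
    def ratio(self) -> float:
        """Final minority/majority size ratio (>= 2/3 by construction)."""
        return self.minority_final / self.majority_final


def oversample_target(majority_size: int) -> int:
    """Minority size at which oversampling stops: ceil(2/3 * majority)."""
    return -((-2 * majority_size) // 3)


def kmeans_oversample(
    minority: np.ndarray, target: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grow the minority class to at least ``target`` rows by iterated K-means.

    Each round clusters the current Ns rows into k = max(1, floor(Ns/3))
    clusters and appends the k centroids; centroids from one round take part
    in the clustering of the next. All original rows are retained unchanged.

    Returns
    -------
    values, provenance
        The augmented matrix (original rows first, in input order) and the
        per-row provenance flags.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise ValueError("minority class needs >= 2 rows to cluster")
    n0 = minority.shape[0]
    if target < n0:
        warnings.warn(
            f"oversampling target {target} below current size {n0}; returning input",
            stacklevel=2,
        )
        target = n0
    current = minority
    seeds = iter(child_seeds(seed, 64))
    while current.shape[0] < target:
        ns = current.shape[0]
        k = max(1, ns // 3)
        km = KMeans(n_clusters=k, n_init=10, random_state=next(seeds)).fit(current)
        current = np.vstack([current, km.cluster_centers_])
    provenance = np.array([ORIGINAL] * n0 + [CENTROID] * (current.shape[0] - n0))
    return current, provenance


def _kmedoids(X: np.ndarray, k: int, seed: int, max_iter: int = 300) -> np.ndarray:
    """Seeded alternate-style K-medoids; returns sorted medoid row indices.

    Random distinct initial medoids, then alternating assignment / medoid
    update (each medoid moves to the in-cluster point minimising the summed
    Euclidean distance to its cluster) until the medoid set is stable or
    ``max_iter`` is hit. Ties break towards the lowest row index, so a fixed
    seed gives a fixed output.
    """
    n = X.shape[0]
    if k == n:
        return np.arange(n)
    D = cdist(X, X)
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:  # can happen with duplicate points
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new[c] = members[np.argmin(within)]
        new = np.sort(new)
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def kmedoids_undersample(
    majority: np.ndarray, target: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce the majority class to ``target`` rows via K-medoids (k = target).

    Every returned row is an exact row of the input (medoids are data points).

    Returns
    -------
    values, indices
        The medoid rows and their row indices into ``majority``.
    """
    majority = np.asarray(majority, dtype=float)
    n = majority.shape[0]
    if not 1 <= target <= n:
        raise ValueError(f"undersampling target {target} out of range [1, {n}]")
    idx = _kmedoids(majority, target, seed)
    return majority[idx], idx


def rebalance(
    values: np.ndarray,
    labels: np.ndarray,
    seed: int,
    undersample: str = "balanced",
) -> RebalancedSet:
    """Rebalance a binary-labeled training set.

    Parameters
    ----------
    values : (n, p) matrix in the scaled feature space.
    labels : length-n label array with exactly two distinct values.
    undersample : {"balanced", "none", "ratio_3_2"}
        Majority target after minority oversampling: the final minority size
        (default, balanced output), no undersampling, or ceil(3/2 x minority).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"rebalance requires exactly 2 classes, got {classes.size}")
    mi, ma = (0, 1) if counts[0] <= counts[1] else (1, 0)
    minority_label, majority_label = classes[mi], classes[ma]
    X_min = values[labels == minority_label]
    X_maj = values[labels == majority_label]
    m = X_maj.shape[0]

    seeds = child_seeds(seed, 2)
    threshold = max(oversample_target(m), X_min.shape[0])
    X_min_aug, prov_min = kmeans_oversample(X_min, target=threshold, seed=seeds[0])
    n_min = X_min_aug.shape[0]

    if undersample == "balanced":
        maj_target = min(n_min, m)
    elif undersample == "none":
        maj_target = m
    elif undersample == "ratio_3_2":
        maj_target = min(m, -((-3 * n_min) // 2))
    else:
        raise ValueError(f"unknown undersample mode {undersample!r}")
    X_maj_sub, _ = kmedoids_undersample(X_maj, maj_target, seed=seeds[1])

    out_values = np.vstack([X_min_aug, X_maj_sub])
    out_labels = np.concatenate(
        [np.repeat(minority_label, n_min), np.repeat(majority_label, maj_target)]
    )
    provenance = np.concatenate([prov_min, np.repeat(ORIGINAL, maj_target)])
    return RebalancedSet(
        values=out_values,
        labels=out_labels,
        provenance=provenance,
        minority_label=str(minority_label),
        majority_label=str(majority_label),
        minority_final=n_min,
        majority_final=maj_target,
    )
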