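"""Coarse partitioning by spherical k-means.

Vectors are unit-normalized and clustered under the cosine distance
1 − cos(x, c); centroids are the normalized mean directions of their
members.  This is the coarse "ballpark" phase of the two-phase scheme —
each coarse cluster is subsequently refined by hierarchical clustering.
Initialization is a k-means++-style seeding adapted to cosine distance,
with a fixed RNG seed for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .microenv import MicroenvironmentSet

DEFAULT_K = 40
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6
DEFAULT_N_RESTARTS = 10


@dataclass
class CoarseClustering:
    k: int
    assignments: np.ndarray  # per-site cluster index in [0, k)
    centroids: np.ndarray  # k × D, unit rows
    objective: float  # Σ_sites (1 − cos to assigned centroid)
    n_iter: int
    seed: int

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)

    def to_tsv(self, ms: MicroenvironmentSet, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "structure_id": [s.structure_id for s in ms.sites],
                "chain": [s.chain for s in ms.sites],
                "residue_number": [s.residue_number for s in ms.sites],
                "residue_name": [s.residue_name for s in ms.sites],
                "coarse_cluster": self.assignments,
            }
        ).to_csv(path, sep="\t", index=False)

    def centroids_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "centroids": self.centroids.tolist()}, fh)


def unit_rows(x: np.ndarray) -> np.ndarray:
    """Row-normalize to the unit sphere; raises on all-zero rows."""
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"all-zero vector at row {int(np.flatnonzero(norms == 0)[0])}")
    return x / norms[:, None]


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with cosine distance: sample proportional to 1 − cos."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d = np.maximum(1.0 - x @ centers[0], 0.0)
    for j in range(1, k):
        total = d.sum()
        if total <= 0:  # all points coincide with chosen centers
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d / total)
        centers[j] = x[idx]
        d = np.minimum(d, np.maximum(1.0 - x @ centers[j], 0.0))
    return centers


def _update_centroids(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Normalized member means; empty clusters reseeded with the point
    cosine-farthest from its current centroid."""
    k = centroids.shape[0]
    new = np.zeros_like(centroids)
    for j in range(k):
        mask = labels == j
        if mask.any():
            mean = x[mask].mean(axis=0)
            norm = np.linalg.norm(mean)
            new[j] = mean / norm if norm > 0 else centroids[j]
        else:
            sim = np.einsum("ij,ij->i", x, centroids[labels])
            new[j] = x[int(np.argmin(sim))]
    return new


def kmeans_cosine(ms: MicroenvironmentSet, k: int, seed: int = 0,
                  max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL) -> CoarseClustering:
    """Spherical k-means on a microenvironment set.

    Iterates assignment/update until the assignment reaches a fixed point,
    the objective improves by less than ``tol``, or ``max_iter`` passes.
    Deterministic given ``seed``.  The objective Σ (1 − cos) is
    non-increasing across iterations (asserted).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ms.n_sites:
        raise ValueError(f"k={k} exceeds n_sites={ms.n_sites}")
    x = unit_rows(ms.features)
    rng = np.random.default_rng(seed)
    centroids = _plusplus_init(x, k, rng)

    labels = None
    prev_objective = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sim = x @ centroids.T
        new_labels = np.argmax(sim, axis=1)
        objective = float(np.sum(1.0 - sim[np.arange(len(x)), new_labels]))
        assert objective <= prev_objective + 1e-9, "k-means objective increased"
        converged = labels is not None and (
            np.array_equal(new_labels, labels) or prev_objective - objective < tol
        )
        labels = new_labels
        prev_objective = objective
        if converged:
            break
        centroids = _update_centroids(x, labels, centroids)

    # final centroids consistent with final labels
    centroids = _update_centroids(x, labels, centroids)
    sim = x @ centroids.T
    labels = np.argmax(sim, axis=1)
    objective = float(np.sum(1.0 - sim[np.arange(len(x)), labels]))
    return CoarseClustering(
        k=k, assignments=labels, centroids=centroids,
        objective=objective, n_iter=n_iter, seed=seed,
    )


def restarts(ms: MicroenvironmentSet, k: int, n_restarts: int = DEFAULT_N_RESTARTS,
             base_seed: int = 0, **kwargs) -> CoarseClustering:
    """Best of ``n_restarts`` seeded runs (seeds base_seed..base_seed+n−1);
    ties go to the lowest seed."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    for s in range(base_seed, base_seed + n_restarts):
        result = kmeans_cosine(ms, k, seed=s, **kwargs)
        if best is None or result.objective < best.objective:
            best = result
    return best
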