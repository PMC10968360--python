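"""Correspondence search and the registration mean-squared error.

The registration fitness of a candidate parameter vector is the mean of
squared distances between every transformed source point and its nearest
target point:

    f(params) = (1/N) * sum_j || q_j @ H(params).T - p_{c(j)} ||^2
    c(j) = argmin_i || q_j @ H.T - p_i ||

The objective is asymmetric (source onto target), has no outlier rejection
and no distance cap.  Nearest neighbours are exact, served by a spatial
index built once per target cloud and reused across all fitness
evaluations; ``batch`` evaluates a whole population in one query, which is
what makes population metaheuristics tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._kdtree import HAVE_NUMBA, ExactNN
from .geometry import (
    AffineParams,
    apply_transform,
    as_cloud,
    compose_matrix,
    compose_matrix_batch,
)

__all__ = [
    "Correspondence",
    "nearest_correspondences",
    "registration_mse",
    "RegistrationObjective",
]


@dataclass(frozen=True)
class Correspondence:
    """Nearest-target assignment for each source point.

    ``indices[j]`` is the target index of source point j's exact Euclidean
    nearest neighbour (ties broken by the lowest target index) and
    ``sq_distances[j]`` the corresponding squared distance.
    """

    indices: np.ndarray
    sq_distances: np.ndarray


def nearest_correspondences(
    transformed_source: np.ndarray, target: np.ndarray
) -> Correspondence:
    """Exact nearest-neighbour assignment from source points to the target.

    Ties (several target points at the same minimal distance) resolve to
    the lowest target index.
    """
    src = as_cloud(transformed_source)
    tgt = as_cloud(target)
    tree = cKDTree(tgt)
    dist, idx = tree.query(src, k=1)
    # k-d tree tie-breaking is implementation-defined; re-resolve exact ties
    # against the full candidate set at that distance.
    for j in range(src.shape[0]):
        cands = tree.query_ball_point(src[j], dist[j] + 1e-300)
        if len(cands) > 1:
            d2 = np.sum((tgt[cands] - src[j]) ** 2, axis=1)
            best = min((d, i) for d, i in zip(d2, cands))
            idx[j] = best[1]
            dist[j] = np.sqrt(best[0])
    return Correspondence(indices=np.asarray(idx), sq_distances=np.asarray(dist) ** 2)


def registration_mse(
    params: AffineParams | np.ndarray, source: np.ndarray, target: np.ndarray
) -> float:
    """Registration MSE of a single candidate parameter vector."""
    obj = RegistrationObjective(source, target)
    return obj(params)


class RegistrationObjective:
    """Reusable registration fitness for one source/target cloud pair.

    The target's spatial index is built once.  Squared nearest-neighbour
    distances come from a compiled exact k-d tree kernel when numba is
    available and from scipy's cKDTree otherwise; both paths honour the
    exact-nearest-neighbour contract.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray):
        self.source = as_cloud(source)
        self.target = as_cloud(target)
        self._ckdtree = cKDTree(self.target)
        self._nn = ExactNN(self.target) if HAVE_NUMBA else None

    @property
    def n_source(self) -> int:
        return self.source.shape[0]

    def _sq_dists(self, queries: np.ndarray) -> np.ndarray:
        if self._nn is not None:
            return self._nn.sq_dists(queries)
        dist, _ = self._ckdtree.query(queries, k=1)
        return dist * dist

    def mse_of_matrix(self, H: np.ndarray) -> float:
        moved = apply_transform(self.source, H)
        return float(np.mean(self._sq_dists(moved)))

    def __call__(self, params: AffineParams | np.ndarray) -> float:
        if isinstance(params, AffineParams):
            H = compose_matrix(params)
        else:
            H = compose_matrix(AffineParams.from_vector(params))
        return self.mse_of_matrix(H)

    def batch(self, param_matrix: np.ndarray) -> np.ndarray:
        """Fitness of (K, 15) parameter rows, returned as a (K,) vector."""
        P = np.asarray(param_matrix, dtype=float)
        H = compose_matrix_batch(P)  # (K, 4, 4)
        K = P.shape[0]
        n = self.n_source
        # one BLAS product for the whole population: (N, 3) @ (3, K*3)
        R_flat = H[:, :3, :3].reshape(K * 3, 3)
        moved = (self.source @ R_flat.T).reshape(n, K, 3) + H[:, :3, 3][None, :, :]
        d2 = self._sq_dists(moved.reshape(n * K, 3)).reshape(n, K)
        return d2.mean(axis=0)

    def correspondences_of(self, params: AffineParams | np.ndarray) -> np.ndarray:
        """Nearest-target indices at ``params`` (no tie post-processing)."""
        if isinstance(params, AffineParams):
            params = params.to_vector()
        H = compose_matrix(AffineParams.from_vector(params))
        moved = apply_transform(self.source, H)
        _, idx = self._ckdtree.query(moved, k=1)
        return idx

    def frozen(self, params: AffineParams | np.ndarray) -> "FrozenCorrespondenceMSE":
        """Freeze correspondences at ``params`` (the ICP inner objective)."""
        idx = self.correspondences_of(params)
        return FrozenCorrespondenceMSE(self.source, self.target[idx])


class FrozenCorrespondenceMSE:
    """Smooth MSE against a fixed correspondence assignment."""

    def __init__(self, source: np.ndarray, matched_target: np.ndarray):
        self.source = source
        self.matched_target = matched_target

    def __call__(self, vec: np.ndarray) -> float:
        H = compose_matrix_batch(np.asarray(vec, dtype=float)[None, :])[0]
        moved = self.source @ H[:3, :3].T + H[:3, 3]
        diff = moved - self.matched_target
        return float(np.mean(np.sum(diff * diff, axis=1)))
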