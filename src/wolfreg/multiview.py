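"""Hierarchical registration of consecutive views into one reconstruction.

Multi-view scans of one object are merged bottom-up: level 1 registers
every consecutive view pair; at higher levels the surviving merged clouds
are registered pairwise until a single reconstruction remains.  Because
consecutive views share only part of the object, each pairwise
registration first narrows both clouds to their mutual overlap: points are
optionally random-subsampled, then kept only when their occupied voxel is
occupied by both clouds (voxel-hull overlap), with one representative per
voxel.  After the coarse-to-fine registration, the overlap is re-selected
in the aligned frame with progressively smaller voxels and re-polished
(``refine_overlap``), which removes boundary points lacking a true
counterpart and the bias they induce.  The recovered transform is then
applied to the *full* source view for merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import SearchBounds, DEFAULT_BOUNDS, apply_transform, as_cloud
from .objective import RegistrationObjective
from .optimizer import GWOConfig, optimize
from .refine import ICPConfig, icp_refine
from .result import RegistrationResult

__all__ = [
    "overlap_sample",
    "voxel_overlap",
    "refine_overlap",
    "register_pair",
    "register_views",
    "MultiviewResult",
]


def _voxel_keys(pts: np.ndarray, origin: np.ndarray, voxel_size: float) -> np.ndarray:
    return np.floor((pts - origin) / voxel_size).astype(np.int64)


def overlap_sample(
    cloud: np.ndarray,
    fraction: float = 0.6,
    voxel_size: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """Random subsample followed by one representative point per voxel.

    Keeps ceil(fraction * N) uniformly chosen points, then bins them on a
    regular grid of side ``voxel_size`` (default: 1/50 of the bounding-box
    diagonal) and keeps, per occupied voxel, the point nearest the voxel's
    centroid of members.
    """
    pts = as_cloud(cloud)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = pts.shape[0]
    keep = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=keep, replace=False)
    sub = pts[np.sort(idx)]

    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    diag = float(np.linalg.norm(hi - lo))
    if voxel_size is None:
        voxel_size = max(diag / 50.0, 1e-12)
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if voxel_size > max(diag, 1e-300):
        warnings.warn(
            "voxel size exceeds the cloud extent; a single representative "
            "point will be returned",
            stacklevel=2,
        )
    keys = _voxel_keys(sub, lo, voxel_size)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    out = []
    for v in np.unique(inverse):
        members = np.flatnonzero(inverse == v)
        centroid = sub[members].mean(axis=0)
        d2 = np.sum((sub[members] - centroid) ** 2, axis=1)
        out.append(sub[members[np.argmin(d2)]])
    return np.asarray(out)


def _mutual_voxel_masks(
    a: np.ndarray, b: np.ndarray, voxel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of points whose voxel is occupied by both clouds."""
    lo = np.minimum(a.min(axis=0), b.min(axis=0))
    ka = _voxel_keys(a, lo, voxel_size)
    kb = _voxel_keys(b, lo, voxel_size)
    set_b = {tuple(k) for k in kb}
    set_a = {tuple(k) for k in ka}
    mask_a = np.fromiter((tuple(k) in set_b for k in ka), bool, count=len(ka))
    mask_b = np.fromiter((tuple(k) in set_a for k in kb), bool, count=len(kb))
    return mask_a, mask_b


def voxel_overlap(
    cloud_a: np.ndarray, cloud_b: np.ndarray, voxel_size: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subsets of two clouds lying in voxels occupied by both.

    The grid is anchored at the joint minimum corner; the default voxel
    side is 1/50 of the joint bounding-box diagonal.
    """
    a = as_cloud(cloud_a)
    b = as_cloud(cloud_b)
    lo = np.minimum(a.min(axis=0), b.min(axis=0))
    hi = np.maximum(a.max(axis=0), b.max(axis=0))
    if voxel_size is None:
        voxel_size = max(float(np.linalg.norm(hi - lo)) / 50.0, 1e-12)
    mask_a, mask_b = _mutual_voxel_masks(a, b, voxel_size)
    if not mask_a.any() or not mask_b.any():
        return a, b  # no detectable overlap: fall back to the full clouds
    return a[mask_a], b[mask_b]


def refine_overlap(
    source: np.ndarray,
    target: np.ndarray,
    result: RegistrationResult,
    icp_cfg: Optional[ICPConfig] = None,
    divisors: Sequence[float] = (50.0, 150.0, 400.0, 1000.0),
    min_points: int = 30,
) -> RegistrationResult:
    """Iteratively re-select the mutual overlap in the aligned frame and re-polish.

    The initial overlap selection happens before alignment, so points near
    the boundary of the shared region but without a true counterpart
    survive and bias the registration optimum.  Once a first estimate
    exists, the source can be mapped into the target frame and the mutual
    voxel occupancy re-evaluated there with progressively smaller voxels
    (joint bounding-box diagonal divided by each entry of ``divisors``),
    shrinking the stray band at each pass; the transform is then re-polished
    on the cleaned subsets.  Each pass is validated on the full clouds with
    the *median* squared nearest-neighbour distance — a stray-robust
    alignment score — and rejected (stopping the ladder) if it does not
    improve it, so a stray-dominated subset cannot drag the alignment away.
    Shrinking also stops when either cleaned side drops below
    ``min_points``.  The returned MSE refers to the final cleaned overlap
    subsets.
    """
    src = as_cloud(source)
    tgt = as_cloud(target)
    joint = np.vstack([src, tgt])
    diag = float(np.linalg.norm(joint.max(axis=0) - joint.min(axis=0)))

    full_obj = RegistrationObjective(src, tgt)

    def median_score(res: RegistrationResult) -> float:
        moved = apply_transform(src, res.matrix)
        return float(np.median(full_obj._sq_dists(moved)))

    best = result
    best_score = median_score(best)
    for div in divisors:
        moved = apply_transform(src, best.matrix)
        mask_s, mask_t = _mutual_voxel_masks(moved, tgt, max(diag / div, 1e-12))
        if mask_s.sum() < min_points or mask_t.sum() < min_points:
            break
        res = icp_refine(best.params, src[mask_s], tgt[mask_t], icp_cfg)
        score = median_score(res)
        if score > best_score:
            break
        res.trace = best.trace
        res.coarse_mse = best.coarse_mse
        res.seed = best.seed
        res.branch_counts = best.branch_counts
        best, best_score = res, score
    return best


def register_pair(
    source: np.ndarray,
    target: np.ndarray,
    gwo_cfg: Optional[GWOConfig] = None,
    icp_cfg: Optional[ICPConfig] = None,
    bounds: SearchBounds = DEFAULT_BOUNDS,
    use_icp: bool = True,
) -> RegistrationResult:
    """Coarse-to-fine registration of one source cloud onto one target."""
    gwo_cfg = gwo_cfg or GWOConfig()
    obj = RegistrationObjective(source, target)
    coarse = optimize(obj, bounds, gwo_cfg, batch_objective=obj.batch)
    if use_icp:
        res = icp_refine(coarse.x, source, target, icp_cfg)
        res.trace = coarse.trace
        res.coarse_mse = coarse.fun
        res.seed = gwo_cfg.seed
        res.branch_counts = coarse.branch_counts
        return res
    return RegistrationResult(
        params=coarse.params,
        mse=coarse.fun,
        trace=coarse.trace,
        refined=False,
        coarse_mse=coarse.fun,
        seed=gwo_cfg.seed,
        branch_counts=coarse.branch_counts,
    )


@dataclass
class MultiviewResult:
    """Outcome of a hierarchical multi-view registration."""

    merged: np.ndarray
    level1: list[RegistrationResult]
    all_results: list[tuple[str, RegistrationResult]]
    final_mse: float


def register_views(
    views: Sequence[np.ndarray],
    gwo_cfg: Optional[GWOConfig] = None,
    icp_cfg: Optional[ICPConfig] = None,
    bounds: SearchBounds = DEFAULT_BOUNDS,
    fraction: float = 1.0,
    voxel_size: Optional[float] = None,
    use_icp: bool = True,
    topology: str = "balanced",
    seed: int = 0,
    overlap_refine: bool = True,
) -> MultiviewResult:
    """Hierarchically register F ordered views into one merged cloud.

    Level 1 registers every consecutive pair (1,2), (2,3), ..., (F-1,F):
    the later view is the source, the earlier the target, and each
    registration works on the voxel-hull overlap of the (optionally
    ``fraction``-subsampled) pair.  Survivor merging is then either
    ``balanced`` — merge (1,2), (3,4), ...; re-register merged survivors
    pairwise until one cloud remains (odd survivors carry over) — or
    ``chain`` — fold each next view into the running reconstruction.  The
    final MSE is the registration MSE of the last merge.
    """
    views = [as_cloud(v) for v in views]
    F = len(views)
    if F < 2:
        raise ValueError("need at least two views")
    if topology not in ("balanced", "chain"):
        raise ValueError("topology must be 'balanced' or 'chain'")
    gwo_cfg = gwo_cfg or GWOConfig()

    def run(src: np.ndarray, tgt: np.ndarray, label: str, run_seed: int) -> RegistrationResult:
        if fraction < 1.0:
            src_s = overlap_sample(src, fraction, voxel_size=None, seed=run_seed)
            tgt_s = overlap_sample(tgt, fraction, voxel_size=None, seed=run_seed + 1)
        else:
            src_s, tgt_s = src, tgt
        src_o, tgt_o = voxel_overlap(src_s, tgt_s, voxel_size)
        cfg = GWOConfig(**{**gwo_cfg.__dict__, "seed": run_seed})
        try:
            res = register_pair(src_o, tgt_o, cfg, icp_cfg, bounds, use_icp)
            if overlap_refine and use_icp:
                res = refine_overlap(src_s, tgt_s, res, icp_cfg)
            return res
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"registration of pair {label} failed: {exc}") from exc

    all_results: list[tuple[str, RegistrationResult]] = []

    # level 1: consecutive pairs, later view onto earlier view
    level1 = []
    for k in range(F - 1):
        label = f"{k + 1} vs. {k + 2}"
        res = run(views[k + 1], views[k], label, seed + k)
        level1.append(res)
        all_results.append((label, res))

    # higher levels
    if topology == "chain":
        merged = views[0]
        last = None
        for k in range(1, F):
            res = level1[k - 1] if k == 1 else run(views[k], merged, f"view {k + 1} vs. merged", seed + 100 + k)
            merged = np.vstack([merged, apply_transform(views[k], res.matrix)])
            last = res
        final_mse = last.mse
    else:
        # merge level-1 odd/even pairs: (1,2), (3,4), ...
        survivors = []
        k = 0
        pair_i = 0
        while k < F:
            if k + 1 < F:
                res = level1[k]  # registration of view k+2 onto view k+1
                merged_pair = np.vstack(
                    [views[k], apply_transform(views[k + 1], res.matrix)]
                )
                survivors.append(merged_pair)
                last = res
            else:
                survivors.append(views[k])
            k += 2
            pair_i += 1
        level = 2
        run_id = 0
        while len(survivors) > 1:
            nxt = []
            for i in range(0, len(survivors) - 1, 2):
                label = f"level {level} merge {i // 2 + 1}"
                res = run(survivors[i + 1], survivors[i], label, seed + 1000 * level + run_id)
                run_id += 1
                all_results.append((label, res))
                nxt.append(
                    np.vstack([survivors[i], apply_transform(survivors[i + 1], res.matrix)])
                )
                last = res
            if len(survivors) % 2:
                nxt.append(survivors[-1])
            survivors = nxt
            level += 1
        merged = survivors[0]
        final_mse = last.mse

    return MultiviewResult(
        merged=merged,
        level1=level1,
        all_results=all_results,
        final_mse=float(final_mse),
    )
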