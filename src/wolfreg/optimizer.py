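"""Grey wolf optimizer with behaviour considerations and dimensional learning.

The pack of K wolves minimizes a scalar objective over a 15-dimensional
box.  Each iteration runs four stages:

1. *Leader pull* — every wolf moves to a weighted combination of pulls
   toward the three fitness-ranked leaders (alpha, beta, delta).  The
   alpha distance is modulated by a sine/cosine factor and the C vectors
   shrink deterministically over iterations; the leader weights start
   alpha-dominated and converge to 1/3 each.
2. *Behaviour consideration* — an exploration/exploitation branch.  While
   a per-wolf control scalar |A| > 1 the candidate adds heavy-tailed Lévy
   steps (either one step on the weighted pull, or Lévy-perturbed pulls of
   all three leaders); once |A| <= 1 the candidate is a random-opposition
   point of the wolf's personal best.  Accepted only on strict improvement.
3. *Dimensional learning* — a per-dimension candidate mixing a random
   neighbourhood wolf (within the radius of the wolf's own displacement)
   and a random pack member.  Accepted only on strict improvement.
4. *Final greedy* — the wolf keeps its old position unless the surviving
   candidate strictly improves its fitness, so per-wolf and global best
   fitness are non-increasing.

All candidates are clipped to the search box.  Every random draw comes
from one seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gamma as _gamma

from .geometry import SearchBounds
from .result import OptimizeResult

__all__ = [
    "GWOConfig",
    "schedule_a",
    "schedule_c",
    "sample_C",
    "leader_weights",
    "levy_sigma_u",
    "leader_pull",
    "levy_step",
    "rol_point",
    "behavior_candidate",
    "neighborhood_indices",
    "dimensional_candidate",
    "optimize",
]


@dataclass(frozen=True)
class GWOConfig:
    """Optimizer settings.

    ``population`` (K) and ``iterations`` (T) default to the benchmark
    configuration (100 wolves, 2000 iterations).  ``mu`` shapes the decay
    of the control parameter a = 2((T-t)/T)^mu; ``beta_levy`` is the Lévy
    index of the Mantegna step construction.
    """

    population: int = 100
    iterations: int = 2000
    mu: float = 1.0
    beta_levy: float = 1.5
    seed: int = 0
    a0: float = 2.0
    c_min: float = 0.0
    c_max: float = 1.0
    sca_angle_mode: str = "literal"  # "literal": U[0,1] angles; "scaled": U[0,2pi]
    levy_alpha_mode: str = "hyperbolic"  # or "exponential"

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be at least 4 (three leaders plus omega)")
        if self.iterations < 2:
            raise ValueError("iterations must be at least 2")
        if not 0 < self.mu <= 2:
            raise ValueError("mu must lie in (0, 2]")
        if not 1 < self.beta_levy <= 2:
            raise ValueError("beta_levy must lie in (1, 2]")
        if self.sca_angle_mode not in ("literal", "scaled"):
            raise ValueError("sca_angle_mode must be 'literal' or 'scaled'")
        if self.levy_alpha_mode not in ("hyperbolic", "exponential"):
            raise ValueError("levy_alpha_mode must be 'hyperbolic' or 'exponential'")


def schedule_a(t: int, T: int, mu: float, a0: float = 2.0) -> float:
    """Nonlinear decay of the encircling control parameter.

    a(t) = a0 * ((T - t) / T)^mu, equal to a0 at t = 0 and 0 at t = T,
    strictly decreasing in between.
    """
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, T={T}]")
    return a0 * ((T - t) / T) ** mu


def schedule_c(t: int, T: int, c_min: float = 0.0, c_max: float = 1.0) -> float:
    """Linear decay of the C-vector spread: c(1) = c_max, c(T) = c_min."""
    if T == 1:
        return c_max
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} outside [1, T={T}]")
    return c_max - (c_max - c_min) * (t - 1) / (T - 1)


def sample_C(c: float, rng: np.random.Generator, d: int = 15) -> np.ndarray:
    """Draw one leader's C vector: C_j = 1 + (2 r_j - 1) c^2, r_j ~ U[0,1].

    Elements lie in [1 - c^2, 1 + c^2]; for c = 0 the vector is exactly 1.
    """
    r = rng.random(d)
    return 1.0 + (2.0 * r - 1.0) * c * c


def leader_weights(t: float, grouping: str = "consistent") -> tuple[float, float, float]:
    """Aggregation weights of the three leader pulls at iteration t.

    w1 = cos(theta), w2 = 0.5 sin(theta) cos(phi), w3 = 1 - w1 - w2, with
    phi = 0.5 arctan(t) and theta = (2/pi) arccos(1/3) arctan(t) (the
    grouping under which w1 -> 1 as t -> 0 and all three -> 1/3 as
    t -> inf).  ``grouping="literal"`` uses theta = 2 pi arccos(1/3)
    arctan(t) instead, which oscillates and does not satisfy those limits.
    """
    at = math.atan(t)
    if grouping == "consistent":
        theta = (2.0 / math.pi) * math.acos(1.0 / 3.0) * at
    elif grouping == "literal":
        theta = 2.0 * math.pi * math.acos(1.0 / 3.0) * at
    else:
        raise ValueError("grouping must be 'consistent' or 'literal'")
    phi = 0.5 * at
    w1 = math.cos(theta)
    w2 = 0.5 * math.sin(theta) * math.cos(phi)
    w3 = 1.0 - w1 - w2
    return w1, w2, w3


def levy_sigma_u(beta: float) -> float:
    """Mantegna scale sigma_u of the Lévy step numerator.

    sigma_u = [Gamma(1+b) sin(pi b / 2) / (Gamma((1+b)/2) b 2^((b-1)/2))]^(1/b)
    with sigma_v = 1.
    """
    num = _gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def _levy_alpha(bounds: SearchBounds, t: int, d: int, mode: str) -> np.ndarray:
    """Per-dimension Lévy step scale, decaying over iterations."""
    L = bounds.widths
    if mode == "hyperbolic":
        return L / (10.0 * max(t, 1) * d)
    return L * 10.0 ** (-float(t) * d)


def _sca_scale(rng: np.random.Generator, mode: str) -> float:
    """Sine/cosine modulation factor of the alpha distance (one wolf)."""
    coin = rng.random()
    r_amp = rng.random()
    ang = rng.random()
    if mode == "scaled":
        ang *= 2.0 * math.pi
    return r_amp * (math.sin(ang) if coin < 0.5 else math.cos(ang))


def leader_pull(
    wolf: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    A: np.ndarray,
    C: np.ndarray,
    rng: np.random.Generator,
    sca_angle_mode: str = "literal",
    sca_scale: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pulls x1, x2, x3 of one wolf toward alpha, beta, delta.

    ``A`` and ``C`` are (3, d) stacks of per-leader control vectors.  The
    alpha distance |C_a * x_a - x| is additionally scaled by a sine/cosine
    factor (``sca_scale`` overrides the random draw, for tests).
    """
    xa, xb, xd = leaders
    wolf = np.asarray(wolf, dtype=float)
    scale = _sca_scale(rng, sca_angle_mode) if sca_scale is None else sca_scale
    Da = scale * np.abs(C[0] * xa - wolf)
    Db = np.abs(C[1] * xb - wolf)
    Dd = np.abs(C[2] * xd - wolf)
    x1 = xa - A[0] * Da
    x2 = xb - A[1] * Db
    x3 = xd - A[2] * Dd
    return x1, x2, x3


def levy_step(
    wolf_pos: np.ndarray,
    alpha_pos: np.ndarray,
    t: int,
    bounds: SearchBounds,
    config: GWOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Heavy-tailed per-dimension step scaled by the wolf-to-alpha offset.

    step_j = eta_j * alpha_j * (u_j / |v_j|^(1/beta)) * (x_j - x_alpha_j)
    with eta ~ N(0,1), u ~ N(0, sigma_u^2), v ~ N(0,1).
    """
    wolf_pos = np.asarray(wolf_pos, dtype=float)
    alpha_pos = np.asarray(alpha_pos, dtype=float)
    d = wolf_pos.size
    beta = config.beta_levy
    su = levy_sigma_u(beta)
    eta = rng.standard_normal(d)
    u = rng.standard_normal(d) * su
    v = rng.standard_normal(d)
    alpha_j = _levy_alpha(bounds, t, d, config.levy_alpha_mode)
    return eta * alpha_j * (u / np.abs(v) ** (1.0 / beta)) * (wolf_pos - alpha_pos)


def rol_point(
    personal_best: np.ndarray, bounds: SearchBounds, rng: np.random.Generator
) -> np.ndarray:
    """Random-opposition point of a personal best, clipped to the box.

    x_hat_j = lb_j + ub_j - r_j * xb_j with fresh r_j ~ U[0,1] per
    dimension.
    """
    xb = np.asarray(personal_best, dtype=float)
    r = rng.random(xb.size)
    return bounds.clip(bounds.lb + bounds.ub - r * xb)


def behavior_candidate(
    wolf_pos: np.ndarray,
    personal_best: np.ndarray,
    pulls: tuple[np.ndarray, np.ndarray, np.ndarray],
    weights: tuple[float, float, float],
    alpha_pos: np.ndarray,
    A_branch: float,
    t: int,
    bounds: SearchBounds,
    config: GWOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """The behaviour-consideration candidate of one wolf.

    Exploration (|A| > 1): with probability 1/2 the weighted leader pull
    plus one Lévy step, otherwise the weighted sum of three Lévy-perturbed
    pulls.  Exploitation (|A| <= 1): the random-opposition point of the
    personal best.  Clipped to bounds.
    """
    x1, x2, x3 = pulls
    w1, w2, w3 = weights
    if abs(A_branch) > 1.0:
        wsum = w1 * x1 + w2 * x2 + w3 * x3
        if rng.random() <= 0.5:
            cand = wsum + levy_step(wolf_pos, alpha_pos, t, bounds, config, rng)
        else:
            l1 = levy_step(wolf_pos, alpha_pos, t, bounds, config, rng)
            l2 = levy_step(wolf_pos, alpha_pos, t, bounds, config, rng)
            l3 = levy_step(wolf_pos, alpha_pos, t, bounds, config, rng)
            cand = w1 * (x1 + l1) + w2 * (x2 + l2) + w3 * (x3 + l3)
        return bounds.clip(cand)
    return rol_point(personal_best, bounds, rng)


def neighborhood_indices(
    wolf_pos: np.ndarray, next_pos: np.ndarray, pack: np.ndarray
) -> np.ndarray:
    """Pack indices within R = ||x - x_next|| of the wolf's position.

    The wolf itself qualifies at distance 0.  When no *other* wolf lies
    within R, the single nearest other wolf is returned instead.
    """
    wolf_pos = np.asarray(wolf_pos, dtype=float)
    pack = np.asarray(pack, dtype=float)
    R = float(np.linalg.norm(wolf_pos - np.asarray(next_pos, dtype=float)))
    dists = np.linalg.norm(pack - wolf_pos, axis=1)
    neigh = np.flatnonzero(dists <= R)
    others = np.flatnonzero(dists > 0)
    only_self = len(neigh) == 0 or (len(neigh) == 1 and dists[neigh[0]] == 0.0)
    if only_self and len(others):
        return np.array([others[np.argmin(dists[others])]])
    if len(neigh) == 0:
        return np.arange(pack.shape[0])
    return neigh


def dimensional_candidate(
    wolf_pos: np.ndarray,
    next_pos: np.ndarray,
    pack: np.ndarray,
    bounds: SearchBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-dimension neighbourhood-learning candidate of one wolf.

    The neighbourhood is every pack member within R = ||x - x_next|| of
    the wolf's current position (the wolf itself qualifies at distance 0).
    If no *other* wolf lies within R, the nearest other wolf is used as
    the sole neighbour.  Per dimension j:
    cand_j = x_j + r_j (x_{n,j} - x_{r,j}), with x_n drawn from the
    neighbourhood and x_r from the whole pack, fresh draws per dimension.
    """
    wolf_pos = np.asarray(wolf_pos, dtype=float)
    pack = np.asarray(pack, dtype=float)
    d = wolf_pos.size
    K = pack.shape[0]
    neigh = neighborhood_indices(wolf_pos, next_pos, pack)
    n_idx = neigh[rng.integers(0, len(neigh), d)]
    r_idx = rng.integers(0, K, d)
    r = rng.random(d)
    j = np.arange(d)
    cand = wolf_pos + r * (pack[n_idx, j] - pack[r_idx, j])
    return bounds.clip(cand)


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: SearchBounds,
    config: GWOConfig,
    batch_objective: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    callback: Optional[Callable[[int, float], None]] = None,
    record_history: bool = False,
) -> OptimizeResult:
    """Run the full optimizer loop and return the global best.

    ``batch_objective`` (mapping a (K, d) position block to a (K,) fitness
    vector) enables vectorized fitness evaluation; when absent the scalar
    ``objective`` is mapped row by row.  The returned trace holds the
    global best fitness after every iteration and is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    d = bounds.lb.size
    K = config.population
    T = config.iterations
    mode = config.sca_angle_mode

    if batch_objective is None:
        def batch_objective(P: np.ndarray) -> np.ndarray:  # noqa: F811
            return np.array([objective(row) for row in P], dtype=float)

    def evaluate(P: np.ndarray) -> np.ndarray:
        f = np.asarray(batch_objective(P), dtype=float)
        if not np.all(np.isfinite(f)):
            bad = np.flatnonzero(~np.isfinite(f))
            raise ValueError(
                f"objective returned non-finite fitness for {len(bad)} candidate(s); "
                f"first offending position: {P[bad[0]]!r}"
            )
        return f

    X = bounds.sample(rng, K)
    fit = evaluate(X)
    pbest = X.copy()
    pbest_fit = fit.copy()

    su = levy_sigma_u(config.beta_levy)
    inv_beta = 1.0 / config.beta_levy

    trace = np.empty(T)
    branch_counts = {"levy_single": 0, "levy_leaders": 0, "rol": 0}
    history_fitness = np.empty((T, K)) if record_history else None
    history_positions = np.empty((T, K, d)) if record_history else None

    lb, ub = bounds.lb, bounds.ub

    def levy_block(offset: np.ndarray, alpha_j: np.ndarray) -> np.ndarray:
        eta = rng.standard_normal((K, d))
        u = rng.standard_normal((K, d)) * su
        v = rng.standard_normal((K, d))
        return eta * alpha_j * (u / np.abs(v) ** inv_beta) * offset

    for t in range(1, T + 1):
        order = np.argsort(fit, kind="stable")
        ia, ib, idl = order[0], order[1], order[2]
        xa, xb, xd = X[ia], X[ib], X[idl]

        a = schedule_a(t, T, config.mu, config.a0)
        c = schedule_c(t, T, config.c_min, config.c_max)
        w1, w2, w3 = leader_weights(t)

        A = 2.0 * a * rng.random((3, K, d)) - a
        C = 1.0 + (2.0 * rng.random((3, K, d)) - 1.0) * c * c

        coin = rng.random(K)
        amp = rng.random(K)
        ang = rng.random(K)
        if mode == "scaled":
            ang = ang * (2.0 * math.pi)
        sca = amp * np.where(coin < 0.5, np.sin(ang), np.cos(ang))

        Da = sca[:, None] * np.abs(C[0] * xa - X)
        Db = np.abs(C[1] * xb - X)
        Dd = np.abs(C[2] * xd - X)
        x1 = xa - A[0] * Da
        x2 = xb - A[1] * Db
        x3 = xd - A[2] * Dd
        wsum = w1 * x1 + w2 * x2 + w3 * x3

        X_next = np.clip(wsum, lb, ub)
        fit_next = evaluate(X_next)

        # --- behaviour consideration ---
        A_branch = 2.0 * a * rng.random(K) - a
        bc_coin = rng.random(K)
        alpha_j = _levy_alpha(bounds, t, d, config.levy_alpha_mode)
        offset = X - xa
        levy0 = levy_block(offset, alpha_j)
        l1 = levy_block(offset, alpha_j)
        l2 = levy_block(offset, alpha_j)
        l3 = levy_block(offset, alpha_j)
        bc_single = wsum + levy0
        bc_leaders = wsum + w1 * l1 + w2 * l2 + w3 * l3
        rol = lb + ub - rng.random((K, d)) * pbest

        explore = np.abs(A_branch) > 1.0
        single = explore & (bc_coin <= 0.5)
        multi = explore & ~single
        XBC = np.where(single[:, None], bc_single, np.where(multi[:, None], bc_leaders, rol))
        XBC = np.clip(XBC, lb, ub)
        branch_counts["levy_single"] += int(single.sum())
        branch_counts["levy_leaders"] += int(multi.sum())
        branch_counts["rol"] += int((~explore).sum())

        fit_bc = evaluate(XBC)
        imp = fit_bc < fit_next
        X_next[imp] = XBC[imp]
        fit_next[imp] = fit_bc[imp]

        # --- dimensional learning ---
        R = np.linalg.norm(X - X_next, axis=1)
        diff = X[:, None, :] - X[None, :, :]
        Dmat = np.sqrt(np.einsum("lkj,lkj->lk", diff, diff))
        n_pick = rng.random((K, d))
        r_idx = rng.integers(0, K, (K, d))
        r_dl = rng.random((K, d))
        n_idx = np.empty((K, d), dtype=np.intp)
        for l in range(K):
            neigh = np.flatnonzero(Dmat[l] <= R[l])
            if len(neigh) == 0 or (len(neigh) == 1 and neigh[0] == l):
                others = np.delete(np.arange(K), l)
                dl = Dmat[l, others]
                neigh = np.array([others[np.argmin(dl)]])
            n_idx[l] = neigh[(n_pick[l] * len(neigh)).astype(np.intp)]
        cols = np.arange(d)
        XDL = X + r_dl * (X[n_idx, cols] - X[r_idx, cols])
        XDL = np.clip(XDL, lb, ub)

        fit_dl = evaluate(XDL)
        imp = fit_dl < fit_next
        X_next[imp] = XDL[imp]
        fit_next[imp] = fit_dl[imp]

        # --- final greedy: keep the old position unless strictly better ---
        acc = fit_next < fit
        X[acc] = X_next[acc]
        fit[acc] = fit_next[acc]

        pb = fit < pbest_fit
        pbest[pb] = X[pb]
        pbest_fit[pb] = fit[pb]

        best_l = int(np.argmin(pbest_fit))
        trace[t - 1] = pbest_fit[best_l]
        if record_history:
            history_fitness[t - 1] = fit
            history_positions[t - 1] = X
        if callback is not None:
            callback(t, float(pbest_fit[best_l]))

    best_l = int(np.argmin(pbest_fit))
    return OptimizeResult(
        x=pbest[best_l].copy(),
        fun=float(pbest_fit[best_l]),
        trace=trace,
        branch_counts=branch_counts,
        population=X,
        population_fitness=fit,
        config=config,
        history_fitness=history_fitness,
        history_positions=history_positions,
    )
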