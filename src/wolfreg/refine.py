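"""ICP polishing of a coarse registration with a Nelder-Mead simplex.

The coarse optimizer lands near the optimum; the iterative closest point
loop then alternates (i) freezing nearest-neighbour correspondences at the
current parameters and (ii) minimizing the resulting smooth
frozen-correspondence MSE over all 15 affine parameters with a
derivative-free simplex, until the true MSE stops improving.  Outer steps
that do not improve are rejected, so the refined MSE never exceeds the
starting MSE.  Refined parameters are unconstrained (polishing may leave
the search box).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import AffineParams
from .objective import RegistrationObjective
from .result import RegistrationResult

__all__ = ["ICPConfig", "icp_refine"]


@dataclass(frozen=True)
class ICPConfig:
    """Refinement settings.

    ``fatol`` is the absolute simplex function tolerance: reaching MSE
    floors around 1e-20..1e-27 on exact synthetic pairs requires it to be
    effectively zero (default 1e-30).  ``restarts`` re-launches the
    simplex from the best point with a shrunken initial simplex, which
    recovers precision a collapsed simplex leaves behind.
    """

    max_outer_iters: int = 50
    fatol: float = 1e-30
    xatol: float = 1e-14
    maxfev: int = 20000
    mse_change_tol: float = 0.0
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.max_outer_iters < 1 or self.maxfev < 1 or self.restarts < 0:
            raise ValueError("iteration counts must be positive")
        if self.fatol <= 0 or self.xatol <= 0:
            raise ValueError("tolerances must be positive")
        if self.mse_change_tol < 0:
            raise ValueError("mse_change_tol must be non-negative")


def _simplex_min(fun, x0: np.ndarray, cfg: ICPConfig, scale: float) -> np.ndarray:
    """One Nelder-Mead run started from x0 with an explicit initial simplex."""
    d = x0.size
    sim = np.tile(x0, (d + 1, 1))
    for j in range(d):
        step = scale * max(abs(x0[j]), 1.0)
        sim[j + 1, j] += step
    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": sim,
            "fatol": cfg.fatol,
            "xatol": cfg.xatol,
            "maxfev": cfg.maxfev,
            "adaptive": True,
        },
    )
    return res.x


def icp_refine(
    start: AffineParams | np.ndarray,
    source: np.ndarray,
    target: np.ndarray,
    cfg: ICPConfig | None = None,
) -> RegistrationResult:
    """Polish ``start`` on the given cloud pair; never worsens the MSE."""
    cfg = cfg or ICPConfig()
    if isinstance(start, AffineParams):
        x = start.to_vector()
    else:
        x = np.asarray(start, dtype=float).ravel().copy()
    if x.shape != (15,) or not np.all(np.isfinite(x)):
        raise ValueError("start must be a finite 15-parameter vector")

    obj = RegistrationObjective(source, target)
    best_x = x.copy()
    best_mse = obj(best_x)

    scale = 1e-3
    for _ in range(cfg.max_outer_iters):
        frozen = obj.frozen(best_x)
        cand = _simplex_min(frozen, best_x, cfg, scale)
        for _ in range(cfg.restarts):
            cand = _simplex_min(frozen, cand, cfg, scale * 1e-3)
        cand_mse = obj(cand)
        if not cand_mse < best_mse:
            break  # non-improving outer step: reject and stop
        improvement = best_mse - cand_mse
        ratio = cand_mse / best_mse if best_mse > 0 else 0.0
        best_x, best_mse = cand, cand_mse
        if best_mse == 0.0 or improvement <= cfg.mse_change_tol:
            break
        if ratio > 0.5:
            break  # diminishing returns: under one halving per outer round
        scale = max(scale * 0.1, 1e-9)

    return RegistrationResult(
        params=AffineParams.from_vector(best_x),
        mse=float(best_mse),
        refined=True,
    )
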