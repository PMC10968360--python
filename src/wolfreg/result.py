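"""Result containers for optimizer runs and registrations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .geometry import AffineParams, compose_matrix, invert_matrix

__all__ = ["OptimizeResult", "RegistrationResult"]


@dataclass
class OptimizeResult:
    """Raw outcome of one optimizer run on a 15-dimensional objective."""

    x: np.ndarray
    fun: float
    trace: np.ndarray
    branch_counts: dict
    population: np.ndarray
    population_fitness: np.ndarray
    config: Any
    history_fitness: Optional[np.ndarray] = None
    history_positions: Optional[np.ndarray] = None

    @property
    def params(self) -> AffineParams:
        return AffineParams.from_vector(self.x)


@dataclass
class RegistrationResult:
    """A registration solution: parameters, matrix, fitness and provenance.

    ``mse`` is the registration MSE (squared length units) of ``params``
    on the source/target pair the run was made on; ``trace`` the
    per-iteration global best fitness of the coarse optimizer; ``refined``
    is True when ICP polishing produced these parameters.
    """

    params: AffineParams
    mse: float
    trace: Optional[np.ndarray] = None
    refined: bool = False
    coarse_mse: Optional[float] = None
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    branch_counts: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return compose_matrix(self.params)

    @property
    def matrix_inverse(self) -> np.ndarray:
        return invert_matrix(self.matrix)

    def to_dict(self, objective=None, schema: str = "1") -> dict:
        """JSON-serializable report.

        When ``objective`` (a RegistrationObjective) is given, the stored
        MSE is recomputed and must agree to 1e-12 relative.
        """
        if objective is not None:
            recomputed = objective(self.params)
            denom = max(abs(self.mse), abs(recomputed), 1e-300)
            if abs(recomputed - self.mse) > 1e-12 * denom and abs(recomputed - self.mse) > 1e-300:
                raise ValueError(
                    f"stored MSE {self.mse!r} does not match recomputed "
                    f"MSE {recomputed!r}"
                )
        out = {
            "schema": schema,
            "params": {k: float(v) for k, v in zip(
                ("tx", "ty", "tz", "phi_x", "phi_y", "phi_z",
                 "sx", "sy", "sz", "sh1", "sh2", "sh3", "sh4", "sh5", "sh6"),
                self.params.to_vector())},
            "matrix": [[float(v) for v in row] for row in self.matrix],
            "matrix_inverse": [[float(v) for v in row] for row in self.matrix_inverse],
            "mse": float(self.mse),
            "refined": bool(self.refined),
            "seed": self.seed,
            "config": self.config,
        }
        if self.coarse_mse is not None:
            out["coarse_mse"] = float(self.coarse_mse)
        if self.trace is not None:
            out["trace_final"] = float(self.trace[-1])
        if self.branch_counts:
            out["branch_counts"] = {k: int(v) for k, v in self.branch_counts.items()}
        return out
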