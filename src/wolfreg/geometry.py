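"""Fifteen-parameter 3D affine transforms.

A registration candidate is parameterized by translation (tx, ty, tz, in
the cloud's length unit), rotation angles about the x/y/z axes (degrees),
anisotropic scale factors (sx, sy, sz), and six shear coefficients
(sh1..sh6).  The homogeneous 4x4 matrix is composed as

    H = T @ S @ R @ SH

where T is the translation matrix, S the diagonal scale matrix, R the
combined rotation matrix and SH the shear matrix.  Points are row vectors;
a cloud Q (N x 3) transforms as ``Q_h @ H.T`` with a homogeneous 1 appended
to every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "AffineParams",
    "SearchBounds",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
    "compose_matrix",
    "compose_matrix_batch",
    "invert_matrix",
    "apply_transform",
    "params_from_vector",
    "as_cloud",
    "DegenerateTransformError",
]

PARAM_NAMES = (
    "tx", "ty", "tz",
    "phi_x", "phi_y", "phi_z",
    "sx", "sy", "sz",
    "sh1", "sh2", "sh3", "sh4", "sh5", "sh6",
)


class DegenerateTransformError(ValueError):
    """Raised when a transform matrix cannot be inverted."""


@dataclass(frozen=True)
class AffineParams:
    """The 15-dimensional affine search vector.

    Angles are stored in degrees and converted to radians only inside the
    trigonometric evaluation.  Scale and shear coefficients are
    dimensionless; translations carry the cloud's length unit.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    phi_x: float = 0.0
    phi_y: float = 0.0
    phi_z: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    sz: float = 1.0
    sh1: float = 0.0
    sh2: float = 0.0
    sh3: float = 0.0
    sh4: float = 0.0
    sh5: float = 0.0
    sh6: float = 0.0

    def __post_init__(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("affine parameters must all be finite")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "AffineParams":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.shape != (15,):
            raise ValueError(f"expected a 15-vector, got shape {vec.shape}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))


def params_from_vector(vec: np.ndarray) -> AffineParams:
    """Convenience alias for :meth:`AffineParams.from_vector`."""
    return AffineParams.from_vector(vec)


@dataclass(frozen=True)
class SearchBounds:
    """Per-dimension box bounds of a search space.

    Registration uses the 15-parameter box (:data:`DEFAULT_BOUNDS`), but the
    container works for any dimensionality — the optimizer itself is generic.
    """

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float).ravel()
        ub = np.asarray(self.ub, dtype=float).ravel()
        if lb.shape != ub.shape or lb.size < 1:
            raise ValueError("lower and upper bounds must be equal-length vectors")
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite")
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def widths(self) -> np.ndarray:
        """Interval widths L_j = ub_j - lb_j."""
        return self.ub - self.lb

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lb - atol) and np.all(x <= self.ub + atol))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.lb, self.ub, size=(n, self.lb.size))


# Translations +-1.5, angles +-45 deg, scales in [0.8, 1.2] (20% down/up),
# shears +-0.5.  Shear coefficients are dimensionless multipliers even
# though they act alongside translations of unit length.
DEFAULT_BOUNDS = SearchBounds(
    lb=np.array([-1.5, -1.5, -1.5, -45.0, -45.0, -45.0, 0.8, 0.8, 0.8,
                 -0.5, -0.5, -0.5, -0.5, -0.5, -0.5]),
    ub=np.array([1.5, 1.5, 1.5, 45.0, 45.0, 45.0, 1.2, 1.2, 1.2,
                 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]),
)


def as_cloud(points: np.ndarray) -> np.ndarray:
    """Validate and return an (N, 3) float point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"a point cloud must have shape (N, 3), got {pts.shape}")
    if pts.shape[0] < 1:
        raise ValueError("a point cloud must contain at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


def compose_matrix(params: AffineParams | np.ndarray) -> np.ndarray:
    """Compose the homogeneous 4x4 matrix H = T @ S @ R @ SH.

    Implemented through the closed-form entries of the product: the linear
    block is the shear matrix left-multiplied by the row-scaled rotation,
    and the translation occupies the last column.
    """
    if not isinstance(params, AffineParams):
        params = AffineParams.from_vector(params)
    H = compose_matrix_batch(params.to_vector()[None, :])[0]
    return H


def compose_matrix_batch(param_matrix: np.ndarray) -> np.ndarray:
    """Vectorized composition: (K, 15) parameter rows -> (K, 4, 4) matrices."""
    P = np.asarray(param_matrix, dtype=float)
    if P.ndim != 2 or P.shape[1] != 15:
        raise ValueError(f"expected (K, 15) parameters, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("affine parameters must all be finite")
    K = P.shape[0]
    t = P[:, 0:3]
    ang = np.deg2rad(P[:, 3:6])
    cox, coy, coz = np.cos(ang).T
    six, siy, siz = np.sin(ang).T
    s = P[:, 6:9]
    sh1, sh2, sh3, sh4, sh5, sh6 = P[:, 9:15].T

    # Combined rotation block (single printed matrix form).
    R = np.empty((K, 3, 3))
    R[:, 0, 0] = coy * coz
    R[:, 0, 1] = -coy * siz
    R[:, 0, 2] = siy
    R[:, 1, 0] = six * siy * coz + cox * siz
    R[:, 1, 1] = -six * siy * siz + cox * coz
    R[:, 1, 2] = -six * coy
    R[:, 2, 0] = -cox * siy * coz + six * siz
    R[:, 2, 1] = cox * siy * siz + six * coz
    R[:, 2, 2] = cox * coy

    SR = s[:, :, None] * R  # scale acts on rows

    SH = np.empty((K, 3, 3))
    SH[:, 0, 0] = 1.0
    SH[:, 0, 1] = sh1
    SH[:, 0, 2] = sh2
    SH[:, 1, 0] = sh3
    SH[:, 1, 1] = 1.0
    SH[:, 1, 2] = sh4
    SH[:, 2, 0] = sh5
    SH[:, 2, 1] = sh6
    SH[:, 2, 2] = 1.0

    H = np.zeros((K, 4, 4))
    H[:, :3, :3] = SR @ SH
    H[:, :3, 3] = t
    H[:, 3, 3] = 1.0
    return H


def invert_matrix(H: np.ndarray) -> np.ndarray:
    """Invert a homogeneous affine matrix via a dense solve.

    Raises :class:`DegenerateTransformError` when the linear block is
    singular (e.g. zero scale).  The bottom row of the result is exactly
    (0, 0, 0, 1).
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {H.shape}")
    A = H[:3, :3]
    t = H[:3, 3]
    try:
        Ainv = np.linalg.solve(A, np.eye(3))
    except np.linalg.LinAlgError as exc:
        raise DegenerateTransformError("transform matrix is singular") from exc
    if not np.all(np.isfinite(Ainv)):
        raise DegenerateTransformError("transform matrix is numerically singular")
    out = np.zeros((4, 4))
    out[:3, :3] = Ainv
    out[:3, 3] = -Ainv @ t
    out[3, 3] = 1.0
    return out


def apply_transform(cloud: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Apply a homogeneous transform to a cloud of row-vector points.

    Each point q maps to the first three components of ``[q, 1] @ H.T``.
    """
    pts = as_cloud(cloud)
    H = np.asarray(H, dtype=float)
    if H.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {H.shape}")
    return pts @ H[:3, :3].T + H[:3, 3]
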