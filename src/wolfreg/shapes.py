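"""Synthetic benchmark fixtures: cylinder and pyramid surface clouds.

The benchmark pair construction keeps the target cloud as the original
shape and produces the source by pushing every point through a fixed
ground-truth affine matrix (an in-bounds mix of translation, rotation,
scaling and shear, printed to six decimals).  Because source and target
share point identities, an exact alignment with MSE 0 exists and the
recoverable transform is the matrix inverse of the generator.
"""

from __future__ import annotations

import numpy as np

from .geometry import apply_transform, as_cloud, invert_matrix

__all__ = [
    "GROUND_TRUTH_FORWARD",
    "GROUND_TRUTH_INVERSE",
    "make_cylinder",
    "make_pyramid",
    "make_pair",
    "make_slab_views",
]

# Forward generator (target -> source), printed to 6 decimals.
GROUND_TRUTH_FORWARD = np.array(
    [
        [0.882050, -0.285362, -0.555884, -0.061153],
        [0.225174, 1.041540, 0.181496, 0.063487],
        [0.249299, -0.413927, 0.966936, -0.163016],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

# Its inverse (the transform a registration must recover), printed to the
# same precision; invert_matrix(GROUND_TRUTH_FORWARD) agrees to ~1e-6.
GROUND_TRUTH_INVERSE = np.array(
    [
        [0.901895, 0.421703, 0.439339, 0.1],
        [-0.143742, 0.826257, -0.237726, -0.1],
        [-0.294063, 0.244980, 0.819157, 0.1],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def make_cylinder(
    n_points: int = 500, radius: float = 1.0, height: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Uniform sample of the closed cylindrical surface, centred at origin.

    Points fall on the lateral wall and the two caps with probability
    proportional to area; lateral points satisfy x^2 + y^2 = radius^2 and
    z spans [-height/2, +height/2].
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    rng = np.random.default_rng(seed)
    lateral_area = 2.0 * np.pi * radius * height
    cap_area = np.pi * radius**2
    total = lateral_area + 2.0 * cap_area
    u = rng.random(n_points)
    pts = np.empty((n_points, 3))
    theta = rng.random(n_points) * 2.0 * np.pi
    on_lateral = u < lateral_area / total
    on_top = (~on_lateral) & (u < (lateral_area + cap_area) / total)
    # lateral wall
    z = (rng.random(n_points) - 0.5) * height
    pts[:, 0] = radius * np.cos(theta)
    pts[:, 1] = radius * np.sin(theta)
    pts[:, 2] = z
    # caps: radius sampled as sqrt for uniform area density
    r_cap = radius * np.sqrt(rng.random(n_points))
    caps = ~on_lateral
    pts[caps, 0] = r_cap[caps] * np.cos(theta[caps])
    pts[caps, 1] = r_cap[caps] * np.sin(theta[caps])
    pts[on_top, 2] = height / 2.0
    pts[caps & ~on_top, 2] = -height / 2.0
    return pts


def make_pyramid(
    n_points: int = 500, base: float = 2.0, height: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Uniform sample of a square-based pyramid's five faces.

    The base square (side ``base``) lies in the plane z = -height/2 and
    the apex sits at (0, 0, +height/2); the shape is centred at the
    origin in z.
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    rng = np.random.default_rng(seed)
    half = base / 2.0
    z0 = -height / 2.0
    apex = np.array([0.0, 0.0, height / 2.0])
    # face corner triples: base (two triangles) + 4 lateral triangles
    c = [
        np.array([-half, -half, z0]),
        np.array([half, -half, z0]),
        np.array([half, half, z0]),
        np.array([-half, half, z0]),
    ]
    tris = [
        (c[0], c[1], c[2]),
        (c[0], c[2], c[3]),
        (c[0], c[1], apex),
        (c[1], c[2], apex),
        (c[2], c[3], apex),
        (c[3], c[0], apex),
    ]
    areas = np.array(
        [0.5 * np.linalg.norm(np.cross(b - a, d - a)) for a, b, d in tris]
    )
    probs = areas / areas.sum()
    which = rng.choice(len(tris), size=n_points, p=probs)
    u = rng.random(n_points)
    v = rng.random(n_points)
    flip = u + v > 1.0
    u[flip] = 1.0 - u[flip]
    v[flip] = 1.0 - v[flip]
    pts = np.empty((n_points, 3))
    for k, (a, b, d) in enumerate(tris):
        m = which == k
        pts[m] = a + np.outer(u[m], b - a) + np.outer(v[m], d - a)
    return pts


def make_pair(shape: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a (source, target, truth) benchmark triple from a shape cloud.

    target = shape; source = shape pushed through the forward ground-truth
    matrix; truth = the inverse matrix a registration must recover (equal
    to the printed inverse to six decimals).
    """
    target = as_cloud(shape)
    source = apply_transform(target, GROUND_TRUTH_FORWARD)
    truth = invert_matrix(GROUND_TRUTH_FORWARD)
    return source, target, truth


def make_slab_views(
    shape: np.ndarray,
    n_views: int = 6,
    overlap: float = 0.35,
    max_translation: float = 0.05,
    max_rotation_deg: float = 2.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cut a cloud into overlapping z-slabs, each perturbed by a small affine.

    Emulates consecutive partial scans of one object: view k covers a z
    window overlapping its neighbours by ``overlap`` of the slab height,
    then receives its own small random rigid-ish perturbation (translation
    up to ``max_translation``, rotations up to ``max_rotation_deg``).

    Returns (views, truths): the perturbed view clouds and the 4x4
    matrices that map each view back into the common frame (the inverses
    of the applied perturbations).
    """
    pts = as_cloud(shape)
    rng = np.random.default_rng(seed)
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    span = zmax - zmin
    slab = span / (n_views - (n_views - 1) * overlap)
    stride = slab * (1.0 - overlap)
    views: list[np.ndarray] = []
    truths: list[np.ndarray] = []
    from .geometry import compose_matrix, AffineParams

    for k in range(n_views):
        lo = zmin + k * stride
        hi = lo + slab
        m = (pts[:, 2] >= lo - 1e-12) & (pts[:, 2] <= hi + 1e-12)
        cloud = pts[m]
        if cloud.shape[0] < 10:
            raise ValueError(f"view {k} has too few points ({cloud.shape[0]})")
        t = rng.uniform(-max_translation, max_translation, 3)
        ang = rng.uniform(-max_rotation_deg, max_rotation_deg, 3)
        H = compose_matrix(AffineParams(
            tx=t[0], ty=t[1], tz=t[2],
            phi_x=ang[0], phi_y=ang[1], phi_z=ang[2],
        ))
        views.append(apply_transform(cloud, H))
        truths.append(invert_matrix(H))
    return views, truths
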