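"""Rigid-body and internal-rotation geometry used by the pose sampler.

Rotations are represented as 3x3 orthogonal matrices. Uniform random
rotations come from the quaternion method (a unit quaternion drawn uniformly
from S^3 maps to a rotation uniform over SO(3)). Torsion changes are proper
internal rotations: they move one side of the split bond graph about the
central bond axis, leaving all bond lengths and bond angles untouched.
"""

from __future__ import annotations

import numpy as np

from .core import LigandTopology

__all__ = [
    "quaternion_to_matrix",
    "random_rotation_matrix",
    "random_point_in_ball",
    "rotation_about_axis",
    "dihedral_angle",
    "set_torsion_angles",
    "rotation_angle_deg",
]


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float) / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Rotation uniform over SO(3) via a Gaussian-normalized quaternion."""
    q = rng.normal(size=4)
    return quaternion_to_matrix(q)


def random_point_in_ball(rng: np.random.Generator, center: np.ndarray, radius: float) -> np.ndarray:
    """Point uniform over the solid ball of given center and radius.

    Uses the exact direction x r^(1/3) construction, so the radial density
    is proportional to r^2 as required for a uniform ball.
    """
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return np.asarray(center, dtype=float) + r * direction


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def rotation_angle_deg(rot: np.ndarray) -> float:
    """Rotation angle of a rotation matrix, degrees in [0, 180]."""
    c = (np.trace(rot) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3, degrees in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)


def set_torsion_angles(
    ligand: LigandTopology, coords: np.ndarray, angles_deg: np.ndarray
) -> np.ndarray:
    """Return coordinates with each rotatable torsion set to the given angle.

    Angles are absolute target dihedrals in degrees, one per ligand torsion,
    applied in torsion-list order. Only the smaller side of each split bond
    graph moves (deterministic tie-break by lower minimum atom index), so
    bond lengths and angles are exactly preserved.
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles_deg.shape[0] != ligand.n_torsions:
        raise ValueError(
            f"expected {ligand.n_torsions} torsion angles, got {angles_deg.shape[0]}"
        )
    out = np.array(coords, dtype=float)
    for torsion, target in zip(ligand.torsions, angles_deg):
        a, b, c, d = torsion
        current = dihedral_angle(out[a], out[b], out[c], out[d])
        moving, anchor, pivot = ligand.torsion_moving_side(torsion)
        delta = np.radians(target - current)
        # Sign convention: rotating the d-side by +delta about the b->c axis
        # DEcreases the dihedral a-b-c-d; rotating the a-side increases it.
        if pivot == c:
            rot = rotation_about_axis(out[c] - out[b], -delta)
            origin = out[c]
        else:
            rot = rotation_about_axis(out[c] - out[b], delta)
            origin = out[b]
        idx = list(moving)
        out[idx] = (out[idx] - origin) @ rot.T + origin
    return out
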