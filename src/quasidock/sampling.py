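"""Random start-pose generation inside the binding-site sphere.

The multi-start search throws the flexible ligand into the active site at
random: each start applies random continuous torsion changes (uniform on
[0, 360) per rotatable bond), then a random rigid-body placement — a
rotation uniform over SO(3) and a translation putting the ligand's
geometric center at a point uniform over the site ball. Starts whose atoms
clash with the receptor or with each other are rejected and redrawn. The
clash criterion is geometric: two atoms clash when their distance falls
below ``clash_scale`` times the sum of their Bondi van der Waals radii
(1-2 and 1-3 bonded ligand pairs are exempt, since bonded geometry is
legitimately short).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import LigandTopology, Pose, RigidReceptor, vdw_radius
from .geometry import random_point_in_ball, random_rotation_matrix, set_torsion_angles

__all__ = [
    "SamplerConfig",
    "SamplingExhaustedError",
    "random_rigid_transform",
    "random_torsion_set",
    "has_clash",
    "generate_start_pose",
]


class SamplingExhaustedError(RuntimeError):
    """All attempts at a clash-free start pose failed — the site is overfilled
    or the clash criterion too strict."""


@dataclass(frozen=True)
class SamplerConfig:
    """Start-pose generator settings.

    ``clash_scale`` is the dimensionless fraction of the summed van der
    Waals radii below which a pair counts as clashing; 0.5 is permissive
    enough that soft overlaps are left for the local optimizer to resolve.
    """

    site_radius: float = 8.0
    clash_scale: float = 0.5
    max_attempts_per_start: int = 200

    def __post_init__(self):
        if not self.site_radius > 0:
            raise ValueError("site_radius must be positive")
        if not 0 < self.clash_scale < 1:
            raise ValueError("clash_scale must be in (0, 1)")
        if self.max_attempts_per_start < 1:
            raise ValueError("max_attempts_per_start must be >= 1")


def random_rigid_transform(
    rng: np.random.Generator,
    site_center,
    site_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a random rigid placement ``(rotation, target_center)``.

    The rotation is uniform over SO(3) (quaternion method); the target
    center is uniform over the ball of ``site_radius`` about
    ``site_center``. Applying the transform rotates the ligand about its
    geometric center and moves that center to ``target_center``.
    """
    rot = random_rotation_matrix(rng)
    target = random_point_in_ball(rng, np.asarray(site_center, dtype=float), site_radius)
    return rot, target


def apply_rigid_transform(coords: np.ndarray, rotation: np.ndarray, target_center) -> np.ndarray:
    center = coords.mean(axis=0)
    return (coords - center) @ rotation.T + np.asarray(target_center, dtype=float)


def random_torsion_set(ligand: LigandTopology, rng: np.random.Generator) -> np.ndarray:
    """One uniform angle on [0, 360) degrees per rotatable bond."""
    return rng.uniform(0.0, 360.0, size=ligand.n_torsions)


def _pair_clash_thresholds(elements_a, elements_b, clash_scale: float) -> np.ndarray:
    ra = np.array([vdw_radius(e) for e in elements_a])
    rb = np.array([vdw_radius(e) for e in elements_b])
    return clash_scale * (ra[:, None] + rb[None, :])


def has_clash(
    receptor: RigidReceptor,
    ligand: LigandTopology,
    pose: Pose,
    config: SamplerConfig,
) -> bool:
    """True iff any ligand-receptor pair, or any non-bonded (>= 1-4)
    ligand-ligand pair, sits closer than ``clash_scale x (r_vdw_i + r_vdw_j)``.

    Receptor-ligand screening goes through a k-d tree; ligand self-pairs are
    checked directly (ligands are small).
    """
    lig = pose.coords
    lig_radii = np.array([vdw_radius(e) for e in ligand.elements])
    if receptor.n_atoms:
        rec = receptor.coords()
        rec_radii = np.array([vdw_radius(e) for e in receptor.elements])
        cutoff = config.clash_scale * (lig_radii.max() + rec_radii.max())
        tree = cKDTree(rec)
        for i, neighbors in enumerate(tree.query_ball_point(lig, cutoff)):
            if not neighbors:
                continue
            d = np.linalg.norm(rec[neighbors] - lig[i], axis=1)
            thresh = config.clash_scale * (lig_radii[i] + rec_radii[neighbors])
            if np.any(d < thresh):
                return True
    excluded = ligand.excluded_self_pairs()
    n = ligand.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in excluded:
                continue
            if np.linalg.norm(lig[i] - lig[j]) < config.clash_scale * (
                lig_radii[i] + lig_radii[j]
            ):
                return True
    return False


def generate_start_pose(
    receptor: RigidReceptor,
    ligand: LigandTopology,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Pose:
    """Draw clash-free start poses until one is accepted.

    Torsions are randomized first, then the rigid placement; the pose is
    accepted when :func:`has_clash` is false. Raises
    :class:`SamplingExhaustedError` after ``max_attempts_per_start``
    rejections.
    """
    template = ligand.coords()
    for _ in range(config.max_attempts_per_start):
        conf = (
            set_torsion_angles(ligand, template, random_torsion_set(ligand, rng))
            if ligand.n_torsions
            else template
        )
        rot, target = random_rigid_transform(rng, receptor.site_center, config.site_radius)
        pose = Pose(apply_rigid_transform(conf, rot, target))
        if not has_clash(receptor, ligand, pose, config):
            return pose
    raise SamplingExhaustedError(
        f"no clash-free start pose in {config.max_attempts_per_start} attempts"
    )
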