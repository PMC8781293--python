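"""Desk-scale toy systems with known answers, plus packaged evaluation tables.

Real quasi-docking targets need thousands of CPU-hours of multi-start
search and an external quantum-chemistry program, so every pipeline stage
is exercised here on toy complexes whose stage-1 energy landscape can be
enumerated independently:

* The receptor is a set of pseudo-atom "anchors" arranged in K disjoint
  pockets around the binding site. Each pocket is a rigidly transformed
  copy of the ligand's equilibrium geometry; anchor ``i`` of a pocket
  attracts ligand atom ``i`` (and only it) through a smooth Lorentzian
  well. Pockets get strictly decreasing well depths, so the stage-1
  landscape has exactly K basins with known ordering, one per pocket, and
  the global minimum is pocket 0.
* Pocket anchors carry a different element per pocket. The surrogate
  stage-2 model scores contacts by element, so its pocket ordering differs
  from the stage-1 depth ordering — re-ranking genuinely permutes the pool,
  which is what the second docking stage is for.
* The ligand templates range from a rigid scalene triatomic (used for the
  K-pocket complexes) to torsional chains (double-well torsion landscape,
  enumerable by a 1D dihedral scan) and a symmetric six-ring (exercises the
  symmetry-corrected RMSD).

The minima oracle never uses the production search: candidates come from a
dense translation x orientation grid sweep, are refined by conjugate
gradients, and are deduplicated by RMSD. All potentials are smooth (no
cutoffs), so local refinement is well posed.

The module also packages the published evaluation tables (test-set
characteristics, per-complex positioning results, and measured vs
calculated binding enthalpies) as TSV data files with checksum
verification.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import AtomRecord, EnergyModel, LigandTopology, Pose, RigidReceptor
from .geometry import dihedral_angle, random_rotation_matrix, set_torsion_angles

__all__ = [
    "ToySpecError",
    "ToyComplexSpec",
    "ToyComplex",
    "standard_spec",
    "reranking_surrogate",
    "toy_model_from_files",
    "spec_to_yaml",
    "spec_from_yaml",
    "ToyFieldModel",
    "make_ligand",
    "build_toy_complex",
    "enumerate_toy_minima",
    "enumerate_torsion_minima",
    "ReferenceTables",
    "load_reference_tables",
]


class ToySpecError(ValueError):
    """The toy-complex specification cannot be realized as stated."""


# ---------------------------------------------------------------------------
# ligand templates
# ---------------------------------------------------------------------------

_LIGAND_TEMPLATES = {
    # rigid scalene triatomic: no torsions, no internal symmetry
    "rigid3": dict(
        elements=["C", "N", "O"],
        coords=[[0.0, 0.0, 0.0], [1.45, 0.0, 0.0], [0.62, 1.28, 0.35]],
        bonds=[(0, 1, 1), (1, 2, 1)],
        torsions=[],
    ),
    # butane-like chain, one rotatable torsion
    "chain4": dict(
        elements=["C", "C", "C", "C"],
        coords=[
            [0.0, 0.0, 0.0],
            [1.50, 0.0, 0.0],
            [2.22, 1.32, 0.0],
            [3.72, 1.32, 0.0],
        ],
        bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1)],
        torsions=[(0, 1, 2, 3)],
    ),
    # five-atom chain, two rotatable torsions
    "chain5": dict(
        elements=["C", "C", "C", "C", "N"],
        coords=[
            [0.0, 0.0, 0.0],
            [1.50, 0.0, 0.0],
            [2.22, 1.32, 0.0],
            [3.72, 1.32, 0.0],
            [4.44, 2.64, 0.0],
        ],
        bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1)],
        torsions=[(0, 1, 2, 3), (1, 2, 3, 4)],
    ),
    # planar symmetric six-ring (benzene-like heavy skeleton)
    "ring6": dict(
        elements=["C"] * 6,
        coords=[
            [1.40 * np.cos(k * np.pi / 3), 1.40 * np.sin(k * np.pi / 3), 0.0]
            for k in range(6)
        ],
        bonds=[(k, (k + 1) % 6, 1) for k in range(6)],
        torsions=[],
    ),
}


def make_ligand(template: str, formal_charge: int = 0) -> LigandTopology:
    """Instantiate one of the bundled toy ligand templates."""
    try:
        t = _LIGAND_TEMPLATES[template]
    except KeyError:
        raise ToySpecError(
            f"unknown ligand template {template!r}; options: {sorted(_LIGAND_TEMPLATES)}"
        ) from None
    atoms = tuple(
        AtomRecord(element=e, coords=tuple(c), name=f"{e}{i+1}")
        for i, (e, c) in enumerate(zip(t["elements"], t["coords"]))
    )
    return LigandTopology(
        atoms=atoms,
        bonds=tuple(t["bonds"]),
        torsions=tuple(t["torsions"]),
        formal_charge=formal_charge,
    )


# ---------------------------------------------------------------------------
# stage-1 toy field
# ---------------------------------------------------------------------------


class ToyFieldModel(EnergyModel):
    """Smooth stage-1 search field for toy complexes.

    Intramolecular part: harmonic bond terms, harmonic 1-3 (angle-proxy)
    terms, and a Fourier torsion potential
    ``V(phi) = c1 cos(phi) + c2 cos(2 phi) + c3 cos(3 phi)`` per rotatable
    bond. Intermolecular part: one Lorentzian well
    ``-depth / (1 + r^2 / sigma^2)`` per (anchor atom, ligand atom) pair —
    long-tailed, so every start inside the site sphere feels a pull.

    The anchor pairing is positional, not element-based: the model stores
    its anchor coordinates, so evaluating with an empty receptor (the
    unbound-ligand protocols) yields the intramolecular energy alone.
    The analytic gradient covers the torsion-free case; torsional ligands
    fall back to finite differences.
    """

    def __init__(
        self,
        ligand: LigandTopology,
        anchor_coords: Optional[np.ndarray] = None,
        anchor_lig_idx: Optional[np.ndarray] = None,
        anchor_depths: Optional[np.ndarray] = None,
        well_sigma: float = 1.2,
        bond_k: float = 300.0,
        angle_k: float = 150.0,
        torsion_coeffs: tuple[float, float, float] = (0.6, 0.0, 1.0),
    ):
        self.name = "toy-field"
        self.well_sigma = float(well_sigma)
        self.bond_k = float(bond_k)
        self.angle_k = float(angle_k)
        self.torsion_coeffs = tuple(float(c) for c in torsion_coeffs)
        if anchor_coords is None:
            self.anchor_coords = np.zeros((0, 3))
            self.anchor_lig_idx = np.zeros(0, dtype=int)
            self.anchor_depths = np.zeros(0)
        else:
            self.anchor_coords = np.asarray(anchor_coords, dtype=float)
            self.anchor_lig_idx = np.asarray(anchor_lig_idx, dtype=int)
            self.anchor_depths = np.asarray(anchor_depths, dtype=float)
        ref = ligand.coords()
        self._bonds = [(i, j, float(np.linalg.norm(ref[i] - ref[j]))) for i, j, _ in ligand.bonds]
        self._pairs13 = []
        g = ligand.bond_graph()
        for j in g.nodes:
            nbrs = sorted(g.neighbors(j))
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    i, k = nbrs[a], nbrs[b]
                    self._pairs13.append((i, k, float(np.linalg.norm(ref[i] - ref[k]))))
        self._torsions = tuple(ligand.torsions)

    # -- energy pieces ------------------------------------------------------

    def _intra(self, x: np.ndarray) -> float:
        e = 0.0
        for i, j, r0 in self._bonds:
            e += self.bond_k * (np.linalg.norm(x[i] - x[j]) - r0) ** 2
        for i, k, r0 in self._pairs13:
            e += self.angle_k * (np.linalg.norm(x[i] - x[k]) - r0) ** 2
        c1, c2, c3 = self.torsion_coeffs
        for a, b, c, d in self._torsions:
            phi = np.radians(dihedral_angle(x[a], x[b], x[c], x[d]))
            e += c1 * np.cos(phi) + c2 * np.cos(2 * phi) + c3 * np.cos(3 * phi)
        return e

    def _wells(self, x: np.ndarray) -> float:
        if self.anchor_coords.shape[0] == 0:
            return 0.0
        d = x[self.anchor_lig_idx] - self.anchor_coords
        r2 = np.sum(d * d, axis=1)
        return float(np.sum(-self.anchor_depths / (1.0 + r2 / self.well_sigma**2)))

    def evaluate(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose) -> float:
        x = pose.coords
        e = self._intra(x)
        if receptor.n_atoms > 0:
            e += self._wells(x)
        return float(e)

    def gradient(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose):
        if self._torsions:
            return None  # torsional templates use the finite-difference path
        x = pose.coords
        g = np.zeros_like(x)
        for i, j, r0 in self._bonds:
            dv = x[i] - x[j]
            r = np.linalg.norm(dv)
            f = 2.0 * self.bond_k * (r - r0) / r * dv
            g[i] += f
            g[j] -= f
        for i, k, r0 in self._pairs13:
            dv = x[i] - x[k]
            r = np.linalg.norm(dv)
            f = 2.0 * self.angle_k * (r - r0) / r * dv
            g[i] += f
            g[k] -= f
        if receptor.n_atoms > 0 and self.anchor_coords.shape[0] > 0:
            d = x[self.anchor_lig_idx] - self.anchor_coords
            r2 = np.sum(d * d, axis=1)
            s2 = self.well_sigma**2
            coef = 2.0 * self.anchor_depths / (s2 * (1.0 + r2 / s2) ** 2)
            np.add.at(g, self.anchor_lig_idx, coef[:, None] * d)
        return g


# ---------------------------------------------------------------------------
# toy complex construction
# ---------------------------------------------------------------------------

#: anchor element per pocket; chosen from the van der Waals table so clash
#: screening works, and distinct so the surrogate can tell pockets apart.
_ANCHOR_PALETTE = ("N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se", "C")


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a toy complex with an enumerable stage-1 landscape.

    ``n_pockets`` is K, the number of basins; pockets sit on a Fibonacci
    sphere of radius ``pocket_radius`` around the site center with well
    depths ``well_depth0 - k * well_depth_step`` (strictly decreasing, so
    basin energies are distinct and pocket 0 is the stage-1 global
    minimum).
    """

    ligand_template: str = "rigid3"
    n_pockets: int = 2
    pocket_radius: float = 5.0
    well_sigma: float = 1.2
    well_depth0: float = 6.0
    well_depth_step: float = 0.4
    site_radius: float = 6.0
    bond_k: float = 300.0
    angle_k: float = 150.0
    torsion_coeffs: tuple[float, float, float] = (0.6, 0.0, 1.0)
    rng_seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_pockets <= 20:
            raise ToySpecError("n_pockets must be in 1..20")
        if self.well_depth_step <= 0 or self.well_depth0 <= self.n_pockets * self.well_depth_step:
            raise ToySpecError("well depths must stay positive and strictly decreasing")


def standard_spec(n_pockets: int, rng_seed: int = 0) -> ToyComplexSpec:
    """Standard K-pocket spec: pocket separation grows with K so every
    pocket stays a distinct basin (verified by the enumeration oracle)."""
    radius = 5.0 if n_pockets <= 6 else 6.5
    return ToyComplexSpec(
        n_pockets=n_pockets,
        pocket_radius=radius,
        site_radius=radius + 1.0,
        rng_seed=rng_seed,
    )


@dataclass
class ToyComplex:
    """A built toy system: structures, native pose, stage-1 field and the
    independently enumerated minima (ascending energy)."""

    spec: ToyComplexSpec
    receptor: RigidReceptor
    ligand: LigandTopology
    native: Pose
    stage1_model: ToyFieldModel
    oracle_minima: list[tuple[float, Pose]] = field(default_factory=list)

    @property
    def oracle_energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.oracle_minima])


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    if n == 1:
        return np.array([[radius, 0.0, 0.0]])
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def build_toy_complex(spec: ToyComplexSpec, enumerate_oracle: bool = True) -> ToyComplex:
    """Construct receptor, ligand, stage-1 field and the minima oracle.

    Each pocket's anchors are the ligand equilibrium geometry under a
    seeded random rotation, centered on the pocket position, so the docked
    pose in each pocket is frustration-free (intra and inter terms are
    minimized simultaneously). The native pose is the oracle global
    minimum. Raises :class:`ToySpecError` if enumeration does not find
    exactly ``n_pockets`` basins.
    """
    ligand = make_ligand(spec.ligand_template)
    if ligand.n_torsions:
        raise ToySpecError("K-pocket complexes require a torsion-free ligand template")
    rng = np.random.default_rng(spec.rng_seed)
    template = ligand.coords()
    template = template - template.mean(axis=0)
    centers = _fibonacci_sphere(spec.n_pockets, spec.pocket_radius)

    anchor_atoms = []
    anchor_coords = []
    anchor_lig_idx = []
    anchor_depths = []
    for k in range(spec.n_pockets):
        rot = random_rotation_matrix(rng)
        pocket = template @ rot.T + centers[k]
        elem = _ANCHOR_PALETTE[k % len(_ANCHOR_PALETTE)]
        depth = spec.well_depth0 - k * spec.well_depth_step
        for i in range(ligand.n_atoms):
            anchor_atoms.append(
                AtomRecord(
                    element=elem,
                    coords=tuple(pocket[i]),
                    name=f"P{k}A{i}",
                    # 3-char residue tag so the pocket index survives PDB round trips
                    residue=f"P{chr(ord('A') + k)}",
                )
            )
            anchor_coords.append(pocket[i])
            anchor_lig_idx.append(i)
            anchor_depths.append(depth)

    receptor = RigidReceptor(
        atoms=tuple(anchor_atoms),
        site_center=(0.0, 0.0, 0.0),
        site_radius=spec.site_radius,
    )
    model = ToyFieldModel(
        ligand,
        anchor_coords=np.array(anchor_coords),
        anchor_lig_idx=np.array(anchor_lig_idx),
        anchor_depths=np.array(anchor_depths),
        well_sigma=spec.well_sigma,
        bond_k=spec.bond_k,
        angle_k=spec.angle_k,
        torsion_coeffs=spec.torsion_coeffs,
    )

    complex_ = ToyComplex(
        spec=spec,
        receptor=receptor,
        ligand=ligand,
        # pocket-0 anchor positions; replaced by the refined oracle GM below
        native=Pose(np.array(anchor_coords[: ligand.n_atoms])),
        stage1_model=model,
    )
    if enumerate_oracle:
        minima = enumerate_toy_minima(model, receptor, ligand, spec)
        if len(minima) != spec.n_pockets:
            raise ToySpecError(
                f"grid enumeration found {len(minima)} basins, expected {spec.n_pockets}"
            )
        complex_.oracle_minima = minima
        complex_.native = minima[0][1]
    return complex_


def toy_model_from_files(
    receptor: RigidReceptor, ligand: LigandTopology, spec: ToyComplexSpec
) -> ToyFieldModel:
    """Rebuild the stage-1 toy field from structures read back off disk.

    Anchor coordinates come from the receptor file (written pocket-major,
    atom-minor by :func:`build_toy_complex`); depths and widths come from
    the spec. This lets the command-line search run a toy complex through
    the production structure readers.
    """
    n = ligand.n_atoms
    if receptor.n_atoms != spec.n_pockets * n:
        raise ToySpecError(
            f"receptor has {receptor.n_atoms} atoms; spec expects {spec.n_pockets * n}"
        )
    depths = np.repeat(
        spec.well_depth0 - np.arange(spec.n_pockets) * spec.well_depth_step, n
    )
    return ToyFieldModel(
        ligand,
        anchor_coords=receptor.coords(),
        anchor_lig_idx=np.tile(np.arange(n), spec.n_pockets),
        anchor_depths=depths,
        well_sigma=spec.well_sigma,
        bond_k=spec.bond_k,
        angle_k=spec.angle_k,
        torsion_coeffs=spec.torsion_coeffs,
    )


def spec_to_yaml(spec: ToyComplexSpec, path):
    from dataclasses import asdict
    from pathlib import Path

    d = asdict(spec)
    d["torsion_coeffs"] = list(d["torsion_coeffs"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def spec_from_yaml(path) -> ToyComplexSpec:
    from pathlib import Path

    d = yaml.safe_load(Path(path).read_text())
    d["torsion_coeffs"] = tuple(d["torsion_coeffs"])
    return ToyComplexSpec(**d)


def reranking_surrogate():
    """A surrogate stage-2 model that inverts the stage-1 pocket ordering.

    Pocket 0 anchors are nitrogen and pocket 1 anchors oxygen; weighting
    oxygen contacts far above nitrogen makes the second-deepest stage-1
    basin the surrogate global minimum, so re-ranking genuinely changes
    the predicted binding mode on the standard two-pocket complex.
    """
    from .rescoring import SurrogateModel, SurrogateParams

    params = SurrogateParams(
        charges={},
        eps={"N": 0.5, "O": 4.0, "C": 1.0, "S": 1.0, "P": 1.0},
    )
    return SurrogateModel(params, name="surrogate-reranking")


# ---------------------------------------------------------------------------
# oracle enumeration
# ---------------------------------------------------------------------------


def _orientation_set() -> list[np.ndarray]:
    """24 rotations (the chiral octahedral group) for the grid sweep."""
    from scipy.spatial.transform import Rotation

    return list(Rotation.create_group("O").as_matrix())


def enumerate_toy_minima(
    model: ToyFieldModel,
    receptor: RigidReceptor,
    ligand: LigandTopology,
    spec: ToyComplexSpec,
    grid_step: float = 1.5,
    n_refine: int = 60,
    dedup_rmsd: float = 0.5,
) -> list[tuple[float, Pose]]:
    """Independent minima enumeration: grid sweep + conjugate-gradient refine.

    Rigid copies of the ligand template are scored on a dense translation x
    orientation grid inside the site ball; the best candidates (spatially
    thinned) are refined in full Cartesians with nonlinear conjugate
    gradients — deliberately not the production optimizer — and the refined
    points are deduplicated by heavy-atom RMSD. Returns ``(energy, pose)``
    pairs in ascending energy.
    """
    from scipy.optimize import minimize

    if ligand.n_torsions:
        raise ToySpecError("grid oracle supports torsion-free ligands only")
    template = ligand.coords()
    template = template - template.mean(axis=0)
    center = np.asarray(receptor.site_center)
    reach = spec.pocket_radius + 2.0 * grid_step
    axis = np.arange(-reach, reach + 1e-9, grid_step)
    pts = np.array([[x, y, z] for x in axis for y in axis for z in axis])
    pts = pts[np.linalg.norm(pts, axis=1) <= reach] + center

    orientations = _orientation_set()
    # The template is rigid during the sweep, so its intra energy is one
    # constant; only the well sum varies and vectorizes over translations.
    intra_const = model.evaluate(
        RigidReceptor(atoms=(), site_center=(0.0, 0.0, 0.0), site_radius=1.0),
        ligand,
        Pose(template),
    )
    s2 = model.well_sigma**2
    candidates = []
    for rot in orientations:
        conf = template @ rot.T
        # (n_pts, n_anchors, 3): anchored-atom positions minus anchor coords
        diff = (
            conf[model.anchor_lig_idx][None, :, :]
            + pts[:, None, :]
            - model.anchor_coords[None, :, :]
        )
        r2 = np.sum(diff * diff, axis=2)
        wells = np.sum(-model.anchor_depths[None, :] / (1.0 + r2 / s2), axis=1)
        for p, w in zip(pts, wells):
            candidates.append((intra_const + w, conf + p))
    candidates.sort(key=lambda t: t[0])

    # spatial thinning: keep the best candidate per neighborhood
    kept: list[tuple[tuple[float, np.ndarray], np.ndarray]] = []
    for e, x in candidates:
        c = x.mean(axis=0)
        if all(np.linalg.norm(c - kc) > 1.5 * grid_step for _, kc in kept):
            kept.append(((e, x), c))
        if len(kept) >= n_refine:
            break
    seeds = [t for t, _ in kept]

    def fun(v):
        pose = Pose(v.reshape(-1, 3))
        g = model.gradient(receptor, ligand, pose)
        return model.evaluate(receptor, ligand, pose), g.ravel()

    heavy = ligand.heavy_indices
    minima: list[tuple[float, np.ndarray]] = []
    for e0, x0 in seeds:
        res = minimize(fun, x0.ravel(), jac=True, method="CG", options={"maxiter": 2000})
        x = res.x.reshape(-1, 3)
        e = float(res.fun)
        gmax = float(np.max(np.abs(res.jac)))
        if gmax > 1e-2:  # CG stalled on a plateau; not a genuine minimum
            continue
        dup = False
        for idx, (em, xm) in enumerate(minima):
            d = x[heavy] - xm[heavy]
            if np.sqrt(np.mean(np.sum(d * d, axis=1))) < dedup_rmsd:
                if e < em:
                    minima[idx] = (e, x)
                dup = True
                break
        if not dup:
            minima.append((e, x))
    minima.sort(key=lambda t: t[0])
    return [(e, Pose(x)) for e, x in minima]


def enumerate_torsion_minima(
    model: ToyFieldModel,
    ligand: LigandTopology,
    grid_deg: float = 1.0,
) -> list[tuple[float, float]]:
    """1D dihedral-scan oracle for a single-torsion ligand (no receptor).

    Scans the torsion on a periodic grid, locates grid-local minima and
    polishes each with a bounded scalar minimization. Returns
    ``(angle_deg, energy)`` pairs in ascending energy.
    """
    from scipy.optimize import minimize_scalar

    if ligand.n_torsions != 1:
        raise ToySpecError("torsion-scan oracle requires exactly one torsion")
    empty = RigidReceptor(atoms=(), site_center=(0.0, 0.0, 0.0), site_radius=1.0)
    template = ligand.coords()

    def energy_at(angle):
        x = set_torsion_angles(ligand, template, np.array([angle]))
        return model.evaluate(empty, ligand, Pose(x))

    angles = np.arange(0.0, 360.0, grid_deg)
    energies = np.array([energy_at(a) for a in angles])
    n = len(angles)
    minima = []
    for i in range(n):
        if energies[i] <= energies[(i - 1) % n] and energies[i] <= energies[(i + 1) % n]:
            lo, hi = angles[i] - grid_deg, angles[i] + grid_deg
            res = minimize_scalar(energy_at, bounds=(lo, hi), method="bounded")
            minima.append((float(res.x) % 360.0, float(res.fun)))
    # merge duplicates from flat grid neighbors
    merged: list[tuple[float, float]] = []
    for a, e in sorted(minima, key=lambda t: t[0]):
        if merged and min(abs(a - merged[-1][0]), 360 - abs(a - merged[-1][0])) < 2 * grid_deg:
            if e < merged[-1][1]:
                merged[-1] = (a, e)
        else:
            merged.append((a, e))
    if (
        len(merged) > 1
        and min(abs(merged[0][0] - merged[-1][0]), 360 - abs(merged[0][0] - merged[-1][0]))
        < 2 * grid_deg
    ):
        if merged[-1][1] < merged[0][1]:
            merged[0] = merged[-1]
        merged.pop()
    return sorted(merged, key=lambda t: t[1])


def search_recovers_oracle(
    tc: ToyComplex,
    seed: int,
    n_starts: Optional[int] = None,
    energy_tol: float = 1e-4,
    rmsd_tol: float = 0.5,
) -> bool:
    """Run the production multi-start search and compare with the oracle.

    True iff the pool holds exactly the enumerated basins: same count, each
    energy within ``energy_tol`` kcal/mol of its oracle counterpart and each
    pose within ``rmsd_tol`` (heavy-atom RMSD) of the oracle pose — no basin
    missed, none spurious. ``n_starts`` defaults to 50 starts per basin.
    """
    from .pool import PoolConfig as _PoolConfig
    from .runtime import RunConfig, run_search
    from .sampling import SamplerConfig

    if not tc.oracle_minima:
        raise ToySpecError("toy complex has no enumerated oracle minima")
    k = len(tc.oracle_minima)
    config = RunConfig(
        n_starts=n_starts if n_starts is not None else 50 * k,
        seed=seed,
        sampler=SamplerConfig(site_radius=tc.spec.site_radius),
        pool=_PoolConfig(capacity=max(64, 4 * k)),
    )
    result = run_search(tc.stage1_model, tc.receptor, tc.ligand, config)
    if len(result.pool) != k:
        return False
    heavy = tc.ligand.heavy_indices
    for rec, (e_oracle, p_oracle) in zip(result.pool.records, tc.oracle_minima):
        if abs(rec.e_stage1 - e_oracle) > energy_tol:
            return False
        d = rec.pose.coords[heavy] - p_oracle.coords[heavy]
        if np.sqrt(np.mean(np.sum(d * d, axis=1))) > rmsd_tol:
            return False
    return True


# ---------------------------------------------------------------------------
# packaged evaluation tables
# ---------------------------------------------------------------------------

_DATA_PACKAGE = "quasidock.data"


@dataclass(frozen=True)
class ReferenceTables:
    """The packaged evaluation tables.

    ``test_set``: 25 complexes with protein/ligand sizes and torsion
    counts. ``positioning``: per-complex N_min, INN and GM RMSD for both
    stage-2 methods. ``enthalpy``: measured vs calculated binding
    enthalpies (missing calculated entries are NaN). ``metadata``: the
    exclusion lists and reported correlation coefficients.
    """

    test_set: pd.DataFrame
    positioning: pd.DataFrame
    enthalpy: pd.DataFrame
    metadata: dict


def _read_checksums() -> dict[str, str]:
    text = resources.files(_DATA_PACKAGE).joinpath("checksums.txt").read_text()
    out = {}
    for line in text.splitlines():
        if line.strip():
            digest, name = line.split()
            out[name] = digest
    return out


def _verified_bytes(name: str, checksums: dict[str, str]) -> bytes:
    raw = resources.files(_DATA_PACKAGE).joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if checksums.get(name) != digest:
        raise IOError(f"checksum mismatch for packaged table {name}")
    return raw


def load_reference_tables() -> ReferenceTables:
    """Load the packaged tables, verifying each file's SHA-256 checksum."""
    import io

    checksums = _read_checksums()
    t1 = pd.read_csv(io.BytesIO(_verified_bytes("table1_test_set.tsv", checksums)), sep="\t")
    t2 = pd.read_csv(io.BytesIO(_verified_bytes("table2_positioning.tsv", checksums)), sep="\t")
    t3 = pd.read_csv(io.BytesIO(_verified_bytes("table3_enthalpy.tsv", checksums)), sep="\t")
    meta = yaml.safe_load(_verified_bytes("evaluation_metadata.yaml", checksums))
    return ReferenceTables(test_set=t1, positioning=t2, enthalpy=t3, metadata=meta)
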