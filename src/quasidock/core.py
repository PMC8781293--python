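"""Core domain types shared by every stage of the quasi-docking pipeline.

A quasi-docking run manipulates four kinds of objects: a rigid receptor
(protein atoms that never move, plus a binding-site sphere), a flexible
ligand (atoms, bonds, rotatable torsions), poses (full Cartesian coordinate
sets of the ligand in the receptor frame, in Angstrom), and energy models.
Two energy models plug into one contract: the fast stage-1 search field used
during multi-start minimization, and the slow stage-2 model (an external
semiempirical QM program, or a surrogate potential) used for single-point
re-ranking of the collected minima.

All energies are kcal/mol; all coordinates are Cartesian Angstrom in the
receptor frame. No superposition is ever applied: poses of the same complex
live in one common frame, which is the docking RMSD convention.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AtomRecord",
    "LigandTopology",
    "RigidReceptor",
    "Pose",
    "EnergyModel",
    "MinimumRecord",
    "VDW_RADII",
    "vdw_radius",
    "finite_difference_gradient",
    "GradientEvaluationError",
    "TopologyError",
]

#: Bondi van der Waals radii, Angstrom. Used only for geometric clash
#: screening of start poses, never for energetics.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "B": 1.92,
    "Si": 2.10,
    "Se": 1.90,
}


class TopologyError(ValueError):
    """Raised when a ligand/receptor description violates its invariants."""


class GradientEvaluationError(RuntimeError):
    """Raised when an energy model returns a non-finite value during
    finite-difference gradient evaluation; carries the offending atom index."""

    def __init__(self, atom_index: int, message: str = ""):
        self.atom_index = atom_index
        super().__init__(
            message or f"non-finite energy while displacing atom {atom_index}"
        )


def _normalize_element(element: str) -> str:
    e = element.strip()
    if not e:
        raise TopologyError("empty element symbol")
    return e[0].upper() + e[1:].lower()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for an element symbol.

    Raises
    ------
    TopologyError
        If the element has no entry in the bundled radius table.
    """
    e = _normalize_element(element)
    try:
        return VDW_RADII[e]
    except KeyError:
        raise TopologyError(f"no van der Waals radius for element {e!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, Cartesian coordinates (A), opaque metadata.

    ``is_heavy`` is derived: every element except hydrogen counts as heavy,
    matching the convention that ligand positioning RMSD is computed over
    non-hydrogen atoms only.
    """

    element: str
    coords: tuple[float, float, float]
    name: str = ""
    residue: str = ""

    def __post_init__(self):
        object.__setattr__(self, "element", _normalize_element(self.element))
        c = tuple(float(x) for x in self.coords)
        if len(c) != 3 or not all(np.isfinite(c)):
            raise TopologyError(f"atom {self.name or self.element}: bad coords {self.coords}")
        object.__setattr__(self, "coords", c)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class LigandTopology:
    """Atoms, bonds, rotatable torsions and formal charge of the mobile molecule.

    Parameters
    ----------
    atoms:
        Ordered atom list; this order is fixed at load time and defines the
        identity atom mapping used by pose RMSD.
    bonds:
        ``(i, j, order)`` triples with 0-based atom indices; ``order`` is the
        integer bond order (1 single, 2 double, ...). The bond graph must be
        connected.
    torsions:
        Rotatable bonds as 4-atom index tuples ``(a, b, c, d)``; the central
        bond ``b-c`` must be a single bond outside any ring.
    formal_charge:
        Total formal charge, elementary units.
    """

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, int], ...]
    torsions: tuple[tuple[int, int, int, int], ...] = ()
    formal_charge: int = 0

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(
            self, "bonds", tuple((int(i), int(j), int(o)) for i, j, o in self.bonds)
        )
        object.__setattr__(
            self, "torsions", tuple(tuple(int(x) for x in t) for t in self.torsions)
        )
        n = len(self.atoms)
        if n == 0:
            raise TopologyError("ligand has no atoms")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i},{j}) out of range for {n} atoms")
        g = self.bond_graph()
        if n > 1 and not nx.is_connected(g):
            raise TopologyError("ligand bond graph is not connected")
        bond_orders = {frozenset((i, j)): o for i, j, o in self.bonds}
        ring_edges = {
            frozenset(e) for cycle in nx.cycle_basis(g) for e in zip(cycle, cycle[1:] + cycle[:1])
        }
        for t in self.torsions:
            if len(t) != 4 or len(set(t)) != 4:
                raise TopologyError(f"torsion {t} must name 4 distinct atoms")
            a, b, c, d = t
            key = frozenset((b, c))
            if key not in bond_orders:
                raise TopologyError(f"torsion {t}: {b}-{c} is not a bond")
            if bond_orders[key] != 1:
                raise TopologyError(f"torsion {t}: central bond {b}-{c} is not single")
            if key in ring_edges:
                raise TopologyError(f"torsion {t}: central bond {b}-{c} is in a ring")
            if key not in {frozenset((a, b)), frozenset((b, c))} and frozenset((a, b)) not in bond_orders:
                raise TopologyError(f"torsion {t}: {a}-{b} is not a bond")
            if frozenset((c, d)) not in bond_orders:
                raise TopologyError(f"torsion {t}: {c}-{d} is not a bond")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([k for k, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def coords(self) -> np.ndarray:
        """Template coordinates as an (N, 3) float array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        for k, a in enumerate(self.atoms):
            g.add_node(k, element=a.element)
        for i, j, o in self.bonds:
            g.add_edge(i, j, order=o)
        return g

    def heavy_graph(self) -> nx.Graph:
        """Bond graph restricted to heavy atoms (hydrogens stripped)."""
        g = self.bond_graph()
        g.remove_nodes_from([k for k, a in enumerate(self.atoms) if not a.is_heavy])
        return g

    def excluded_self_pairs(self) -> frozenset[frozenset[int]]:
        """1-2 and 1-3 bonded pairs, excluded from ligand self-clash checks."""
        g = self.bond_graph()
        pairs = {frozenset((i, j)) for i, j, _ in self.bonds}
        for j in g.nodes:
            nbrs = list(g.neighbors(j))
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    pairs.add(frozenset((nbrs[a], nbrs[b])))
        return frozenset(pairs)

    def torsion_moving_side(
        self, torsion: tuple[int, int, int, int]
    ) -> tuple[tuple[int, ...], int, int]:
        """Which atoms rotate when this torsion turns, and about which axis.

        Removing the central bond splits the molecule in two; the smaller
        side moves (tie broken toward the side containing the lower minimum
        atom index). Returns ``(moving_atoms, axis_anchor, axis_pivot)``:
        the moving atoms rotate about the axis from ``axis_anchor`` to
        ``axis_pivot`` (both central-bond atoms; the pivot sits on the
        moving side).
        """
        _, b, c, _ = torsion
        g = self.bond_graph()
        g.remove_edge(b, c)
        side_b = nx.node_connected_component(g, b) - {b}
        side_c = nx.node_connected_component(g, c) - {c}
        if len(side_c) < len(side_b):
            return tuple(sorted(side_c)), b, c
        if len(side_b) < len(side_c):
            return tuple(sorted(side_b)), c, b
        if min(side_b, default=b) < min(side_c, default=c):
            return tuple(sorted(side_b)), c, b
        return tuple(sorted(side_c)), b, c


@dataclass(frozen=True)
class RigidReceptor:
    """Receptor atoms (fixed for the whole run) plus the binding-site sphere.

    The site sphere is the only restriction on ligand placement: the
    geometric center of the ligand must stay inside it (default radius 8 A).
    """

    atoms: tuple[AtomRecord, ...]
    site_center: tuple[float, float, float]
    site_radius: float = 8.0

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        c = tuple(float(x) for x in self.site_center)
        if len(c) != 3 or not all(np.isfinite(c)):
            raise TopologyError(f"bad site center {self.site_center}")
        object.__setattr__(self, "site_center", c)
        if not self.site_radius > 0:
            raise TopologyError("site_radius must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)


class Pose:
    """A full per-atom Cartesian coordinate set of the ligand, Angstrom.

    Immutable wrapper over an ``(N, 3)`` float array in the receptor frame.
    """

    __slots__ = ("_coords",)

    def __init__(self, coords: np.ndarray | Sequence[Sequence[float]]):
        arr = np.asarray(coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"pose must be (N, 3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pose contains non-finite coordinates")
        arr = arr.copy()
        arr.setflags(write=False)
        self._coords = arr

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @property
    def n_atoms(self) -> int:
        return self._coords.shape[0]

    def center(self) -> np.ndarray:
        return self._coords.mean(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pose) and np.array_equal(self._coords, other._coords)

    def __hash__(self):
        return hash(self._coords.tobytes())

    def __repr__(self):
        return f"Pose(n_atoms={self.n_atoms})"


class EnergyModel(ABC):
    """Contract both docking stages plug into.

    ``evaluate`` must be deterministic: identical inputs give bit-identical
    energies. ``gradient`` is optional; models without an analytic gradient
    (external single-point QM backends) return ``None`` and callers fall back
    to :func:`finite_difference_gradient`.
    """

    name: str = "energy-model"

    @abstractmethod
    def evaluate(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose) -> float:
        """Total energy of the complex at this pose, kcal/mol."""

    def gradient(
        self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose
    ) -> Optional[np.ndarray]:
        """Per-atom energy gradient, kcal/mol/A, or None when not available."""
        return None

    def receptor_energy(self, receptor: RigidReceptor) -> float:
        """Energy of the unbound receptor in its fixed conformation, kcal/mol.

        The receptor is rigid, so this is an additive constant for any model;
        models that only score receptor-ligand interactions report 0. It
        enters the binding-enthalpy protocol as the unbound-protein term.
        """
        return 0.0


def finite_difference_gradient(
    model: EnergyModel,
    receptor: RigidReceptor,
    ligand: LigandTopology,
    pose: Pose,
    h: float = 1e-4,
) -> np.ndarray:
    """Central-difference gradient of ``model.evaluate`` w.r.t. pose coordinates.

    Used whenever a model supplies no analytic gradient. ``h`` is the
    displacement step in Angstrom.

    Raises
    ------
    GradientEvaluationError
        If the energy is non-finite at any displaced point; the error names
        the atom being displaced.
    """
    if not h > 0:
        raise ValueError("finite-difference step h must be positive")
    base = pose.coords
    grad = np.zeros_like(base)
    for i in range(base.shape[0]):
        for k in range(3):
            plus = base.copy()
            minus = base.copy()
            plus[i, k] += h
            minus[i, k] -= h
            e_plus = model.evaluate(receptor, ligand, Pose(plus))
            e_minus = model.evaluate(receptor, ligand, Pose(minus))
            if not (np.isfinite(e_plus) and np.isfinite(e_minus)):
                raise GradientEvaluationError(i)
            grad[i, k] = (e_plus - e_minus) / (2.0 * h)
    return grad


@dataclass
class MinimumRecord:
    """An optimized pose with its stage-1 and (after rescoring) stage-2 energies.

    ``rank`` is assigned by the rescoring stage: 1 = lowest stage-2 energy.
    ``converged`` records whether the local optimizer met its gradient
    tolerance; non-converged minima stay eligible for the pool but carry the
    flag. ``record_id`` is the insertion sequence number within its pool.
    """

    pose: Pose
    e_stage1: float
    e_stage2: Optional[float] = None
    rank: Optional[int] = None
    converged: bool = True
    record_id: Optional[int] = None
    rescore_failed: bool = False

    def __post_init__(self):
        if not np.isfinite(self.e_stage1):
            raise ValueError("e_stage1 must be finite")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be a positive integer")

    def with_stage2(self, e2: float) -> "MinimumRecord":
        return replace(self, e_stage2=float(e2))
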