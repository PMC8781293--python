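"""Force-field energy model backed by RDKit's MMFF94 implementation.

The stage-1 search field for real (non-toy) systems is MMFF94. The force
field itself is consumed from RDKit behind the :class:`EnergyModel`
contract; this module only adapts coordinates and gradients.

The model is bound at construction to a specific chemical system (an RDKit
molecule that MMFF94 can type: complete valences, explicit hydrogens). For
a protein-ligand complex the combined molecule lists receptor atoms first
and ligand atoms last; ``evaluate`` rewrites the ligand block of the
conformer and returns the total MMFF94 energy, so the rigid receptor's
internal energy enters as an additive constant. Whether typing succeeds on
a given receptor depends on its chemistry (nonstandard residues or missing
hydrogens fail with a clear error); the ligand-alone model covers the
unbound-ligand legs of the enthalpy protocol.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .core import EnergyModel, LigandTopology, Pose, RigidReceptor

__all__ = ["MMFF94Model", "MMFFTypingError"]


class MMFFTypingError(RuntimeError):
    """MMFF94 atom typing failed for the supplied molecule."""


class MMFF94Model(EnergyModel):
    """MMFF94 energies/gradients of a fixed chemical system via RDKit.

    Parameters
    ----------
    system:
        RDKit molecule with one 3D conformer covering the whole system.
    n_ligand_atoms:
        Number of trailing atoms that belong to the (mobile) ligand. The
        leading atoms are treated as the rigid receptor block whose
        coordinates come from the construction conformer.
    """

    def __init__(self, system: Chem.Mol, n_ligand_atoms: int, name: str = "mmff94"):
        if system.GetNumConformers() == 0:
            raise ValueError("system molecule needs a 3D conformer")
        if not 0 < n_ligand_atoms <= system.GetNumAtoms():
            raise ValueError("n_ligand_atoms out of range")
        props = AllChem.MMFFGetMoleculeProperties(system)
        if props is None:
            raise MMFFTypingError(
                "MMFF94 could not type this system (check valences/hydrogens)"
            )
        self._ff = AllChem.MMFFGetMoleculeForceField(system, props)
        if self._ff is None:
            raise MMFFTypingError("MMFF94 force field setup failed")
        self.name = name
        self.n_ligand_atoms = n_ligand_atoms
        conf = system.GetConformer()
        self._base = np.array(
            [list(conf.GetAtomPosition(k)) for k in range(system.GetNumAtoms())]
        )

    @classmethod
    def for_ligand(cls, mol: Chem.Mol, name: str = "mmff94-ligand") -> "MMFF94Model":
        """Ligand-alone MMFF94 model (no receptor block)."""
        return cls(mol, n_ligand_atoms=mol.GetNumAtoms(), name=name)

    def _positions(self, pose: Pose) -> np.ndarray:
        full = self._base.copy()
        full[-self.n_ligand_atoms :] = pose.coords
        return full.ravel()

    def evaluate(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose) -> float:
        if pose.n_atoms != self.n_ligand_atoms:
            raise ValueError("pose does not match the bound ligand block")
        return float(self._ff.CalcEnergy(tuple(self._positions(pose))))

    def gradient(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose):
        grad = np.array(self._ff.CalcGrad(tuple(self._positions(pose)))).reshape(-1, 3)
        return grad[-self.n_ligand_atoms :]
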