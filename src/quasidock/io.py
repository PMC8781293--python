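"""Structure and pool I/O.

Ligands come from SDF/MOL (preferred — the file carries the bond table and
formal charges) or from PDB with distance-based bond perception, both
through RDKit. Receptors come from PDB through gemmi. Pools are serialized
as a multi-record SDF (one record per minimum, energies and ranks as SD
tags) plus a TSV index; both round-trip losslessly.

Rotatable torsions are enumerated from the bond table: every
non-ring single bond whose two atoms each carry at least one further heavy
neighbor defines one torsion, with reference atoms chosen deterministically
(lowest heavy neighbor index on each side).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from rdkit import Chem

from .core import AtomRecord, LigandTopology, MinimumRecord, Pose, RigidReceptor
from .pool import MinimaPool, PoolConfig

__all__ = [
    "StructureIOError",
    "ligand_from_rdkit",
    "ligand_to_rdkit",
    "load_ligand",
    "load_receptor",
    "write_ligand_sdf",
    "write_receptor_pdb",
    "write_pool_sdf",
    "read_pool_sdf",
    "write_pool_tsv",
    "write_manifest",
]


class StructureIOError(IOError):
    """A structure file could not be read or failed validation."""


def enumerate_rotatable_torsions(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Rotatable torsions of an RDKit molecule: single, non-ring bonds with
    a heavy continuation on both sides (internal rotations around ordinary
    chemical bonds)."""
    torsions = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        b, c = bond.GetBeginAtom(), bond.GetEndAtom()

        def heavy_neighbors(atom, exclude_idx):
            return sorted(
                n.GetIdx()
                for n in atom.GetNeighbors()
                if n.GetIdx() != exclude_idx and n.GetAtomicNum() > 1
            )

        nb = heavy_neighbors(b, c.GetIdx())
        nc = heavy_neighbors(c, b.GetIdx())
        if nb and nc:
            torsions.append((nb[0], b.GetIdx(), c.GetIdx(), nc[0]))
    return torsions


def ligand_from_rdkit(mol: Chem.Mol, formal_charge: Optional[int] = None) -> LigandTopology:
    """Convert an RDKit molecule (with a 3D conformer) to a ligand topology."""
    if mol.GetNumConformers() == 0:
        raise StructureIOError("ligand molecule has no 3D conformer")
    conf = mol.GetConformer()
    atoms = tuple(
        AtomRecord(
            element=a.GetSymbol(),
            coords=tuple(conf.GetAtomPosition(a.GetIdx())),
            name=f"{a.GetSymbol()}{a.GetIdx() + 1}",
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(round(b.GetBondTypeAsDouble())))
        for b in mol.GetBonds()
    )
    charge = formal_charge if formal_charge is not None else Chem.GetFormalCharge(mol)
    return LigandTopology(
        atoms=atoms,
        bonds=bonds,
        torsions=tuple(enumerate_rotatable_torsions(mol)),
        formal_charge=charge,
    )


def ligand_to_rdkit(ligand: LigandTopology, pose: Optional[Pose] = None) -> Chem.Mol:
    """Rebuild an RDKit molecule (with conformer) from a ligand topology.

    The total formal charge is stored on the first atom — atom-resolved
    charges are not tracked by the topology.
    """
    _BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    rw = Chem.RWMol()
    for a in ligand.atoms:
        atom = Chem.Atom(a.element)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in ligand.bonds:
        rw.AddBond(i, j, _BOND_TYPES.get(order, Chem.BondType.SINGLE))
    if ligand.formal_charge:
        rw.GetAtomWithIdx(0).SetFormalCharge(ligand.formal_charge)
    mol = rw.GetMol()
    coords = pose.coords if pose is not None else ligand.coords()
    conf = Chem.Conformer(ligand.n_atoms)
    for k, xyz in enumerate(coords):
        conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


def load_ligand(path: str | Path, formal_charge: Optional[int] = None) -> LigandTopology:
    """Read a ligand from SDF/MOL (bond table from file) or PDB (bonds
    perceived from geometry). ``formal_charge`` overrides file metadata."""
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"ligand file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise StructureIOError(f"no readable molecule in {path}")
        mol = mols[0]
    elif suffix == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise StructureIOError(f"could not parse PDB ligand {path}")
    else:
        raise StructureIOError(f"unsupported ligand format {suffix!r} (use SDF/MOL/PDB)")
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    except Exception as exc:
        raise StructureIOError(f"ligand sanitization failed for {path}: {exc}") from exc
    return ligand_from_rdkit(mol, formal_charge=formal_charge)


def load_receptor(
    path: str | Path,
    site_center: tuple[float, float, float],
    site_radius: float = 8.0,
) -> RigidReceptor:
    """Read a rigid receptor from PDB (via gemmi) plus the site sphere."""
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"receptor file not found: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except Exception as exc:
        raise StructureIOError(f"could not parse receptor PDB {path}: {exc}") from exc
    atoms = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(
                        AtomRecord(
                            element=atom.element.name,
                            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                            name=atom.name,
                            residue=f"{chain.name}/{residue.name}{residue.seqid.num}",
                        )
                    )
        break  # first model only; receptors are rigid single-model inputs
    if not atoms:
        raise StructureIOError(f"receptor {path} contains no atoms")
    return RigidReceptor(atoms=tuple(atoms), site_center=site_center, site_radius=site_radius)


def write_ligand_sdf(ligand: LigandTopology, path: str | Path, pose: Optional[Pose] = None):
    writer = Chem.SDWriter(str(path))
    try:
        writer.write(ligand_to_rdkit(ligand, pose))
    finally:
        writer.close()


def write_receptor_pdb(receptor: RigidReceptor, path: str | Path):
    """Write receptor atoms as a PDB file (HETATM records via gemmi)."""
    structure = gemmi.Structure()
    structure.name = "receptor"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res_by_tag: dict[str, gemmi.Residue] = {}
    for k, atom in enumerate(receptor.atoms):
        tag = atom.residue or "UNK1"
        if tag not in res_by_tag:
            residue = gemmi.Residue()
            residue.name = (tag.split("/")[-1][:3] or "UNK").upper()
            residue.seqid = gemmi.SeqId(len(res_by_tag) + 1, " ")
            residue.het_flag = "H"
            res_by_tag[tag] = residue
        a = gemmi.Atom()
        a.name = (atom.name or f"{atom.element}{k + 1}")[:4]
        a.element = gemmi.Element(atom.element)
        a.pos = gemmi.Position(*atom.coords)
        res_by_tag[tag].add_atom(a)
    for residue in res_by_tag.values():
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


# --- pool serialization ----------------------------------------------------

_SD_TAGS = ("e_stage1", "e_stage2", "rank", "record_id", "converged")


def write_pool_sdf(pool: MinimaPool, path: str | Path):
    """Multi-record SDF of the pool: one molecule per minimum, energies,
    rank and flags as SD tags, records in ascending stage-1 energy."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in pool.records:
            mol = ligand_to_rdkit(pool.ligand, rec.pose)
            mol.SetProp("e_stage1", f"{rec.e_stage1:.10f}")
            if rec.e_stage2 is not None:
                mol.SetProp("e_stage2", f"{rec.e_stage2:.10f}")
            if rec.rank is not None:
                mol.SetProp("rank", str(rec.rank))
            mol.SetProp("record_id", str(rec.record_id))
            mol.SetProp("converged", "1" if rec.converged else "0")
            writer.write(mol)
    finally:
        writer.close()


def read_pool_sdf(
    path: str | Path, ligand: LigandTopology, config: PoolConfig = PoolConfig()
) -> MinimaPool:
    """Reload a pool written by :func:`write_pool_sdf` (lossless for poses
    at the written precision, energies, ranks and flags)."""
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"pool file not found: {path}")
    pool = MinimaPool(ligand, config)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    records = []
    for mol in supplier:
        if mol is None:
            raise StructureIOError(f"unreadable record in pool SDF {path}")
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(k)) for k in range(mol.GetNumAtoms())]
        )
        rec = MinimumRecord(
            pose=Pose(coords),
            e_stage1=float(mol.GetProp("e_stage1")),
            e_stage2=float(mol.GetProp("e_stage2")) if mol.HasProp("e_stage2") else None,
            rank=int(mol.GetProp("rank")) if mol.HasProp("rank") else None,
            converged=mol.GetProp("converged") == "1" if mol.HasProp("converged") else True,
            record_id=int(mol.GetProp("record_id")) if mol.HasProp("record_id") else None,
        )
        records.append(rec)
    # records were written sorted and unique: rebuild pool state directly so
    # the reload is lossless even if thresholds would now merge basins
    pool.records = sorted(records, key=lambda r: r.e_stage1)
    pool._energies = [r.e_stage1 for r in pool.records]
    pool.n_processed = len(records)
    pool.n_inserted = len(records)
    pool._next_id = 1 + max((r.record_id or 0) for r in records) if records else 0
    return pool


def write_pool_tsv(
    pool: MinimaPool,
    path: str | Path,
    native: Optional[Pose] = None,
    symmetry: bool = True,
):
    """TSV index of the pool: rank, energies, and RMSD to the native pose
    when a native reference is given. Deterministic formatting."""
    from .analysis import heavy_rmsd, symmetry_corrected_rmsd

    lines = ["record_id\trank\te_stage1\te_stage2\tconverged\trmsd_to_native"]
    ordered = sorted(
        pool.records, key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0)
    )
    for rec in ordered:
        if native is not None:
            if symmetry:
                rmsd, _ = symmetry_corrected_rmsd(rec.pose, native, pool.ligand)
            else:
                rmsd = heavy_rmsd(rec.pose, native, pool.ligand)
            rmsd_s = f"{rmsd:.6f}"
        else:
            rmsd_s = ""
        e2 = f"{rec.e_stage2:.10f}" if rec.e_stage2 is not None else ""
        rank = str(rec.rank) if rec.rank is not None else ""
        lines.append(
            f"{rec.record_id}\t{rank}\t{rec.e_stage1:.10f}\t{e2}\t"
            f"{int(rec.converged)}\t{rmsd_s}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, payload: dict):
    """JSON run manifest (seed, config, counters, saturation)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
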