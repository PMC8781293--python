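"""Positioning metrics, docking-paradigm verdicts and binding enthalpy.

Positioning accuracy of a ranked pool is judged against the
crystallographic native pose. RMSD is computed over heavy (non-hydrogen)
ligand atoms in the common receptor frame — never superposed, which is the
docking convention. Chemically symmetric ligands can match the native pose
under a non-identity atom mapping, so the symmetry-corrected RMSD minimizes
over all element- and bond-preserving automorphisms of the heavy-atom bond
graph.

INN (Index Near Native) is the rank — 1 meaning lowest stage-2 energy — of
the lowest-energy minimum whose RMSD to the native pose is below 2 A. When
INN equals 1 the docking paradigm holds: the predicted global minimum is
the crystallographic binding mode.

Binding enthalpy is estimated from global-minimum energies alone
(contributions of higher minima and vibrations are neglected):

    dH_bind = E1(PL) - E1(P) - E1(L)

with each term the stage-2 energy of the corresponding global minimum:
the complex relaxed (ligand atoms only) under the vacuum stage-2 model
from the docked GM then single-pointed with solvent; the receptor in its
fixed docking conformation; and the best unbound-ligand conformer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .core import EnergyModel, LigandTopology, Pose, RigidReceptor
from .optimize import OptimizerConfig, optimize_ligand_alone, optimize_pose
from .pool import MinimaPool

__all__ = [
    "EvaluationRow",
    "EnthalpyComponents",
    "heavy_rmsd",
    "symmetry_corrected_rmsd",
    "ligand_automorphisms",
    "compute_inn",
    "paradigm_verdict",
    "count_paradigm_failures",
    "binding_enthalpy",
    "enthalpy_protocol",
    "pearson_r",
    "positioning_rows",
    "positioning_summary",
    "enthalpy_summary",
    "render_tables_report",
    "AutomorphismCapError",
]

NEAR_NATIVE_CUTOFF = 2.0  # A; strict '<' — a boundary value counts as failure


class AutomorphismCapError(RuntimeError):
    """Symmetry enumeration exceeded its cap; supply an explicit mapping."""


@dataclass
class EvaluationRow:
    """One complex's evaluation record (mirrors the per-complex summary table).

    ``inn`` is None when no ranked minimum lies near the native pose;
    ``dh_exp``/``dh_calc`` are the measured and computed binding enthalpies
    where available.
    """

    complex_id: str
    n_min: int
    inn: Optional[int]
    rmsd_gm: Optional[float] = None
    dh_exp: Optional[float] = None
    dh_calc: Optional[float] = None

    def __post_init__(self):
        if self.inn is not None:
            if self.inn < 1:
                raise ValueError("inn must be >= 1 when defined")
            if self.n_min < self.inn:
                raise ValueError("n_min cannot be smaller than inn")


@dataclass(frozen=True)
class EnthalpyComponents:
    """Global-minimum energies of complex, protein and ligand plus their
    combination ``dh_bind = e1_pl - e1_p - e1_l`` (exact arithmetic)."""

    e1_pl: float
    e1_p: float
    e1_l: float

    @property
    def dh_bind(self) -> float:
        return self.e1_pl - self.e1_p - self.e1_l


def heavy_rmsd(
    pose_a: Pose,
    pose_b: Pose,
    ligand: LigandTopology,
    mapping: Optional[dict[int, int]] = None,
) -> float:
    """Heavy-atom RMSD between two poses in the common frame, Angstrom.

    ``mapping`` sends atom indices of ``pose_a`` to the indices of
    ``pose_b`` they should be compared against (identity when omitted); it
    must be a bijection on the heavy atoms. No superposition is applied.
    """
    heavy = ligand.heavy_indices
    if mapping is None:
        idx_b = heavy
    else:
        try:
            idx_b = np.array([mapping[int(i)] for i in heavy], dtype=int)
        except KeyError as exc:
            raise ValueError(f"mapping misses heavy atom {exc}") from None
        if len(set(idx_b.tolist())) != len(heavy) or not set(idx_b.tolist()) <= set(
            heavy.tolist()
        ):
            raise ValueError("mapping is not a bijection on heavy atoms")
    d = pose_a.coords[heavy] - pose_b.coords[idx_b]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def ligand_automorphisms(ligand: LigandTopology, cap: int = 10_000) -> list[dict[int, int]]:
    """All element- and bond-order-preserving automorphisms of the
    heavy-atom bond graph (the identity is always included).

    Raises :class:`AutomorphismCapError` when more than ``cap`` exist.
    """
    g = ligand.heavy_graph()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    autos = list(islice(matcher.isomorphisms_iter(), cap + 1))
    if len(autos) > cap:
        raise AutomorphismCapError(
            f"more than {cap} graph automorphisms; pass an explicit mapping instead"
        )
    return [dict(a) for a in autos]


def symmetry_corrected_rmsd(
    pose_a: Pose,
    pose_b: Pose,
    ligand: LigandTopology,
    cap: int = 10_000,
) -> tuple[float, dict[int, int]]:
    """Minimum heavy-atom RMSD over all ligand-graph automorphisms.

    Returns the best RMSD and the mapping achieving it. For an asymmetric
    ligand this is exactly :func:`heavy_rmsd` with the identity mapping.
    """
    best_rmsd = np.inf
    best_map: dict[int, int] = {}
    for mapping in ligand_automorphisms(ligand, cap=cap):
        r = heavy_rmsd(pose_a, pose_b, ligand, mapping)
        if r < best_rmsd:
            best_rmsd = r
            best_map = mapping
    return float(best_rmsd), best_map


def compute_inn(
    ranked: MinimaPool,
    native: Pose,
    ligand: LigandTopology,
    cutoff: float = NEAR_NATIVE_CUTOFF,
    symmetry: bool = True,
    alternative_native: Optional[Pose] = None,
) -> tuple[Optional[int], Optional[float]]:
    """Index Near Native and the RMSD of the rank-1 pose.

    ``inn`` is the smallest rank whose (symmetry-corrected) RMSD to the
    native pose is strictly below ``cutoff``; None when no ranked minimum
    qualifies. ``alternative_native`` covers two-fold symmetric binding
    sites (homodimers): each minimum is compared against both references
    and the smaller RMSD counts.
    """
    ranked_records = sorted(
        (r for r in ranked.records if r.rank is not None), key=lambda r: r.rank
    )
    if not ranked_records:
        raise ValueError("pool has no ranked records; run rescoring first")

    references = [native] + ([alternative_native] if alternative_native is not None else [])

    def rmsd_to_native(pose: Pose) -> float:
        vals = []
        for ref in references:
            if symmetry:
                r, _ = symmetry_corrected_rmsd(pose, ref, ligand)
            else:
                r = heavy_rmsd(pose, ref, ligand)
            vals.append(r)
        return min(vals)

    inn = None
    rmsd_gm = None
    for rec in ranked_records:
        r = rmsd_to_native(rec.pose)
        if rec.rank == 1:
            rmsd_gm = r
        if inn is None and r < cutoff:
            inn = rec.rank
            if rmsd_gm is not None:
                break
    return inn, rmsd_gm


def paradigm_verdict(row: EvaluationRow) -> bool:
    """True iff the docking paradigm is satisfied: INN == 1."""
    return row.inn == 1


def count_paradigm_failures(rows: Sequence[EvaluationRow]) -> int:
    """Number of complexes where the paradigm fails (INN > 1 or absent)."""
    if not rows:
        raise ValueError("no evaluation rows")
    return sum(0 if paradigm_verdict(r) else 1 for r in rows)


def binding_enthalpy(e1_pl: float, e1_p: float, e1_l: float) -> float:
    """dH_bind = E1(PL) - E1(P) - E1(L), kcal/mol (exact arithmetic).

    All three terms must come from the same stage-2 method and solvent
    combination; mixing methods is a caller error guarded at the protocol
    level, not here.
    """
    return e1_pl - e1_p - e1_l


def enthalpy_protocol(
    gm_pose: Pose,
    receptor: RigidReceptor,
    ligand: LigandTopology,
    solvent_model: EnergyModel,
    vacuum_model: Optional[EnergyModel] = None,
    optimizer: OptimizerConfig = OptimizerConfig(),
    ligand_pool: Sequence[Pose] = (),
) -> EnthalpyComponents:
    """Compute the three global-minimum energies entering dH_bind.

    * E1(PL): ligand atoms are relaxed in the rigid receptor under the
      *vacuum* stage-2 model starting from the docked GM pose, then the
      relaxed geometry gets one solvent-model single point.
    * E1(P): solvent-model energy of the receptor in its fixed docking
      conformation — no optimization.
    * E1(L): every unbound-ligand conformer in ``ligand_pool`` is relaxed
      under the vacuum model (no receptor), single-pointed with solvent,
      and the lowest energy wins.

    ``vacuum_model`` defaults to ``solvent_model`` (useful for surrogate
    models with no solvent split, and for the self-consistency checks).
    """
    if not ligand_pool:
        raise ValueError("ligand_pool must hold at least one unbound conformer")
    vac = vacuum_model if vacuum_model is not None else solvent_model

    relaxed = optimize_pose(vac, receptor, ligand, gm_pose, optimizer)
    e1_pl = solvent_model.evaluate(receptor, ligand, relaxed.pose)

    e1_p = solvent_model.receptor_energy(receptor)

    from .core import RigidReceptor as _RR

    empty = _RR(atoms=(), site_center=(0.0, 0.0, 0.0), site_radius=1.0)
    e1_l = np.inf
    for conformer in ligand_pool:
        rel = optimize_ligand_alone(vac, ligand, conformer, optimizer)
        e = solvent_model.evaluate(empty, ligand, rel.pose)
        e1_l = min(e1_l, e)

    return EnthalpyComponents(e1_pl=float(e1_pl), e1_p=float(e1_p), e1_l=float(e1_l))


def positioning_rows(positioning_df, method: str) -> list[EvaluationRow]:
    """Per-complex evaluation rows from the packaged positioning table.

    ``method`` selects the stage-2 column set: ``pm6d3h4x_cosmo`` or
    ``pm7_cosmo``.
    """
    inn_col, rmsd_col = f"inn_{method}", f"rmsd_{method}"
    if inn_col not in positioning_df.columns:
        raise KeyError(f"no positioning columns for method {method!r}")
    rows = []
    for _, r in positioning_df.iterrows():
        inn = None if np.isnan(r[inn_col]) else int(r[inn_col])
        rows.append(
            EvaluationRow(
                complex_id=str(r["pdb_id"]),
                n_min=int(r["n_min"]),
                inn=inn,
                rmsd_gm=float(r[rmsd_col]),
            )
        )
    return rows


def positioning_summary(positioning_df) -> dict:
    """Paradigm failure/success counts for both stage-2 methods."""
    out = {}
    n = len(positioning_df)
    for method in ("pm6d3h4x_cosmo", "pm7_cosmo"):
        rows = positioning_rows(positioning_df, method)
        failures = count_paradigm_failures(rows)
        out[method] = {"n_complexes": n, "failures": failures, "successes": n - failures}
    return out


def enthalpy_summary(enthalpy_df) -> dict:
    """Correlations between measured and calculated binding enthalpies.

    Incomplete pairs (no calculated value for a method) are dropped by
    :func:`pearson_r`; the summary also reports whether every calculated
    enthalpy is negative (bound state enthalpically favourable).
    """
    exp = [None if np.isnan(v) else float(v) for v in enthalpy_df["dh_exp"]]
    out = {}
    for method in ("pm6d3h4x_cosmo", "pm7_cosmo"):
        col = f"dh_{method}"
        calc = [None if np.isnan(v) else float(v) for v in enthalpy_df[col]]
        complete = [c for c in calc if c is not None]
        out[method] = {
            "r": pearson_r(exp, calc),
            "n_pairs": sum(1 for e, c in zip(exp, calc) if e is not None and c is not None),
            "all_negative": all(c < 0 for c in complete),
        }
    return out


def render_tables_report(tables) -> str:
    """Markdown report over the packaged tables: per-complex positioning,
    failure counts and enthalpy correlations."""
    pos = positioning_summary(tables.positioning)
    ent = enthalpy_summary(tables.enthalpy)
    lines = ["# Quasi-docking evaluation (packaged tables)", ""]
    lines.append("## Ligand positioning")
    lines.append("")
    lines.append(tables.positioning.to_markdown(index=False))
    lines.append("")
    for method, s in pos.items():
        lines.append(
            f"- {method}: paradigm fulfilled for {s['successes']}/{s['n_complexes']} "
            f"complexes ({s['failures']} failures, INN > 1 or no near-native minimum)"
        )
    lines.append("")
    lines.append("## Binding enthalpy")
    lines.append("")
    lines.append(tables.enthalpy.to_markdown(index=False))
    lines.append("")
    for method, s in ent.items():
        lines.append(
            f"- {method}: Pearson R = {s['r']:.2f} over {s['n_pairs']} pairs; "
            f"all calculated enthalpies negative: {s['all_negative']}"
        )
    return "\n".join(lines) + "\n"


def pearson_r(x: Sequence[Optional[float]], y: Sequence[Optional[float]]) -> float:
    """Sample Pearson correlation; pairs with a missing value are dropped.

    Requires at least 3 complete pairs and nonzero variance in both
    variables.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if a is not None and b is not None and np.isfinite(a) and np.isfinite(b)
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(pairs)}")
    xs, ys = (np.array(v) for v in zip(*pairs))
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(np.corrcoef(xs, ys)[0, 1])
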