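"""Stage 2 of quasi-docking: single-point re-ranking of the minima pool.

Every minimum collected under the stage-1 search field is re-evaluated by a
second, slower energy model *without moving a single atom* (the 1SCF
contract), and the pool is re-ranked by the new energies: rank 1 — the
lowest stage-2 energy — is the declared global minimum (GM) whose pose is
the predicted binding mode.

Two stage-2 backends are provided. The external backend writes
MOPAC-dialect input files (semiempirical PM7 or PM6-D3H4X, MOZYME localized
orbitals, COSMO implicit water with dielectric 78.4) and parses the final
heat of formation from the program's output; the program itself is an
optional runtime dependency. The surrogate backend is a smooth pairwise
potential (soft Lennard-Jones plus screened Coulomb) that runs everywhere,
differs from the stage-1 field, and genuinely permutes stage-1 rankings —
it powers the full-pipeline test path.
"""

from __future__ import annotations

import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .core import EnergyModel, LigandTopology, Pose, RigidReceptor
from .pool import MinimaPool

__all__ = [
    "RescoreJob",
    "RescoreError",
    "QMParseError",
    "write_qm_input",
    "parse_qm_energy",
    "SurrogateParams",
    "SurrogateModel",
    "surrogate_energy",
    "model_runner",
    "mopac_runner",
    "rescore_pool",
]

_KNOWN_METHODS = ("PM7", "PM6-D3H4X", "surrogate")

#: Coulomb constant in kcal/mol * A / e^2.
_COULOMB_K = 332.0637


class RescoreError(RuntimeError):
    """Run-level rescoring failure (e.g., too many failed jobs)."""


class QMParseError(RuntimeError):
    """External-program output could not be parsed; carries the file tail."""

    def __init__(self, message: str, tail: str = ""):
        self.tail = tail
        super().__init__(message + ("\n--- output tail ---\n" + tail if tail else ""))


@dataclass(frozen=True)
class RescoreJob:
    """What the stage-2 single-point calculation should be.

    ``single_point`` mirrors the 1SCF keyword: geometry is never modified
    by rescoring. ``cosmo_eps`` is the COSMO water dielectric (78.4 at room
    temperature); ``solvent='none'`` drops the COSMO keyword (used by the
    vacuum legs of the enthalpy protocol). ``total_charge`` overrides the
    ligand formal charge when the receptor carries a net charge of its own.
    """

    method: str = "PM7"
    solvent: str = "cosmo"
    cosmo_eps: float = 78.4
    single_point: bool = True
    total_charge: Optional[int] = None
    max_parallel: int = 1

    def __post_init__(self):
        if self.method not in _KNOWN_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {_KNOWN_METHODS}"
            )
        if self.solvent not in ("none", "cosmo"):
            raise ValueError(f"unknown solvent {self.solvent!r}")
        if self.max_parallel < 1:
            raise ValueError("max_parallel must be >= 1")


def write_qm_input(
    receptor: RigidReceptor,
    ligand: LigandTopology,
    pose: Pose,
    job: RescoreJob,
    title: str = "quasidock single point",
) -> str:
    """Render a MOPAC-dialect input deck for one complex single point.

    The keyword line carries the method token, 1SCF (single point), MOZYME
    (localized orbitals for protein-sized systems), the total charge, and
    EPS=<dielectric> when COSMO solvent is requested. Coordinate lines list
    receptor atoms first, then ligand atoms, in fixed order.
    """
    if job.method == "surrogate":
        raise ValueError("the surrogate backend never writes external input files")
    charge = job.total_charge if job.total_charge is not None else ligand.formal_charge
    keywords = [job.method, "MOZYME", f"CHARGE={charge}"]
    if job.single_point:
        keywords.insert(1, "1SCF")
    if job.solvent == "cosmo":
        keywords.append(f"EPS={job.cosmo_eps:g}")
    lines = [" ".join(keywords), title, ""]
    for atom in receptor.atoms:
        x, y, z = atom.coords
        lines.append(f"{atom.element:<2s} {x:14.8f} 1 {y:14.8f} 1 {z:14.8f} 1")
    for atom, xyz in zip(ligand.atoms, pose.coords):
        lines.append(
            f"{atom.element:<2s} {xyz[0]:14.8f} 1 {xyz[1]:14.8f} 1 {xyz[2]:14.8f} 1"
        )
    return "\n".join(lines) + "\n"


_HEAT_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL", re.IGNORECASE
)
_FAILURE_MARKERS = (
    "CALCULATION IS TERMINATED",
    "EXCESS NUMBER OF OPTIMIZATION CYCLES",
    "UNRECOGNIZED KEY-WORDS",
    "JOB ENDED ABNORMALLY",
)


def parse_qm_energy(output_text: str) -> float:
    """Final heat of formation (kcal/mol) from an external-program output.

    When the output prints several heats of formation (restarts, multi-step
    decks) the last one wins — that is the external program's convention for
    the final result. Raises :class:`QMParseError` when a failure marker is
    present or no heat-of-formation line exists (truncated run).
    """
    tail = "\n".join(output_text.splitlines()[-15:])
    for marker in _FAILURE_MARKERS:
        if marker in output_text.upper():
            raise QMParseError(f"external program reported failure: {marker}", tail)
    matches = _HEAT_RE.findall(output_text)
    if not matches:
        raise QMParseError("no final heat of formation found (truncated output?)", tail)
    return float(matches[-1])


# --- surrogate backend -----------------------------------------------------

_DEFAULT_EPS = {
    "C": 0.8, "N": 1.6, "O": 2.4, "S": 3.2, "P": 4.0, "F": 1.2,
    "Cl": 2.0, "Br": 2.8, "I": 3.6, "H": 0.2,
}
_DEFAULT_CHARGES = {
    "C": 0.0, "N": -0.2, "O": -0.3, "S": -0.1, "P": 0.1, "F": -0.2,
    "Cl": -0.1, "Br": -0.1, "I": -0.05, "H": 0.1,
}


@dataclass(frozen=True)
class SurrogateParams:
    """Soft-LJ + screened-Coulomb parameters of the surrogate rescorer.

    Pair well depth is the geometric mean of per-element ``eps`` values;
    the soft core (``soft_delta``) keeps the potential finite and smooth at
    contact, so single points at force-field minima never blow up.
    """

    eps: dict = field(default_factory=lambda: dict(_DEFAULT_EPS))
    charges: dict = field(default_factory=lambda: dict(_DEFAULT_CHARGES))
    sigma: float = 1.6
    soft_delta: float = 1.6
    dielectric: float = 10.0
    screening_length: float = 6.0


class SurrogateModel(EnergyModel):
    """Deterministic stand-in for a semiempirical single-point backend.

    Receptor-ligand pairwise energy only (the rigid receptor's internal
    energy is an additive constant and is omitted):

        E = sum_ij eps_ij * (s^6 - 2 s^3) + k q_i q_j exp(-r/λ) / (ε sqrt(r² + δ²)),
        s = σ² / (r² + δ²)

    It is smooth everywhere, attractive at contact, and — having nothing in
    common with the stage-1 search field — genuinely reorders its minima.
    """

    def __init__(self, params: SurrogateParams = SurrogateParams(), name: str = "surrogate"):
        self.params = params
        self.name = name

    def _pair_tables(self, receptor, ligand):
        p = self.params
        eps_r = np.array([p.eps.get(e, 1.0) for e in receptor.elements])
        eps_l = np.array([p.eps.get(e, 1.0) for e in ligand.elements])
        q_r = np.array([p.charges.get(e, 0.0) for e in receptor.elements])
        q_l = np.array([p.charges.get(e, 0.0) for e in ligand.elements])
        return np.sqrt(np.outer(eps_r, eps_l)), np.outer(q_r, q_l)

    def evaluate(self, receptor: RigidReceptor, ligand: LigandTopology, pose: Pose) -> float:
        if receptor.n_atoms == 0:
            return 0.0
        p = self.params
        eps_ij, q_ij = self._pair_tables(receptor, ligand)
        diff = receptor.coords()[:, None, :] - pose.coords[None, :, :]
        r2 = np.sum(diff * diff, axis=2)
        s = p.sigma**2 / (r2 + p.soft_delta**2)
        lj = eps_ij * (s**6 - 2.0 * s**3)
        r = np.sqrt(r2)
        coul = (
            _COULOMB_K
            * q_ij
            * np.exp(-r / p.screening_length)
            / (p.dielectric * np.sqrt(r2 + p.soft_delta**2))
        )
        return float(np.sum(lj) + np.sum(coul))


def surrogate_energy(
    receptor: RigidReceptor,
    ligand: LigandTopology,
    pose: Pose,
    params: SurrogateParams = SurrogateParams(),
) -> float:
    """Functional form of :class:`SurrogateModel` for one-off evaluations."""
    return SurrogateModel(params).evaluate(receptor, ligand, pose)


# --- pool rescoring --------------------------------------------------------


def model_runner(
    model: EnergyModel, receptor: RigidReceptor, ligand: LigandTopology
) -> Callable[[Pose], float]:
    """Adapt an in-process :class:`EnergyModel` to the runner contract
    (``Pose -> stage-2 energy``)."""

    def run(pose: Pose) -> float:
        return model.evaluate(receptor, ligand, pose)

    return run


def mopac_runner(
    receptor: RigidReceptor,
    ligand: LigandTopology,
    job: RescoreJob,
    executable: str = "mopac",
    workdir: str | None = None,
) -> Callable[[Pose], float]:
    """Runner that executes the external semiempirical program per pose.

    Writes one input deck per call, invokes ``executable`` and parses the
    final heat of formation from the ``.out`` file. The external program is
    an optional runtime dependency: constructing the runner fails fast when
    the executable cannot be found.
    """
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    exe = shutil.which(executable)
    if exe is None:
        raise RescoreError(f"external QM executable {executable!r} not found on PATH")
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="quasidock-qm-"))
    base.mkdir(parents=True, exist_ok=True)
    counter = {"n": 0}

    def run(pose: Pose) -> float:
        counter["n"] += 1
        stem = base / f"sp_{counter['n']:06d}"
        stem.with_suffix(".mop").write_text(write_qm_input(receptor, ligand, pose, job))
        subprocess.run(
            [exe, str(stem.with_suffix(".mop"))],
            check=True,
            capture_output=True,
            timeout=3600,
        )
        return parse_qm_energy(stem.with_suffix(".out").read_text())

    return run


def rescore_pool(
    pool: MinimaPool,
    job: RescoreJob,
    runner: Callable[[Pose], float],
    max_failure_fraction: float = 0.1,
) -> MinimaPool:
    """Set every record's stage-2 energy and assign ranks, in place.

    The runner is called once per record (at most ``job.max_parallel`` jobs
    in flight; results are identified by record index, so completion order
    is irrelevant). Poses are never modified — the 1SCF contract. A failing
    job flags its record and drops it from ranking; more than
    ``max_failure_fraction`` failures aborts with :class:`RescoreError`.

    Ranks are 1..N by ascending stage-2 energy; ties break by ascending
    stage-1 energy, then by insertion order. Rank 1 is the global minimum.
    """
    records = pool.records
    if not records:
        raise RescoreError("cannot rescore an empty pool")

    def one(idx: int):
        try:
            return idx, float(runner(records[idx].pose)), None
        except Exception as exc:  # runner failures are per-record, not fatal
            return idx, None, exc

    if job.max_parallel > 1:
        with ThreadPoolExecutor(max_workers=job.max_parallel) as ex:
            results = list(ex.map(one, range(len(records))))
    else:
        results = [one(i) for i in range(len(records))]

    n_failed = 0
    for idx, energy, err in results:
        rec = records[idx]
        if err is not None or energy is None or not np.isfinite(energy):
            rec.rescore_failed = True
            rec.e_stage2 = None
            rec.rank = None
            n_failed += 1
        else:
            rec.rescore_failed = False
            rec.e_stage2 = energy
    if n_failed > max_failure_fraction * len(records):
        raise RescoreError(
            f"{n_failed}/{len(records)} rescoring jobs failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )

    ranked = [r for r in records if not r.rescore_failed]
    ranked.sort(key=lambda r: (r.e_stage2, r.e_stage1, r.record_id))
    for rank, rec in enumerate(ranked, start=1):
        rec.rank = rank
    return pool
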