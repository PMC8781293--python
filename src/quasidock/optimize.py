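"""Local minimization of the stage-1 energy over all ligand Cartesians.

Each random start pose is refined by L-BFGS acting on the full 3N vector of
ligand atom coordinates (the receptor never moves). The stage-2 model is
never optimized against during docking — geometry relaxation happens only
under the search field; the quantum model sees single points.

Convergence is declared on the projected-gradient infinity norm. The
returned energy is always <= the start energy (the optimizer is a descent
method; if a pathological line search ends higher, the start point is
returned unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import minimize

from .core import (
    EnergyModel,
    LigandTopology,
    Pose,
    RigidReceptor,
    finite_difference_gradient,
)

__all__ = ["OptimizerConfig", "OptimizationResult", "optimize_pose", "optimize_ligand_alone"]


@dataclass(frozen=True)
class OptimizerConfig:
    """L-BFGS settings: gradient tolerance (kcal/mol/A, infinity norm),
    iteration cap, and history size.

    The default tolerance is deliberately tight: flat saddle regions (e.g. a
    terminal atom free to swing about a bond axis) can push the gradient
    under a loose threshold and contaminate the minima pool with
    non-minima. At 1e-5 the optimizer walks off such saddles."""

    grad_tol: float = 1e-5
    max_iter: int = 2000
    history_size: int = 10
    fd_step: float = 1e-4

    def __post_init__(self):
        if not self.grad_tol > 0:
            raise ValueError("grad_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class OptimizationResult:
    pose: Pose
    energy: float
    converged: bool
    n_iter: int
    message: str = ""


class _NonFiniteEnergy(Exception):
    pass


def _objective(model, receptor, ligand, use_fd, fd_step):
    def fun(x: np.ndarray):
        pose = Pose(x.reshape(-1, 3))
        e = model.evaluate(receptor, ligand, pose)
        if not np.isfinite(e):
            raise _NonFiniteEnergy
        if use_fd:
            g = finite_difference_gradient(model, receptor, ligand, pose, h=fd_step)
        else:
            g = model.gradient(receptor, ligand, pose)
        return e, np.asarray(g, dtype=float).ravel()

    return fun


def optimize_pose(
    model: EnergyModel,
    receptor: RigidReceptor,
    ligand: LigandTopology,
    start: Pose,
    config: OptimizerConfig = OptimizerConfig(),
) -> OptimizationResult:
    """L-BFGS descent of ``model`` from ``start`` over all ligand coordinates.

    Returns the optimized pose, its energy and a convergence flag (true iff
    the max gradient component reached ``grad_tol``). A non-finite energy
    encountered mid-search aborts the descent; the caller should discard the
    start (logged, not fatal to the run).
    """
    if start.n_atoms != ligand.n_atoms:
        raise ValueError("start pose does not match ligand atom count")
    e0 = model.evaluate(receptor, ligand, start)
    if not np.isfinite(e0):
        raise ValueError("energy non-finite at the start pose")
    use_fd = model.gradient(receptor, ligand, start) is None
    fun = _objective(model, receptor, ligand, use_fd, config.fd_step)
    try:
        res = minimize(
            fun,
            start.coords.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iter,
                "maxcor": config.history_size,
                "gtol": config.grad_tol,
                # ftol left effectively off so the gradient criterion governs
                "ftol": 1e-16,
            },
        )
    except _NonFiniteEnergy:
        raise ArithmeticError("non-finite energy during line search; pose discarded")
    pose = Pose(res.x.reshape(-1, 3))
    energy = float(res.fun)
    if energy > e0:  # descent guarantee: never return worse than the start
        pose, energy = start, float(e0)
    grad_inf = float(np.max(np.abs(res.jac)))
    converged = grad_inf <= config.grad_tol
    return OptimizationResult(
        pose=pose,
        energy=energy,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )


_EMPTY_SITE = (0.0, 0.0, 0.0)


def optimize_ligand_alone(
    model: EnergyModel,
    ligand: LigandTopology,
    start: Pose,
    config: OptimizerConfig = OptimizerConfig(),
) -> OptimizationResult:
    """Minimize the isolated ligand (empty receptor) from ``start``.

    Used by the unbound-ligand leg of the binding-enthalpy protocol: each
    stage-1 conformer is relaxed under the chosen model without any protein.
    """
    if ligand.n_atoms == 0:
        raise ValueError("ligand has no atoms")
    from .core import RigidReceptor as _RR

    empty = _RR(atoms=(), site_center=_EMPTY_SITE, site_radius=1.0)
    return optimize_pose(model, empty, ligand, start, config)
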