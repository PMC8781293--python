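"""Run orchestration: the two-step quasi-docking procedure as library calls.

``run_search`` drives stage 1 (multi-start sampling + local minimization +
pool collection), ``run_rescore`` stage 2 (single-point re-ranking), and
``run_evaluate`` the positioning metrics. The command-line interface is a
thin wrapper over these.

Reproducibility contract: the start-pose stream is a pure function of the
inputs and the master seed — start ``i`` draws from its own generator
seeded ``(master_seed, i)`` — so the collected pool is independent of how
many workers executed the starts, and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import EnergyModel, LigandTopology, MinimumRecord, Pose, RigidReceptor
from .optimize import OptimizerConfig, optimize_pose
from .pool import MinimaPool, PoolConfig
from .sampling import SamplerConfig, SamplingExhaustedError, generate_start_pose

logger = logging.getLogger("quasidock")

__all__ = ["RunConfig", "SearchResult", "run_search", "run_rescore", "run_evaluate"]


@dataclass(frozen=True)
class RunConfig:
    """Full stage-1 run configuration (serializable; config + seed
    reproduce the pose stream)."""

    n_starts: int = 200
    seed: int = 0
    n_workers: int = 1
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    pool: PoolConfig = field(default_factory=PoolConfig)
    saturation_window: int = 100

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SearchResult:
    pool: MinimaPool
    manifest: dict
    n_failed_starts: int = 0


def _run_one_start(args):
    model, receptor, ligand, sampler_cfg, optimizer_cfg, master_seed, index = args
    rng = np.random.default_rng([master_seed, index])
    try:
        start = generate_start_pose(receptor, ligand, sampler_cfg, rng)
    except SamplingExhaustedError:
        return index, None
    try:
        res = optimize_pose(model, receptor, ligand, start, optimizer_cfg)
    except ArithmeticError:
        return index, None  # non-finite energy mid-search: discard this start
    return index, (res.pose.coords, res.energy, res.converged)


def run_search(
    model: EnergyModel,
    receptor: RigidReceptor,
    ligand: LigandTopology,
    config: RunConfig,
) -> SearchResult:
    """Stage 1: collect unique low-energy minima from ``n_starts`` starts.

    With ``n_workers > 1`` the starts are executed by a process pool; the
    per-start seeding makes results identical to a serial run, and merging
    in start order keeps pool contents deterministic.
    """
    if config.sampler.site_radius != receptor.site_radius:
        sampler_cfg = SamplerConfig(
            site_radius=receptor.site_radius,
            clash_scale=config.sampler.clash_scale,
            max_attempts_per_start=config.sampler.max_attempts_per_start,
        )
    else:
        sampler_cfg = config.sampler
    tasks = [
        (model, receptor, ligand, sampler_cfg, config.optimizer, config.seed, i)
        for i in range(config.n_starts)
    ]
    if config.n_workers > 1:
        with ProcessPoolExecutor(max_workers=config.n_workers) as ex:
            outcomes = list(ex.map(_run_one_start, tasks, chunksize=32))
    else:
        outcomes = [_run_one_start(t) for t in tasks]
    outcomes.sort(key=lambda t: t[0])

    pool = MinimaPool(ligand, config.pool)
    n_failed = 0
    for index, payload in outcomes:
        if payload is None:
            n_failed += 1
            logger.debug("start %d discarded (sampling or optimizer failure)", index)
            continue
        coords, energy, converged = payload
        pool.try_insert(
            MinimumRecord(pose=Pose(coords), e_stage1=energy, converged=converged)
        )
    window = min(config.saturation_window, max(pool.n_processed, 1))
    saturation = (
        pool.saturation_report(window) if pool.n_processed else {"saturated": False}
    )
    manifest = {
        "seed": config.seed,
        "n_starts": config.n_starts,
        "n_workers": config.n_workers,
        "config_hash": config.config_hash(),
        "counters": pool.counters(),
        "n_failed_starts": n_failed,
        "saturation": saturation,
        "pool_size": len(pool),
    }
    logger.info(
        "search done: %d starts, %d unique minima, saturated=%s",
        config.n_starts,
        len(pool),
        saturation.get("saturated"),
    )
    return SearchResult(pool=pool, manifest=manifest, n_failed_starts=n_failed)


def run_rescore(pool: MinimaPool, job, runner) -> dict:
    """Stage 2 wrapper: rescore + rank, returning a manifest."""
    from .rescoring import rescore_pool

    rescore_pool(pool, job, runner)
    ranked = [r for r in pool.records if r.rank is not None]
    gm = min(ranked, key=lambda r: r.rank) if ranked else None
    manifest = {
        "method": job.method,
        "solvent": job.solvent,
        "n_ranked": len(ranked),
        "n_failed": sum(1 for r in pool.records if r.rescore_failed),
        "gm_e_stage2": gm.e_stage2 if gm else None,
    }
    logger.info("rescore done: %d ranked, GM e2=%s", len(ranked), manifest["gm_e_stage2"])
    return manifest


def run_evaluate(pool: MinimaPool, native: Pose, ligand: LigandTopology, **kwargs) -> dict:
    """Positioning evaluation of a ranked pool against a native pose."""
    from .analysis import NEAR_NATIVE_CUTOFF, compute_inn

    inn, rmsd_gm = compute_inn(pool, native, ligand, **kwargs)
    return {
        "inn": inn,
        "rmsd_gm": rmsd_gm,
        "paradigm_fulfilled": inn == 1,
        "cutoff": kwargs.get("cutoff", NEAR_NATIVE_CUTOFF),
        "n_min": len(pool),
    }
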