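"""Fixed-capacity pool of unique low-energy minima.

The multi-start search streams optimized poses into this pool. A candidate
is a *duplicate* when its heavy-atom RMSD (identity atom mapping, no
superposition) to a stored record falls below the uniqueness threshold —
the two points then belong to one basin and the better-converged (lower
stage-1 energy) representative is kept. Unique candidates are inserted in
ascending stage-1 energy order; once the pool is full, a new record below
the current maximum evicts the highest-energy record, so the pool always
holds the lowest-energy unique minima seen so far.

Saturation is the stopping diagnostic: the search has saturated when a
whole window of recent candidates produced no insertion below the previous
pool maximum — continued sampling reveals no new minimum under any stored
one.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .core import LigandTopology, MinimumRecord

__all__ = ["PoolConfig", "MinimaPool", "InsertionOutcome"]

InsertionOutcome = Literal["inserted", "duplicate", "above_cutoff"]


@dataclass(frozen=True)
class PoolConfig:
    """Pool size and uniqueness settings.

    ``capacity`` defaults to 8192 but may be raised freely — hard targets
    can need several times more minima before one lies near the native
    pose. ``uniqueness_rmsd`` (A, heavy atoms) separates basins without
    splitting optimizer jitter; ``energy_merge_tol`` is the energy scale
    below which two basin representatives count as the same level.
    """

    capacity: int = 8192
    uniqueness_rmsd: float = 0.5
    energy_merge_tol: float = 1e-6

    def __post_init__(self):
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if not self.uniqueness_rmsd > 0:
            raise ValueError("uniqueness_rmsd must be positive")


class MinimaPool:
    """Uniqueness-enforcing, energy-sorted pool of :class:`MinimumRecord`.

    Records are kept strictly sorted by ``e_stage1`` (insertion order breaks
    ties). Counters partition every processed candidate into inserted /
    duplicate / above-cutoff, and the pool tracks the candidate index of the
    last insertion below the previous maximum for the saturation report.
    """

    def __init__(self, ligand: LigandTopology, config: PoolConfig = PoolConfig()):
        self.ligand = ligand
        self.config = config
        self.records: list[MinimumRecord] = []
        self._energies: list[float] = []  # parallel sort keys
        self._heavy_idx = ligand.heavy_indices
        self.n_processed = 0
        self.n_inserted = 0
        self.n_rejected_duplicate = 0
        self.n_above_cutoff = 0
        self.n_evicted = 0
        self._next_id = 0
        #: 1-based candidate indices of insertions that improved on the
        #: then-current pool maximum (drives the saturation report).
        self._improvement_indices: list[int] = []

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def energies(self) -> np.ndarray:
        return np.array(self._energies, dtype=float)

    def _find_duplicate(self, candidate: MinimumRecord) -> int | None:
        if not self.records:
            return None
        cand = candidate.pose.coords[self._heavy_idx]
        stack = np.stack([r.pose.coords[self._heavy_idx] for r in self.records])
        d = stack - cand[None, :, :]
        rmsds = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
        k = int(np.argmin(rmsds))
        return k if rmsds[k] < self.config.uniqueness_rmsd else None

    def try_insert(self, candidate: MinimumRecord) -> InsertionOutcome:
        """Insert a candidate minimum, enforcing uniqueness and capacity.

        Returns the outcome: ``inserted`` (new basin), ``duplicate`` (an
        existing basin; the stored representative is replaced if the
        candidate has lower energy), or ``above_cutoff`` (pool full and the
        candidate is worse than every stored record).
        """
        if not np.isfinite(candidate.e_stage1):
            raise ValueError("candidate stage-1 energy must be finite")
        self.n_processed += 1
        prev_max = self._energies[-1] if self._energies else np.inf
        full = len(self.records) >= self.config.capacity

        dup = self._find_duplicate(candidate)
        if dup is not None:
            if candidate.e_stage1 < self.records[dup].e_stage1:
                kept = MinimumRecord(
                    pose=candidate.pose,
                    e_stage1=candidate.e_stage1,
                    converged=candidate.converged,
                    record_id=self.records[dup].record_id,
                )
                del self.records[dup]
                del self._energies[dup]
                pos = bisect.bisect_right(self._energies, kept.e_stage1)
                self.records.insert(pos, kept)
                self._energies.insert(pos, kept.e_stage1)
            self.n_rejected_duplicate += 1
            return "duplicate"

        if full and candidate.e_stage1 >= self._energies[-1]:
            self.n_above_cutoff += 1
            return "above_cutoff"

        stored = MinimumRecord(
            pose=candidate.pose,
            e_stage1=candidate.e_stage1,
            converged=candidate.converged,
            record_id=self._next_id,
        )
        self._next_id += 1
        pos = bisect.bisect_right(self._energies, stored.e_stage1)
        self.records.insert(pos, stored)
        self._energies.insert(pos, stored.e_stage1)
        if full:
            self.records.pop()
            self._energies.pop()
            self.n_evicted += 1
        self.n_inserted += 1
        if stored.e_stage1 < prev_max:
            self._improvement_indices.append(self.n_processed)
        return "inserted"

    def extend(self, candidates: Iterable[MinimumRecord]) -> list[InsertionOutcome]:
        return [self.try_insert(c) for c in candidates]

    def saturation_report(self, window: int) -> dict:
        """Has the last ``window`` of candidates improved the pool?

        Saturated means zero insertions below the then-current pool maximum
        occurred among the last ``window`` processed candidates.
        """
        if window < 1:
            raise ValueError("window must be >= 1")
        if window > self.n_processed:
            raise ValueError(
                f"window {window} exceeds processed candidate count {self.n_processed}"
            )
        cutoff = self.n_processed - window
        new_low = sum(1 for idx in self._improvement_indices if idx > cutoff)
        return {
            "new_low_minima_in_window": new_low,
            "saturated": new_low == 0,
            "n_processed": self.n_processed,
            "pool_size": len(self.records),
        }

    def counters(self) -> dict:
        return {
            "n_processed": self.n_processed,
            "n_inserted": self.n_inserted,
            "n_rejected_duplicate": self.n_rejected_duplicate,
            "n_above_cutoff": self.n_above_cutoff,
            "n_evicted": self.n_evicted,
        }
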