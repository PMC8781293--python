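"""Shared fixtures: toy complexes (built once per session) and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from quasidock.core import MinimumRecord, Pose, RigidReceptor
from quasidock.fixtures import (
    ToyFieldModel,
    build_toy_complex,
    make_ligand,
    standard_spec,
)


@pytest.fixture(scope="session")
def toy2():
    """Two-pocket complex with enumerated minima (the re-ranking workhorse)."""
    return build_toy_complex(standard_spec(2, rng_seed=3))


@pytest.fixture(scope="session")
def toy5():
    return build_toy_complex(standard_spec(5, rng_seed=1))


@pytest.fixture(scope="session")
def chain4_ligand():
    return make_ligand("chain4")


@pytest.fixture(scope="session")
def chain4_model(chain4_ligand):
    """Isolated-chain field: double-well torsion potential, no receptor."""
    return ToyFieldModel(chain4_ligand)


@pytest.fixture(scope="session")
def ring6_ligand():
    return make_ligand("ring6")


@pytest.fixture
def empty_receptor():
    return RigidReceptor(atoms=(), site_center=(0.0, 0.0, 0.0), site_radius=1.0)


def synthetic_minima_stream(rng, n_candidates, n_basins, n_atoms=3):
    """Candidates drawn from well-separated basins with tiny jitter.

    Basin base energies are separated by ~1 kcal/mol while per-candidate
    jitter stays below 1e-3, so the best-representative-per-basin result is
    independent of arrival order. Returns (records, basin_ids, base_coords).
    """
    centers = 10.0 * np.arange(n_basins)[:, None] * np.array([1.0, 0.0, 0.0])
    template = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.7, 1.2, 0.0]])[:n_atoms]
    base_energy = -50.0 + 1.0 * np.arange(n_basins)
    records, basins = [], []
    for _ in range(n_candidates):
        b = int(rng.integers(n_basins))
        jitter_xyz = rng.normal(scale=0.01, size=(n_atoms, 3))
        e = base_energy[b] + float(rng.uniform(0.0, 1e-3))
        records.append(
            MinimumRecord(pose=Pose(template + centers[b] + jitter_xyz), e_stage1=e)
        )
        basins.append(b)
    return records, basins, base_energy
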