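"""Positioning metrics (RMSD, symmetry correction, INN), paradigm verdicts,
binding enthalpy and correlation."""

import itertools

import numpy as np
import pytest

from quasidock.analysis import (
    EnthalpyComponents,
    EvaluationRow,
    binding_enthalpy,
    compute_inn,
    count_paradigm_failures,
    enthalpy_protocol,
    heavy_rmsd,
    ligand_automorphisms,
    paradigm_verdict,
    pearson_r,
    symmetry_corrected_rmsd,
)
from quasidock.core import AtomRecord, LigandTopology, MinimumRecord, Pose
from quasidock.geometry import rotation_about_axis
from quasidock.pool import MinimaPool, PoolConfig


@pytest.fixture
def hetero_ligand():
    """Three heavy atoms + one hydrogen, to check hydrogen exclusion."""
    atoms = (
        AtomRecord(element="C", coords=(0.0, 0.0, 0.0)),
        AtomRecord(element="N", coords=(1.4, 0.0, 0.0)),
        AtomRecord(element="O", coords=(2.1, 1.2, 0.0)),
        AtomRecord(element="H", coords=(-0.5, 0.9, 0.0)),
    )
    return LigandTopology(atoms=atoms, bonds=((0, 1, 1), (1, 2, 1), (0, 3, 1)))


class TestHeavyRMSD:
    def test_identical_poses_zero(self, hetero_ligand):
        pose = Pose(hetero_ligand.coords())
        assert heavy_rmsd(pose, pose, hetero_ligand) == 0.0

    def test_uniform_shift_is_exact(self, hetero_ligand):
        a = Pose(hetero_ligand.coords())
        b = Pose(hetero_ligand.coords() + np.array([3.0, 4.0, 0.0]))
        assert heavy_rmsd(a, b, hetero_ligand) == pytest.approx(5.0, abs=1e-12)

    def test_hydrogens_excluded(self, hetero_ligand):
        coords = hetero_ligand.coords()
        moved_h = coords.copy()
        moved_h[3] += [10.0, 0.0, 0.0]  # hydrogen only
        assert heavy_rmsd(Pose(coords), Pose(moved_h), hetero_ligand) == 0.0

    def test_closed_form_two_displaced(self):
        atoms = (
            AtomRecord(element="C", coords=(0.0, 0.0, 0.0)),
            AtomRecord(element="C", coords=(1.5, 0.0, 0.0)),
        )
        lig = LigandTopology(atoms=atoms, bonds=((0, 1, 1),))
        a = Pose(lig.coords())
        shifted = lig.coords()
        shifted[1] += [0.0, 2.0, 0.0]  # displacements 0 and 2 -> sqrt(2)
        assert heavy_rmsd(a, Pose(shifted), lig) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_non_bijective_mapping_rejected(self, hetero_ligand):
        pose = Pose(hetero_ligand.coords())
        with pytest.raises(ValueError):
            heavy_rmsd(pose, pose, hetero_ligand, mapping={0: 0, 1: 0, 2: 2})


def brute_force_automorphisms(ligand):
    """Independent enumeration: all heavy-atom permutations preserving
    elements and adjacency (test-side oracle, O(n!))."""
    heavy = list(ligand.heavy_indices)
    elements = {i: ligand.atoms[i].element for i in heavy}
    adj = {}
    for i, j, o in ligand.bonds:
        if i in elements and j in elements:
            adj[frozenset((i, j))] = o
    autos = []
    for perm in itertools.permutations(heavy):
        m = dict(zip(heavy, perm))
        if any(elements[i] != elements[m[i]] for i in heavy):
            continue
        ok = True
        for pair, order in adj.items():
            i, j = tuple(pair)
            if adj.get(frozenset((m[i], m[j]))) != order:
                ok = False
                break
        if ok:
            autos.append(m)
    return autos


class TestSymmetryCorrectedRMSD:
    def test_asymmetric_ligand_identity_mapping(self, hetero_ligand):
        rng = np.random.default_rng(1)
        a = Pose(hetero_ligand.coords())
        b = Pose(hetero_ligand.coords() + rng.normal(scale=0.5, size=(4, 3)))
        r_sym, mapping = symmetry_corrected_rmsd(a, b, hetero_ligand)
        assert r_sym == heavy_rmsd(a, b, hetero_ligand)
        assert mapping == {i: i for i in range(3)}

    def test_ring_flip_gives_zero(self, ring6_ligand):
        """A symmetric planar six-ring rotated 180 degrees about an in-plane
        symmetry axis superposes onto itself under a non-identity mapping."""
        coords = ring6_ligand.coords()
        rot = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi)
        flipped = coords @ rot.T
        a, b = Pose(coords), Pose(flipped)
        assert heavy_rmsd(a, b, ring6_ligand) > 1.0
        r_sym, mapping = symmetry_corrected_rmsd(a, b, ring6_ligand)
        assert r_sym == pytest.approx(0.0, abs=1e-10)
        assert mapping != {i: i for i in range(6)}

    def test_matches_brute_force_on_random_pairs(self, ring6_ligand):
        autos = brute_force_automorphisms(ring6_ligand)
        assert len(autos) == 12  # dihedral symmetry of the six-ring
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = Pose(ring6_ligand.coords() + rng.normal(scale=1.0, size=(6, 3)))
            b = Pose(ring6_ligand.coords() + rng.normal(scale=1.0, size=(6, 3)))
            expected = min(heavy_rmsd(a, b, ring6_ligand, m) for m in autos)
            got, _ = symmetry_corrected_rmsd(a, b, ring6_ligand)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got <= heavy_rmsd(a, b, ring6_ligand) + 1e-12

    def test_automorphism_cap(self, ring6_ligand):
        from quasidock.analysis import AutomorphismCapError

        with pytest.raises(AutomorphismCapError):
            ligand_automorphisms(ring6_ligand, cap=5)


def _ranked_pool_with_rmsds(ligand, native, rmsds):
    """Pool whose rank-k pose sits at exactly rmsds[k-1] A from native
    (uniform x-shift of all atoms)."""
    pool = MinimaPool(ligand, PoolConfig(capacity=len(rmsds), uniqueness_rmsd=1e-9))
    for k, r in enumerate(rmsds):
        rec = MinimumRecord(
            pose=Pose(native.coords + np.array([r, 0.0, 0.0])),
            e_stage1=float(k),
            record_id=k,
        )
        rec.e_stage2 = float(k)
        rec.rank = k + 1
        pool.records.append(rec)
        pool._energies.append(rec.e_stage1)
    pool.n_processed = pool.n_inserted = len(rmsds)
    return pool


class TestINN:
    def test_first_subcutoff_rank(self, toy2):
        native = toy2.native
        pool = _ranked_pool_with_rmsds(toy2.ligand, native, [2.5, 2.1, 1.0, 0.5])
        inn, rmsd_gm = compute_inn(pool, native, toy2.ligand)
        assert inn == 3
        assert rmsd_gm == pytest.approx(2.5, abs=1e-9)

    def test_rank1_near_native_fulfils_paradigm(self, toy2):
        pool = _ranked_pool_with_rmsds(toy2.ligand, toy2.native, [0.43, 3.0])
        inn, rmsd_gm = compute_inn(pool, toy2.native, toy2.ligand)
        assert inn == 1
        row = EvaluationRow(complex_id="toy", n_min=2, inn=inn, rmsd_gm=rmsd_gm)
        assert paradigm_verdict(row)

    def test_absent_when_nothing_near_native(self, toy2):
        pool = _ranked_pool_with_rmsds(toy2.ligand, toy2.native, [2.0, 2.6, 9.0])
        inn, _ = compute_inn(pool, toy2.native, toy2.ligand)
        assert inn is None  # strict cutoff: exactly 2.0 A is a failure

    def test_alternative_native_reference(self, toy2):
        """Symmetric homodimer sites: the better of two native references
        counts."""
        native = toy2.native
        alt = Pose(native.coords + np.array([0.0, 8.0, 0.0]))
        pool = _ranked_pool_with_rmsds(toy2.ligand, alt, [0.5])
        inn_without, _ = compute_inn(pool, native, toy2.ligand)
        inn_with, _ = compute_inn(pool, native, toy2.ligand, alternative_native=alt)
        assert inn_without is None
        assert inn_with == 1

    def test_unranked_pool_rejected(self, toy2):
        pool = MinimaPool(toy2.ligand, PoolConfig())
        pool.try_insert(MinimumRecord(pose=toy2.native, e_stage1=0.0))
        with pytest.raises(ValueError, match="ranked"):
            compute_inn(pool, toy2.native, toy2.ligand)


class TestParadigmCounts:
    def test_verdicts(self):
        assert paradigm_verdict(EvaluationRow("x", 10, 1))
        assert not paradigm_verdict(EvaluationRow("x", 10, 2))
        assert not paradigm_verdict(EvaluationRow("x", 10, None))

    def test_all_fulfilled_counts_zero(self):
        rows = [EvaluationRow(f"c{i}", 5, 1) for i in range(4)]
        assert count_paradigm_failures(rows) == 0

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            count_paradigm_failures([])

    def test_row_invariants(self):
        with pytest.raises(ValueError):
            EvaluationRow("x", 10, 0)
        with pytest.raises(ValueError):
            EvaluationRow("x", 2, 5)  # n_min < inn


class TestBindingEnthalpy:
    def test_arithmetic(self):
        assert binding_enthalpy(-100.0, -60.0, -10.0) == -30.0

    def test_non_interacting_limit(self):
        assert binding_enthalpy(-70.0, -60.0, -10.0) == 0.0

    def test_components_combination_is_exact(self):
        c = EnthalpyComponents(e1_pl=-100.25, e1_p=-60.125, e1_l=-10.0625)
        assert c.dh_bind == -100.25 - (-60.125) - (-10.0625)

    def test_protocol_deterministic(self, toy2):
        sur_args = dict(
            gm_pose=toy2.native,
            receptor=toy2.receptor,
            ligand=toy2.ligand,
            solvent_model=toy2.stage1_model,
            ligand_pool=[Pose(toy2.ligand.coords())],
        )
        a = enthalpy_protocol(**sur_args)
        b = enthalpy_protocol(**sur_args)
        assert (a.e1_pl, a.e1_p, a.e1_l) == (b.e1_pl, b.e1_p, b.e1_l)

    def test_single_optimal_conformer_gives_its_single_point(self, toy2, empty_receptor):
        """A one-conformer pool already at the vacuum optimum: E1(L) is just
        that conformer's solvent single point."""
        from quasidock.optimize import optimize_ligand_alone

        relaxed = optimize_ligand_alone(
            toy2.stage1_model, toy2.ligand, Pose(toy2.ligand.coords())
        )
        comp = enthalpy_protocol(
            gm_pose=toy2.native,
            receptor=toy2.receptor,
            ligand=toy2.ligand,
            solvent_model=toy2.stage1_model,
            ligand_pool=[relaxed.pose],
        )
        direct = toy2.stage1_model.evaluate(empty_receptor, toy2.ligand, relaxed.pose)
        assert comp.e1_l == pytest.approx(direct, abs=1e-9)

    def test_self_consistency_with_identical_models(self, toy2, empty_receptor):
        """With stage-2 = stage-1 and a single-conformer ligand pool, the
        combination equals the directly computed interaction energy."""
        from quasidock.optimize import optimize_ligand_alone, optimize_pose

        comp = enthalpy_protocol(
            gm_pose=toy2.native,
            receptor=toy2.receptor,
            ligand=toy2.ligand,
            solvent_model=toy2.stage1_model,
            ligand_pool=[Pose(toy2.ligand.coords())],
        )
        # independent recomposition through separate optimizer calls
        relaxed_complex = optimize_pose(
            toy2.stage1_model, toy2.receptor, toy2.ligand, toy2.native
        )
        relaxed_ligand = optimize_ligand_alone(
            toy2.stage1_model, toy2.ligand, Pose(toy2.ligand.coords())
        )
        direct = relaxed_complex.energy - 0.0 - toy2.stage1_model.evaluate(
            empty_receptor, toy2.ligand, relaxed_ligand.pose
        )
        assert comp.dh_bind == pytest.approx(direct, abs=1e-8)

    def test_empty_ligand_pool_rejected(self, toy2):
        with pytest.raises(ValueError, match="conformer"):
            enthalpy_protocol(
                gm_pose=toy2.native,
                receptor=toy2.receptor,
                ligand=toy2.ligand,
                solvent_model=toy2.stage1_model,
                ligand_pool=[],
            )


class TestPearson:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_incomplete_pairs_dropped(self):
        x = [1.0, 2.0, None, 3.0, 4.0]
        y = [2.0, 4.1, 9.0, 5.9, 8.2]
        r_full = pearson_r([1.0, 2.0, 3.0, 4.0], [2.0, 4.1, 5.9, 8.2])
        assert pearson_r(x, y) == r_full

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])
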