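"""Stage-2 rescoring: external-program file dialect, surrogate model,
pool re-ranking."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from quasidock.core import AtomRecord, LigandTopology, MinimumRecord, Pose, RigidReceptor
from quasidock.fixtures import reranking_surrogate
from quasidock.pool import MinimaPool, PoolConfig
from quasidock.rescoring import (
    QMParseError,
    RescoreError,
    RescoreJob,
    SurrogateModel,
    model_runner,
    parse_qm_energy,
    rescore_pool,
    surrogate_energy,
    write_qm_input,
)


def _tiny_complex():
    rec = RigidReceptor(
        atoms=(AtomRecord(element="O", coords=(0.0, 0.0, 0.0), name="O1"),),
        site_center=(0, 0, 0),
        site_radius=5.0,
    )
    lig = LigandTopology(
        atoms=(AtomRecord(element="C", coords=(2.0, 0.0, 0.0), name="C1"),),
        bonds=(),
        formal_charge=1,
    )
    return rec, lig


class TestQMInputWriter:
    def test_keyword_line_contents(self):
        rec, lig = _tiny_complex()
        text = write_qm_input(rec, lig, Pose([[2.0, 0.0, 0.0]]), RescoreJob(method="PM7"))
        keywords = text.splitlines()[0]
        for token in ("PM7", "1SCF", "MOZYME", "CHARGE=1", "EPS=78.4"):
            assert token in keywords

    def test_vacuum_job_omits_solvent(self):
        rec, lig = _tiny_complex()
        text = write_qm_input(
            rec, lig, Pose([[2.0, 0.0, 0.0]]), RescoreJob(method="PM6-D3H4X", solvent="none")
        )
        assert "PM6-D3H4X" in text.splitlines()[0]
        assert "EPS" not in text.splitlines()[0]

    def test_surrogate_never_writes_files(self):
        rec, lig = _tiny_complex()
        with pytest.raises(ValueError):
            write_qm_input(rec, lig, Pose([[2.0, 0.0, 0.0]]), RescoreJob(method="surrogate"))

    def test_one_coordinate_line_per_atom(self):
        rec, lig = _tiny_complex()
        text = write_qm_input(rec, lig, Pose([[2.0, 0.0, 0.0]]), RescoreJob(method="PM7"))
        lines = text.rstrip("\n").splitlines()
        # keyword line, title, blank, then exactly two atoms
        assert len(lines) == 3 + 2
        assert lines[3].split()[0] == "O"
        assert lines[4].split()[0] == "C"

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            RescoreJob(method="AM1")


class TestQMOutputParser:
    def test_last_heat_of_formation_wins(self):
        from importlib import resources

        text = (
            resources.files("quasidock.data")
            .joinpath("mopac_output_synthetic.txt")
            .read_text()
        )
        assert parse_qm_energy(text) == pytest.approx(-1234.56789)

    def test_truncated_output_raises(self):
        with pytest.raises(QMParseError, match="no final heat"):
            parse_qm_energy("SCF FIELD WAS ACHIEVED\n ... run cut short ...")

    def test_failure_marker_raises_with_tail(self):
        text = "stuff\nCALCULATION IS TERMINATED\nmore stuff"
        with pytest.raises(QMParseError) as err:
            parse_qm_energy(text)
        assert "more stuff" in err.value.tail

    def test_single_value_roundtrip(self):
        text = "  FINAL HEAT OF FORMATION =  -42.00000 KCAL/MOL = -175.7 KJ/MOL\n"
        assert parse_qm_energy(text) == -42.0


class TestSurrogateModel:
    def test_deterministic(self, toy2):
        pose = toy2.native
        model = SurrogateModel()
        e1 = model.evaluate(toy2.receptor, toy2.ligand, pose)
        e2 = model.evaluate(toy2.receptor, toy2.ligand, pose)
        assert e1 == e2

    def test_bound_pose_beats_distant_ligand(self, toy2):
        model = SurrogateModel()
        bound = model.evaluate(toy2.receptor, toy2.ligand, toy2.native)
        far = model.evaluate(
            toy2.receptor,
            toy2.ligand,
            Pose(toy2.native.coords + np.array([200.0, 0.0, 0.0])),
        )
        assert bound < far
        assert far == pytest.approx(0.0, abs=1e-6)

    def test_functional_form_matches_class(self, toy2):
        assert surrogate_energy(toy2.receptor, toy2.ligand, toy2.native) == SurrogateModel().evaluate(
            toy2.receptor, toy2.ligand, toy2.native
        )

    def test_reranking_surrogate_permutes_stage1_order(self, toy2):
        """Kendall tau between stage-1 and surrogate orderings < 1: the
        re-ranking genuinely changes which basin is the global minimum."""
        sur = reranking_surrogate()
        e1 = [e for e, _ in toy2.oracle_minima]
        e2 = [sur.evaluate(toy2.receptor, toy2.ligand, p) for _, p in toy2.oracle_minima]
        tau, _ = kendalltau(e1, e2)
        assert tau < 1.0
        assert int(np.argmin(e2)) != int(np.argmin(e1))


def _pool_of_random_minima(ligand, n=100, seed=77, stage1=None, receptor=None):
    """Pool of synthetic well-separated records; ``stage1`` (with its
    receptor) computes genuine stage-1 energies, else they are random."""
    rng = np.random.default_rng(seed)
    pool = MinimaPool(ligand, PoolConfig(capacity=n, uniqueness_rmsd=1e-6))
    for k in range(n):
        pose = Pose(ligand.coords() + rng.uniform(-6, 6, size=3))
        if stage1 is not None:
            e1 = stage1.evaluate(receptor, ligand, pose)
        else:
            e1 = float(rng.normal())
        pool.try_insert(MinimumRecord(pose=pose, e_stage1=e1))
    assert len(pool) == n
    return pool


class TestRescorePool:
    def test_identity_rescoring_preserves_stage1_order(self, toy2):
        pool = _pool_of_random_minima(
            toy2.ligand, n=20, stage1=toy2.stage1_model, receptor=toy2.receptor
        )
        runner = model_runner(toy2.stage1_model, toy2.receptor, toy2.ligand)
        rescore_pool(pool, RescoreJob(method="surrogate"), runner)
        ranks = [r.rank for r in pool.records]  # records sorted by e_stage1
        assert ranks == sorted(ranks)

    def test_known_energy_triple_ranks(self, toy2):
        pool = _pool_of_random_minima(toy2.ligand, n=3)
        by_pose = {r.pose: e for r, e in zip(pool.records, (-10.0, -30.0, -20.0))}
        rescore_pool(pool, RescoreJob(method="surrogate"), lambda pose: by_pose[pose])
        assert [r.rank for r in pool.records] == [3, 1, 2]

    def test_rank1_is_brute_force_surrogate_minimum(self, toy2):
        pool = _pool_of_random_minima(toy2.ligand, n=100)
        sur = SurrogateModel()
        rescore_pool(
            pool, RescoreJob(method="surrogate"), model_runner(sur, toy2.receptor, toy2.ligand)
        )
        direct = [sur.evaluate(toy2.receptor, toy2.ligand, r.pose) for r in pool.records]
        gm = next(r for r in pool.records if r.rank == 1)
        assert gm.e_stage2 == min(direct)

    def test_poses_untouched_by_rescoring(self, toy2):
        """The 1SCF contract: single-point rescoring never moves an atom."""
        pool = _pool_of_random_minima(toy2.ligand, n=10)
        before = [r.pose.coords.tobytes() for r in pool.records]
        rescore_pool(
            pool,
            RescoreJob(method="surrogate"),
            model_runner(SurrogateModel(), toy2.receptor, toy2.ligand),
        )
        after = [r.pose.coords.tobytes() for r in pool.records]
        assert before == after

    def test_ranks_are_a_permutation(self, toy2):
        pool = _pool_of_random_minima(toy2.ligand, n=50)
        rescore_pool(
            pool,
            RescoreJob(method="surrogate"),
            model_runner(SurrogateModel(), toy2.receptor, toy2.ligand),
        )
        assert sorted(r.rank for r in pool.records) == list(range(1, 51))

    def test_parallel_runner_matches_serial(self, toy2):
        pool_a = _pool_of_random_minima(toy2.ligand, n=30)
        pool_b = _pool_of_random_minima(toy2.ligand, n=30)
        runner = model_runner(SurrogateModel(), toy2.receptor, toy2.ligand)
        rescore_pool(pool_a, RescoreJob(method="surrogate", max_parallel=1), runner)
        rescore_pool(pool_b, RescoreJob(method="surrogate", max_parallel=4), runner)
        assert [r.e_stage2 for r in pool_a.records] == [r.e_stage2 for r in pool_b.records]
        assert [r.rank for r in pool_a.records] == [r.rank for r in pool_b.records]

    def test_sparse_failures_flagged_and_excluded(self, toy2):
        pool = _pool_of_random_minima(toy2.ligand, n=20)
        doomed = pool.records[7].pose

        def flaky(pose):
            if pose == doomed:
                raise RuntimeError("backend crashed")
            return SurrogateModel().evaluate(toy2.receptor, toy2.ligand, pose)

        rescore_pool(pool, RescoreJob(method="surrogate"), flaky)
        failed = [r for r in pool.records if r.rescore_failed]
        assert len(failed) == 1
        assert failed[0].rank is None
        ranked = [r.rank for r in pool.records if r.rank is not None]
        assert sorted(ranked) == list(range(1, 20))

    def test_too_many_failures_abort(self, toy2):
        pool = _pool_of_random_minima(toy2.ligand, n=10)

        def broken(pose):
            raise RuntimeError("backend down")

        with pytest.raises(RescoreError, match="failed"):
            rescore_pool(pool, RescoreJob(method="surrogate"), broken)
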