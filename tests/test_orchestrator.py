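"""Iteration-loop orchestration: modes, determinism, resume, seed ledger."""

import copy
import shutil
import warnings

import numpy as np
import pandas as pd
import pytest

from genalign.generator import TrainSchedule
from genalign.orchestrator import (
    LoopConfig,
    derive_seed,
    fine_tune_iteration,
    make_surrogate_factory,
    evaluate_iteration,
    prepare_run,
    run_loop,
)
from genalign.scoring import InteractionProfile
from genalign.synthetic import make_corpus


def _micro_config(**overrides):
    """Very small profile for orchestration tests (code-path exercise only)."""
    base = dict(
        score_threshold=11.0,
        n_iterations=1,
        pretrain_schedule=TrainSchedule(batch_size=16, epochs=10, peak_lr=6e-4, final_lr=6e-5),
        generation_size=300,
        generation_attempt_factor=4,
        k=5,
        n_restarts=5,
        n_components=6,
        per_cluster_cap=8,
        scored_subset_size=40,
        replica_floor=60,
        sampling_budget=60,
    )
    base.update(overrides)
    return LoopConfig.tiny(**base)


@pytest.fixture(scope="module")
def micro_corpus():
    return make_corpus(150, seed=2)


@pytest.fixture(scope="module")
def micro_run(micro_corpus):
    """One pretrained micro state, reused (copied) across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state, prep = prepare_run(_micro_config(), micro_corpus)
    return state, prep


def _clone(state, mode="complete", **overrides):
    cfg = _micro_config(mode=mode, **overrides)
    new = copy.deepcopy(state)
    new.config = cfg
    new.metrics = []
    new.iteration = 0
    return new


class TestSeedLedger:
    def test_distinct_per_stage_and_iteration(self):
        seeds = {
            derive_seed(7, stage, it)
            for stage in ("generate", "cluster", "select", "finetune")
            for it in range(4)
        }
        assert len(seeds) == 16
        assert all(0 <= s < 2**31 for s in seeds)

    def test_stable_across_calls(self):
        assert derive_seed(3, "generate", 2) == derive_seed(3, "generate", 2)


class TestRunLoop:
    def test_zero_iterations_gives_single_row(self, micro_corpus, micro_run):
        state, _ = micro_run
        cfg = _micro_config(n_iterations=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_loop(
                cfg, micro_corpus, model=copy.deepcopy(state.model),
                projection=state.projection,
            )
        table = out.metrics_table()
        assert list(table.iteration) == [0]

    def test_two_iterations_give_three_rows_and_determinism(self, micro_corpus, micro_run):
        state, _ = micro_run
        tables = []
        for _ in range(2):
            cfg = _micro_config(n_iterations=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = run_loop(
                    cfg, micro_corpus, model=copy.deepcopy(state.model),
                    projection=state.projection,
                )
            tables.append(out.metrics_table())
        assert list(tables[0].iteration) == [0, 1, 2]
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_resume_reproduces_uninterrupted_metrics(self, micro_corpus, micro_run, tmp_path):
        state, _ = micro_run
        full_dir = tmp_path / "full"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = run_loop(
                _micro_config(n_iterations=2), micro_corpus,
                model=copy.deepcopy(state.model), projection=state.projection,
                workdir=full_dir,
            )
        # simulate an interrupt after iteration 0: keep only its checkpoint + row
        resume_dir = tmp_path / "resumed"
        resume_dir.mkdir()
        shutil.copy(full_dir / "checkpoint_0.npz", resume_dir / "checkpoint_0.npz")
        table = pd.read_csv(full_dir / "metrics.csv")
        table[table.iteration <= 0].to_csv(resume_dir / "metrics.csv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resumed = run_loop(
                _micro_config(n_iterations=2), micro_corpus,
                model=copy.deepcopy(state.model), projection=state.projection,
                workdir=resume_dir,
            )
        cols = ["iteration", "fraction_above_threshold", "mean_score", "max_score"]
        pd.testing.assert_frame_equal(
            full.metrics_table()[cols], resumed.metrics_table()[cols]
        )

    def test_manifest_written(self, micro_corpus, micro_run, tmp_path):
        state, _ = micro_run
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_loop(
                _micro_config(n_iterations=0), micro_corpus,
                model=copy.deepcopy(state.model), projection=state.projection,
                workdir=tmp_path,
            )
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["score_threshold"] == 11.0
        assert "seed_ledger" in manifest and manifest["versions"]["rdkit"]


class TestModes:
    @staticmethod
    def _factory_for(state, prep, cfg):
        from genalign.chemspace import compute_descriptors, project
        from genalign.synthetic import SurrogateScorer

        provider = cfg.descriptor_provider()
        matrix = compute_descriptors(prep.corpus, provider=provider)
        coords = project(state.projection, matrix)
        scorer = SurrogateScorer.from_reference(coords, threshold=cfg.score_threshold)
        return make_surrogate_factory(scorer, state.projection, provider)

    def test_naive_al_set_contains_only_passing_replicas(self, micro_run):
        state, prep = micro_run
        naive = _clone(state, mode="naive")
        factory = self._factory_for(state, prep, naive.config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evaluate_iteration(naive, factory)
            fine_tune_iteration(naive)
        al = naive.al_set
        if al is not None:  # empty only if nothing passed the threshold
            assert al.sampled == []
            passing = {
                s.smiles for s in naive.scored if s.score >= naive.config.score_threshold
            }
            assert set(al.replicas) == passing
            assert al.multiplicity * len(al.replicas) >= naive.config.replica_floor

    def test_uniform_equals_complete_under_equal_scores(self, micro_run):
        """With a constant-score provider the two cluster-based modes yield
        identical sampling fractions and allocations."""
        state, prep = micro_run
        constant = lambda smiles: InteractionProfile(van_der_waals=12)  # noqa: E731
        allocations = {}
        for mode in ("complete", "uniform"):
            st = _clone(state, mode=mode)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evaluate_iteration(st, lambda coords: constant)
                fine_tune_iteration(st)
            allocations[mode] = (st.al_set.fractions, st.al_set.allocations)
        f_c, a_c = allocations["complete"]
        f_u, a_u = allocations["uniform"]
        for label in f_c:
            assert f_c[label] == pytest.approx(f_u[label], abs=1e-12)
        assert a_c == a_u

    def test_ensemble_size_meets_config_or_reports_shortfall(self, micro_run):
        state, prep = micro_run
        st = _clone(state)
        factory = self._factory_for(state, prep, st.config)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            evaluate_iteration(st, factory)
        n = st.metrics[-1].n_generated
        if n < st.config.generation_size:
            assert any("shortfall" in str(w.message) for w in caught)

    def test_projection_fixed_across_iterations(self, micro_corpus, micro_run):
        state, _ = micro_run
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_loop(
                _micro_config(n_iterations=1), micro_corpus,
                model=copy.deepcopy(state.model), projection=state.projection,
            )
        np.testing.assert_array_equal(out.projection.components, state.projection.components)
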