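"""AL training-set construction: replicas, softmax fractions, allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genalign.al_sampler import (
    ALConfig,
    allocate,
    build_al_set,
    cluster_fractions,
    replica_multiplicity,
)
from genalign.chemspace import Clustering
from genalign.scoring import InteractionProfile, ScoredMolecule


class TestReplicaMultiplicity:
    @pytest.mark.parametrize(
        "n_passing, floor, expected",
        [(400, 5000, 13), (5000, 5000, 1), (1, 5000, 5000), (500, 5000, 10)],
    )
    def test_known_values(self, n_passing, floor, expected):
        assert replica_multiplicity(n_passing, floor) == expected

    def test_bound_exhaustive(self):
        """N*n >= floor and (N-1)*n < floor for every n in 1..10000."""
        floor = 5000
        for n in range(1, 10_001):
            N = replica_multiplicity(n, floor)
            assert N * n >= floor
            assert (N - 1) * n < floor

    def test_zero_passing_signalled(self):
        with pytest.raises(ValueError):
            replica_multiplicity(0, 5000)


class TestClusterFractions:
    def test_equal_means_give_equal_fractions(self):
        f = cluster_fractions({0: 3.0, 1: 3.0, 2: 3.0, 3: 3.0})
        assert all(v == pytest.approx(0.25) for v in f.values())

    def test_closed_form_softmax(self):
        f = cluster_fractions({0: 0.0, 1: np.log(2.0)})
        assert f[0] == pytest.approx(1 / 3, abs=1e-12)
        assert f[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_shift_invariance_and_normalization(self, rng):
        means = {i: float(m) for i, m in enumerate(rng.normal(size=12))}
        shifted = {i: m + 123.456 for i, m in means.items()}
        f1, f2 = cluster_fractions(means), cluster_fractions(shifted)
        assert sum(f1.values()) == pytest.approx(1.0, abs=1e-12)
        for i in means:
            assert f1[i] == pytest.approx(f2[i], abs=1e-12)

    def test_overflow_safety(self):
        f = cluster_fractions({0: 1e4, 1: 1e4 - np.log(2.0)})
        assert f[0] == pytest.approx(2 / 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cluster_fractions({})


def _waterfill_oracle(fractions, sizes, budget):
    """Exact continuous cap-respecting proportional allocation.

    Solves count_i = min(size_i, f_i * t) with the fill level t chosen by
    bisection so the counts sum to min(budget, total population). This is
    the fixed point the iterative surplus-redistribution scheme converges
    to, computed by an independent route.
    """
    labels = sorted(fractions)
    target = min(budget, sum(sizes.get(l, 0) for l in labels))
    hi = max(
        (sizes.get(l, 0) / fractions[l] for l in labels if fractions[l] > 0),
        default=0.0,
    ) + 1.0
    lo = 0.0
    for _ in range(200):
        t = (lo + hi) / 2
        total = sum(min(sizes.get(l, 0), fractions[l] * t) for l in labels)
        if total < target:
            lo = t
        else:
            hi = t
    return {l: min(sizes.get(l, 0), fractions[l] * hi) for l in labels}


class TestAllocate:
    def test_even_split_ample(self):
        out = allocate({0: 0.5, 1: 0.5}, {0: 10_000, 1: 10_000}, 5000)
        assert out == {0: 2500, 1: 2500}

    def test_capped_cluster_redistributes_surplus(self):
        out = allocate({0: 0.8, 1: 0.2}, {0: 1000, 1: 10_000}, 5000)
        assert out == {0: 1000, 1: 4000}

    def test_population_exhaustion(self):
        out = allocate({0: 0.6, 1: 0.4}, {0: 2000, 1: 1000}, 5000)
        assert out == {0: 2000, 1: 1000}

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=8).flatmap(
            lambda k: st.tuples(
                st.lists(
                    st.floats(min_value=0.01, max_value=10.0),
                    min_size=k, max_size=k,
                ),
                st.lists(st.integers(min_value=0, max_value=300), min_size=k, max_size=k),
                st.integers(min_value=1, max_value=600),
            )
        )
    )
    def test_budget_conservation_random_instances(self, case):
        weights, sizes_list, budget = case
        total_w = sum(weights)
        fractions = {i: w / total_w for i, w in enumerate(weights)}
        sizes = dict(enumerate(sizes_list))
        out = allocate(fractions, sizes, budget)
        assert all(out[i] <= sizes[i] for i in out)
        assert sum(out.values()) == min(budget, sum(sizes_list))

    def test_matches_waterfill_oracle(self, rng):
        """Integer allocations track the exact continuous solution.

        Totals and caps must agree exactly; per-cluster counts may differ
        from the continuous fixed point only by integer-rounding slack
        accumulated over redistribution rounds (at most a couple of units).
        """
        for _ in range(100):
            k = int(rng.integers(2, 9))
            w = rng.uniform(0.05, 1.0, size=k)
            fractions = {i: float(x) for i, x in enumerate(w / w.sum())}
            sizes = {i: int(rng.integers(0, 120)) for i in range(k)}
            budget = int(rng.integers(1, 250))
            ours = allocate(fractions, sizes, budget)
            oracle = _waterfill_oracle(fractions, sizes, budget)
            assert sum(ours.values()) == round(sum(oracle.values()))
            for i in range(k):
                assert ours[i] <= sizes[i]
                assert abs(ours[i] - oracle[i]) <= 2.0


def _make_clustering(labels):
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    return Clustering(
        k=k, labels=labels, centroids=np.zeros((k, 1)), inertia=0.0,
        size_variance=0.0, n_restarts=1, chosen_run=0, restart_inertias=np.zeros(1),
    )


def _scored(smiles, score, label):
    return ScoredMolecule(
        id=smiles, smiles=smiles, score=score,
        profile=InteractionProfile(van_der_waals=int(round(score))),
        cluster_label=label,
    )


class TestBuildAlSet:
    def _setup(self, n_ensemble=1000, k=10, rng=None):
        ensemble = [f"mol{i}" for i in range(n_ensemble)]
        labels = np.arange(n_ensemble) % k
        return ensemble, _make_clustering(labels)

    def test_half_passing_reaches_ten_thousand(self):
        ensemble = [f"mol{i}" for i in range(20_000)]
        labels = np.arange(20_000) % 10
        clustering = _make_clustering(labels)
        scored = [
            _scored(f"mol{i}", 50.0 if i < 500 else 1.0, int(labels[i]))
            for i in range(1000)
        ]
        config = ALConfig(score_threshold=37.0)
        al = build_al_set(scored, clustering, ensemble, config, seed=0)
        assert al.multiplicity == 10
        assert len(al.replicas) == 500
        assert len(al.sampled) == 5000
        assert len(al) == 10_000

    def test_all_passing(self):
        ensemble, clustering = self._setup(20_000, 10)
        scored = [_scored(f"mol{i}", 40.0, i % 10) for i in range(1000)]
        al = build_al_set(scored, clustering, ensemble, ALConfig(score_threshold=37.0), seed=0)
        assert al.multiplicity == 5
        assert len(al.replicas) * al.multiplicity == 5000

    def test_zero_passing_falls_back_to_sampling_only(self):
        ensemble, clustering = self._setup(2000, 4)
        scored = [_scored(f"mol{i}", 1.0, i % 4) for i in range(100)]
        with pytest.warns(UserWarning, match="threshold"):
            al = build_al_set(
                scored, clustering, ensemble, ALConfig(score_threshold=37.0), seed=0
            )
        assert al.replicas == []
        assert len(al.sampled) == 5000 if len(ensemble) >= 5000 else len(ensemble)

    def test_sampled_part_duplicate_free_and_from_ensemble(self):
        ensemble, clustering = self._setup(3000, 6)
        scored = [_scored(f"mol{i}", float(10 + i % 5), i % 6) for i in range(60)]
        al = build_al_set(
            scored, clustering, ensemble,
            ALConfig(score_threshold=11.0, replica_floor=100, sampling_budget=500),
            seed=1,
        )
        assert len(al.sampled) == len(set(al.sampled)) == 500
        assert set(al.sampled) <= set(ensemble)

    def test_replica_multiset_counts(self):
        ensemble, clustering = self._setup(1000, 5)
        scored = [_scored(f"mol{i}", 20.0 if i < 3 else 0.0, i % 5) for i in range(50)]
        al = build_al_set(
            scored, clustering, ensemble,
            ALConfig(score_threshold=11.0, replica_floor=10, sampling_budget=20),
            seed=0,
        )
        mols = al.molecules()
        for smiles in al.replicas:
            assert mols.count(smiles) >= al.multiplicity  # may also be sampled

    def test_uniform_fractions_control(self):
        ensemble, clustering = self._setup(4000, 8)
        scored = [_scored(f"mol{i}", float(i % 40), i % 8) for i in range(80)]
        al = build_al_set(
            scored, clustering, ensemble,
            ALConfig(score_threshold=39.0, replica_floor=50, sampling_budget=400),
            seed=0, uniform_fractions=True,
        )
        assert all(f == pytest.approx(1 / 8) for f in al.fractions.values())
        assert all(v == 50 for v in al.allocations.values())

    def test_deterministic_under_seed(self):
        ensemble, clustering = self._setup(2000, 4)
        scored = [_scored(f"mol{i}", float(i), i % 4) for i in range(40)]
        cfg = ALConfig(score_threshold=20.0, replica_floor=100, sampling_budget=200)
        a = build_al_set(scored, clustering, ensemble, cfg, seed=5)
        b = build_al_set(scored, clustering, ensemble, cfg, seed=5)
        assert a.molecules() == b.molecules()
        assert a.allocations == b.allocations
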