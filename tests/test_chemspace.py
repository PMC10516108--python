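"""Chemical-space proxy: descriptors, one-time PCA, clustering, selection."""

import numpy as np
import pytest

from genalign.chemspace import (
    DescriptorMatrix,
    cluster,
    compute_descriptors,
    fit_projection,
    project,
    select_for_scoring,
)


def _provider_from_table(table):
    def provider(mol):
        from rdkit import Chem

        return dict(table[Chem.MolToSmiles(mol)])

    return provider


class TestComputeDescriptors:
    def test_matches_provider_oracle(self):
        table = {
            "CCO": {"a": 1.0, "b": 2.0},
            "CCN": {"a": 3.0, "b": 4.0},
            "CCC": {"a": 5.0, "b": 6.0},
        }
        m = compute_descriptors(list(table), provider=_provider_from_table(table))
        assert m.names == ["a", "b"]
        np.testing.assert_array_equal(m.values, [[1, 2], [3, 4], [5, 6]])

    def test_nonfinite_column_dropped(self):
        table = {
            "CCO": {"a": 1.0, "bad": float("nan")},
            "CCN": {"a": 2.0, "bad": 1.0},
        }
        m = compute_descriptors(list(table), provider=_provider_from_table(table))
        assert m.names == ["a"]
        assert m.dropped_columns == ["bad"]
        assert np.isfinite(m.values).all()

    def test_all_finite_provider_keeps_all_columns(self, descriptor_provider):
        m = compute_descriptors(["CCO", "c1ccccc1", "CC(=O)O"], provider=descriptor_provider)
        assert len(m.names) >= 20
        assert m.dropped_columns == []

    def test_unparsable_molecule_dropped_with_warning(self, descriptor_provider):
        with pytest.warns(UserWarning, match="failed"):
            m = compute_descriptors(["CCO", "C("], provider=descriptor_provider)
        assert m.ids == ["CCO"]
        assert m.failed_ids == ["C("]


class TestProjection:
    def test_collinear_points_have_one_component(self):
        values = np.array([[t, 2 * t] for t in np.linspace(-3, 3, 12)])
        m = DescriptorMatrix(ids=[str(i) for i in range(12)], names=["x", "y"], values=values)
        model = fit_projection(m, n_components=2, standardize=False)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_ratios_non_increasing(self, rng):
        values = rng.normal(size=(60, 8)) @ np.diag([5, 4, 3, 2, 1, 0.5, 0.2, 0.1])
        m = DescriptorMatrix(
            ids=[str(i) for i in range(60)], names=list("abcdefgh"), values=values
        )
        model = fit_projection(m, n_components=8)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()
        assert model.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_projected_variance_matches_eigenvalues(self, rng):
        values = rng.normal(size=(200, 5))
        m = DescriptorMatrix(
            ids=[str(i) for i in range(200)], names=list("abcde"), values=values
        )
        model = fit_projection(m, n_components=5, standardize=False)
        coords = project(model, m)
        np.testing.assert_allclose(
            coords.var(axis=0, ddof=1), model.explained_variance, rtol=1e-8
        )

    def test_mean_row_projects_to_origin(self, corpus_projection):
        model, matrix = corpus_projection
        mean_matrix = DescriptorMatrix(
            ids=["mean"], names=matrix.names, values=matrix.values.mean(0, keepdims=True)
        )
        np.testing.assert_allclose(project(model, mean_matrix), 0.0, atol=1e-8)

    def test_projection_deterministic_and_row_order_invariant(self, corpus_projection):
        model, matrix = corpus_projection
        coords = project(model, matrix)
        np.testing.assert_array_equal(coords, project(model, matrix))
        rev = DescriptorMatrix(
            ids=matrix.ids[::-1], names=matrix.names, values=matrix.values[::-1]
        )
        np.testing.assert_allclose(project(model, rev)[::-1], coords)

    def test_missing_column_named_in_error(self, corpus_projection):
        model, matrix = corpus_projection
        crippled = DescriptorMatrix(
            ids=matrix.ids, names=matrix.names[1:], values=matrix.values[:, 1:]
        )
        with pytest.raises(ValueError, match=matrix.names[0]):
            project(model, crippled)

    def test_too_many_components_raises(self, corpus_projection):
        _, matrix = corpus_projection
        with pytest.raises(ValueError, match="n_components"):
            fit_projection(matrix, n_components=10_000)


class TestCluster:
    def test_two_blobs_recovered(self, rng):
        a = rng.normal(loc=0.0, scale=0.3, size=(6, 2))
        b = rng.normal(loc=10.0, scale=0.3, size=(6, 2))
        coords = np.vstack([a, b])
        result = cluster(coords, k=2, n_restarts=10, seed=0)
        labels = result.labels
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_k_equals_one(self, rng):
        coords = rng.normal(size=(30, 3))
        result = cluster(coords, k=1, n_restarts=3, seed=0)
        assert result.size_variance == 0.0
        expected = ((coords - coords.mean(0)) ** 2).sum()
        assert result.inertia == pytest.approx(expected, rel=1e-6)

    def test_selection_rule_among_five_best(self, rng):
        """Chosen run has inertia <= 5th-smallest and minimal size variance there."""
        coords = rng.normal(size=(200, 4))
        result = cluster(coords, k=8, n_restarts=100, seed=11)
        inertias = result.restart_inertias
        fifth = np.sort(inertias)[4]
        assert result.inertia <= fifth + 1e-9
        # independently re-rank the five lowest-inertia restarts
        from sklearn.cluster import KMeans

        best5 = np.argsort(inertias, kind="stable")[:5]
        variances = {}
        for r in best5:
            km = KMeans(n_clusters=8, init="k-means++", n_init=1, random_state=11 + int(r))
            km.fit(coords)
            variances[int(r)] = float(np.var(np.bincount(km.labels_, minlength=8)))
        assert result.size_variance == pytest.approx(min(variances.values()))

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            cluster(rng.normal(size=(3, 2)), k=5, n_restarts=2, seed=0)

    def test_every_point_gets_one_label(self, corpus_coords):
        result = cluster(corpus_coords, k=10, n_restarts=5, seed=0)
        assert result.labels.shape == (len(corpus_coords),)
        assert set(result.labels) <= set(range(10))


class TestSelectForScoring:
    @staticmethod
    def _clustering_with_sizes(sizes, rng):
        """Synthetic clustering: well-separated 1-D blobs with given sizes."""
        coords, labels = [], []
        for label, size in enumerate(sizes):
            coords.extend(rng.normal(loc=100.0 * label, scale=0.1, size=(size, 1)))
            labels.extend([label] * size)
        coords = np.asarray(coords)
        from genalign.chemspace import Clustering

        labels = np.asarray(labels)
        return (
            Clustering(
                k=len(sizes), labels=labels, centroids=np.zeros((len(sizes), 1)),
                inertia=0.0, size_variance=0.0, n_restarts=1, chosen_run=0,
                restart_inertias=np.zeros(1),
            ),
            [f"m{i}" for i in range(len(labels))],
        )

    def test_ample_clusters_exact_total(self, rng):
        clustering, ids = self._clustering_with_sizes([15] * 100, rng)
        out = select_for_scoring(clustering, ids, per_cluster_cap=10, total=1000, seed=0)
        assert len(out) == 1000
        assert len(set(out)) == 1000
        labels = {i: l for i, l in zip(ids, clustering.labels)}
        counts = np.bincount([labels[i] for i in out], minlength=100)
        assert counts.min() >= 10  # 10 per cluster plus top-up

    def test_small_cluster_taken_whole(self, rng):
        clustering, ids = self._clustering_with_sizes([7, 50], rng)
        out = select_for_scoring(clustering, ids, per_cluster_cap=10, total=20, seed=0)
        small = [i for i, l in zip(ids, clustering.labels) if l == 0]
        assert set(small) <= set(out)

    def test_population_shortfall_warns(self, rng):
        clustering, ids = self._clustering_with_sizes([3, 4], rng)
        with pytest.warns(UserWarning, match="shortfall"):
            out = select_for_scoring(clustering, ids, per_cluster_cap=10, total=1000, seed=0)
        assert sorted(out) == sorted(ids)

    def test_topup_only_from_clusters_above_cap(self, rng):
        clustering, ids = self._clustering_with_sizes([5, 30], rng)
        out = select_for_scoring(clustering, ids, per_cluster_cap=10, total=25, seed=0)
        labels = {i: l for i, l in zip(ids, clustering.labels)}
        counts = np.bincount([labels[i] for i in out], minlength=2)
        assert counts[0] == 5  # nothing more to take from the small cluster
        assert counts[1] == 20
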