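import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonofocus import (
    ClusterAssignment,
    ExpressionMatrix,
    MarkerSet,
    log2_transform,
    modified_z,
    pca_cluster,
    select_markers,
    signature_correlation,
    simulate_expression,
)
from clonofocus.immune_signature import signature_scores


def matrix_from(values, scale="log2", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        df=pd.DataFrame(values, index=genes, columns=samples), scale_flag=scale
    )


def planted_labels_vector(truth, samples):
    return [truth["cluster_labels"][s] for s in samples]


class TestLog2Transform:
    def test_values(self):
        m = matrix_from([[0.0, 7.0], [1.0, 3.0]], scale="linear")
        out = log2_transform(m)
        assert out.scale_flag == "log2"
        np.testing.assert_allclose(out.df.values, [[0.0, 3.0], [1.0, 2.0]])

    def test_all_ones_is_fixed_point(self):
        m = matrix_from(np.ones((3, 4)), scale="linear")
        np.testing.assert_allclose(log2_transform(m).df.values, 1.0)

    def test_negative_and_double_transform_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(matrix_from([[-1.0]], scale="linear"))
        m = log2_transform(matrix_from([[1.0]], scale="linear"))
        with pytest.raises(ValueError):
            log2_transform(m)


class TestPcaCluster:
    def test_separated_groups_fully_recovered(self):
        matrix, _, truth = simulate_expression(
            n_samples=20, n_background_genes=100,
            n_markers={"T cell": 20, "microglia": 20, "macrophage": 10},
            infiltration_levels=(0.0, 5.0, 10.0), noise_sd=1.0, seed=1,
        )
        clusters = pca_cluster(matrix, k=3)
        ari = adjusted_rand_score(
            planted_labels_vector(truth, matrix.samples),
            [clusters.labels[s] for s in matrix.samples],
        )
        assert ari == pytest.approx(1.0)

    def test_high_signature_group_gets_label_k(self):
        matrix, _, truth = simulate_expression(
            n_samples=18, infiltration_levels=(0.0, 6.0, 12.0), noise_sd=0.5, seed=4,
            n_background_genes=100,
        )
        clusters = pca_cluster(matrix, k=3)
        high = [s for s, lab in truth["cluster_labels"].items() if lab == 3]
        assert all(clusters.labels[s] == 3 for s in high)

    def test_k_one_rejected(self):
        matrix, _, _ = simulate_expression(n_samples=10, n_background_genes=20, seed=0)
        with pytest.raises(ValueError):
            pca_cluster(matrix, k=1)
        with pytest.raises(ValueError):
            pca_cluster(matrix, k=11)

    def test_invariant_to_gene_and_sample_order(self):
        matrix, _, _ = simulate_expression(
            n_samples=15, n_background_genes=60, noise_sd=1.0, seed=9
        )
        clusters = pca_cluster(matrix, k=3)
        rng = np.random.default_rng(0)
        shuffled = ExpressionMatrix(
            df=matrix.df.iloc[
                rng.permutation(len(matrix.genes)), rng.permutation(len(matrix.samples))
            ],
            scale_flag="log2",
        )
        clusters2 = pca_cluster(shuffled, k=3)
        assert clusters.labels == clusters2.labels

    def test_duplicated_samples_co_cluster(self):
        matrix, _, _ = simulate_expression(
            n_samples=12, n_background_genes=40, noise_sd=0.5, seed=2
        )
        dup = matrix.df.copy()
        dup.columns = [f"{s}_dup" for s in matrix.samples]
        doubled = ExpressionMatrix(
            df=pd.concat([matrix.df, dup], axis=1), scale_flag="log2"
        )
        clusters = pca_cluster(doubled, k=3)
        for s in matrix.samples:
            assert clusters.labels[s] == clusters.labels[f"{s}_dup"]

    def test_requires_log2_scale(self):
        m = matrix_from(np.ones((5, 6)), scale="linear")
        with pytest.raises(ValueError):
            pca_cluster(m, k=2)


class TestSelectMarkers:
    def _planted(self, seed=7, n_up=50, n_null=500, n_samples=30, effect=3.0):
        rng = np.random.default_rng(seed)
        half = n_samples // 2
        values = rng.normal(5.0, 1.0, size=(n_up + n_null, n_samples))
        values[:n_up, half:] += effect  # up in the target cluster
        genes = [f"UP{i}" if i < n_up else f"NULL{i}" for i in range(n_up + n_null)]
        samples = [f"S{i}" for i in range(n_samples)]
        matrix = matrix_from(values, genes=genes, samples=samples)
        labels = {s: (2 if i >= half else 1) for i, s in enumerate(samples)}
        clusters = ClusterAssignment(labels=labels, k=2)
        return matrix, clusters

    def test_planted_up_genes_recovered(self):
        matrix, clusters = self._planted()
        hits = select_markers(matrix, clusters, target=2, alpha=1e-4)
        up_hits = [g for g in hits if g.startswith("UP")]
        false_hits = [g for g in hits if g.startswith("NULL")]
        assert len(up_hits) >= 48
        assert len(false_hits) <= 1  # expected count << 1 at alpha 1e-4

    def test_identical_expression_yields_nothing(self):
        matrix = matrix_from(np.outer(np.arange(4.0), np.ones(6)))
        labels = {s: 1 + (i % 2) for i, s in enumerate(matrix.samples)}
        clusters = ClusterAssignment(labels=labels, k=2)
        assert select_markers(matrix, clusters, target=2, alpha=1e-4) == []

    def test_alpha_one_returns_all_higher_mean_genes(self):
        matrix, clusters = self._planted(n_up=10, n_null=20)
        hits = select_markers(matrix, clusters, target=2, alpha=1.0)
        higher = (
            matrix.df[clusters.samples_in(2)].mean(axis=1)
            > matrix.df[clusters.samples_in(1)].mean(axis=1)
        )
        assert set(hits) == set(matrix.df.index[higher])

    def test_small_target_cluster_rejected(self):
        matrix, _ = self._planted(n_up=5, n_null=5)
        labels = {s: 1 for s in matrix.samples}
        labels[matrix.samples[0]] = 2
        with pytest.raises(ValueError):
            select_markers(matrix, ClusterAssignment(labels=labels, k=2), target=2)

    def test_null_false_positive_rate_within_binomial_bounds(self):
        from scipy import stats

        rng = np.random.default_rng(314)
        n_genes, n_samples, n_reps, alpha = 1000, 30, 100, 1e-4
        half = n_samples // 2
        samples = [f"S{i}" for i in range(n_samples)]
        labels = {s: (2 if i >= half else 1) for i, s in enumerate(samples)}
        clusters = ClusterAssignment(labels=labels, k=2)
        n_fp = 0
        for _ in range(n_reps):
            matrix = matrix_from(
                rng.normal(size=(n_genes, n_samples)), samples=samples,
                genes=[f"G{i}" for i in range(n_genes)],
            )
            n_fp += len(select_markers(matrix, clusters, target=2, alpha=alpha))
        # one-vs-rest with higher-mean restriction: two-sided alpha halves
        n_tests = n_genes * n_reps
        lo, hi = stats.binom.ppf([0.005, 0.995], n_tests, alpha / 2)
        assert lo <= n_fp <= hi


class TestModifiedZ:
    def test_constant_row_is_zero(self):
        z = modified_z(matrix_from(np.full((1, 5), 3.0)))
        np.testing.assert_allclose(z.values, 0.0)

    def test_hand_computation(self):
        z = modified_z(matrix_from([[1.0, 2.0, 3.0, 4.0, 100.0]]))
        assert z.values[0, -1] == pytest.approx(0.6745 * 97, abs=1e-6)
        assert z.values[0, 2] == 0.0  # the median maps to 0

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 11))
        z1 = modified_z(matrix_from(base))
        z2 = modified_z(matrix_from(3.5 * base - 2.0))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_zero_mad_falls_back_to_mean_deviation(self):
        # median 1, MAD 0, MeanAD 2/5
        row = np.array([[1.0, 1.0, 1.0, 1.0, 3.0]])
        z = modified_z(matrix_from(row))
        assert z.values[0, -1] == pytest.approx(2 / (1.253314 * 0.4), rel=1e-6)


class TestSignatureCorrelation:
    def test_affine_copy_gives_r_one(self):
        rng = np.random.default_rng(0)
        t_genes = rng.normal(5, 1, size=(10, 12))
        m_genes = 2.0 * t_genes.mean(axis=0, keepdims=True) + 1.0
        values = np.vstack([t_genes, np.tile(m_genes, (5, 1))])
        genes = [f"T{i}" for i in range(10)] + [f"M{i}" for i in range(5)]
        matrix = matrix_from(values, genes=genes)
        markers = MarkerSet(
            classes={**{f"T{i}": "T cell" for i in range(10)},
                     **{f"M{i}": "microglia" for i in range(5)}}
        )
        r, _ = signature_correlation(matrix, markers, "T cell", "microglia")
        assert r == pytest.approx(1.0)

    def test_shared_infiltration_drives_high_correlation(self):
        matrix, markers, _ = simulate_expression(
            n_samples=53, noise_sd=0.3, infiltration_levels=(0.0, 2.0, 5.0), seed=11,
        )
        r, p = signature_correlation(matrix, markers, "T cell", "microglia")
        assert r > 0.8 and p < 1e-6

    def test_independent_noise_rarely_correlates(self):
        rng = np.random.default_rng(3)
        n_ok = 0
        for _ in range(200):
            scores = rng.normal(size=(20, 53))
            matrix = matrix_from(scores, genes=[f"G{i}" for i in range(20)])
            markers = MarkerSet(
                classes={**{f"G{i}": "T cell" for i in range(10)},
                         **{f"G{i}": "microglia" for i in range(10, 20)}}
            )
            r, p = signature_correlation(matrix, markers, "T cell", "microglia")
            if abs(r) < 0.5 and p > 0.001:
                n_ok += 1
        assert n_ok >= 190  # >= 95% of replicates

    def test_missing_gene_set_rejected(self):
        matrix = matrix_from(np.ones((3, 4)), genes=["A", "B", "C"])
        markers = MarkerSet(classes={"A": "T cell", "Z": "microglia"})
        with pytest.raises(ValueError):
            signature_correlation(matrix, markers, "T cell", "microglia")

    def test_scores_are_per_sample_means(self):
        matrix = matrix_from([[1.0, 2.0], [3.0, 4.0]], genes=["A", "B"])
        markers = MarkerSet(classes={"A": "T cell", "B": "T cell"})
        scores = signature_scores(matrix, markers, "T cell")
        np.testing.assert_allclose(scores.values, [2.0, 3.0])
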