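import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matpercept import perceptual_space as ps
from matpercept.core_data import ATTRIBUTES, DomainError, ParameterError
from matpercept.perceptual_space import (
    DegeneracyError,
    pca_mean_ratings,
    polychoric_correlation,
    polychoric_pca,
    predict_all_observers,
    predict_binary_from_ratings,
    significant_attribute_counts,
    tsne_embed,
)
from matpercept.synthetic import SyntheticConfig, generate_panel


def table_from_array(data, index=None):
    return pd.DataFrame(data, columns=list(ATTRIBUTES), index=index)


class TestPCAMeanRatings:
    def test_rank_one_unstandardized(self):
        rng = np.random.default_rng(0)
        data = np.full((30, 5), 3.0)
        data[:, 0] = rng.uniform(1, 6, 30)   # all variance in see_throughness
        res = pca_mean_ratings(table_from_array(data), standardize=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert abs(res.loadings.iloc[0, 0]) == pytest.approx(1.0)

    def test_antisymmetric_pair_loadings(self):
        rng = np.random.default_rng(1)
        soft = rng.uniform(1, 6, 40)
        data = np.full((40, 5), 3.0)
        data[:, ATTRIBUTES.index("softness")] = soft
        data[:, ATTRIBUTES.index("density")] = 7 - soft
        table = table_from_array(data)
        res = pca_mean_ratings(table, standardize=False)
        l_soft = res.loadings.loc["softness", "PC1"]
        l_dens = res.loadings.loc["density", "PC1"]
        assert abs(l_soft) == pytest.approx(abs(l_dens))
        assert np.sign(l_soft) == -np.sign(l_dens)
        # oracle: eigendecomposition of the 5x5 covariance
        cov = np.cov(data, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        top = eigvecs[:, np.argmax(eigvals)]
        expected = abs(top[ATTRIBUTES.index("softness")])
        assert abs(l_soft) == pytest.approx(expected)
        assert res.explained_variance_ratio[0] == pytest.approx(
            eigvals.max() / eigvals.sum()
        )

    def test_explained_variance_sums_to_one(self, small_panels):
        color, _ = small_panels
        res = pca_mean_ratings(color.mean_ratings())
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_zero_variance_attribute_rejected(self):
        data = np.random.default_rng(2).uniform(1, 6, (20, 5))
        data[:, 3] = 2.0
        with pytest.raises(DegeneracyError, match="glow"):
            pca_mean_ratings(table_from_array(data), standardize=True)

    def test_affine_rescale_invariance(self, small_panels):
        color, _ = small_panels
        table = color.mean_ratings()
        rescaled = table * [2.0, 0.5, 3.0, 1.5, 0.25] + [1, -2, 0, 5, 3]
        a = pca_mean_ratings(table, standardize=True)
        b = pca_mean_ratings(rescaled, standardize=True)
        np.testing.assert_allclose(
            a.explained_variance_ratio, b.explained_variance_ratio, atol=1e-10
        )
        np.testing.assert_allclose(
            a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-8
        )

    def test_loading_geometry_on_synthetic(self):
        """Light-transmission centroid vs softness/density centroid > 60 deg."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SyntheticConfig(n_images=80, n_observers_binary=10,
                                  n_observers_category=6, seed=seed)
            color, _ = generate_panel(cfg)
            res = pca_mean_ratings(color.mean_ratings())
            two = res.loadings[["PC1", "PC2"]]
            trans = two.loc[["see_throughness", "glow", "glossiness"]].mean().to_numpy()
            # softness and density are anti-correlated, so the direction they
            # span is their difference, not their (near-cancelling) centroid
            span = two.loc["softness"].to_numpy() - two.loc["density"].to_numpy()
            cosine = trans @ span / (np.linalg.norm(trans) * np.linalg.norm(span))
            angle = np.degrees(np.arccos(np.clip(abs(cosine), 0, 1)))
            hits += angle > 60
        assert hits >= 0.9 * n_seeds


class TestPolychoric:
    @staticmethod
    def _discretize(z, thresholds=(-1.0, -0.3, 0.3, 1.0, 1.7)):
        return np.searchsorted(np.asarray(thresholds), z) + 1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        latent = rng.multivariate_normal([0, 0], cov, size=500)
        x = self._discretize(latent[:, 0])
        y = self._discretize(latent[:, 1])
        est = polychoric_correlation(x, y)
        assert abs(est - rho) < 0.1

    def test_identical_columns_unit(self):
        x = np.array([1, 2, 3, 2, 1, 3, 2, 2, 1, 3])
        assert polychoric_correlation(x, x) == 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            x = self._discretize(rng.standard_normal(500))
            y = self._discretize(rng.standard_normal(500))
            hits += abs(polychoric_correlation(x, y)) < 0.15
        assert hits >= 0.95 * n_rep

    def test_single_level_rejected(self):
        with pytest.raises(DegeneracyError):
            polychoric_correlation(np.ones(20), np.arange(20) % 3)

    def test_pca_identical_columns_share_pc1(self):
        rng = np.random.default_rng(4)
        base = self._discretize(rng.standard_normal(100))
        table = pd.DataFrame(
            {a: (base if a in ("glow", "glossiness") else
                 self._discretize(rng.standard_normal(100)))
             for a in ATTRIBUTES}
        )
        res = polychoric_pca(table)
        l1 = res.loadings.loc["glow", "PC1"]
        l2 = res.loadings.loc["glossiness", "PC1"]
        assert l1 == pytest.approx(l2, abs=1e-6)
        assert abs(l1) > 0.3

    def test_pca_on_observer_slice(self, small_panels):
        color, _ = small_panels
        table, _ = color.observer_slice(color.observers[0])
        res = polychoric_pca(table)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert res.loadings.shape[0] == 5

    def test_too_few_images(self):
        table = pd.DataFrame({a: [1, 2] for a in ATTRIBUTES})
        with pytest.raises(DomainError):
            polychoric_pca(table)


class TestPrediction:
    def _deterministic_slice(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        ratings = pd.DataFrame(
            {a: rng.integers(1, 7, n) for a in ATTRIBUTES},
            index=[f"i{k}" for k in range(n)],
        )
        labels = (ratings["see_throughness"] >= 4).astype(int)
        return ratings, labels

    def test_separable_rule_perfect_accuracy(self):
        ratings, labels = self._deterministic_slice()
        res = predict_binary_from_ratings(ratings, labels, "obs", "color", seed=0)
        assert res.mean_accuracy == 1.0
        assert all(
            "see_throughness" in s for s in res.significant_attributes_per_fold
        )
        # the rule is separable, so folds fall back to the ridge fit
        assert not all(res.wald_reliable)

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(100):
            ratings = pd.DataFrame(
                {a: rng.integers(1, 7, 60) for a in ATTRIBUTES},
                index=[f"i{k}" for k in range(60)],
            )
            labels = pd.Series(rng.integers(0, 2, 60), index=ratings.index)
            if labels.nunique() < 2:
                continue
            res = predict_binary_from_ratings(ratings, labels, "obs", "color", seed=0)
            accs.append(res.mean_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_fold_accuracies_bounded_and_partition(self):
        ratings, labels = self._deterministic_slice(seed=5)
        res = predict_binary_from_ratings(ratings, labels, "obs", "color", seed=1)
        assert len(res.fold_accuracies) == 3
        assert all(0.0 <= a <= 1.0 for a in res.fold_accuracies)

    def test_single_class_observer_rejected(self):
        ratings, _ = self._deterministic_slice(seed=6)
        labels = pd.Series(1, index=ratings.index)
        with pytest.raises(DegeneracyError):
            predict_binary_from_ratings(ratings, labels, "obs", "color")

    def test_too_few_images_rejected(self):
        ratings, labels = self._deterministic_slice(n=20, seed=7)
        with pytest.raises(DomainError):
            predict_binary_from_ratings(ratings, labels, "obs", "color")

    def test_predict_all_skips_degenerate(self, small_panels):
        color, _ = small_panels
        results, skipped = predict_all_observers(color, seed=0)
        assert len(results) + len(skipped) == color.n_observers

    def test_accuracy_high_on_synthetic(self, default_panels):
        color, _ = default_panels
        results, _ = predict_all_observers(color, seed=0)
        accs = np.array([r.mean_accuracy for r in results])
        assert np.mean(accs > 0.7) >= 0.8


class TestSignificantAttributeCounts:
    def _result(self, sig_per_fold):
        return ps.PredictionResult(
            "o", "color", (1.0, 1.0, 1.0),
            tuple(frozenset(s) for s in sig_per_fold),
            (pd.Series(dtype=float),) * 3, (True, True, True), 0,
        )

    def test_all_observers_every_fold(self):
        results = [self._result([{"see_throughness"}] * 3) for _ in range(20)]
        counts = significant_attribute_counts(results)
        assert counts["see_throughness"]["median"] == 20
        assert counts["see_throughness"]["range"] == 0

    def test_never_significant(self):
        results = [self._result([set()] * 3) for _ in range(5)]
        assert significant_attribute_counts(results)["glow"]["median"] == 0

    def test_median_invariant_to_fold_order(self):
        base = [{"glow"}, {"glow", "softness"}, set()]
        a = significant_attribute_counts([self._result(base)] * 4)
        b = significant_attribute_counts([self._result(base[::-1])] * 4)
        assert a["glow"]["median"] == b["glow"]["median"]


class TestTSNE:
    def _clusters(self, rng, n_per=60, delta=3.0, sigma=0.3):
        low = rng.normal(2.0, sigma, (n_per, 5))
        high = rng.normal(2.0 + delta, sigma, (n_per, 5))
        data = np.clip(np.vstack([low, high]), 1, 6)
        return pd.DataFrame(data, columns=list(ATTRIBUTES))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        table = self._clusters(rng)
        a = tsne_embed(table, seed=3)
        b = tsne_embed(table, seed=3)
        np.testing.assert_array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())

    def test_separated_clusters_silhouette(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        table = self._clusters(rng)
        emb = tsne_embed(table, seed=0)
        labels = np.repeat([0, 1], 60)
        assert silhouette_score(emb.coordinates.to_numpy(), labels) > 0.5

    def test_duplicated_points_near_coincident(self):
        rng = np.random.default_rng(10)
        table = self._clusters(rng)
        table.iloc[1] = table.iloc[0]   # exact duplicate
        emb = tsne_embed(table, seed=0)
        coords = emb.coordinates.to_numpy()
        dup_dist = np.linalg.norm(coords[0] - coords[1])
        spread = np.linalg.norm(coords[:60] - coords[:60].mean(axis=0), axis=1).mean()
        assert dup_dist < spread

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame(np.ones((10, 5)), columns=list(ATTRIBUTES))
        with pytest.raises(ParameterError):
            tsne_embed(table, perplexity=15)
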