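"""Tests of the (log10 D, α) Gaussian-mixture population model and the
BIC/AIC model-selection rule."""

import numpy as np
import pandas as pd
import pytest

from sptfcs import populations


def make_estimates(d, alpha, mobility="mobile"):
    n = len(d)
    return pd.DataFrame(
        {
            "track_id": np.arange(n),
            "n_detections": 20,
            "d60": d,
            "d_alpha": d,
            "alpha": alpha,
            "mobility_class": mobility if isinstance(mobility, (list, np.ndarray)) else [mobility] * n,
        }
    )


def gaussian_cloud(rng, center, sd, n):
    return rng.normal(center, sd, size=(n, 2))


class TestFeatureTable:
    def test_log_transform(self):
        tab = populations.build_feature_table(make_estimates([1.0, 10.0], [1.0, 0.5]))
        assert np.allclose(tab.values[:, 0], [0.0, 1.0])

    def test_exclusions_counted(self):
        est = make_estimates([1.0, 0.0, -0.5, np.nan, 2.0], [1.0] * 5)
        tab = populations.build_feature_table(est)
        assert len(tab) == 2 and tab.n_excluded == 3

    def test_immobile_excluded_separately(self):
        est = make_estimates([1.0, 2e-3, 2.0], [1.0] * 3, mobility=["mobile", "immobile", "mobile"])
        tab = populations.build_feature_table(est)
        assert len(tab) == 2 and tab.n_immobile == 1

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            populations.build_feature_table(make_estimates([0.0, -1.0], [1.0, 1.0]))


class TestGMMFit:
    def test_k1_closed_form(self, rng):
        x = gaussian_cloud(rng, [0.0, 1.0], [0.3, 0.2], 300)
        tab = populations.FeatureTable(
            table=pd.DataFrame({"track_id": np.arange(300), "log10_d": x[:, 0], "alpha": x[:, 1]}),
            n_excluded=0,
            n_immobile=0,
        )
        model = populations.fit_gmm_k(tab, 1, seed=0)
        assert np.allclose(model.means[0], x.mean(axis=0), atol=1e-8)
        assert np.allclose(model.covariances[0], np.cov(x.T, bias=True), atol=1e-6)
        assert model.weights[0] == pytest.approx(1.0)

    def _table(self, x):
        return populations.FeatureTable(
            table=pd.DataFrame(
                {"track_id": np.arange(len(x)), "log10_d": x[:, 0], "alpha": x[:, 1]}
            ),
            n_excluded=0,
            n_immobile=0,
        )

    def test_separated_clusters_recovered(self, rng):
        x = np.vstack(
            [gaussian_cloud(rng, [0.0, 1.0], [0.1, 0.1], 300), gaussian_cloud(rng, [1.0, 0.3], [0.1, 0.1], 300)]
        )
        model = populations.fit_gmm_k(self._table(x), 2, seed=1)
        means = model.means[np.argsort(model.means[:, 0])]
        assert np.allclose(means[0], [0.0, 1.0], atol=0.05)
        assert np.allclose(means[1], [1.0, 0.3], atol=0.05)
        assert np.allclose(model.weights, 0.5, atol=0.05)
        assert np.allclose(model.assigned_fractions.sum(), 1.0)

    def test_determinism(self, rng):
        x = gaussian_cloud(rng, [0.0, 1.0], [0.5, 0.3], 200)
        a = populations.fit_gmm_k(self._table(x), 3, seed=42)
        b = populations.fit_gmm_k(self._table(x), 3, seed=42)
        assert np.array_equal(a.weights, b.weights) and np.array_equal(a.means, b.means)

    def test_insufficient_rows_rejected(self, rng):
        x = gaussian_cloud(rng, [0, 1], [0.1, 0.1], 9)
        with pytest.raises(ValueError):
            populations.fit_gmm_k(self._table(x), 2, seed=0)

    def test_log_likelihood_nondecreasing_in_k(self, rng):
        x = np.vstack(
            [gaussian_cloud(rng, [0.0, 1.0], [0.2, 0.2], 200), gaussian_cloud(rng, [1.2, 0.4], [0.2, 0.2], 200)]
        )
        tab = self._table(x)
        lls = [populations.fit_gmm_k(tab, k, seed=3).log_likelihood for k in range(1, 6)]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))


class TestModelSelection:
    def _table(self, x):
        return populations.FeatureTable(
            table=pd.DataFrame(
                {"track_id": np.arange(len(x)), "log10_d": x[:, 0], "alpha": x[:, 1]}
            ),
            n_excluded=0,
            n_immobile=0,
        )

    def test_single_cloud_selects_one(self, rng):
        x = gaussian_cloud(rng, [0.0, 0.9], [0.2, 0.3], 400)
        curve = populations.model_selection_curves(self._table(x), k_max=6, seed=0)
        assert curve.selected_k == 1

    def test_two_clusters_select_two(self, rng):
        x = np.vstack(
            [gaussian_cloud(rng, [0.1, 0.9], [0.15, 0.3], 400), gaussian_cloud(rng, [0.55, 0.9], [0.15, 0.3], 400)]
        )
        curve = populations.model_selection_curves(self._table(x), k_max=8, seed=0)
        assert curve.selected_k == 2

    def test_k_capped_by_sample_size(self, rng):
        x = gaussian_cloud(rng, [0, 1], [0.1, 0.1], 30)
        curve = populations.model_selection_curves(self._table(x), k_max=10, seed=0)
        assert curve.k_values.max() <= 6


class TestComponentMerging:
    def _model(self, means, covs, weights):
        k = len(weights)
        return populations.MixtureModel(
            k=k,
            weights=np.array(weights),
            means=np.array(means, dtype=float),
            covariances=np.array(covs, dtype=float),
            bic=0.0,
            aic=0.0,
            log_likelihood=0.0,
            seed=0,
            converged=True,
        )

    def test_concentric_components_count_as_one(self):
        # a narrow and a wide component sharing a center describe one
        # heavy-tailed population, not substructure
        model = self._model(
            [[0.0, 0.9], [0.05, 0.85]],
            [np.eye(2) * 0.01, np.eye(2) * 0.09],
            [0.7, 0.3],
        )
        groups = populations._distinguishable_groups(model)
        assert groups == [[0, 1]]

    def test_separated_components_stay_distinct(self):
        model = self._model(
            [[0.0, 0.9], [0.6, 0.9]],
            [np.eye(2) * 0.02, np.eye(2) * 0.02],
            [0.5, 0.5],
        )
        groups = populations._distinguishable_groups(model)
        assert sorted(map(tuple, groups)) == [(0,), (1,)]

    def test_merge_preserves_mixture_moments(self):
        model = self._model(
            [[0.0, 1.0], [0.2, 0.8]],
            [np.eye(2) * 0.04, np.eye(2) * 0.09],
            [0.6, 0.4],
        )
        merged = populations.merge_components(model, [[0, 1]])
        assert merged.k == 1
        assert merged.weights[0] == pytest.approx(1.0)
        expect_mean = 0.6 * model.means[0] + 0.4 * model.means[1]
        assert np.allclose(merged.means[0], expect_mean)
        # total second moment preserved
        second = sum(
            w * (c + np.outer(m, m))
            for w, m, c in zip(model.weights, model.means, model.covariances)
        )
        assert np.allclose(
            merged.covariances[0] + np.outer(merged.means[0], merged.means[0]), second
        )


class TestSummaries:
    def test_back_transform(self):
        model = populations.MixtureModel(
            k=1,
            weights=np.array([1.0]),
            means=np.array([[-1.7, 0.31]]),
            covariances=np.array([[[0.04, 0.0], [0.0, 0.01]]]),
            bic=0.0,
            aic=0.0,
            log_likelihood=0.0,
            seed=0,
            converged=True,
        )
        s = populations.summarize_populations(model)
        assert s.loc[0, "d_center"] == pytest.approx(10**-1.7)
        assert s.loc[0, "alpha_center"] == pytest.approx(0.31)
        assert s.loc[0, "weight"] == 1.0

    def test_sorted_by_weight(self):
        model = populations.MixtureModel(
            k=2,
            weights=np.array([0.2, 0.8]),
            means=np.array([[0.0, 1.0], [1.0, 0.5]]),
            covariances=np.tile(np.eye(2) * 0.01, (2, 1, 1)),
            bic=0.0,
            aic=0.0,
            log_likelihood=0.0,
            seed=0,
            converged=True,
        )
        s = populations.summarize_populations(model)
        assert list(s["weight"]) == [0.8, 0.2]


class TestPDFGrid:
    def _model(self):
        return populations.MixtureModel(
            k=2,
            weights=np.array([0.4, 0.6]),
            means=np.array([[0.0, 1.0], [1.0, 0.4]]),
            covariances=np.array([[[0.04, 0.01], [0.01, 0.09]], [[0.09, 0.0], [0.0, 0.04]]]),
            bic=0.0,
            aic=0.0,
            log_likelihood=0.0,
            seed=0,
            converged=True,
        )

    def test_normalization(self):
        model = self._model()
        gx, gy, dens = populations.population_pdf_grid(model, ((-2, 3), (-1.5, 2.5)), resolution=220)
        integral = np.trapezoid(np.trapezoid(dens, gy, axis=1), gx)
        assert 0.99 <= integral <= 1.0 + 1e-6

    def test_density_peaks_at_component_means(self):
        model = self._model()
        gx, gy, dens = populations.population_pdf_grid(model, ((-2, 3), (-1.5, 2.5)), resolution=200)
        ix = np.argmin(np.abs(gx - 0.0))
        iy = np.argmin(np.abs(gy - 1.0))
        ix_far = np.argmin(np.abs(gx - 0.0))
        iy_far = np.argmin(np.abs(gy - (1.0 + 3 * 0.3)))
        assert dens[ix, iy] >= dens[ix_far, iy_far]

    def test_matches_pointwise_oracle(self):
        model = self._model()
        gx, gy, dens = populations.population_pdf_grid(model, ((-1, 2), (-1, 2)), resolution=40)
        # hand-written bivariate normal mixture evaluation
        def pdf(pt):
            total = 0.0
            for w, mu, cov in zip(model.weights, model.means, model.covariances):
                diff = pt - mu
                inv = np.linalg.inv(cov)
                norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(cov)))
                total += w * norm * np.exp(-0.5 * diff @ inv @ diff)
            return total

        for i in (0, 13, 39):
            for j in (0, 21, 39):
                assert dens[i, j] == pytest.approx(pdf(np.array([gx[i], gy[j]])), rel=1e-10)
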