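"""Pair mixtures, Mahalanobis edge weights and the baseline model."""

import numpy as np
import pandas as pd
import pytest

from parenclitic import (BaselineModel, BetaMatrix, GMMSettings,
                         SyntheticConfig, ValidationError, edge_weight,
                         fit_baseline, fit_pair_gmm, generate_dataset,
                         mahalanobis_to_component, top_variant_loci)
from parenclitic.gmm import PairGMM
from conftest import random_pair_gmm
from oracles import edge_weight_bruteforce


class TestMahalanobis:
    def test_point_at_mean_is_zero(self):
        cov = np.array([[0.02, 0.0], [0.0, 0.02]])
        assert mahalanobis_to_component((0.3, 0.7), (0.3, 0.7), cov) == 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        d = mahalanobis_to_component((0.9, 0.9), (0.1, 0.1), np.eye(2))
        assert d == pytest.approx(0.8 * np.sqrt(2), abs=1e-12)

    def test_diagonal_covariance_closed_form(self):
        cov = np.diag([0.04, 0.04])
        d = mahalanobis_to_component((0.1, 0.3), (0.1, 0.1), cov)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValidationError, match="positive definite"):
            mahalanobis_to_component((0, 0), (1, 1), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            mahalanobis_to_component((0, 0), (1, 1), np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestEdgeWeight:
    def test_min_over_two_components(self):
        model = PairGMM(pair=(0, 1), weights=np.array([0.5, 0.5]),
                        means=np.array([[0.1, 0.1], [0.9, 0.9]]),
                        covariances=np.stack([np.diag([0.04, 0.04]),
                                              np.diag([0.01, 0.01])]),
                        bic={}, converged={})
        assert edge_weight((0.1, 0.3), model) == pytest.approx(1.0, abs=1e-12)

    def test_zero_at_any_component_mean(self, rng):
        model = random_pair_gmm(rng)
        for k in range(model.n_components):
            assert edge_weight(tuple(model.means[k]), model) == pytest.approx(0.0, abs=1e-12)

    def test_min_property_against_each_component(self, rng):
        for _ in range(50):
            model = random_pair_gmm(rng)
            point = rng.uniform(0, 1, size=2)
            w = edge_weight(point, model)
            for k in range(model.n_components):
                assert w <= mahalanobis_to_component(
                    point, model.means[k], model.covariances[k]) + 1e-12

    def test_axis_swap_invariance(self, rng):
        for _ in range(20):
            model = random_pair_gmm(rng)
            swapped = PairGMM(
                pair=model.pair, weights=model.weights,
                means=model.means[:, ::-1],
                covariances=model.covariances[:, ::-1, :][:, :, ::-1],
                bic={}, converged={})
            point = rng.uniform(0, 1, size=2)
            assert edge_weight(point, model) == pytest.approx(
                edge_weight(point[::-1], swapped), abs=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            model = random_pair_gmm(rng)
            point = rng.uniform(-0.2, 1.2, size=2)
            assert edge_weight(point, model) == pytest.approx(
                edge_weight_bruteforce(point, model.means, model.covariances),
                abs=1e-10)


class TestFitPairGMM:
    def test_two_well_separated_clusters_recovered(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(500 + seed)
            pts = np.vstack([r.normal(0.1, 0.1, size=(70, 2)),
                             r.normal(0.9, 0.1, size=(71, 2))])
            g = fit_pair_gmm(pts, seed=seed)
            if g.n_components == 2:
                m = g.means[np.argsort(g.means[:, 0])]
                if (np.abs(m[0] - 0.1).max() < 0.05
                        and np.abs(m[1] - 0.9).max() < 0.05):
                    hits += 1
        assert hits >= 18

    def test_single_gaussian_selects_one_component(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(700 + seed)
            g = fit_pair_gmm(r.normal(0.5, 0.1, size=(141, 2)), seed=seed)
            hits += g.n_components == 1
        assert hits >= 18

    def test_constant_points_degenerate_contract(self):
        g = fit_pair_gmm(np.tile([[0.2, 0.8]], (12, 1)), seed=0,
                         covariance_floor=1e-6)
        assert g.n_components == 1
        assert np.allclose(g.means[0], [0.2, 0.8])
        assert np.allclose(g.covariances[0], 1e-6 * np.eye(2))

    def test_bic_never_selects_unconverged_count(self, rng):
        pts = rng.uniform(size=(30, 2))
        g = fit_pair_gmm(pts, seed=1)
        assert g.converged[g.n_components]
        assert g.n_components <= 4

    def test_too_few_points_caps_component_count(self, caplog):
        import logging

        pts = np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]])
        with caplog.at_level(logging.WARNING):
            g = fit_pair_gmm(pts, max_components=4, seed=0)
        assert max(g.bic) == 3  # only counts 1..3 attempted
        assert any("capped" in r.message for r in caplog.records)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValidationError, match="2 points"):
            fit_pair_gmm(np.array([[0.5, 0.5]]))

    def test_matches_sklearn_reference_likelihood(self):
        """Independent cross-check: on well-separated data, the selected
        fit's likelihood and means agree with sklearn's EM."""
        from sklearn.mixture import GaussianMixture

        r = np.random.default_rng(42)
        pts = np.vstack([r.normal(0.15, 0.05, size=(70, 2)),
                         r.normal(0.85, 0.05, size=(71, 2))])
        ours = fit_pair_gmm(pts, seed=0)
        ref = GaussianMixture(n_components=2, n_init=3, random_state=0,
                              reg_covar=1e-6).fit(pts)
        assert ours.n_components == 2
        ours_ll = ref.score_samples(pts).mean()  # reference scale
        ours_means = ours.means[np.argsort(ours.means[:, 0])]
        ref_means = ref.means_[np.argsort(ref.means_[:, 0])]
        assert np.abs(ours_means - ref_means).max() < 0.01
        # our mean per-point log-likelihood is within 1% of sklearn's optimum
        from parenclitic.gmm import _log_gauss

        lp = _log_gauss(pts[None], ours.means[None], ours.covariances[None])[0]
        mix = lp + np.log(ours.weights)[None, :]
        ll = np.logaddexp.reduce(mix, axis=1).mean()
        assert ll >= ours_ll - abs(ours_ll) * 0.01


@pytest.fixture(scope="module")
def small_fit():
    cfg = SyntheticConfig(n_baseline=60, n_train_pos=5, n_train_neg=5,
                          n_eval_pos=5, n_eval_neg=5, n_loci=10,
                          n_planted=4, seed=21)
    beta, _, phen, truth = generate_dataset(cfg)
    modeling = phen.index[phen["cohort"] == "modeling"].tolist()
    panel = top_variant_loci(beta, 10)
    model = fit_baseline(beta.select_samples(modeling), panel, master_seed=5)
    return beta, phen, truth, panel, model


class TestFitBaseline:
    def test_all_pairs_fitted(self, small_fit):
        *_, model = small_fit
        assert model.n_pairs == 45
        assert np.all(model.n_components >= 1)
        assert np.all(model.n_components <= 4)

    def test_chunking_does_not_change_results(self, small_fit):
        beta, phen, _, panel, model = small_fit
        modeling = phen.index[phen["cohort"] == "modeling"].tolist()
        odd = fit_baseline(beta.select_samples(modeling), panel,
                           settings=GMMSettings(chunk_size=7), master_seed=5)
        assert np.array_equal(model.n_components, odd.n_components)
        assert np.array_equal(model.means, odd.means, equal_nan=True)
        assert np.array_equal(model.covariances, odd.covariances, equal_nan=True)

    def test_serialization_round_trip(self, small_fit, tmp_path):
        *_, model = small_fit
        path = tmp_path / "baseline.bin"
        model.save(path)
        back = BaselineModel.load(path)
        assert back.panel.loci == model.panel.loci
        assert np.array_equal(back.n_components, model.n_components)
        assert np.array_equal(back.means, model.means, equal_nan=True)
        assert np.array_equal(back.covariances, model.covariances, equal_nan=True)
        assert back.master_seed == model.master_seed

    def test_save_is_byte_deterministic(self, small_fit, tmp_path):
        *_, model = small_fit
        model.save(tmp_path / "a.bin")
        model.save(tmp_path / "b.bin")
        assert (tmp_path / "a.bin").read_bytes() == (tmp_path / "b.bin").read_bytes()

    def test_vectorised_edge_weights_match_per_pair(self, small_fit, rng):
        *_, model = small_fit
        loci = list(model.panel.loci)
        for _ in range(5):
            sample = rng.uniform(size=len(loci))
            fast = model.edge_weights(sample)
            p = 0
            for i in range(len(loci)):
                for j in range(i + 1, len(loci)):
                    g = model.get_pair(loci[i], loci[j])
                    assert fast[p] == pytest.approx(
                        edge_weight((sample[i], sample[j]), g), abs=1e-10)
                    p += 1

    def test_missing_values_rejected(self, small_fit):
        beta, phen, _, panel, _ = small_fit
        frame = beta.frame.copy()
        frame.iloc[0, 0] = np.nan
        modeling = phen.index[phen["cohort"] == "modeling"].tolist()
        with pytest.raises(ValidationError, match="missing"):
            fit_baseline(BetaMatrix(frame[modeling]), panel, master_seed=5)

    def test_correlated_planted_pairs_get_two_components(self):
        """Pairs of planted loci sharing a latent methylation state form two
        joint clusters in the baseline cohort; the fitted mixtures should
        select exactly two components for nearly all of them."""
        cfg = SyntheticConfig(n_baseline=141, n_train_pos=8, n_train_neg=8,
                              n_eval_pos=6, n_eval_neg=6, n_loci=40,
                              n_planted=20, seed=31)
        beta, _, phen, truth = generate_dataset(cfg)
        modeling = phen.index[phen["cohort"] == "modeling"].tolist()
        panel = top_variant_loci(beta.select_samples(modeling), 40)
        model = fit_baseline(beta.select_samples(modeling), panel, master_seed=7)
        two_cluster_pairs = [b for b in truth.blocks if len(b) == 2]
        hits = sum(model.get_pair(a, b).n_components == 2
                   for a, b in two_cluster_pairs)
        assert hits >= 0.9 * len(two_cluster_pairs)
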