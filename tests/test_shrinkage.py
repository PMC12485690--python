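"""Mash-lite: canonical/data-driven covariances, EM fit, posteriors, LFSR."""

import numpy as np
import pandas as pd
import pytest

import gliastate as gs
from gliastate.shrinkage import chord_knee


class TestCanonicalCovariances:
    def test_r1_dedup_keeps_identity_and_ones(self):
        comps = gs.canonical_covariances(1)
        assert [c.name for c in comps] == ["identity", "equal_effects"]

    def test_r3_singletons_have_one_nonzero(self):
        comps = {c.name: c for c in gs.canonical_covariances(3)}
        for r in range(3):
            m = comps[f"singleton_{r}"].matrix
            assert np.count_nonzero(m) == 1 and m[r, r] == 1.0

    def test_all_psd(self):
        for c in gs.canonical_covariances(4):
            assert np.linalg.eigvalsh(c.matrix).min() >= -1e-10

    def test_r0_rejected(self):
        with pytest.raises(ValueError):
            gs.canonical_covariances(0)


class TestScaleGrid:
    def test_endpoints_by_formula(self):
        tab = gs.EffectTable(bhat=[[2.0, -1.0]], shat=[[1.0, 2.0]])
        grid = gs.scale_grid(tab)
        assert grid.sds[0] == pytest.approx(0.1)
        assert grid.sds[-1] >= 4.0 and grid.sds[-1] < 4.0 * np.sqrt(2)

    def test_strictly_increasing(self):
        tab = gs.EffectTable(bhat=[[3.0, 0.5]], shat=[[0.7, 1.1]])
        assert np.all(np.diff(gs.scale_grid(tab).sds) > 0)

    def test_scale_equivariance(self):
        tab = gs.EffectTable(bhat=[[2.0, -1.0]], shat=[[1.0, 2.0]])
        tab2 = gs.EffectTable(bhat=[[4.0, -2.0]], shat=[[2.0, 4.0]])
        g1, g2 = gs.scale_grid(tab), gs.scale_grid(tab2)
        assert g2.sds[0] == pytest.approx(2 * g1.sds[0])
        assert g2.sds[-1] == pytest.approx(2 * g1.sds[-1])

    def test_all_zero_effects(self):
        tab = gs.EffectTable(bhat=[[0.0, 0.0]], shat=[[1.0, 1.0]])
        assert len(gs.scale_grid(tab).sds) == 0


class TestFitMixture:
    def test_single_feature_single_component_pi_one(self):
        tab = gs.EffectTable(bhat=[[1.0]], shat=[[1.0]])
        comps = [gs.CovarianceComponent("identity", np.eye(1))]
        grid = gs.ScaleGrid(sds=np.array([1.0]))
        fit = gs.fit_mixture(tab, comps, grid)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-8)

    def test_loglik_monotone(self):
        tab, _ = gs.simulate_effect_table(
            3, 300, [(np.zeros((3, 3)), 0.5), (np.ones((3, 3)), 0.5)], seed=1
        )
        fit = gs.fit_mixture(tab, gs.canonical_covariances(3), max_iter=200)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-7 * np.abs(fit.loglik_trace[:-1]))

    def test_pure_null_mass_on_null_and_small_scales(self):
        rng = np.random.default_rng(2)
        tab = gs.EffectTable(bhat=rng.normal(0, 1, (1500, 3)), shat=np.ones((1500, 3)))
        fit = gs.fit_mixture(tab, gs.canonical_covariances(3))
        summ = gs.mixture_summary(fit, null_sd=0.5)
        assert summ["null"] > 0.95

    def test_shrinkage_to_zero_under_null_mass(self):
        tab = gs.EffectTable(bhat=[[0.5, -0.5]], shat=[[1.0, 1.0]])
        comps = [gs.CovarianceComponent("identity", np.eye(2))]
        grid = gs.ScaleGrid(sds=np.array([1.0]))
        fit = gs.fit_mixture(tab, comps, grid)
        fit.pi = np.array([1.0, 0.0])  # all mass on the null point mass
        mean, sd, lfsr = gs.posterior_lfsr(tab, fit)
        assert np.allclose(mean, 0.0) and np.allclose(lfsr, 1.0)


class TestPosteriorLfsr:
    def test_overwhelming_signal_tiny_lfsr(self):
        tab = gs.EffectTable(bhat=[[10.0]], shat=[[0.1]])
        comps = [gs.CovarianceComponent("identity", np.eye(1))]
        grid = gs.ScaleGrid(sds=np.array([1.0]))
        fit = gs.fit_mixture(tab, comps, grid)
        _, _, lfsr = gs.posterior_lfsr(tab, fit)
        assert lfsr[0, 0] < 1e-6

    def test_posterior_matches_quadrature_oracle(self):
        """R=2 mixture posterior vs an independent oracle: Gauss-Hermite
        quadrature in the latent coordinates b = A s for the moments, and the
        latent-Gaussian closed form (posterior precision I + A'V^-1 A) for
        the sign probabilities."""
        from oracles import posterior_oracle

        bhat = np.array([[1.3, -0.4]])
        shat = np.array([[0.8, 1.2]])
        tab = gs.EffectTable(bhat=bhat, shat=shat)
        comps = [
            gs.CovarianceComponent("identity", np.eye(2)),
            gs.CovarianceComponent("equal_effects", np.ones((2, 2))),
        ]
        grid = gs.ScaleGrid(sds=np.array([0.5, 1.0, 2.0]))
        fit = gs.fit_mixture(tab, comps, grid)
        mean, sd, lfsr = gs.posterior_lfsr(tab, fit)
        o_mean, o_sd, o_lfsr = posterior_oracle(bhat[0], shat[0], fit)
        np.testing.assert_allclose(mean[0], o_mean, atol=1e-6)
        np.testing.assert_allclose(sd[0], o_sd, atol=1e-6)
        np.testing.assert_allclose(lfsr[0], o_lfsr, atol=1e-6)


class TestStrongSubset:
    def test_huge_z_selected(self):
        rng = np.random.default_rng(3)
        bhat = rng.normal(0, 1, (200, 2))
        bhat[0, 0] = 20.0
        tab = gs.EffectTable(bhat=bhat, shat=np.ones((200, 2)))
        idx, _ = gs.strong_subset(tab, 1e-4)
        assert 0 in idx

    def test_vacuous_threshold_selects_all(self):
        rng = np.random.default_rng(4)
        tab = gs.EffectTable(bhat=rng.normal(0, 1, (50, 2)), shat=np.ones((50, 2)))
        idx, _ = gs.strong_subset(tab, 1.0)
        assert len(idx) == 50

    def test_all_null_passes_none_at_stringent_threshold(self):
        rng = np.random.default_rng(5)
        tab = gs.EffectTable(bhat=rng.normal(0, 1, (500, 2)), shat=np.ones((500, 2)))
        idx, _ = gs.strong_subset(tab, 1e-4)
        assert len(idx) <= 2


class TestDataDriven:
    def test_rank1_structure_recovered(self):
        rng = np.random.default_rng(6)
        v = np.array([1.0, 1.0, -1.0])
        v = v / np.linalg.norm(v)
        a = rng.normal(0, 3, 300)
        B = np.outer(a, v) + rng.normal(0, 0.01, (300, 3))
        tab = gs.EffectTable(bhat=B, shat=np.full((300, 3), 0.01))
        comps = gs.data_driven_covariances(tab)
        lead = comps[0].matrix
        w, Q = np.linalg.eigh(lead)
        cos = abs(Q[:, -1] @ v)
        assert cos > 0.99

    def test_ed_loglik_monotone(self):
        rng = np.random.default_rng(7)
        B = rng.normal(0, 1, (100, 3))
        _, _, trace = gs.extreme_deconvolution(
            B, np.ones((100, 3)), [np.eye(3), np.ones((3, 3)) / 3]
        )
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_small_variance_pc_excluded(self):
        rng = np.random.default_rng(8)
        B = np.column_stack(
            [rng.normal(0, 10, 400), rng.normal(0, 10, 400), rng.normal(0, 0.5, 400)]
        )
        tab = gs.EffectTable(bhat=B, shat=np.ones((400, 3)))
        comps = gs.data_driven_covariances(tab, var_explained_min=0.05)
        # third PC is ~0.25% of variance: only 2 rank-1 comps + tPCA expected
        assert len(comps) == 3

    def test_too_few_strong_features(self):
        tab = gs.EffectTable(bhat=[[1.0, 2.0]], shat=[[1.0, 1.0]])
        with pytest.raises(ValueError):
            gs.data_driven_covariances(tab)


@pytest.fixture(scope="module")
def two_component_fit():
    R = 3
    mix = [(np.zeros((R, R)), 0.5), (np.ones((R, R)), 0.5)]
    tab, truth = gs.simulate_effect_table(R, 1500, mix, seed=9)
    fit = gs.fit_mixture(tab, gs.canonical_covariances(R))
    return tab, truth, fit


class TestMixtureSummaryAndPatterns:

    def test_summary_sums_to_one(self, two_component_fit):
        _, _, fit = two_component_fit
        assert gs.mixture_summary(fit).sum() == pytest.approx(1.0, abs=1e-8)

    def test_dominant_planted_component_ranks_first(self, two_component_fit):
        _, _, fit = two_component_fit
        summ = gs.mixture_summary(fit, null_sd=0.5)
        non_null = summ.drop("null")
        assert non_null.idxmax() == "equal_effects"

    def test_pattern_genes_from_planted_component(self, two_component_fit):
        tab, truth, fit = two_component_fit
        genes = set(gs.pattern_genes(fit, "equal_effects"))
        planted = {
            tab.features[j]
            for j in range(len(tab.features))
            if truth["assignments"][j] == 1 and np.abs(truth["true_effects"][j]).min() > 1
        }
        overlap = len(genes & planted) / max(len(planted), 1)
        assert overlap > 0.9

    def test_unknown_component_rejected(self, two_component_fit):
        _, _, fit = two_component_fit
        with pytest.raises(KeyError):
            gs.pattern_genes(fit, "nope")


class TestKmeansPatterns:
    def test_two_separated_clusters_knee_at_two(self):
        rng = np.random.default_rng(10)
        X = np.vstack(
            [rng.normal(0, 0.2, (60, 4)), rng.normal(5, 0.2, (60, 4))]
        )
        labels, curve, k_star = gs.kmeans_patterns(X, seed=0)
        assert k_star == 2
        a = labels[:60]
        assert len(set(a)) == 1 and len(set(labels[60:])) == 1

    def test_k1_wss_is_total_variance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (50, 3))
        _, curve, _ = gs.kmeans_patterns(X, k_range=range(1, 4), seed=0)
        total = float(((X - X.mean(axis=0)) ** 2).sum())
        assert curve.loc[1] == pytest.approx(total, rel=1e-9)

    def test_wss_nonincreasing(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (80, 3))
        _, curve, _ = gs.kmeans_patterns(X, seed=0)
        assert np.all(np.diff(curve.values) <= 1e-9)

    def test_k_exceeding_features_rejected(self):
        with pytest.raises(ValueError):
            gs.kmeans_patterns(np.zeros((2, 2)), k_range=range(5, 6), seed=0)


def test_chord_knee_on_piecewise_linear():
    y = np.concatenate([10 - 2.0 * np.arange(5), np.full(6, 2.0)])
    assert chord_knee(y) == 4
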