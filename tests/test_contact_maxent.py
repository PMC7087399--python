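import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from tandemloop.contact_maxent import (
    ContactMap,
    contact_map_from_ensemble,
    compute_targets,
    ensemble_pair_contacts,
    fit_contact_multiplier,
    grid_optimize_parameters,
    kruskal_stress,
    maxent_fit,
    nmds_embed,
    regrid_to_bins,
    rescale_viewpoint_profiles,
    reweight_ensemble,
)
from tandemloop.extrusion_1d import ExtrusionParams
from tandemloop.locus_model import bin_interval
from tandemloop.polymer_3d import Schedule, simulate_ensemble
from tandemloop.synthetic_data import gen_4c_profiles

from conftest import uniform_locus


class TestContactMap:
    def test_diagonal_symmetry_and_range(self, small_ensemble):
        cmap = contact_map_from_ensemble(small_ensemble, 2.0)
        p = cmap.probabilities
        assert np.all(np.diag(p) == 1.0)
        assert np.array_equal(p, p.T)
        assert p.min() >= 0 and p.max() <= 1

    def test_backbone_neighbours_in_contact(self, small_ensemble):
        cmap = contact_map_from_ensemble(small_ensemble, 2.0)
        off_diag = np.diag(cmap.probabilities, k=1)
        assert off_diag.min() > 0.99  # bond length ~1 << radius 2

    def test_contact_probability_decays_with_separation(self, small_ensemble):
        cmap = contact_map_from_ensemble(small_ensemble, 2.0)
        iu = np.triu_indices(cmap.probabilities.shape[0], k=1)
        r = spearmanr(iu[1] - iu[0], cmap.probabilities[iu])
        assert r.statistic < -0.3

    def test_empty_ensemble_rejected(self, small_ensemble):
        from tandemloop.polymer_3d import ConformationEnsemble

        empty = ConformationEnsemble(
            positions=small_ensemble.positions[:0], box=small_ensemble.box
        )
        with pytest.raises(ValueError):
            contact_map_from_ensemble(empty, 2.0)


class TestRegrid:
    def test_fragment_inside_one_bin(self):
        _, bins = bin_interval("chr1", 0, 3000, 600)
        frags = pd.DataFrame({"start": [100], "end": [400], "frequency": [7.0]})
        out = regrid_to_bins(frags, bins)
        assert out["frequency"].iloc[0] == pytest.approx(7.0)
        assert out["frequency"].iloc[1:].sum() == 0

    def test_fragment_split_forty_sixty(self):
        _, bins = bin_interval("chr1", 0, 1200, 600)
        frags = pd.DataFrame({"start": [360], "end": [960], "frequency": [10.0]})
        out = regrid_to_bins(frags, bins)
        assert out["frequency"].tolist() == pytest.approx([4.0, 6.0])

    def test_empty_input(self):
        _, bins = bin_interval("chr1", 0, 1200, 600)
        out = regrid_to_bins(pd.DataFrame(columns=["start", "end", "frequency"]),
                             bins)
        assert out["frequency"].sum() == 0

    def test_outside_fragment_dropped(self, caplog):
        _, bins = bin_interval("chr1", 0, 1200, 600)
        frags = pd.DataFrame({"start": [5000], "end": [5600], "frequency": [3.0]})
        out = regrid_to_bins(frags, bins)
        assert out["frequency"].sum() == 0


class TestRescaling:
    def test_noiseless_recovery_is_exact(self):
        prof, truth = gen_4c_profiles(3, 30, alpha=1.25,
                                      k_scales=[1.0, 2.5, 0.4],
                                      noise_gsd=1.0, replicates=2, seed=0)
        res = rescale_viewpoint_profiles(prof)
        assert res.alpha == pytest.approx(1.25, abs=1e-9)
        assert res.scales[0] == pytest.approx(1.0)
        assert res.scales[1] == pytest.approx(2.5, abs=1e-9)
        assert res.scales[2] == pytest.approx(0.4, abs=1e-9)
        assert res.gsd == pytest.approx(1.0, abs=1e-9)

    def test_single_viewpoint_identity(self):
        prof, _ = gen_4c_profiles(1, 20, alpha=1.0, k_scales=[1.0],
                                  noise_gsd=1.1, replicates=1, seed=1)
        res = rescale_viewpoint_profiles(prof)
        assert res.scales[0] == 1.0
        assert np.allclose(res.table["rescaled"], res.table["frequency"])

    def test_scale_equivariance(self):
        prof, _ = gen_4c_profiles(2, 30, alpha=1.0, k_scales=[1.0, 1.5],
                                  noise_gsd=1.2, replicates=1, seed=3)
        res1 = rescale_viewpoint_profiles(prof)
        scaled = prof.copy()
        mask = scaled["viewpoint"] == 1
        scaled.loc[mask, "frequency"] *= 5.0
        res2 = rescale_viewpoint_profiles(scaled)
        assert res2.scales[1] == pytest.approx(5.0 * res1.scales[1])
        assert res2.alpha == pytest.approx(res1.alpha)

    def test_rescaling_never_worse_than_unit_scales(self):
        prof, _ = gen_4c_profiles(3, 40, alpha=1.0, noise_gsd=1.3,
                                  replicates=1, seed=7)
        res = rescale_viewpoint_profiles(prof)
        # restricted fit: k_i = 1, best alpha by simple regression
        logu = np.log(prof["frequency"])
        logs = np.log(prof["distance"])
        slope = np.polyfit(logs, logu, 1)[0]
        resid = logu - slope * logs
        gsd_unit = np.exp(np.sqrt(np.mean((resid - resid.mean()) ** 2)))
        assert res.gsd <= gsd_unit + 1e-12

    def test_all_equal_distances_rejected(self):
        prof = pd.DataFrame({
            "viewpoint": [0, 0, 0], "partner": [0, 1, 2],
            "distance": [100.0, 100.0, 100.0], "frequency": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError):
            rescale_viewpoint_profiles(prof)

    def test_zero_mean_pairs_excluded(self):
        prof = pd.DataFrame({
            "viewpoint": 0, "partner": [0, 1, 2, 3],
            "distance": [10.0, 20.0, 40.0, 80.0],
            "frequency": [1.0, 0.5, 0.25, 0.0],
        })
        res = rescale_viewpoint_profiles(prof)
        assert len(res.table) == 3


class TestContactMultiplier:
    def test_exact_match_gives_unit_multiplier(self):
        p = np.array([0.5, 0.8, 0.2])
        p_hat = 0.3
        u = np.maximum(0, p - p_hat)
        assert fit_contact_multiplier(u, p, p_hat) == pytest.approx(1.0)

    def test_halved_frequencies_double_the_multiplier(self):
        p = np.array([0.5, 0.8, 0.2])
        p_hat = 0.3
        u = np.maximum(0, p - p_hat) / 2
        assert fit_contact_multiplier(u, p, p_hat) == pytest.approx(2.0)

    def test_flat_map_rejected(self):
        p = np.full(4, 0.5)
        with pytest.raises(ValueError):
            fit_contact_multiplier(np.ones(4), p, 0.5)

    def test_targets_clipped_to_unit_interval(self):
        xi = compute_targets(np.array([10.0, 0.01]), np.array([0.6, 0.1]),
                             p_hat=0.3, k=1.0)
        assert xi[0] == 1.0
        assert xi[1] == pytest.approx(0.11)


def _gamma_scalar(lam, C, xi, sigma2):
    logits = -C @ lam
    return (logsumexp(logits) - np.log(C.shape[0]) + xi @ lam
            + 0.5 * np.sum(lam**2 * sigma2))


class TestMaxEnt:
    def test_lambda_zero_when_targets_equal_prior_means(self):
        rng = np.random.default_rng(0)
        C = (rng.random((400, 8)) < 0.25).astype(float)
        model = maxent_fit(C, C.mean(axis=0))
        assert np.allclose(model.lambdas, 0.0, atol=1e-10)
        assert model.gamma == pytest.approx(0.0, abs=1e-12)

    def test_single_constraint_matches_dense_grid(self):
        C = np.array([[1.0], [0.0], [1.0]])
        xi = np.array([0.4])
        model = maxent_fit(C, xi)
        # two-stage dense grid on the 1D dual
        coarse = np.linspace(-30, 30, 60001)
        vals = [_gamma_scalar(np.array([l]), C, xi, model.sigma2) for l in coarse]
        l0 = coarse[int(np.argmin(vals))]
        fine = np.linspace(l0 - 2e-3, l0 + 2e-3, 40001)
        vals = [_gamma_scalar(np.array([l]), C, xi, model.sigma2) for l in fine]
        l_star = fine[int(np.argmin(vals))]
        assert abs(model.lambdas[0] - l_star) < 1e-6

    def test_dual_is_convex_along_random_directions(self):
        rng = np.random.default_rng(1)
        C = (rng.random((200, 5)) < 0.4).astype(float)
        xi = np.clip(C.mean(axis=0) + rng.normal(0, 0.05, 5), 0, 1)
        model = maxent_fit(C, xi)
        for _ in range(20):
            direction = rng.normal(size=5)
            ts = np.linspace(-2, 2, 41)
            vals = [_gamma_scalar(model.lambdas + t * direction, C, xi,
                                  model.sigma2) for t in ts]
            second = np.diff(vals, 2)
            assert np.all(second >= -1e-9)

    def test_first_order_condition_at_optimum(self):
        rng = np.random.default_rng(2)
        C = (rng.random((500, 6)) < 0.3).astype(float)
        xi = np.clip(C.mean(axis=0) + rng.normal(0, 0.08, 6), 0.01, 0.99)
        model = maxent_fit(C, xi)
        w = np.exp(-C @ model.lambdas)
        w /= w.sum()
        weighted_means = w @ C
        # grad = xi - <c> + lambda sigma^2 = 0, so <c> - lambda sigma^2 = xi
        # (the Gaussian slack absorbs -lambda sigma^2 of each constraint)
        resid = weighted_means - model.lambdas * model.sigma2 - xi
        assert np.max(np.abs(resid)) < 1e-6

    def test_variance_floor_applied(self):
        C = np.array([[1.0], [0.0]])
        model = maxent_fit(C, np.array([0.5]), variances=np.array([1e-8]),
                           sigma_min2=0.01)
        assert model.sigma2[0] == 0.01

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            maxent_fit(np.zeros((3, 1)), np.array([1.5]))


class TestReweighting:
    @pytest.fixture(scope="class")
    def fitted(self, small_ensemble):
        pairs = np.array([[0, 30], [10, 50], [5, 40]])
        cmap = contact_map_from_ensemble(small_ensemble, 2.0)
        p_hat = cmap.median_background
        p_pairs = cmap.probabilities[pairs[:, 0], pairs[:, 1]]
        C = ensemble_pair_contacts(small_ensemble, pairs, 2.0)
        xi = np.clip(p_pairs + np.array([0.05, -0.02, 0.04]), 0.01, 0.99)
        model = maxent_fit(C.astype(float), xi, pairs=pairs, capture_radius=2.0)
        return model

    def test_zero_lambdas_give_uniform_weights(self, small_ensemble, fitted):
        from dataclasses import replace

        model0 = replace(fitted, lambdas=np.zeros_like(fitted.lambdas))
        weighted, _ = reweight_ensemble(small_ensemble, model0)
        assert np.allclose(weighted.weights, 1.0 / small_ensemble.n_samples)

    def test_weights_normalized(self, small_ensemble, fitted):
        weighted, corrected = reweight_ensemble(small_ensemble, fitted)
        assert weighted.weights.sum() == pytest.approx(1.0)
        assert np.all(corrected.probabilities <= 1.0 + 1e-12)

    def test_reweighted_means_satisfy_first_order_condition(
            self, small_ensemble, fitted):
        weighted, _ = reweight_ensemble(small_ensemble, fitted)
        C = ensemble_pair_contacts(small_ensemble, fitted.pairs, 2.0).astype(float)
        means = weighted.weights @ C
        resid = means - fitted.lambdas * fitted.sigma2 - fitted.targets
        assert np.max(np.abs(resid)) < 1e-5

    def test_entropy_identity_at_convergence(self, small_ensemble, fitted):
        """The converged dual value estimates the relative entropy S[Q][Q0]."""
        C = ensemble_pair_contacts(small_ensemble, fitted.pairs, 2.0).astype(float)
        lam = fitted.lambdas
        logits = -C @ lam
        w = np.exp(logits - logsumexp(logits))
        means = w @ C
        entropy = (logsumexp(logits) - np.log(C.shape[0])
                   + lam @ (means - lam * fitted.sigma2)
                   + 0.5 * np.sum(lam**2 * fitted.sigma2))
        assert entropy == pytest.approx(fitted.gamma, abs=1e-5)

    def test_wildtype_multipliers_transfer_to_mutant_ensemble(self, fitted):
        """Multipliers fitted on one sample reweight another sample's prior."""
        mutant_locus = uniform_locus(60)
        schedule = Schedule.reduced(n_1d_anneal=300, n_3d_anneal_blocks=50,
                                    steps_per_block=20, n_sample_blocks=150)
        mutant = simulate_ensemble(mutant_locus, ExtrusionParams(100, 30, seed=5),
                                   schedule, seed=21)
        weighted, corrected = reweight_ensemble(mutant, fitted)
        assert weighted.weights.sum() == pytest.approx(1.0)
        assert corrected.probabilities.shape == (60, 60)


class TestGridOptimize:
    def test_single_cell_grid_returns_that_cell(self):
        locus = uniform_locus(40)
        schedule = Schedule.reduced(n_1d_anneal=200, n_3d_anneal_blocks=30,
                                    steps_per_block=15, n_sample_blocks=120)
        pairs = np.array([[5, 8], [10, 15], [20, 24]])
        u_bar = np.array([0.5, 0.2, 0.3])
        proc, sep, results = grid_optimize_parameters(
            locus, u_bar, pairs, grid=[(100, 20)], radii=(2.0,),
            schedule=schedule, seed=3,
        )
        assert (proc, sep) == (100, 20)
        assert np.all(np.isfinite(results[(100, 20)]))

    def test_gamma_finite_on_small_grid(self):
        locus = uniform_locus(40)
        schedule = Schedule.reduced(n_1d_anneal=200, n_3d_anneal_blocks=30,
                                    steps_per_block=15, n_sample_blocks=100)
        pairs = np.array([[5, 9], [10, 16]])
        u_bar = np.array([0.4, 0.2])
        proc, sep, results = grid_optimize_parameters(
            locus, u_bar, pairs, grid=[(50, 20), (200, 20)], radii=(2.0, 3.0),
            schedule=schedule, seed=1,
        )
        assert (proc, sep) in results
        for gammas in results.values():
            assert np.all(np.isfinite(gammas))


class TestNMDS:
    def test_perfect_distances_embed_with_negligible_stress(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        coords, stress, _ = nmds_embed(D, dim=3, seed=0)
        assert stress < 1e-3

    def test_stress_non_increasing_across_iterations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        D = D * np.exp(rng.normal(0, 0.3, D.shape))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        _, _, trace = nmds_embed(D, dim=2, seed=1)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_stress_invariant_under_rigid_motions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        coords, stress, _ = nmds_embed(D, dim=3, seed=0)
        # distances, hence stress, are unchanged by rotation + translation
        from scipy.stats import special_ortho_group

        R = special_ortho_group.rvs(3, random_state=1)
        moved = coords @ R + np.array([3.0, -1.0, 2.0])
        d0 = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        d1 = np.sqrt(((moved[:, None] - moved[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(8, 1)
        assert kruskal_stress(d1[iu], d0[iu]) < 1e-12

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            nmds_embed(D)
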