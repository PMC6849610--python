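import itertools

import numpy as np
import pytest

from occuedge.model import (
    DynamicOccupancyModel,
    ParamIndex,
    PriorSpec,
    detection_logit,
    inv_logit,
    pair_marginal_loglik,
    persistence_logit,
    transition_expectation,
)


def brute_force_pair_loglik(y1, y2, p1, p2, psi, phi, gamma):
    """Independent enumeration oracle over the latent states (z1, z2)."""
    total = 0.0
    for z1, z2 in itertools.product((0, 1), repeat=2):
        pz1 = psi if z1 else 1 - psi
        pz2_given = z1 * phi + (1 - z1) * gamma
        pz2 = pz2_given if z2 else 1 - pz2_given
        like = 1.0
        for y, p in zip(y1, p1):
            like *= (p if y else 1 - p) if z1 else (0.0 if y else 1.0)
        for y, p in zip(y2, p2):
            like *= (p if y else 1 - p) if z2 else (0.0 if y else 1.0)
        total += pz1 * pz2 * like
    return np.log(total) if total > 0 else -np.inf


class TestPersistenceLogit:
    # closed-form spot checks with the published posterior-mean magnitudes
    def test_palearctic_unconverted_midrange(self):
        lphi = persistence_logit(0.5, 0, 0, [9.067, 0, 0, 0], [0, 0, 0, 0])
        assert lphi == pytest.approx(9.067)
        assert inv_logit(lphi) == pytest.approx(0.99988, abs=5e-5)

    def test_palearctic_edge_with_negative_slope(self):
        lphi = persistence_logit(1.0, 0, 0, [9.067, 0, 0, 0], [-7.719, 0, 0, 0])
        assert lphi == pytest.approx(9.067 - 7.719 * 0.5)
        assert inv_logit(lphi) == pytest.approx(0.9946, abs=5e-4)

    def test_indomalaya_converted_intercept_composite(self):
        lphi = persistence_logit(0.5, 1, 1, [0, 1.821, 0, 0.882], [0, 0, 0, 0])
        assert lphi == pytest.approx(1.821 + 0.882)
        assert inv_logit(lphi) == pytest.approx(0.937, abs=1e-3)

    def test_species_random_effects_shift_both_terms(self):
        base = persistence_logit(0.8, 0, 1, [1, 2, 3, 4], [1, 1, 1, 1])
        shifted = persistence_logit(0.8, 0, 1, [1, 2, 3, 4], [1, 1, 1, 1], u=0.5, v=2.0)
        assert shifted == pytest.approx(base + 0.5 + 2.0 * 0.3)

    def test_centering_flag(self):
        a = persistence_logit(0.7, 0, 0, [1, 0, 0, 0], [2, 0, 0, 0], center=True)
        b = persistence_logit(0.7, 0, 0, [1, 0, 0, 0], [2, 0, 0, 0], center=False)
        assert b - a == pytest.approx(2 * 0.5)


class TestDetectionLogit:
    def test_long_list_period1(self):
        lp = detection_logit(0, 1, 1, delta_t=0.5, delta1=-1.487, delta3=2.188)
        assert lp == pytest.approx(0.701)
        assert inv_logit(lp) == pytest.approx(0.668, abs=1e-3)

    def test_single_list_period1(self):
        lp = detection_logit(0, 0, 1, delta_t=0.5, delta1=-1.487, delta2=1.0, delta3=2.0)
        assert inv_logit(lp) == pytest.approx(0.184, abs=1e-3)

    def test_period2_offset_applies(self):
        lp1 = detection_logit(1, 0, 1, delta_t=0.3, delta1=-1.0, delta2=0.7)
        lp2 = detection_logit(1, 0, 2, delta_t=0.3, delta1=-1.0, delta2=0.7)
        assert lp2 - lp1 == pytest.approx(0.3)


class TestTransition:
    @pytest.mark.parametrize("z1,phi,gamma,expected", [(1, 0.9, 0.1, 0.9), (0, 0.9, 0.1, 0.1)])
    def test_expectation(self, z1, phi, gamma, expected):
        assert transition_expectation(z1, phi, gamma) == expected

    def test_occupied_independent_of_gamma(self):
        assert transition_expectation(1, 0.7, 0.1) == transition_expectation(1, 0.7, 0.99)


class TestPairMarginalLoglik:
    def test_no_surveys_gives_unit_likelihood(self):
        ll = pair_marginal_loglik([], [], [], [], 0.3, 0.7, 0.2)
        assert ll == pytest.approx(0.0, abs=1e-14)

    def test_certain_initial_occupancy_single_detection(self):
        # psi=1 so z1=1; one period-2 survey with y=1 and p=0.5:
        # L = phi * p = 0.8 * 0.5
        ll = pair_marginal_loglik([], [1], [], [0.5], 1.0 - 1e-15, 0.8, 0.1)
        assert ll == pytest.approx(np.log(0.4), rel=1e-9)

    def test_matches_enumeration_oracle(self):
        from conftest import make_random_pair_history

        rng = np.random.default_rng(11)
        for _ in range(300):
            args = make_random_pair_history(rng)
            assert pair_marginal_loglik(*args) == pytest.approx(
                brute_force_pair_loglik(*args), rel=1e-12, abs=1e-12
            )

    def test_outcome_probabilities_sum_to_one(self):
        # over all 2^n possible detection vectors the likelihoods normalise
        rng = np.random.default_rng(13)
        for _ in range(20):
            n1, n2 = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            p1 = rng.uniform(0.1, 0.9, n1)
            p2 = rng.uniform(0.1, 0.9, n2)
            psi, phi, gamma = rng.uniform(0.05, 0.95, 3)
            total = 0.0
            for y in itertools.product((0, 1), repeat=n1 + n2):
                total += np.exp(pair_marginal_loglik(y[:n1], y[n1:], p1, p2, psi, phi, gamma))
            assert total == pytest.approx(1.0, abs=1e-10)


class TestParamIndex:
    def test_pack_unpack_roundtrip(self):
        idx = ParamIndex(5)
        rng = np.random.default_rng(0)
        theta = rng.normal(size=idx.dim)
        theta[[idx.names.index(n) for n in idx.names if n.startswith("sigma")]] = 0.7
        state = idx.unpack(theta)
        np.testing.assert_allclose(idx.pack(state), theta)

    def test_monitored_excludes_species_effects(self):
        idx = ParamIndex(3)
        assert all("[" not in n for n in idx.monitored)
        assert "alpha0" in idx.monitored and "sigma_u" in idx.monitored


class TestModelLikelihood:
    def make_theta(self, model, rng):
        theta = rng.normal(0, 0.5, model.index.dim)
        for fam in ("u", "v", "delta1", "delta2", "delta3", "lpsi", "lgamma"):
            theta[model.index.slices[f"sigma_{fam}"]] = np.exp(rng.normal(-0.5, 0.3))
        return theta

    def test_vectorised_matches_reference_per_pair(self, small_dataset):
        """The cached/vectorised likelihood equals the scalar reference op."""
        model = DynamicOccupancyModel(small_dataset)
        rng = np.random.default_rng(5)
        theta = self.make_theta(model, rng)
        s = model.index.unpack(theta)
        terms = model.pair_loglik_terms(theta)
        ds = small_dataset
        for p in rng.choice(ds.n_pairs, size=25, replace=False):
            i = ds.pair_species[p]
            mask = ds.obs_pair == p
            ks = ds.obs_survey[mask]
            ys = ds.obs_y[mask]
            per = ds.survey_period[ks]
            lp = detection_logit(
                ds.survey_short[ks], ds.survey_long[ks], per, s["delta_t"],
                s["delta1"][i], s["delta2"][i], s["delta3"][i],
            )
            pdet = inv_logit(lp)
            phi = inv_logit(persistence_logit(
                ds.pair_dprime[p], ds.pair_R[p], ds.pair_C[p], s["alpha"], s["beta"],
                u=s["u"][i], v=s["v"][i],
            ))
            ref = pair_marginal_loglik(
                ys[per == 1], ys[per == 2], pdet[per == 1], pdet[per == 2],
                inv_logit(s["lpsi"][i]), phi, inv_logit(s["lgamma"][i]),
            )
            assert terms[p] == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_log_posterior_additive_decomposition(self, small_dataset):
        model = DynamicOccupancyModel(small_dataset)
        rng = np.random.default_rng(6)
        theta = self.make_theta(model, rng)
        assert model.log_posterior(theta) == pytest.approx(
            model.log_prior(theta) + model.pair_loglik_terms(theta).sum(), rel=1e-12
        )

    def test_log_posterior_finite_interior(self, small_dataset):
        model = DynamicOccupancyModel(small_dataset)
        theta = self.make_theta(model, np.random.default_rng(7))
        assert np.isfinite(model.log_posterior(theta))

    def test_nonpositive_sigma_rejected(self, small_dataset):
        model = DynamicOccupancyModel(small_dataset)
        theta = self.make_theta(model, np.random.default_rng(8))
        theta[model.index.slices["sigma_u"]] = -0.1
        assert model.log_posterior(theta) == -np.inf

    def test_centering_reparameterisation_identity(self, small_dataset):
        """Shifting alpha by beta/2 maps the centred model onto the
        uncentred one exactly: logit phi = a + b(D'-1/2) = (a - b/2) + b D'."""
        mc = DynamicOccupancyModel(small_dataset, center_dprime=True)
        mu = DynamicOccupancyModel(small_dataset, center_dprime=False)
        rng = np.random.default_rng(9)
        theta = self.make_theta(mc, rng)
        theta_u = theta.copy()
        theta_u[0:4] = theta[0:4] - theta[4:8] / 2.0
        # species random slopes shift the species intercepts likewise
        theta_u[mc.index.slices["u"]] = (
            theta[mc.index.slices["u"]] - theta[mc.index.slices["v"]] / 2.0
        )
        np.testing.assert_allclose(
            mc.pair_loglik_terms(theta), mu.pair_loglik_terms(theta_u), rtol=1e-10
        )

    def test_zero_slopes_make_persistence_flat_in_dprime(self, small_dataset):
        model = DynamicOccupancyModel(small_dataset)
        theta = np.zeros(model.index.dim)
        for fam in ("u", "v", "delta1", "delta2", "delta3", "lpsi", "lgamma"):
            theta[model.index.slices[f"sigma_{fam}"]] = 1.0
        theta[0:4] = [2.0, 1.0, -0.5, 0.5]  # alphas only; betas and v zero
        s = model.index.unpack(theta)
        ds = small_dataset
        lphi = persistence_logit(ds.pair_dprime, ds.pair_R, ds.pair_C, s["alpha"], s["beta"])
        for R in (0, 1):
            for C in (0, 1):
                mask = (ds.pair_R == R) & (ds.pair_C == C)
                if mask.any():
                    assert np.ptp(lphi[mask]) == pytest.approx(0.0, abs=1e-12)

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(fixed_sd=-1.0)

    def test_from_tables_constructor(self, small_sim, small_config, small_dataset):
        records, species_cells, cell_attrs, _ = small_sim
        model = DynamicOccupancyModel.from_tables(
            records, species_cells, cell_attrs, grid=small_config.grid
        )
        assert model.dataset.counts == small_dataset.counts
        assert model.n_pairs == small_dataset.n_pairs
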