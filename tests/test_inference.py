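"""Sampler correctness: likelihood pieces, full conditionals, diagnostics,
determinism, and small-scale simulation-based calibration."""

import numpy as np
import pandas as pd
import pytest

import spomdyn._sampler as smp
from spomdyn.inference import (
    MCMCConfig,
    PriorConfig,
    detection_loglik,
    fit_gvs,
    fit_mcmc,
    rhat,
    z_full_conditional,
)
from spomdyn.kernel import ExtinctionParams, ModelSpec, extinction_prob
from spomdyn.network import OccupancyState
from spomdyn.simulate import simulate_dataset

from conftest import make_params, make_scenario


class TestDetectionLoglik:
    def test_values(self):
        assert detection_loglik([1], 1, 0.7) == pytest.approx(np.log(0.7))
        assert detection_loglik([0, 0, 0], 0, 0.7) == 0.0
        assert detection_loglik([0, 1, 0], 0, 0.7) == -np.inf

    def test_missing_visits_contribute_nothing(self):
        full = detection_loglik([1, 0], 1, 0.6)
        assert detection_loglik([1, 0, np.nan, np.nan], 1, 0.6) == pytest.approx(full)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            detection_loglik([1], 1, 1.5)


class TestZFullConditional:
    def _setup(self, three_patch_network, tiny_history):
        params = make_params(psi1=0.4, delta0=0.2, delta1=-1.0, alpha=0.8, beta=0.6)
        params.detection.p_t = np.array([0.7, 0.8, 0.75])
        state = OccupancyState(z=np.ones((3, 3), dtype=int))
        return params, state

    def test_detection_forces_occupancy(self, three_patch_network, tiny_history):
        params, state = self._setup(three_patch_network, tiny_history)
        # patch a year 0 has a detection
        pr = z_full_conditional(
            0, 0, state, params, ModelSpec(True), tiny_history, three_patch_network
        )
        assert pr == 1.0

    def test_unweighted_equals_local_three_factor(
        self, three_patch_network, tiny_history
    ):
        """Without demographic weighting the conditional only involves the
        patch's own detection, incoming and outgoing transition factors."""
        params, state = self._setup(three_patch_network, tiny_history)
        model = ModelSpec(weighted=False)
        i, t = 2, 1  # unsurveyed patch-year, interior in time
        pr = z_full_conditional(
            i, t, state, params, model, tiny_history, three_patch_network
        )
        eps = extinction_prob(three_patch_network.length, params.extinction)[i]
        # z[i,0] = 1 and z[i,2] = 1 in the fixture state
        w1 = np.log(1 - eps) + np.log(1 - eps)
        w0 = np.log(eps)
        from spomdyn.kernel import ALL_ONES, colonization_prob, connectivity_vector

        S = connectivity_vector(
            three_patch_network, ALL_ONES, params.dispersal.alpha, params.dispersal.beta
        )[i]
        w0 += np.log(colonization_prob(S))
        expected = 1 / (1 + np.exp(w0 - w1))
        assert pr == pytest.approx(expected, rel=1e-12)

    def test_matches_enumerated_conditional(self, three_patch_network, tiny_history):
        """Weighted-model conditional equals the exact conditional computed
        from the exhaustively enumerated joint posterior."""
        from test_acceptance import enumerate_z_posterior

        params, state = self._setup(three_patch_network, tiny_history)
        model = ModelSpec(weighted=True)
        probs = enumerate_z_posterior(three_patch_network, tiny_history, params)
        z = state.z
        i, t = 2, 1
        # conditional from the enumeration: restrict to configs agreeing with
        # `state` everywhere except (i, t)
        num = den = 0.0
        for code in range(512):
            bits = np.array([(code >> (8 - k)) & 1 for k in range(9)]).reshape(3, 3)
            mask = np.ones((3, 3), dtype=bool)
            mask[i, t] = False
            if np.array_equal(bits[mask], z[mask]):
                den += probs[code]
                if bits[i, t] == 1:
                    num += probs[code]
        pr = z_full_conditional(
            i, t, state, params, model, tiny_history, three_patch_network
        )
        assert pr == pytest.approx(num / den, rel=1e-9)


class TestSamplerInternals:
    def test_incremental_connectivity_consistency(self, three_patch_network, tiny_history):
        """Cw maintained across Gibbs flips equals a fresh recomputation."""
        net = three_patch_network
        n, T = 3, 3
        ysum = tiny_history.detections.astype(np.int64)
        J = tiny_history.visits.astype(np.int64)
        forced = (ysum > 0).astype(np.int8)
        eps = extinction_prob(net.length, ExtinctionParams(0.2, -1.0))
        p = np.array([0.7, 0.8, 0.75])
        alpha_tr = np.full(T - 1, 0.8)
        beta_tr = np.full(T - 1, 0.6)
        z = np.ones((n, T), dtype=np.int8)
        K = np.empty((T - 1, n, n))
        smp._kernels_into(net.dist, alpha_tr, K)
        Cw = np.empty((T - 1, n))
        Cu = np.empty((T - 1, n))
        smp._connect_into(K, net.length, z, Cw, Cu)
        np.random.seed(0)
        for _ in range(25):
            smp._z_sweep(
                z, forced, ysum, J, net.length, K, Cw, Cu, beta_tr, eps, p, 0.4, 1
            )
        fresh_w = np.empty_like(Cw)
        fresh_u = np.empty_like(Cu)
        smp._connect_into(K, net.length, z, fresh_w, fresh_u)
        assert np.max(np.abs(Cw - fresh_w)) < 1e-8
        assert np.max(np.abs(Cu - fresh_u)) < 1e-8


class TestRhat:
    def test_identical_white_noise_chains(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(4, 500))
        assert rhat(c) < 1.01

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(2, 200))
        c[1] += 50.0
        assert rhat(c) > 1.1

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        c = rng.normal(size=(3, 400)) + rng.normal(size=(3, 1)) * 0.3
        ref = float(
            az.rhat(az.convert_to_dataset(c), method="split")["x"].values
        )
        mine = rhat(c)
        assert mine == pytest.approx(ref, abs=1e-8)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


@pytest.fixture(scope="module")
def small_di_fit():
    cfg = make_scenario(n=15, T=8, seed=2, delta0=1.0, mu_p=1.8)
    net, truth, occ, hist = simulate_dataset(cfg)
    mcmc = MCMCConfig(n_chains=2, n_iter=1500, n_burnin=700, thin=4, seed=5)
    post = fit_mcmc(hist, net, ModelSpec(weighted=True), mcmc)
    return net, hist, post, mcmc


class TestFitMcmc:
    def test_row_count_bookkeeping(self, small_di_fit):
        net, hist, post, mcmc = small_di_fit
        per_chain = (mcmc.n_iter - mcmc.n_burnin) // mcmc.thin
        assert post.n_draws == mcmc.n_chains * per_chain
        assert post.z_draws.shape == (post.n_draws, net.n, hist.T)

    def test_detected_states_never_zero(self, small_di_fit):
        net, hist, post, _ = small_di_fit
        forced = hist.detections > 0
        assert post.z_draws[:, forced].min() == 1

    def test_determinism(self, small_di_fit):
        net, hist, post, mcmc = small_di_fit
        again = fit_mcmc(hist, net, ModelSpec(weighted=True), mcmc)
        pd.testing.assert_frame_equal(post.draws, again.draws)

    def test_summary_layout(self, small_di_fit):
        _, _, post, _ = small_di_fit
        s = post.summary(["psi1", "alpha", "beta"])
        assert set(s.columns) >= {"mean", "sd", "q2.5", "q50", "q97.5", "rhat"}
        assert (s["q2.5"] <= s["q97.5"]).all()

    def test_probability_draws_within_bounds(self, small_di_fit):
        _, _, post, _ = small_di_fit
        assert post.draws["psi1"].between(0, 1).all()
        assert post.draws["alpha"].between(0, 5).all()
        p_cols = [c for c in post.draws.columns if c.startswith("p_t_")]
        assert post.draws[p_cols].to_numpy().min() > 0
        assert post.draws[p_cols].to_numpy().max() < 1


class TestGVS:
    def test_model_probabilities_normalized(self):
        cfg = make_scenario(n=12, T=6, seed=4, delta0=1.0)
        net, truth, occ, hist = simulate_dataset(cfg)
        mcmc = MCMCConfig(
            n_chains=1, n_iter=800, n_burnin=400, thin=4, seed=9,
            pilot_iter=600, pilot_burn=300,
        )
        post = fit_gvs(hist, net, mcmc)
        probs = post.model_probabilities()
        assert probs["probability"].sum() == pytest.approx(1.0, abs=1e-12)
        assert set(probs.index) == {"UI", "UV", "DI", "DV"}
        ind = post.indicator_probabilities()
        assert probs.loc["DV", "probability"] <= min(ind["pr_I_z"], ind["pr_I_D"]) + 1e-12


class TestSimulationBasedCalibration:
    def test_rank_statistics_uniform(self):
        """Truths drawn from the prior land uniformly within their posteriors."""
        from scipy.stats import chi2

        priors = PriorConfig(delta_sd=1.5, alpha_hi=2.0, beta_hi=1.0, sigp_hi=0.5)
        rng = np.random.default_rng(10)
        n_rep, L = 32, 63
        ranks = {"alpha": [], "beta": []}
        for rep in range(n_rep):
            truth = dict(
                psi1=rng.uniform(),
                delta0=rng.normal(0, 1.5),
                delta1=rng.normal(0, 1.5),
                alpha=rng.uniform(0.01, 2.0),
                beta=rng.uniform(0.0, 1.0),
                mu_p=rng.normal(0, 1.65),
                sigma_p=rng.uniform(0.01, 0.5),
            )
            cfg = make_scenario(n=20, T=8, seed=int(rng.integers(2**31 - 1)), **truth)
            net, tp, occ, hist = simulate_dataset(cfg)
            mcmc = MCMCConfig(
                n_chains=1, n_iter=2020, n_burnin=760, thin=20,
                seed=int(rng.integers(2**31 - 1)), priors=priors,
            )
            post = fit_mcmc(hist, net, ModelSpec(weighted=True), mcmc)
            for name in ranks:
                draws = post.draws[name].to_numpy()[:L]
                ranks[name].append(int(np.sum(draws < truth[name])))
        for name, rk in ranks.items():
            counts = np.bincount(np.array(rk) // 8, minlength=8)
            stat = np.sum((counts - n_rep / 8) ** 2 / (n_rep / 8))
            assert stat < chi2.ppf(0.99, 7), f"{name} ranks non-uniform: {counts}"
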