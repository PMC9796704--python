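"""Metapopulation capacity, colonization surfaces and goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from spomdyn.inference import PosteriorSamples
from spomdyn.kernel import ModelSpec
from spomdyn.network import DetectionHistory, PatchNetwork
from spomdyn.metrics import (
    capacity_posterior,
    colonization_surface,
    freeman_tukey_discrepancy,
    freeman_tukey_gof,
    metapop_capacity,
    network_colonization,
)


def random_network(seed, n):
    rng = np.random.default_rng(seed)
    return PatchNetwork(
        patch_id=[f"p{i}" for i in range(n)],
        x=rng.uniform(0, 10, n),
        y=rng.uniform(0, 10, n),
        length=rng.uniform(0.1, 3.0, n),
    )


class TestMetapopCapacity:
    def test_two_patch_analytic(self, two_patch_network):
        # m = [[0, e^-1], [e^-1, 0]] with unit lengths -> lambda = e^-1
        assert metapop_capacity(two_patch_network, 1.0) == pytest.approx(
            np.exp(-1), abs=1e-12
        )

    def test_equilateral_triangle_analytic(self):
        # three equal patches at pairwise distance d: m = a(J - I) with
        # a = A^2 e^{-alpha d}, dominant eigenvalue 2a
        d = 1.5
        h = d * np.sqrt(3) / 2
        net = PatchNetwork(
            ["a", "b", "c"], x=[0.0, d, d / 2], y=[0.0, 0.0, h], length=[2.0, 2.0, 2.0]
        )
        alpha = 0.7
        expected = 2 * 4.0 * np.exp(-alpha * d)
        assert metapop_capacity(net, alpha) == pytest.approx(expected, rel=1e-9)

    def test_matches_power_iteration(self):
        net = random_network(2, 30)
        alpha = 0.6
        M = np.outer(net.length, net.length) * np.exp(-alpha * net.dist)
        np.fill_diagonal(M, 0.0)
        v = np.ones(30)
        for _ in range(5000):
            w = M @ v
            v = w / np.linalg.norm(w)
        lam_power = float(v @ M @ v)
        assert metapop_capacity(net, alpha) == pytest.approx(lam_power, abs=1e-9)

    def test_relabelling_invariance(self):
        net = random_network(3, 12)
        perm = np.random.default_rng(0).permutation(12)
        net2 = PatchNetwork(
            [net.patch_id[k] for k in perm],
            x=net.x[perm], y=net.y[perm], length=net.length[perm],
        )
        assert metapop_capacity(net, 0.5) == pytest.approx(
            metapop_capacity(net2, 0.5), rel=1e-12
        )

    def test_monotone_adding_patch_and_in_alpha(self):
        net = random_network(4, 10)
        bigger = PatchNetwork(
            net.patch_id + ["extra"],
            x=np.append(net.x, 5.0), y=np.append(net.y, 5.0),
            length=np.append(net.length, 1.0),
        )
        assert metapop_capacity(bigger, 0.5) >= metapop_capacity(net, 0.5)
        assert metapop_capacity(net, 1.0) <= metapop_capacity(net, 0.5)

    def test_singleton_warns_zero(self):
        net = PatchNetwork(["a"], x=[0.0], y=[0.0], length=[1.0])
        with pytest.warns(UserWarning):
            assert metapop_capacity(net, 1.0) == 0.0


def _posterior_from_alpha(alphas, years=None):
    """Minimal PosteriorSamples with given alpha draws (static model)."""
    n = len(alphas)
    df = pd.DataFrame(
        {
            "chain": 0,
            "psi1": 0.5,
            "delta0": 0.0,
            "delta1": 0.0,
            "alpha": alphas,
            "beta": 0.1,
            "sigma_alpha": 0.0,
            "sigma_beta": 0.0,
            "mu_p": 1.0,
            "sigma_p": 0.3,
            "I_z": 1,
            "I_D": 0,
            "loglik": 0.0,
        }
    )
    return PosteriorSamples(df)


class TestCapacityPosterior:
    def test_degenerate_posterior_zero_width(self):
        net = random_network(5, 8)
        post = _posterior_from_alpha(np.full(50, 0.8))
        cap = capacity_posterior(post, net, ModelSpec(True, False))
        row = cap.summary.loc["overall"]
        assert row["q2.5"] == row["q97.5"] == pytest.approx(
            metapop_capacity(net, 0.8)
        )

    def test_monotone_in_alpha_across_draws(self):
        net = random_network(6, 8)
        alphas = np.linspace(0.2, 2.0, 40)
        post = _posterior_from_alpha(alphas)
        cap = capacity_posterior(post, net, ModelSpec(True, False))
        assert np.all(np.diff(cap.lambda_draws) < 0)

    def test_two_point_mixture_matches_hand_mix(self):
        net = random_network(7, 10)
        a1, a2 = 0.4, 1.2
        post = _posterior_from_alpha(np.array([a1] * 30 + [a2] * 10))
        cap = capacity_posterior(post, net, ModelSpec(True, False))
        l1, l2 = metapop_capacity(net, a1), metapop_capacity(net, a2)
        assert cap.summary.loc["overall", "mean"] == pytest.approx(
            0.75 * l1 + 0.25 * l2, abs=1e-9
        )


class TestColonizationSurface:
    def test_beta_zero_all_zero(self):
        net = random_network(8, 5)
        surf = colonization_surface(net, np.ones(5), 0.5, 0.0, cellsize=0.5)
        assert np.all(surf.grid == 0)
        assert surf.summary["mean"] == 0.0

    def test_no_sources_all_zero(self):
        net = random_network(8, 5)
        surf = colonization_surface(net, np.zeros(5), 0.5, 0.3, cellsize=0.5)
        assert np.all(surf.grid == 0)

    def test_single_source_hand_evaluated_pixels(self):
        net = PatchNetwork(["a"], x=[0.0], y=[0.0], length=[1.3])
        alpha, beta = 0.9, 0.4
        surf = colonization_surface(
            net, np.ones(1), alpha, beta, cellsize=1.0, buffer=2.0
        )
        xs, ys = surf.pixel_centres()
        for r in (0, 2):
            for c in (1, 3):
                d = np.hypot(xs[c] - 0.0, ys[r] - 0.0)
                expect = 1 - np.exp(-beta * 1.3 * np.exp(-alpha * d))
                assert surf.grid[r, c] == pytest.approx(expect, abs=1e-12)

    def test_values_are_probabilities_and_extent_buffered(self):
        net = random_network(9, 12)
        surf = colonization_surface(net, np.ones(12), 0.5, 0.5, cellsize=0.25)
        assert surf.grid.min() >= 0 and surf.grid.max() < 1
        assert surf.origin[0] <= net.x.min() - 2.0
        assert surf.origin[1] <= net.y.min() - 2.0

    def test_saturates_with_huge_beta(self):
        net = random_network(10, 6)
        surf = colonization_surface(net, np.ones(6), 0.3, 1e6, cellsize=0.5)
        assert surf.summary["mean"] == pytest.approx(1.0, abs=1e-6)


class TestNetworkColonization:
    def test_log2_beta_gives_half(self):
        # alpha = 0: S_i = beta * sum_{j != i} A_j; equal unit lengths
        net = PatchNetwork(
            ["a", "b", "c"], x=[0.0, 1.0, 2.0], y=[0.0, 0.0, 0.0], length=[1.0, 1.0, 1.0]
        )
        beta = np.log(2) / 2  # S_i = log 2 for every patch
        assert network_colonization(net, np.ones(3), 0.0, beta) == pytest.approx(0.5)

    def test_single_patch_zero(self):
        net = PatchNetwork(["a"], x=[0.0], y=[0.0], length=[1.0])
        assert network_colonization(net, np.ones(1), 0.5, 0.5) == 0.0

    def test_matches_loop(self):
        net = random_network(11, 5)
        z = np.array([1, 0, 1, 1, 0])
        alpha, beta = 0.6, 0.2
        vals = []
        for i in range(5):
            S = sum(
                net.length[j] * z[j] * np.exp(-alpha * net.dist[i, j])
                for j in range(5)
                if j != i
            )
            vals.append(1 - np.exp(-beta * S))
        assert network_colonization(net, z, alpha, beta) == pytest.approx(
            np.mean(vals), abs=1e-12
        )


class TestFreemanTukey:
    def test_spot_value(self):
        assert freeman_tukey_discrepancy([0, 1], [0.25, 0.25]) == pytest.approx(0.5)

    def test_zero_when_exact(self):
        assert freeman_tukey_discrepancy([1, 4, 9], [1, 4, 9]) == 0.0

    def test_gof_invariant_to_ordering(self):
        from spomdyn.inference import MCMCConfig, fit_mcmc
        from spomdyn.simulate import simulate_dataset

        from conftest import make_scenario

        cfg = make_scenario(n=10, T=5, seed=3, delta0=1.0)
        net, truth, occ, hist = simulate_dataset(cfg)
        post = fit_mcmc(
            hist, net, ModelSpec(True),
            MCMCConfig(n_chains=1, n_iter=600, n_burnin=300, thin=3, seed=1),
        )
        p1, t1 = freeman_tukey_gof(hist, post, net, ModelSpec(True), seed=9)
        # permute patches consistently in data and z draws
        perm = np.random.default_rng(0).permutation(net.n)
        hist2 = DetectionHistory(y=hist.y[perm], years=hist.years)
        post2 = PosteriorSamples(post.draws, post.z_draws[:, perm, :])
        p2, t2 = freeman_tukey_gof(hist2, post2, net, ModelSpec(True), seed=9)
        # observed discrepancies are exactly order-invariant; the p-value is
        # invariant in distribution (replicate noise is re-drawn per cell)
        np.testing.assert_allclose(t1["T_obs"], t2["T_obs"], atol=1e-12)
        assert p1 == pytest.approx(p2, abs=0.1)

    def test_empty_posterior_rejected(self):
        with pytest.raises(ValueError):
            freeman_tukey_gof(
                DetectionHistory(y=np.zeros((1, 2, 1)), years=np.arange(2)),
                PosteriorSamples(pd.DataFrame({"chain": []})),
                None,
                ModelSpec(True),
            )
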