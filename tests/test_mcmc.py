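"""Conditional updates of the MCMC engine against independent oracles."""

import numpy as np
import pytest
from scipy.stats import poisson

from stcarclust import (
    AreaGraph,
    CountData,
    ModelConfig,
    Partition,
    Sampler,
    assemble_candidate_set,
    border_candidate_set,
    log_poisson_likelihood,
    run_chain,
)
from stcarclust.car import leroux_precision


def make_sampler(data, cands, seed=0, **cfg):
    config = ModelConfig(n_iter=10, burn_in=1, **cfg)
    return Sampler(data, cands, config, np.random.default_rng(seed))


def tiny_problem(n=5, T=2, seed=0, E_scale=5.0):
    rng = np.random.default_rng(seed)
    edges = [(i, i + 1) for i in range(n - 1)]
    G = AreaGraph(n, edges)
    E = np.full((n, T), E_scale)
    Y = rng.poisson(E)
    return CountData(Y=Y, E=E), border_candidate_set(G)


class TestLogPoissonLikelihood:
    def test_all_zero_counts(self):
        E = np.full((3, 2), 4.0)
        data = CountData(Y=np.zeros((3, 2), int), E=E)
        ll = log_poisson_likelihood(np.zeros((3, 2)), data)
        assert ll == pytest.approx(-E.sum())

    def test_single_cell_value(self):
        data = CountData(Y=np.array([[3]]), E=np.array([[2.0]]))
        assert log_poisson_likelihood(np.zeros((1, 1)), data) == pytest.approx(
            3 * np.log(2.0) - 2.0
        )

    def test_matches_scipy_pmf_up_to_constant(self, rng):
        Y = rng.poisson(5.0, size=(4, 3))
        E = rng.uniform(1, 8, size=(4, 3))
        eta = rng.normal(0, 0.3, size=(4, 3))
        data = CountData(Y=Y, E=E)
        ref = poisson.logpmf(Y, E * np.exp(eta)).sum()
        from scipy.special import gammaln

        assert log_poisson_likelihood(eta, data) == pytest.approx(
            ref + gammaln(Y + 1).sum(), abs=1e-10
        )


class TestGibbsUpdates:
    def test_tau2_zero_phi_matches_prior_posterior(self):
        data, cands = tiny_problem(n=6, T=2)
        sam = make_sampler(data, cands, seed=1)
        sam.state.phi[:] = 0.0
        sam._refresh_quads()
        draws = []
        for _ in range(20_000):
            sam.update_tau2()
            draws.append(sam.state.tau2.copy())
        draws = np.array(draws)
        # IG(1 + n/2, 0.01) mean = 0.01 / (n/2)
        expected = 0.01 / (6 / 2)
        assert draws.mean() == pytest.approx(expected, rel=0.05)

    def test_tau2_conjugate_mean_with_fixed_phi(self, rng):
        data, cands = tiny_problem(n=5, T=1)
        sam = make_sampler(data, cands, seed=2)
        sam.state.phi[:, 0] = rng.normal(0, 0.8, size=5)
        sam.state.rho[:] = 0.7
        sam._refresh_quads()
        qL, qI = sam._qL, sam._qI
        quad = 0.7 * qL[0] + 0.3 * qI[0]
        shape, scale = 1 + 2.5, 0.01 + quad / 2
        draws = []
        for _ in range(50_000):
            sam.update_tau2()
            draws.append(sam.state.tau2[0])
        assert np.mean(draws) == pytest.approx(scale / (shape - 1), rel=0.03)

    def test_sigma2_alpha_with_zero_theta(self):
        data, cands = tiny_problem(n=4, T=4)
        sam = make_sampler(data, cands, seed=3)
        sam.state.theta[:] = 0.0
        s2, al = [], []
        for _ in range(20_000):
            sam.state.theta[:] = 0.0
            sam.update_sigma2_alpha()
            s2.append(sam.state.sigma2)
            al.append(sam.state.alpha)
        # sigma2 ~ IG(1 + T/2, 0.01); alpha ~ Uniform(0,1)
        assert np.mean(s2) == pytest.approx(0.01 / (1 + 2 - 1), rel=0.05)
        assert np.mean(al) == pytest.approx(0.5, abs=0.01)
        assert np.min(al) >= 0.0 and np.max(al) <= 1.0

    def test_alpha_always_in_unit_interval(self, rng):
        data, cands = tiny_problem(n=4, T=6)
        sam = make_sampler(data, cands, seed=4)
        sam.state.theta[:] = rng.normal(0, 1.0, size=6)
        draws = []
        for _ in range(5_000):
            sam.update_sigma2_alpha()
            draws.append(sam.state.alpha)
        assert min(draws) >= 0.0 and max(draws) <= 1.0


class TestThetaUpdate:
    def test_prior_recovery_without_data(self):
        """With uninformative data theta follows the AR(1) prior."""
        n, T = 3, 2
        G = AreaGraph(n, [(0, 1), (1, 2)])
        data = CountData(Y=np.zeros((n, T), int), E=np.full((n, T), 1e-8))
        cands = border_candidate_set(G)
        sam = make_sampler(data, cands, seed=5, step_theta=1.2)
        sam.state.beta[0] = 0.0
        sam.state.phi[:] = 0.0
        sam.state.theta[:] = 0.0
        sam.state.alpha, sam.state.sigma2 = 0.6, 0.5
        draws = np.empty((40_000, T))
        for i in range(40_000):
            sam.update_theta()
            draws[i] = sam.state.theta
        cov = np.cov(draws[2000:].T)
        a, s2 = 0.6, 0.5
        assert cov[0, 0] == pytest.approx(s2, rel=0.1)
        assert cov[0, 1] == pytest.approx(a * s2, rel=0.15)
        assert cov[1, 1] == pytest.approx(s2 * (1 + a * a), rel=0.1)

    def test_strong_data_pins_theta(self, rng):
        n, T = 4, 2
        G = AreaGraph(n, [(0, 1), (1, 2), (2, 3)])
        E = np.full((n, T), 5e4)
        true_theta = np.array([0.3, -0.2])
        Y = rng.poisson(E * np.exp(true_theta)[None, :])
        data = CountData(Y=Y, E=E)
        sam = make_sampler(data, border_candidate_set(G), seed=6, step_theta=0.01)
        sam.state.phi[:] = 0.0
        sam.state.beta[0] = 0.0
        for _ in range(3_000):
            sam.update_theta()
        assert np.allclose(sam.state.theta, true_theta, atol=0.02)


class TestPhiUpdate:
    def test_prior_recovery_without_data(self):
        """Stationary phi moments match tau2 * Q^{-1} when Y is uninformative."""
        n, T = 5, 1
        G = AreaGraph(n, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)])
        data = CountData(Y=np.zeros((n, T), int), E=np.full((n, T), 1e-8))
        cands = border_candidate_set(G)
        sam = make_sampler(data, cands, seed=7, step_phi=1.0)
        rho, tau2 = 0.8, 0.5
        sam.state.beta[0] = 0.0
        sam.state.theta[:] = 0.0
        sam.state.rho[:] = rho
        sam.state.tau2[:] = tau2
        sam.state.phi[:] = 0.0
        draws = np.empty((60_000, n))
        for i in range(60_000):
            sam.update_phi()
            draws[i] = sam.state.phi[:, 0]
        cov_ref = tau2 * np.linalg.inv(leroux_precision(rho, G.W))
        var_emp = draws[5000:].var(axis=0)
        assert np.allclose(var_emp, np.diag(cov_ref), rtol=0.12)

    def test_grid_posterior_oracle(self):
        """Long-run phi marginals match brute-force grid integration (n=3)."""
        G = AreaGraph(3, [(0, 1), (1, 2)])
        data = CountData(Y=np.array([[2], [5], [1]]), E=np.array([[3.0], [4.0], [2.0]]))
        cands = border_candidate_set(G)
        rho, tau2 = 0.6, 0.4
        # brute-force posterior on a grid
        g = np.linspace(-2.5, 2.5, 81)
        P1, P2, P3 = np.meshgrid(g, g, g, indexing="ij")
        Q = leroux_precision(rho, G.W)
        quad = (
            Q[0, 0] * P1**2 + Q[1, 1] * P2**2 + Q[2, 2] * P3**2
            + 2 * Q[0, 1] * P1 * P2 + 2 * Q[1, 2] * P2 * P3
        )
        loglik = (
            data.Y[0, 0] * P1 - data.E[0, 0] * np.exp(P1)
            + data.Y[1, 0] * P2 - data.E[1, 0] * np.exp(P2)
            + data.Y[2, 0] * P3 - data.E[2, 0] * np.exp(P3)
        )
        logpost = loglik - quad / (2 * tau2)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_ref = np.array([(w * P).sum() for P in (P1, P2, P3)])

        sam = make_sampler(data, cands, seed=8, step_phi=0.8)
        sam.state.rho[:] = rho
        sam.state.tau2[:] = tau2
        sam.state.beta[0] = 0.0
        sam.state.theta[:] = 0.0
        sam.state.phi[:] = 0.0
        draws = np.empty((80_000, 3))
        for i in range(80_000):
            sam.update_phi()
            draws[i] = sam.state.phi[:, 0]
        mean_emp = draws[5000:].mean(axis=0)
        assert np.allclose(mean_emp, mean_ref, atol=0.04)


class TestCentering:
    def test_already_centred_state_unchanged(self):
        data, cands = tiny_problem()
        sam = make_sampler(data, cands, seed=9)
        sam.state.phi -= sam.state.phi.mean(axis=0, keepdims=True)
        sam.state.theta -= sam.state.theta.mean()
        phi0, th0 = sam.state.phi.copy(), sam.state.theta.copy()
        sam.center_effects()
        assert np.allclose(sam.state.phi, phi0, atol=1e-14)
        assert np.allclose(sam.state.theta, th0, atol=1e-14)

    def test_predictor_invariance_and_idempotence(self, rng):
        data, cands = tiny_problem()
        sam = make_sampler(data, cands, seed=10)
        sam.state.phi += rng.normal(0, 1, size=sam.state.phi.shape)
        eta0 = sam.state.eta(data)
        sam.center_effects()
        assert np.allclose(sam.state.phi.mean(axis=0), 0.0, atol=1e-12)
        assert sam.state.theta.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sam.state.eta(data), eta0, atol=1e-12)
        phi1 = sam.state.phi.copy()
        sam.center_effects()
        assert np.allclose(sam.state.phi, phi1, atol=1e-14)


def _grid_candidates(seed=0, M=8, K=10, n=6):
    rng = np.random.default_rng(seed)
    G = AreaGraph(n, [(i, i + 1) for i in range(n - 1)])
    parts = {
        (c, k): Partition(rng.integers(1, k + 1, size=n), k=k)
        for c in range(1, M + 1)
        for k in range(2, K + 1)
    }
    return G, assemble_candidate_set(G, parts, variant="A")


class TestProposeW:
    def test_interior_window(self):
        G, cands = _grid_candidates()
        data = CountData(Y=np.ones((6, 1), int), E=np.ones((6, 1)))
        sam = make_sampler(data, cands, s_window=2)
        assert sam._window(5) == [3, 4, 6, 7]
        assert sam._window(1) == [2, 3]
        assert sam._window(10) == [8, 9]

    def test_k2_truncated_window(self):
        G, cands = _grid_candidates(K=2)
        data = CountData(Y=np.ones((6, 1), int), E=np.ones((6, 1)))
        sam = make_sampler(data, cands, s_window=2)
        assert sam._window(1) == [2]
        assert sam._window(2) == [1]

    def test_hastings_ratio_counts_both_windows(self):
        """Asymmetric boundary windows get the |win(cur)| / |win(prop)| factor."""
        G, cands = _grid_candidates()
        data = CountData(Y=np.ones((6, 1), int), E=np.ones((6, 1)))
        sam = make_sampler(data, cands, s_window=2, seed=11)
        for _ in range(50):
            (c, k_new), log_h = sam.propose_W((4, 3), move=1)
            assert c == 4 and k_new in sam._window(3)
            expected = np.log(len(sam._window(3)) / len(sam._window(k_new)))
            assert log_h == pytest.approx(expected)
        # edge case spelled out: 3 -> 1 has ratio |win(3)| / |win(1)| = 4/2
        assert np.log(len(sam._window(3)) / len(sam._window(1))) == pytest.approx(
            np.log(2.0)
        )

    def test_move2_changes_method_only(self):
        G, cands = _grid_candidates()
        data = CountData(Y=np.ones((6, 1), int), E=np.ones((6, 1)))
        sam = make_sampler(data, cands, seed=12)
        for _ in range(50):
            (c_new, k), log_h = sam.propose_W((3, 5), move=2)
            assert k == 5 and c_new != 3 and 1 <= c_new <= 8
            assert log_h == 0.0

    def test_identity_proposal_always_accepted(self):
        G, cands = _grid_candidates()
        data = CountData(Y=np.ones((6, 2), int), E=np.ones((6, 2)))
        sam = make_sampler(data, cands, seed=13)
        current = sam.state.w_label[0]
        assert sam.accept_W(current, 0.0) is True


class TestRunChain:
    def test_seeded_run_is_bit_reproducible(self):
        data, cands = tiny_problem(n=6, T=3, seed=1)
        cfg = ModelConfig(variant="N", n_iter=400, burn_in=200, thin=2, seed=42)
        s1 = run_chain(data, cands, cfg)
        s2 = run_chain(data, cands, cfg)
        assert np.array_equal(s1.deviance, s2.deviance)
        assert np.array_equal(s1.log_risk, s2.log_risk)
        assert np.array_equal(s1.w_pos, s2.w_pos)

    def test_multi_chain_pools_draws(self):
        data, cands = tiny_problem(n=5, T=2, seed=2)
        cfg = ModelConfig(variant="N", n_iter=300, burn_in=100, thin=2, n_chains=2, seed=0)
        s = run_chain(data, cands, cfg)
        assert s.n_samples == 2 * 100
        assert set(np.unique(s.chain)) == {0, 1}

    def test_border_only_model_never_moves_W(self):
        data, cands = tiny_problem(n=5, T=2, seed=3)
        cfg = ModelConfig(variant="N", n_iter=300, burn_in=100, thin=2, seed=1)
        s = run_chain(data, cands, cfg)
        assert np.all(s.w_pos == 0) and np.all(s.w_k == 1)

    def test_variant_b_with_t1_matches_variant_a_posterior(self, rng):
        """With one period the per-period and shared-matrix models coincide."""
        n = 12
        G = AreaGraph(n, [(i, i + 1) for i in range(n - 1)])
        E = np.full((n, 1), 60.0)
        levels = np.repeat([-0.8, 0.8], 6)
        Y = rng.poisson(E * np.exp(levels)[:, None])
        data = CountData(Y=Y, E=E)
        sign_labels = (levels > 0).astype(np.int64) + 1
        parts_a = {(1, k): Partition(sign_labels, k=k) for k in (2, 3)}
        cands_a = assemble_candidate_set(G, parts_a, variant="A")
        parts_b = {(c, k, 1): p for (c, k), p in parts_a.items()}
        cands_b = assemble_candidate_set(G, parts_b, variant="B", T=1)
        out = {}
        for name, (variant, cands) in {
            "A": ("A", cands_a), "B": ("B", cands_b),
        }.items():
            cfg = ModelConfig(variant=variant, rho_mode="fixed", n_iter=4000,
                              burn_in=2000, thin=2, seed=5)
            s = run_chain(data, cands, cfg)
            out[name] = s
        ra = np.exp(out["A"].log_risk.astype(float)).mean(axis=0)
        rb = np.exp(out["B"].log_risk.astype(float)).mean(axis=0)
        assert np.allclose(ra, rb, atol=0.08)
        # both concentrate on the same (modal) candidate
        ka = np.bincount(out["A"].w_k[:, 0]).argmax()
        kb = np.bincount(out["B"].w_k[:, 0]).argmax()
        assert ka == kb
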