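import numpy as np
import pytest
from scipy.stats import norm

import sparsemet as sm
from sparsemet.met import MetFit, MetModelSpec
from sparsemet.response import OmegaFactor
from sparsemet.stage_one import BlueTable


def make_fit(G, varcomps, Cgg, n=None):
    n = n or G.shape[0]
    return MetFit(
        line_ids=[f"L{i}" for i in range(n)],
        env_names=["E1"],
        mu=0.0,
        varcomps=varcomps,
        v_hat=np.zeros(1),
        g_hat=np.zeros(n),
        gv_hat=np.zeros(0),
        Cgg=Cgg,
        G=G,
        E=None,
        cell_lines=np.arange(0),
        cell_envs=np.arange(0),
        y=np.zeros(0),
    )


def iid_factor(n, rho, sg2=1.0):
    """Omega for independent lines and prediction accuracy rho."""
    I = np.eye(n)
    var_ghat = rho**2 * sg2 * I
    omega = np.block([[sg2 * I, var_ghat], [var_ghat, var_ghat]])
    return sm.factor_omega(omega)


class TestBuildOmega:
    def test_prior_only_limit(self):
        # no data: PEV = G sg2, so var(g_hat) = 0
        G = np.array([[1.0, 0.3], [0.3, 1.0]])
        vc = {"sigma_v2": 1.0, "sigma_g2": 0.5, "sigma_gv2": 0.1, "sigma_e2": 0.2}
        fit = make_fit(G, vc, Cgg=G * vc["sigma_g2"] / vc["sigma_e2"])
        om = sm.build_omega(fit)
        np.testing.assert_allclose(om.omega[:2, :2], G * 0.5, atol=1e-12)
        np.testing.assert_allclose(om.omega[2:, 2:], 0.0, atol=1e-12)

    def test_perfect_information_limit(self):
        G = np.array([[1.0, 0.2], [0.2, 1.0]])
        vc = {"sigma_v2": 1.0, "sigma_g2": 0.5, "sigma_gv2": 0.1, "sigma_e2": 1e-12}
        fit = make_fit(G, vc, Cgg=np.zeros((2, 2)))
        om = sm.build_omega(fit)
        for blk in (om.omega[:2, :2], om.omega[:2, 2:], om.omega[2:, 2:]):
            np.testing.assert_allclose(blk, G * 0.5, atol=1e-9)

    def test_two_line_brute_force_mme_oracle(self):
        # 2 lines observed once each in one environment; Omega from an
        # explicitly inverted coefficient matrix, built from scratch here
        G = np.array([[1.0, 0.5], [0.5, 1.2]])
        vc = {"sigma_v2": 0.4, "sigma_g2": 0.6, "sigma_gv2": 0.3, "sigma_e2": 0.25}
        y = np.array([1.0, -0.5])
        blues = BlueTable(["L0", "L1"], ["E1"], y[:, None])
        fit = sm.fit_met(blues, G, varcomps=vc, spec=MetModelSpec(ridge=1e-12))
        # brute force: W = [1 | Zv | Zg | I], C = W'W + D
        W = np.hstack([np.ones((2, 1)), np.ones((2, 1)), np.eye(2), np.eye(2)])
        C = W.T @ W
        C[1, 1] += vc["sigma_e2"] / vc["sigma_v2"]
        C[2:4, 2:4] += np.linalg.inv(G) * vc["sigma_e2"] / vc["sigma_g2"]
        C[4:6, 4:6] += np.linalg.inv(G) * vc["sigma_e2"] / vc["sigma_gv2"]
        Cinv = np.linalg.inv(C)
        pev = Cinv[2:4, 2:4] * vc["sigma_e2"]
        var_g = G * vc["sigma_g2"]
        expect = np.block([[var_g, var_g - pev], [var_g - pev, var_g - pev]])
        om = sm.build_omega(fit)
        np.testing.assert_allclose(om.omega, expect, atol=1e-7)

    def test_broken_pev_raises(self):
        G = np.eye(2)
        vc = {"sigma_v2": 1.0, "sigma_g2": 0.1, "sigma_gv2": 0.1, "sigma_e2": 1.0}
        fit = make_fit(G, vc, Cgg=np.eye(2))  # PEV = 1 >> G sg2 = 0.1
        with pytest.raises(ValueError, match="PEV"):
            sm.build_omega(fit)


class TestFactorOmega:
    def test_identity_gives_orthonormal_gamma(self):
        fac = sm.factor_omega(np.eye(4))
        np.testing.assert_allclose(fac.gamma @ fac.gamma.T, np.eye(4), atol=1e-12)

    def test_rank_deficient_duplicated_line(self):
        G = np.array([[1.0, 1.0], [1.0, 1.0]])  # duplicated line
        omega = np.block([[G, 0.5 * G], [0.5 * G, 0.5 * G]])
        fac = sm.factor_omega(omega)
        assert fac.n_clipped >= 0
        np.testing.assert_allclose(fac.gamma @ fac.gamma.T, omega, atol=1e-10)

    def test_random_psd_reconstruction(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(6, 6))
        omega = A @ A.T
        fac = sm.factor_omega(omega)
        assert fac.reconstruction_error() < 1e-10

    def test_asymmetric_rejected(self):
        bad = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            sm.factor_omega(bad)

    def test_substantially_negative_rejected(self):
        omega = np.diag([1.0, 1.0, 1.0, -0.5])
        with pytest.raises(ValueError, match="negative eigenvalue"):
            sm.factor_omega(omega)

    def test_pivoted_cholesky_reconstructs(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(8, 5))
        omega = A @ A.T  # rank deficient PSD
        fac = sm.factor_omega(omega, method="pivoted-cholesky")
        np.testing.assert_allclose(fac.gamma @ fac.gamma.T, omega, atol=1e-9)


class TestSimulateResponse:
    def test_select_all_gives_zero_response(self):
        fac = iid_factor(100, rho=0.7)
        rc = sm.simulate_response(fac, ratios=(0.5, 1.0), n_runs=2000, seed=1)
        assert rc.responses[-1] == pytest.approx(0.0, abs=0.05)

    def test_useless_predictor_gives_zero(self):
        fac = iid_factor(100, rho=0.0)
        rc = sm.simulate_response(fac, n_runs=2000, seed=2)
        np.testing.assert_allclose(rc.responses, 0.0, atol=0.05)

    def test_iid_closed_form_selection_intensity(self):
        # response at ratio p ~ rho * sg * phi(z_p) / p for large n
        rho, n = 0.6, 400
        fac = iid_factor(n, rho=rho)
        ratios = (0.1, 0.2, 0.5)
        rc = sm.simulate_response(fac, ratios=ratios, n_runs=3000, seed=3)
        for p, got in zip(ratios, rc.responses):
            expect = rho * norm.pdf(norm.ppf(1 - p)) / p
            assert got == pytest.approx(expect, rel=0.05)

    def test_deterministic_under_seed(self):
        fac = iid_factor(30, rho=0.5)
        a = sm.simulate_response(fac, n_runs=200, seed=4, scenario_id="x")
        b = sm.simulate_response(fac, n_runs=200, seed=4, scenario_id="x")
        np.testing.assert_array_equal(a.responses, b.responses)
        c = sm.simulate_response(fac, n_runs=200, seed=4, scenario_id="y")
        assert not np.array_equal(a.responses, c.responses)

    def test_monotone_nonincreasing_in_ratio(self):
        fac = iid_factor(200, rho=0.8)
        rc = sm.simulate_response(fac, n_runs=5000, seed=5)
        assert (np.diff(rc.responses) <= 1e-6).all()

    def test_bounded_by_perfect_selection(self):
        n, rho = 150, 0.6
        fac = iid_factor(n, rho=rho)
        perfect = iid_factor(n, rho=1.0)
        rc = sm.simulate_response(fac, n_runs=3000, seed=6)
        rp = sm.simulate_response(perfect, n_runs=3000, seed=6)
        assert (rc.responses <= rp.responses + 0.02).all()

    def test_eigen_vs_pivoted_cholesky_samplers_agree(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(20, 20))
        omega = A @ A.T + 0.5 * np.eye(20)
        fe = sm.factor_omega(omega, method="eigen")
        fc = sm.factor_omega(omega, method="pivoted-cholesky")
        n_runs = 4000
        re_ = sm.simulate_response(fe, ratios=(0.2, 0.5), n_runs=n_runs, seed=7)
        rc_ = sm.simulate_response(fc, ratios=(0.2, 0.5), n_runs=n_runs, seed=8)
        # 3 Monte-Carlo SEs: estimate the run-to-run sd from chunked reruns
        sds = []
        for r, base_seed in ((0.2, 100), (0.5, 200)):
            reps = [
                sm.simulate_response(fe, ratios=(r,), n_runs=n_runs // 4, seed=s).responses[0]
                for s in range(base_seed, base_seed + 4)
            ]
            sds.append(np.std(reps, ddof=1) / 2.0)  # scale to n_runs draws
        for got_e, got_c, sd in zip(re_.responses, rc_.responses, sds):
            assert abs(got_e - got_c) <= 3 * max(sd, 1e-4)

    def test_invalid_ratios(self):
        fac = iid_factor(10, rho=0.5)
        with pytest.raises(ValueError):
            sm.simulate_response(fac, ratios=(0.0, 0.5))
        with pytest.raises(ValueError):
            sm.simulate_response(fac, ratios=(0.5, 0.4))


class TestSampleCovarianceCheck:
    def test_two_line_empirical_covariance(self):
        G = np.array([[1.0, 0.4], [0.4, 1.0]])
        omega = np.block([[G, 0.6 * G], [0.6 * G, 0.6 * G]])
        fac = sm.factor_omega(omega)
        diag = sm.sample_covariance_check(fac, n_draws=20000, seed=1)
        assert diag["max_rel_error"] < 0.05

    def test_diagonal_omega_cross_covariances_near_zero(self):
        fac = sm.factor_omega(np.diag([1.0, 2.0, 3.0, 4.0]))
        diag = sm.sample_covariance_check(fac, n_draws=20000, seed=2)
        emp = diag["empirical_covariance"]
        off = emp[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_fixed_seed_reproducible(self):
        fac = iid_factor(5, rho=0.5)
        a = sm.sample_covariance_check(fac, n_draws=1000, seed=3)
        b = sm.sample_covariance_check(fac, n_draws=1000, seed=3)
        np.testing.assert_array_equal(
            a["empirical_covariance"], b["empirical_covariance"]
        )
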