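"""Integrated-model likelihoods, fitting, prediction and driver effects."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom

import pestscape as ps
from pestscape.isdm import _Assembler, binomial_cloglog_loglik, cell_quadrature


def _zero_state(mesh) -> ps.LatentState:
    return ps.LatentState(0.0, 0.0, {}, np.zeros(mesh.n_nodes), None, mesh)


@pytest.fixture(scope="module")
def tiny_setup():
    grid = ps.GridSpec(10, 10, 1.0)
    rng = np.random.default_rng(0)
    cov = ps.Raster(grid, rng.normal(size=grid.shape), "x").standardize()
    mesh = ps.build_mesh(grid, 2.0, extension_km=4.0)
    return grid, {"x": cov}, mesh


class TestLinearPredictor:
    def test_zero_state_gives_zero(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        eta = ps.linear_predictor(_zero_state(mesh), covs, grid.center_points())
        np.testing.assert_allclose(eta, 0.0)

    def test_unit_beta_identity_on_covariate(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        state = ps.LatentState(0.0, 0.0, {"x": 1.0}, np.zeros(mesh.n_nodes),
                               None, mesh)
        eta = ps.linear_predictor(state, covs, grid.center_points())
        np.testing.assert_allclose(eta, covs["x"].values.ravel(), atol=1e-12)

    def test_additivity_in_state(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        rng = np.random.default_rng(1)
        xi1, xi2 = rng.normal(size=(2, mesh.n_nodes))
        pts = ps.sample_sites(grid, 17, seed=2)
        s1 = ps.LatentState(0.5, 0.0, {"x": 1.0}, xi1, None, mesh)
        s2 = ps.LatentState(-0.2, 0.0, {"x": -0.3}, xi2, None, mesh)
        s12 = ps.LatentState(0.3, 0.0, {"x": 0.7}, xi1 + xi2, None, mesh)
        eta = ps.linear_predictor(s12, covs, pts)
        np.testing.assert_allclose(
            eta,
            ps.linear_predictor(s1, covs, pts) + ps.linear_predictor(s2, covs, pts),
            atol=1e-10)

    def test_pb_stream_adds_bias_field(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        b = np.full(mesh.n_nodes, 0.4)
        state = ps.LatentState(0.0, 0.0, {}, np.zeros(mesh.n_nodes), b, mesh)
        pts = grid.center_points()[:5]
        np.testing.assert_allclose(
            ps.linear_predictor(state, covs, pts, "pb")
            - ps.linear_predictor(state, covs, pts, "pa"), 0.4, atol=1e-12)


class TestPaLoglik:
    def test_certain_absence_has_probability_one(self):
        ll = binomial_cloglog_loglik(np.full(5, -40.0), np.full(5, 3),
                                     np.zeros(5))
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_single_bernoulli_closed_form(self):
        # n=1, k=1, e_vis*lambda=1: log(1 - e^{-1})
        ll = binomial_cloglog_loglik(np.array([0.0]), np.array([1]),
                                     np.array([1]))
        assert ll == pytest.approx(np.log(1 - np.exp(-1)), abs=1e-12)

    def test_matches_naive_binomial_pmf(self):
        rng = np.random.default_rng(3)
        # keep p away from exact 0/1 so the reference pmf stays finite
        eta = rng.uniform(-3.0, 2.5, size=100)
        n = rng.integers(1, 10, size=100)
        k = rng.integers(0, n + 1)
        p = -np.expm1(-np.exp(eta))
        naive = binom.logpmf(k, n, p).sum()
        assert binomial_cloglog_loglik(eta, n, k) == pytest.approx(naive, rel=1e-10)


class TestPbLoglik:
    def test_homogeneous_closed_form(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        lam = ps.Raster(grid, np.full(grid.shape, np.exp(0.3)))
        pb = ps.simulate_pb_points(lam, None, seed=5)
        state = ps.LatentState(0.0, 0.3, {}, np.zeros(mesh.n_nodes), None, mesh)
        ll = ps.pb_loglik(state, pb, covs, cell_quadrature(grid))
        expected = len(pb) * 0.3 - 100.0 * np.exp(0.3)
        assert ll == pytest.approx(expected, rel=1e-9)
        # ... and is maximized at eta0 = ln(n/|D|)
        etas = np.linspace(-1, 1, 41)
        lls = [len(pb) * e - 100.0 * np.exp(e) for e in etas]
        assert abs(etas[np.argmax(lls)] - np.log(len(pb) / 100.0)) < 0.06

    def test_zero_bias_field_equals_absent_bias(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        lam = ps.Raster(grid, np.ones(grid.shape))
        pb = ps.simulate_pb_points(lam, None, seed=6)
        xi = np.random.default_rng(7).normal(size=mesh.n_nodes)
        with_b = ps.LatentState(0.0, 0.1, {"x": 0.5}, xi,
                                np.zeros(mesh.n_nodes), mesh)
        without = ps.LatentState(0.0, 0.1, {"x": 0.5}, xi, None, mesh)
        q = cell_quadrature(grid)
        assert ps.pb_loglik(with_b, pb, covs, q) == pytest.approx(
            ps.pb_loglik(without, pb, covs, q), rel=1e-12)

    def test_quadrature_refinement_stable(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        # smooth surface: gentle linear trend in x
        cx, _ = grid.cell_centers()
        lam = ps.Raster(grid, np.exp(-1.0 + 0.05 * cx))
        pb = ps.simulate_pb_points(lam, None, seed=8)
        # smooth eta through the field basis: xi linear in x across the mesh
        xi = 0.05 * mesh.node_coords()[:, 0]
        state = ps.LatentState(0.0, -1.0, {}, xi, None, mesh)
        coarse = ps.pb_loglik(state, pb, covs, cell_quadrature(grid, 1))
        fine = ps.pb_loglik(state, pb, covs, cell_quadrature(grid, 2))
        # the point term is identical, so the difference is the integral term
        total_integral = 100.0 * np.exp(-1.0) * np.mean(np.exp(0.05 * cx))
        assert abs(coarse - fine) / total_integral < 0.005

    def test_separability_matches_fit_joint_loglik(self, tiny_setup):
        grid, covs, mesh = tiny_setup
        lam = ps.Raster(grid, np.exp(-0.5 + 0.8 * covs["x"].values))
        pb = ps.simulate_pb_points(lam, None, seed=9)
        sites = ps.sample_sites(grid, 40, seed=10)
        pa = ps.simulate_pa_surveys(lam, sites, np.full(40, 2), 1.0, seed=11)
        cfg = ps.IsdmConfig(covariates=("x",), max_edge_km=2.0,
                            extension_km=4.0, bias_field=False)
        asm = _Assembler(covs, pa, pb, cfg)
        rng = np.random.default_rng(12)
        x = rng.normal(scale=0.3, size=asm.n)
        ll_joint, _, _ = asm.loglik_parts(x)
        nfix = len(asm.fixed_names)
        state = ps.LatentState(x[0], x[1], {"x": x[2]}, x[nfix:], None, asm.mesh)
        ll_split = (ps.pa_loglik(state, pa, covs, cfg.e_vis)
                    + ps.pb_loglik(state, pb, covs, cell_quadrature(grid)))
        assert ll_joint == pytest.approx(ll_split, rel=1e-9)


class TestFitIsdm:
    def test_all_zero_covariate_is_prior_dominated(self, integrated_dataset):
        grid, covs, pa, pb, truth = integrated_dataset
        cfg = ps.IsdmConfig(covariates=("x1", "x2"), max_edge_km=5.0,
                            bias_field=False, hyper_maxiter=25)
        fit0 = ps.fit_isdm(covs, pa, pb, cfg)
        covs2 = dict(covs)
        covs2["nil"] = ps.Raster(grid, np.zeros(grid.shape), "nil")
        fit1 = ps.fit_isdm(covs2, pa, pb,
                           replace(cfg, covariates=("x1", "x2", "nil")))
        for c in ("x1", "x2"):
            assert fit1.coef(c)["mean"] == pytest.approx(
                fit0.coef(c)["mean"], abs=1e-6)
        nil = fit1.coef("nil")
        assert nil["mean"] == pytest.approx(0.0, abs=1e-8)
        assert nil["sd"] == pytest.approx(1.0, abs=1e-6)  # prior sd

    def test_single_replicate_recovery(self, integrated_fit):
        fit = integrated_fit
        assert abs(fit.coef("x1")["mean"] - 1.0) <= 3 * fit.coef("x1")["sd"]
        assert abs(fit.coef("x2")["mean"] + 0.5) <= 3 * fit.coef("x2")["sd"]

    def test_logpost_trace_monotone(self, integrated_fit):
        trace = np.array(integrated_fit.logpost_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_interval_ordering(self, integrated_fit):
        s = integrated_fit.summary
        assert (s["q2.5"] <= s["mean"]).all() and (s["mean"] <= s["q97.5"]).all()

    def test_empty_streams_rejected(self, tiny_setup):
        _, covs, _ = tiny_setup
        with pytest.raises(ValueError):
            ps.fit_isdm(covs, None, None, ps.IsdmConfig(covariates=("x",)))


class TestPrediction:
    def test_mean_positive_and_sd_nonnegative(self, integrated_dataset,
                                              integrated_fit):
        grid, covs, *_ = integrated_dataset
        out = ps.GridSpec(10, 10, 5.0)
        mean, sd = ps.predict_intensity(integrated_fit, covs, out)
        assert (mean.values > 0).all()
        assert (sd.values >= 0).all()

    def test_lognormal_moments_match_monte_carlo(self, integrated_dataset,
                                                 integrated_fit):
        grid, covs, *_ = integrated_dataset
        out = ps.GridSpec(5, 5, 10.0)
        mean, sd = ps.predict_intensity(integrated_fit, covs, out)
        from pestscape.isdm import _prediction_design
        A = _prediction_design(integrated_fit, covs, out.center_points())
        mu = A @ integrated_fit.xhat
        v = np.einsum("ij,ij->i", A @ integrated_fit.Sigma, A.toarray())
        rng = np.random.default_rng(0)
        draws = np.exp(mu[None, :] + np.sqrt(v)[None, :]
                       * rng.standard_normal((200_000, len(mu))))
        np.testing.assert_allclose(mean.values.ravel(), draws.mean(axis=0),
                                   rtol=0.02)
        np.testing.assert_allclose(sd.values.ravel(), draws.std(axis=0),
                                   rtol=0.05)

    def test_rescale_unit_contract(self, integrated_dataset, integrated_fit):
        grid, covs, *_ = integrated_dataset
        mean, sd = ps.predict_intensity(integrated_fit, covs,
                                        ps.GridSpec(10, 10, 5.0))
        m01, s01 = ps.rescale_unit(mean, sd)
        assert m01.values.min() == pytest.approx(0.0)
        assert m01.values.max() == pytest.approx(1.0)
        order = np.argsort(mean.values.ravel())
        assert np.array_equal(order, np.argsort(m01.values.ravel()))
        ratio = s01.values / sd.values
        np.testing.assert_allclose(ratio, ratio.ravel()[0])

    def test_rescale_constant_rejected(self, small_grid):
        r = ps.Raster(small_grid, np.ones(small_grid.shape))
        with pytest.raises(ValueError):
            ps.rescale_unit(r, r)


@pytest.fixture(scope="module")
def confounded_study():
    grid = ps.GridSpec(50, 50, 1.0)
    dag = ps.parse_dag(
        "Z -> X\nZ -> p_e\nX -> p_e\np_e -> y\nlatent: p_e")
    scm = ps.ScmSpec(dag.induced({"Z", "X"}), {("Z", "X"): 1.0}, seed=21)
    raw = ps.simulate_covariate_fields(grid, scm)
    sx = float(np.std(raw["X"].values))
    covs = ps.stack_standardize(raw)
    loglam = -1.5 + 0.7 * raw["X"].values + 1.0 * raw["Z"].values
    lam = ps.Raster(grid, np.exp(loglam))
    pb = ps.simulate_pb_points(lam, None, seed=22)
    sites = ps.sample_sites(grid, 300, seed=23)
    pa = ps.simulate_pa_surveys(lam, sites,
                                ps.sample_visit_counts(300, seed=24),
                                1.0, seed=25)
    truth_std = 0.7 * sx  # total effect on the standardized-X scale
    return dag, covs, pa, pb, truth_std


class TestDriverEffects:
    def test_adjusted_recovers_unadjusted_biased(self, confounded_study):
        dag, covs, pa, pb, truth = confounded_study
        cfg = ps.IsdmConfig(max_edge_km=5.0, bias_field=False, hyper_maxiter=30)
        effs = ps.estimate_driver_effect("X", dag, covs, pa, pb, cfg)
        assert len(effs) == 1 and effs[0].adjustment_set == {"Z"}
        assert abs(effs[0].mean - truth) <= 2 * effs[0].sd
        fit_un = ps.fit_isdm(covs, pa, pb, replace(cfg, covariates=("X",)))
        un = fit_un.coef("X")
        assert abs(un["mean"] - truth) > 2 * un["sd"]

    def test_no_backdoor_focal_matches_unadjusted(self, integrated_dataset):
        grid, covs, pa, pb, truth = integrated_dataset
        dag = ps.parse_dag("x1 -> p_e\nx2 -> p_e\np_e -> y\nlatent: p_e")
        cfg = ps.IsdmConfig(max_edge_km=5.0, bias_field=False, hyper_maxiter=25)
        effs = ps.estimate_driver_effect("x1", dag, covs, pa, pb, cfg)
        assert effs[0].adjustment_set == frozenset()
        fit_un = ps.fit_isdm(covs, pa, pb, replace(cfg, covariates=("x1",)))
        assert effs[0].mean == pytest.approx(fit_un.coef("x1")["mean"], abs=1e-8)

    def test_mediator_excluded_from_fitted_sets(self):
        dag = ps.parse_dag("X -> M\nM -> p_e\nX -> p_e\np_e -> y\nlatent: p_e")
        res = ps.minimal_adjustment_sets(dag, "X")
        assert all("M" not in s for s in res.sets)
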