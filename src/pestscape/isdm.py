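"""The integrated species distribution model (ISDM).

One latent log-Gaussian Cox process drives both observation streams:

* log λ(s) = α + Σ_k β_k x_k(s) + ξ(s), with ξ a Matérn SPDE field;
* presence–absence sites observe Binomial(n_surveys, p) detections with the
  complementary log–log link p = 1 − exp(−e_vis·λ);
* presence-background points follow a thinned Poisson process whose
  log-intensity adds a second Matérn field b (observation bias) and a
  stream-specific intercept.

Inference is empirical-Bayes Laplace: for fixed field hyperparameters the
latent Gaussian state (intercepts, coefficients, field node values) is
maximized by a damped Newton iteration and approximated by a Gaussian at
the mode; the hyperparameters (σ, ρ) of both fields maximize the resulting
Laplace marginal likelihood plus their penalised-complexity priors.
Fixed effects and intercepts carry normal(0, precision 1) priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .causal import Dag, minimal_adjustment_sets
from .fields import (HyperParams, MeshBasis, SparseCholesky, build_mesh,
                     matern_precision, pc_prior_logdensity)
from .grids import GridSpec, Raster
from .io import validate_pa_table, validate_pb_points

_ETA_MAX = 40.0  # clamp for exponentials on the linear-predictor scale


class ConvergenceError(RuntimeError):
    """The inner Newton iteration failed to converge (diagnostics in args)."""


@dataclass(frozen=True)
class PriorSpec:
    """PC-prior thresholds for one Matérn field: p(σ>σ0)=ασ, p(ρ<ρ0)=αρ."""

    sigma0: float = 1.0
    alpha_sigma: float = 0.05
    rho0: float = 10.0
    alpha_rho: float = 0.05


@dataclass(frozen=True)
class IsdmConfig:
    """Configuration of one integrated model fit."""

    covariates: tuple[str, ...] = ()
    max_edge_km: float = 5.0
    extension_km: float | None = None
    e_vis: float = 1.0
    process_field: bool = True
    bias_field: bool = True
    prior: PriorSpec = PriorSpec()
    bias_prior: PriorSpec = PriorSpec()
    fixed_effect_precision: float = 1.0
    hyper_init: tuple[float, float] = (0.5, 15.0)  # (sigma, rho) start
    hyper_maxiter: int = 60
    newton_maxiter: int = 100
    newton_tol: float = 1e-8
    seed: int = 0


@dataclass
class LatentState:
    """One configuration of the latent Gaussian state (for direct likelihood
    evaluation; fitting works on the packed vector internally)."""

    alpha_pa: float
    alpha_pb: float
    beta: dict[str, float]
    xi: np.ndarray
    b: np.ndarray | None
    mesh: MeshBasis


def linear_predictor(state: LatentState, covariates: dict[str, Raster],
                     locations: np.ndarray, stream: str = "pa") -> np.ndarray:
    """η(s) for either observation stream at arbitrary locations.

    The PA stream uses α_PA and the shared field; the PB stream uses α_PB
    and adds the bias field b.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if stream not in ("pa", "pb"):
        raise ValueError("stream must be 'pa' or 'pb'")
    eta = np.full(len(locations), state.alpha_pa if stream == "pa" else state.alpha_pb)
    for name, b_k in state.beta.items():
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r}")
        eta = eta + b_k * covariates[name].value_at(locations)
    proj = state.mesh.projector(locations)
    eta = eta + proj @ state.xi
    if stream == "pb" and state.b is not None:
        eta = eta + proj @ state.b
    return eta


def _cloglog_mu(eta: np.ndarray, e_vis: float) -> np.ndarray:
    return np.exp(np.clip(eta + math.log(e_vis), -_ETA_MAX, _ETA_MAX))


def binomial_cloglog_loglik(eta: np.ndarray, n: np.ndarray, k: np.ndarray,
                            e_vis: float = 1.0) -> float:
    """Σ log Binomial(k | n, 1 − exp(−e_vis·exp(η))); safe at extreme η."""
    from scipy.special import gammaln

    mu = _cloglog_mu(np.asarray(eta, dtype=float), e_vis)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    # log p = log(1 - e^{-mu}); log(1-p) = -mu
    log_p = np.log(np.clip(-np.expm1(-mu), 1e-300, None))
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + k * log_p - (n - k) * mu))


def pa_loglik(state: LatentState, pa: pd.DataFrame,
              covariates: dict[str, Raster], e_vis: float = 1.0) -> float:
    """Presence–absence log-likelihood of a latent state (up to the
    binomial-coefficient constant)."""
    validate_pa_table(pa)
    eta = linear_predictor(state, covariates, pa[["x_km", "y_km"]].to_numpy(), "pa")
    return binomial_cloglog_loglik(eta, pa["n_surveys"].to_numpy(),
                                   pa["n_detections"].to_numpy(), e_vis)


def pb_loglik(state: LatentState, pb: pd.DataFrame,
              covariates: dict[str, Raster],
              quadrature: tuple[np.ndarray, np.ndarray]) -> float:
    """Thinned-Poisson log-density of the PB point pattern (up to a
    data-only constant): Σ_points η − Σ_quad w·exp(η)."""
    validate_pb_points(pb)
    q_pts, q_w = quadrature
    eta_pts = linear_predictor(state, covariates, pb[["x_km", "y_km"]].to_numpy(), "pb")
    eta_q = linear_predictor(state, covariates, q_pts, "pb")
    return float(eta_pts.sum() - np.sum(q_w * np.exp(np.clip(eta_q, -_ETA_MAX, _ETA_MAX))))


def cell_quadrature(grid: GridSpec,
                    refine: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Berman–Turner quadrature: cell centres weighted by cell areas.

    ``refine`` subdivides each cell into ``refine²`` equal sub-cells for a
    finer integration rule.
    """
    if refine < 1:
        raise ValueError("refine must be >= 1")
    if refine == 1:
        pts = grid.center_points()
        return pts, np.full(len(pts), grid.cell_area_km2)
    sub = GridSpec(grid.nrows * refine, grid.ncols * refine,
                   grid.cell_km / refine, grid.origin)
    pts = sub.center_points()
    return pts, np.full(len(pts), sub.cell_area_km2)


# --------------------------------------------------------------------------
# fitting

@dataclass
class IsdmFit:
    """A fitted integrated model: posterior mode, Gaussian covariance and
    hyperparameter estimates."""

    config: IsdmConfig
    mesh: MeshBasis
    covariate_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    xhat: np.ndarray
    Sigma: np.ndarray  # dense posterior covariance of the latent state
    slices: dict[str, slice]
    hyper: dict[str, HyperParams | None]
    log_marginal: float
    logpost_trace: list[float]
    has_pa: bool
    has_pb: bool
    covariate_grid: GridSpec

    @property
    def n_latent(self) -> int:
        return len(self.xhat)

    @property
    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and 95% interval for intercepts and
        coefficients (Gaussian marginals: mean ± 1.96 sd)."""
        sl = self.slices["fixed"]
        mean = self.xhat[sl]
        sd = np.sqrt(np.diag(self.Sigma)[sl])
        return pd.DataFrame({
            "mean": mean, "sd": sd,
            "q2.5": mean - 1.96 * sd, "q97.5": mean + 1.96 * sd,
        }, index=list(self.fixed_names))

    def coef(self, name: str) -> pd.Series:
        return self.summary.loc[f"beta_{name}"]

    def state(self) -> LatentState:
        """Unpack the posterior mode into a :class:`LatentState`."""
        names = list(self.fixed_names)
        x = self.xhat
        a_pa = x[names.index("alpha_pa")] if "alpha_pa" in names else 0.0
        a_pb = x[names.index("alpha_pb")] if "alpha_pb" in names else 0.0
        beta = {c: x[names.index(f"beta_{c}")] for c in self.covariate_names}
        xi = x[self.slices["xi"]] if "xi" in self.slices else np.zeros(self.mesh.n_nodes)
        b = x[self.slices["b"]] if "b" in self.slices else None
        return LatentState(a_pa, a_pb, beta, xi, b, self.mesh)


class _Assembler:
    """Precomputed design matrices and data vectors for one model fit."""

    def __init__(self, covariates: dict[str, Raster], pa: pd.DataFrame | None,
                 pb: pd.DataFrame | None, config: IsdmConfig):
        if (pa is None or len(pa) == 0) and (pb is None or len(pb) == 0):
            raise ValueError("at least one data stream must be non-empty")
        missing = [c for c in config.covariates if c not in covariates]
        if missing:
            raise KeyError(f"covariates not in stack: {missing}")
        self.config = config
        self.has_pa = pa is not None and len(pa) > 0
        self.has_pb = pb is not None and len(pb) > 0
        self.use_bias = config.bias_field and self.has_pb
        self.use_field = config.process_field

        some = covariates[config.covariates[0]] if config.covariates else None
        if some is None:
            raise_grid = pa if self.has_pa else pb
            # no covariates: infer the domain from the data bounding box
            xs = raise_grid[["x_km", "y_km"]].to_numpy()
            lo = np.floor(xs.min(axis=0))
            hi = np.ceil(xs.max(axis=0))
            self.grid = GridSpec(int(max(2, hi[1] - lo[1])), int(max(2, hi[0] - lo[0])),
                                 1.0, (float(lo[0]), float(lo[1])))
        else:
            self.grid = some.grid
        self.mesh = build_mesh(self.grid, config.max_edge_km,
                               extension_km=config.extension_km)

        self.fixed_names: list[str] = []
        if self.has_pa:
            self.fixed_names.append("alpha_pa")
        if self.has_pb:
            self.fixed_names.append("alpha_pb")
        self.fixed_names += [f"beta_{c}" for c in config.covariates]
        nfix = len(self.fixed_names)
        m = self.mesh.n_nodes
        self.slices = {"fixed": slice(0, nfix)}
        pos = nfix
        if self.use_field:
            self.slices["xi"] = slice(pos, pos + m)
            pos += m
        if self.use_bias:
            self.slices["b"] = slice(pos, pos + m)
            pos += m
        self.n = pos

        def design(points: np.ndarray, stream: str) -> sparse.csr_matrix:
            npts = len(points)
            cols = []
            fixed = np.zeros((npts, nfix))
            if self.has_pa:
                fixed[:, self.fixed_names.index("alpha_pa")] = 1.0 if stream == "pa" else 0.0
            if self.has_pb:
                fixed[:, self.fixed_names.index("alpha_pb")] = 1.0 if stream == "pb" else 0.0
            for j, c in enumerate(config.covariates):
                fixed[:, nfix - len(config.covariates) + j] = covariates[c].value_at(points)
            cols.append(sparse.csr_matrix(fixed))
            proj = self.mesh.projector(points)
            if self.use_field:
                cols.append(proj)
            if self.use_bias:
                cols.append(proj if stream == "pb" else
                            sparse.csr_matrix((npts, m)))
            return sparse.hstack(cols).tocsr()

        if self.has_pa:
            validate_pa_table(pa)
            self.pa_n = pa["n_surveys"].to_numpy(dtype=float)
            self.pa_k = pa["n_detections"].to_numpy(dtype=float)
            self.A_pa = design(pa[["x_km", "y_km"]].to_numpy(), "pa")
        if self.has_pb:
            validate_pb_points(pb)
            pts = pb[["x_km", "y_km"]].to_numpy()
            if not self.grid.contains(pts).all():
                raise ValueError("PB point(s) outside the modelled domain")
            self.A_pt = design(pts, "pb")
            q_pts, q_w = cell_quadrature(self.grid)
            self.q_w = q_w
            self.A_q = design(q_pts, "pb")

    # -- likelihood pieces on the packed vector --

    def loglik_parts(self, x: np.ndarray):
        """(loglik, gradient, negative-Hessian weight diagonals per block)."""
        ll = 0.0
        grad = np.zeros(self.n)
        hess_blocks = []
        e_vis = self.config.e_vis
        if self.has_pa:
            eta = self.A_pa @ x
            ll += binomial_cloglog_loglik(eta, self.pa_n, self.pa_k, e_vis)
            mu = _cloglog_mu(eta, e_vis)
            g = 1.0 / np.clip(np.expm1(mu), 1e-300, None)  # e^{-mu}/(1-e^{-mu})
            dl = mu * (self.pa_k * g - (self.pa_n - self.pa_k))
            d2l = dl - mu**2 * self.pa_k * (g + g**2)
            grad += self.A_pa.T @ dl
            hess_blocks.append((self.A_pa, np.maximum(-d2l, 0.0)))
        if self.has_pb:
            eta_pt = self.A_pt @ x
            ll += float(eta_pt.sum())
            grad += np.asarray(self.A_pt.sum(axis=0)).ravel()
            eta_q = np.clip(self.A_q @ x, -_ETA_MAX, _ETA_MAX)
            lam_q = self.q_w * np.exp(eta_q)
            ll -= float(lam_q.sum())
            grad -= self.A_q.T @ lam_q
            hess_blocks.append((self.A_q, lam_q))
        return ll, grad, hess_blocks

    def prior_precision(self, hyper: dict[str, HyperParams | None]) -> tuple[sparse.csc_matrix, float]:
        """Q0 over the latent vector and the log-determinant of its field
        blocks (the fixed-effect block is hyperparameter-free)."""
        blocks = [sparse.eye(len(self.fixed_names)) * self.config.fixed_effect_precision]
        logdet = 0.0
        if self.use_field:
            Qx = matern_precision(self.mesh, hyper["process"])
            blocks.append(Qx.Q)
            logdet += SparseCholesky(Qx.Q).logdet
        if self.use_bias:
            Qb = matern_precision(self.mesh, hyper["bias"])
            blocks.append(Qb.Q)
            logdet += SparseCholesky(Qb.Q).logdet
        return sparse.block_diag(blocks, format="csc"), logdet

    def newton(self, Q0: sparse.csc_matrix, x0: np.ndarray | None = None):
        """Damped Newton ascent of the joint log posterior over the latent
        state. Returns (xhat, H factorization, logpost trace)."""
        cfg = self.config
        x = np.zeros(self.n) if x0 is None else x0.copy()

        def logpost(xv):
            ll, grad, hb = self.loglik_parts(xv)
            return ll - 0.5 * float(xv @ (Q0 @ xv)), grad - Q0 @ xv, hb

        lp, grad, hb = logpost(x)
        trace = [lp]
        chol = None
        for _ in range(cfg.newton_maxiter):
            H = Q0.copy()
            for A, w in hb:
                if w.size:
                    H = H + A.T @ sparse.diags(w) @ A
            chol = SparseCholesky(H.tocsc())
            step = chol.solve(grad)
            t = 1.0
            for _ls in range(30):
                xn = x + t * step
                lpn, gradn, hbn = logpost(xn)
                if lpn >= lp - 1e-12:
                    break
                t *= 0.5
            else:
                raise ConvergenceError("line search failed", trace)
            moved = np.max(np.abs(t * step))
            x, grad, hb = xn, gradn, hbn
            trace.append(max(lpn, lp))
            converged = (lpn - lp) < cfg.newton_tol * (1.0 + abs(lpn)) and moved < 1e-6
            lp = lpn
            if converged:
                break
        else:
            raise ConvergenceError(
                f"Newton did not converge in {cfg.newton_maxiter} iterations", trace)
        return x, chol, trace


def _laplace_lml(asm: _Assembler, hyper: dict[str, HyperParams | None],
                 x0: np.ndarray | None):
    Q0, logdet_q = asm.prior_precision(hyper)
    xhat, chol, trace = asm.newton(Q0, x0)
    ll, _, _ = asm.loglik_parts(xhat)
    lml = (ll - 0.5 * float(xhat @ (Q0 @ xhat))
           + 0.5 * logdet_q - 0.5 * chol.logdet)
    return lml, xhat, chol, trace


def fit_isdm(covariates: dict[str, Raster], pa: pd.DataFrame | None,
             pb: pd.DataFrame | None, config: IsdmConfig) -> IsdmFit:
    """Fit the integrated model by empirical-Bayes Laplace approximation.

    The field hyperparameters (σ, ρ) of the process field — and of the PB
    bias field when active — are chosen by Nelder–Mead maximization of the
    Laplace marginal likelihood plus PC priors (on the log scale, with the
    change-of-variables Jacobian); the latent state is then summarized by
    its Gaussian approximation at the mode.
    """
    asm = _Assembler(covariates, pa, pb, config)
    warm: dict = {"x": None}

    def unpack(theta: np.ndarray) -> dict[str, HyperParams | None]:
        out: dict[str, HyperParams | None] = {"process": None, "bias": None}
        i = 0
        if asm.use_field:
            out["process"] = HyperParams(math.exp(theta[i]), math.exp(theta[i + 1]))
            i += 2
        if asm.use_bias:
            out["bias"] = HyperParams(math.exp(theta[i]), math.exp(theta[i + 1]))
        return out

    n_theta = 2 * (asm.use_field + asm.use_bias)
    if n_theta:
        s0, r0 = config.hyper_init

        def neg_obj(theta: np.ndarray) -> float:
            if np.any(np.abs(theta) > 12):
                return 1e10
            hyper = unpack(theta)
            try:
                lml, xh, _, _ = _laplace_lml(asm, hyper, warm["x"])
            except (ConvergenceError, RuntimeError):
                return 1e10
            warm["x"] = xh
            obj = lml
            for key, pr in (("process", config.prior), ("bias", config.bias_prior)):
                hp = hyper[key]
                if hp is not None:
                    obj += pc_prior_logdensity(hp, pr.sigma0, pr.alpha_sigma,
                                               pr.rho0, pr.alpha_rho)
                    obj += math.log(hp.sigma) + math.log(hp.rho)  # log-scale Jacobian
            return -obj

        theta0 = np.array([math.log(s0), math.log(r0)] * (n_theta // 2))
        res = optimize.minimize(neg_obj, theta0, method="Nelder-Mead",
                                options=dict(maxiter=config.hyper_maxiter,
                                             xatol=0.05, fatol=0.05))
        hyper = unpack(res.x)
    else:
        hyper = {"process": None, "bias": None}

    lml, xhat, chol, trace = _laplace_lml(asm, hyper, warm["x"])
    # dense posterior covariance of the latent state (sizes are desk-scale)
    H = np.zeros((asm.n, asm.n))
    eye = np.eye(asm.n)
    for j in range(asm.n):
        H[:, j] = chol.solve(eye[:, j])
    Sigma = 0.5 * (H + H.T)
    fit = IsdmFit(
        config=config, mesh=asm.mesh,
        covariate_names=tuple(config.covariates),
        fixed_names=tuple(asm.fixed_names),
        xhat=xhat, Sigma=Sigma, slices=asm.slices, hyper=hyper,
        log_marginal=float(lml), logpost_trace=trace,
        has_pa=asm.has_pa, has_pb=asm.has_pb, covariate_grid=asm.grid,
    )
    if asm.has_pa:
        fit._pa_design = asm.A_pa  # retained for pointwise WAIC draws
    return fit


# --------------------------------------------------------------------------
# prediction and effects

def _prediction_design(fit: IsdmFit, covariates: dict[str, Raster],
                       points: np.ndarray) -> sparse.csr_matrix:
    """Design matrix of the *process* linear predictor at points: the
    shared intercept scale, covariates and ξ; the bias field is excluded
    (it models observation, not ecology)."""
    nfix = len(fit.fixed_names)
    fixed = np.zeros((len(points), nfix))
    # one reference intercept: the PB stream's if present, else the PA one
    anchor = "alpha_pb" if "alpha_pb" in fit.fixed_names else "alpha_pa"
    fixed[:, fit.fixed_names.index(anchor)] = 1.0
    for c in fit.covariate_names:
        fixed[:, fit.fixed_names.index(f"beta_{c}")] = covariates[c].value_at(points)
    cols = [sparse.csr_matrix(fixed)]
    if "xi" in fit.slices:
        cols.append(fit.mesh.projector(points))
    if "b" in fit.slices:
        cols.append(sparse.csr_matrix((len(points), fit.mesh.n_nodes)))
    return sparse.hstack(cols).tocsr()


def predict_intensity(fit: IsdmFit, covariates: dict[str, Raster],
                      out_grid: GridSpec) -> tuple[Raster, Raster]:
    """Posterior mean and sd rasters of the intensity surface.

    η is Gaussian at each cell centre under the Laplace approximation, so
    λ = exp(η) has lognormal moments: mean = exp(μ + v/2),
    sd = mean·√(exp(v) − 1). The intensity scale is relative (the intercept
    anchors it to the PB reporting rate); 0–1 rescaling removes the scale.
    """
    pts = out_grid.center_points()
    A = _prediction_design(fit, covariates, pts)
    mu = A @ fit.xhat
    AS = A @ fit.Sigma
    v = np.maximum(np.einsum("ij,ij->i", AS, A.toarray()), 0.0)
    mean = np.exp(np.clip(mu + v / 2.0, -_ETA_MAX, _ETA_MAX))
    sd = mean * np.sqrt(np.expm1(v))
    return (Raster(out_grid, mean.reshape(out_grid.shape), "intensity_mean"),
            Raster(out_grid, sd.reshape(out_grid.shape), "intensity_sd"))


def rescale_unit(mean: Raster, sd: Raster) -> tuple[Raster, Raster]:
    """Rescale the mean map to 0–1 and the sd map by the same factor.

    mean01 = (mean − min)/(max − min); sd01 = sd/(max − min): one positive
    scale factor, no shift, so cell ranking and relative uncertainty are
    preserved.
    """
    vals = mean.values
    finite = vals[np.isfinite(vals)]
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise ValueError("mean raster is constant; cannot rescale to 0-1")
    scale = hi - lo
    return (mean.copy_with((vals - lo) / scale, name=f"{mean.name}_01"),
            sd.copy_with(sd.values / scale, name=f"{sd.name}_01"))


@dataclass(frozen=True)
class EffectEstimate:
    """Posterior summary of one focal driver under one adjustment set."""

    focal: str
    adjustment_set: frozenset[str]
    mean: float
    sd: float
    lo95: float
    hi95: float


def estimate_driver_effect(focal: str, maximal_dag: Dag,
                           covariates: dict[str, Raster],
                           pa: pd.DataFrame | None, pb: pd.DataFrame | None,
                           config: IsdmConfig,
                           outcome: str = "y") -> list[EffectEstimate]:
    """Total-effect estimates of a focal driver, one per minimal back-door
    adjustment set.

    Each adjustment set implies one ISDM fit with covariates
    {focal} ∪ set; the focal coefficient's posterior summarizes the total
    effect (on the standardized-covariate, log-intensity scale).
    """
    result = minimal_adjustment_sets(maximal_dag, focal, outcome)
    out = []
    for zset in result.sets:
        names = (focal, *sorted(zset))
        fit = fit_isdm(covariates, pa, pb, replace(config, covariates=names))
        row = fit.coef(focal)
        out.append(EffectEstimate(focal, zset, float(row["mean"]), float(row["sd"]),
                                  float(row["q2.5"]), float(row["q97.5"])))
    return out
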