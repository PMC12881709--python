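"""Covariate selection by WAIC and intensity/host-cover residual analysis.

WAIC is undefined for the point-process stream, so the covariate search runs
on presence–absence binomial models that share the ISDM's field and priors:
random candidate covariate sets (5–20 covariates, 50 per size, 800 total by
default) are each fitted to the PA data and ranked by WAIC computed from
posterior draws of the pointwise log-likelihood. The winning set is then
carried into the full integrated model.

The residual analysis regresses predicted intensity on host-species cover
with a Huber robust regression and maps the residuals, highlighting areas
with more or less pest/disease pressure than their host cover explains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grids import Raster
from .isdm import IsdmConfig, IsdmFit, fit_isdm


@dataclass(frozen=True)
class CandidateSet:
    """An ordered candidate covariate set for one model."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate covariate in candidate set")

    @property
    def size(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class WaicResult:
    """WAIC decomposition: waic = −2(lppd − p_waic)."""

    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray


@dataclass
class RobustFit:
    """Huber IRLS line fit: y ≈ intercept + slope·x."""

    slope: float
    intercept: float
    scale: float
    residuals: np.ndarray
    weights: np.ndarray
    n_iter: int
    converged: bool
    objective_trace: list[float]


def generate_candidate_sets(names: list[str], min_size: int = 5,
                            max_size: int = 20, per_size: int = 50,
                            seed: int = 0) -> list[CandidateSet]:
    """Random candidate covariate sets, uniform without replacement.

    For each size in [min_size, max_size], ``per_size`` distinct sets are
    drawn (duplicates are resampled with bounded retries); the default
    bounds give (20 − 5 + 1) × 50 = 800 candidates. Deterministic under
    ``seed``.
    """
    names = list(names)
    if len(names) < max_size:
        raise ValueError(f"need at least {max_size} covariates, got {len(names)}")
    rng = np.random.default_rng(seed)
    out: list[CandidateSet] = []
    for size in range(min_size, max_size + 1):
        seen: set[frozenset[str]] = set()
        tries = 0
        while len(seen) < per_size:
            tries += 1
            if tries > 1000 * per_size:
                raise RuntimeError(
                    f"could not draw {per_size} distinct sets of size {size}")
            pick = tuple(rng.choice(names, size=size, replace=False))
            key = frozenset(pick)
            if key in seen:
                continue
            seen.add(key)
            out.append(CandidateSet(pick))
    return out


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from an (S draws × n observations) pointwise log-likelihood.

    lppd_i = log mean_s exp(L_si) (overflow-safe); p_waic,i = Var_s(L_si)
    with the S − 1 denominator; waic = −2 Σ_i (lppd_i − p_waic,i). With a
    single draw the variance is undefined and p_waic is 0 by convention.
    """
    L = np.asarray(pointwise_loglik, dtype=float)
    if L.ndim != 2 or L.size == 0:
        raise ValueError("need an (S, n) matrix of log-likelihood draws")
    if not np.isfinite(L).all():
        raise ValueError("log-likelihood draws must be finite")
    S = L.shape[0]
    lppd_i = logsumexp(L, axis=0) - np.log(S)
    if S == 1:
        import warnings
        warnings.warn("single posterior draw: p_waic set to 0", stacklevel=2)
        p_i = np.zeros(L.shape[1])
    else:
        p_i = L.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(lppd, p_waic, -2.0 * (lppd - p_waic), lppd_i, p_i)


def pa_pointwise_loglik_draws(fit: IsdmFit, pa: pd.DataFrame,
                              n_draws: int = 1000,
                              seed: int = 0) -> np.ndarray:
    """Posterior draws of the per-site PA log-likelihood (S × n_sites).

    Sites' linear predictors are jointly Gaussian under the Laplace
    approximation; draws are taken from that Gaussian and pushed through
    the binomial-cloglog likelihood (including the binomial coefficient so
    WAIC values are proper log-densities).
    """
    from scipy.stats import binom

    from .isdm import _cloglog_mu  # shared clamped exponential

    A = fit._pa_design  # retained by fit_pa_gp_glm
    mu = A @ fit.xhat
    AS = A @ fit.Sigma  # dense (n_sites, n_latent)
    cov = np.asarray(A @ AS.T).T
    cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(len(mu))
    rng = np.random.default_rng(seed)
    eta = rng.multivariate_normal(mu, cov, size=n_draws, method="cholesky")
    m = _cloglog_mu(eta, fit.config.e_vis)
    p = np.clip(-np.expm1(-m), 1e-12, 1.0 - 1e-12)
    n = pa["n_surveys"].to_numpy()
    k = pa["n_detections"].to_numpy()
    return binom.logpmf(k[None, :], n[None, :], p)


def fit_pa_gp_glm(covariates: dict[str, Raster], pa: pd.DataFrame,
                  config: IsdmConfig) -> IsdmFit:
    """Binomial-cloglog spatial GLM on the PA stream alone.

    Exactly the ISDM machinery restricted to presence–absence data (same
    field, same priors, no PB stream and hence no bias field); the fit
    additionally retains its PA design matrix so WAIC draws can be taken.
    """
    if pa is None or len(pa) == 0:
        raise ValueError("PA data must be non-empty")
    return fit_isdm(covariates, pa, None, replace(config, bias_field=False))


def select_best(candidates: list[CandidateSet], covariates: dict[str, Raster],
                pa: pd.DataFrame, config: IsdmConfig,
                n_draws: int = 1000) -> pd.DataFrame:
    """Fit every candidate PA model, rank ascending by WAIC.

    Ties break toward fewer covariates then lexicographic order; failed
    fits are recorded with infinite WAIC and rank last rather than being
    dropped. Returns a DataFrame (rank, waic, lppd, p_waic, covariates,
    error).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    for cand in candidates:
        rec = {"covariates": ",".join(cand.names), "n_covariates": cand.size,
               "waic": np.inf, "lppd": np.nan, "p_waic": np.nan, "error": ""}
        try:
            fit = fit_pa_gp_glm(covariates, pa, replace(config, covariates=cand.names))
            w = waic(pa_pointwise_loglik_draws(fit, pa, n_draws, config.seed))
            rec.update(waic=w.waic, lppd=w.lppd, p_waic=w.p_waic)
        except Exception as exc:  # failures must rank last, never vanish
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    df = pd.DataFrame(rows)
    df = df.sort_values(["waic", "n_covariates", "covariates"],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def huber_rlm(x: np.ndarray, y: np.ndarray, k: float = 1.345,
              tol: float = 1e-8, max_iter: int = 50) -> RobustFit:
    """Huber robust line fit by iteratively reweighted least squares.

    Weights are 1 for standardized residuals within ±k and k·s/|r| beyond;
    the scale s is re-estimated each iteration as MAD/0.6745. Converged
    when the largest parameter change drops below ``tol``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")

    X = np.column_stack([np.ones_like(x), x])
    params = np.linalg.lstsq(X, y, rcond=None)[0]  # start from OLS
    trace: list[float] = []
    w = np.ones_like(x)
    s = 1.0
    converged = False
    for it in range(1, max_iter + 1):
        r = y - X @ params
        mad = np.median(np.abs(r - np.median(r)))
        s = max(mad / 0.6745, 1e-12)
        a = np.abs(r) / s
        w = np.where(a <= k, 1.0, k / np.clip(a, 1e-300, None))
        # Huber objective at current scale
        obj = float(np.sum(np.where(a <= k, 0.5 * r**2,
                                    k * s * np.abs(r) - 0.5 * (k * s) ** 2)))
        trace.append(obj)
        Xw = X * w[:, None]
        new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        change = np.max(np.abs(new - params))
        params = new
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Huber IRLS did not converge in {max_iter} iterations; trace={trace[-5:]}")
    r = y - X @ params
    return RobustFit(slope=float(params[1]), intercept=float(params[0]),
                     scale=float(s), residuals=r, weights=w, n_iter=it,
                     converged=converged, objective_trace=trace)


def host_cover_residuals(intensity: Raster, cover: Raster) -> Raster:
    """Residual map of intensity after a Huber fit on host-species cover.

    Cells missing in either layer are missing in the output. Positive
    residuals mark areas with higher pest/disease intensity than their
    host cover predicts.
    """
    if intensity.grid != cover.grid:
        raise ValueError("intensity and cover must share a grid")
    iv, cv = intensity.values.ravel(), cover.values.ravel()
    mask = np.isfinite(iv) & np.isfinite(cv)
    fit = huber_rlm(cv[mask], iv[mask])
    out = np.full(iv.shape, np.nan)
    out[mask] = iv[mask] - (fit.intercept + fit.slope * cv[mask])
    return intensity.copy_with(out.reshape(intensity.grid.shape),
                               name="host_cover_residuals")
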