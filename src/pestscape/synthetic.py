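"""Synthetic landscapes, covariates with known causal structure, and pest
observation datasets.

Every downstream stage of the pipeline (covariate engineering, causal
adjustment, integrated model fitting, covariate selection) is testable
against data simulated here with fully known ground truth:

* Covariates follow a linear-Gaussian structural causal model (SCM) over a
  user-supplied DAG — each node is a linear combination of its parents plus
  a Matérn noise field — so every total causal effect is an explicit sum of
  path coefficient products.
* The latent pest intensity is a log-Gaussian Cox process: log-linear in
  covariates plus a shared Matérn field.
* Presence–absence surveys are repeat visits at sites with binomial
  detections through a complementary log–log link (per-visit detection
  probability 1 − exp(−e_vis·λ)).
* Presence-background points are a (optionally thinned/biased) Poisson
  process draw from the intensity surface.

All simulators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .causal import Dag
from .fields import HyperParams, SparseCholesky, build_mesh, matern_precision
from .grids import GridSpec, Raster


@dataclass(frozen=True)
class NoiseParams:
    """Matérn noise for one SCM node: marginal sd and spatial range (km)."""

    sd: float = 1.0
    range_km: float = 5.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.range_km <= 0:
            raise ValueError("noise sd and range must be positive")


@dataclass
class ScmSpec:
    """Linear-Gaussian structural causal model over covariate rasters."""

    dag: Dag
    edge_coef: dict[tuple[str, str], float]
    noise: dict[str, NoiseParams] = field(default_factory=dict)
    default_noise: NoiseParams = NoiseParams()
    seed: int = 0

    def __post_init__(self) -> None:
        edges = set(self.dag.edges)
        for e in self.edge_coef:
            if e not in edges:
                raise KeyError(f"edge_coef entry {e} is not an edge of the DAG")

    def noise_for(self, node: str) -> NoiseParams:
        return self.noise.get(node, self.default_noise)

    def coef(self, parent: str, child: str) -> float:
        return self.edge_coef.get((parent, child), 0.0)


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth intensity model: log λ(s) = α + Σ β_k x_k(s) + ξ(s)."""

    alpha: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    field_sd: float = 0.0
    field_range: float = 10.0
    bias_sd: float = 0.0
    bias_range: float = 10.0
    e_vis: float = 1.0

    def __post_init__(self) -> None:
        if self.field_sd < 0 or self.bias_sd < 0:
            raise ValueError("field sds must be non-negative")
        if self.field_range <= 0 or self.bias_range <= 0:
            raise ValueError("field ranges must be positive")
        if self.e_vis <= 0:
            raise ValueError("e_vis must be positive")


def _matern_noise(grid: GridSpec, params: NoiseParams,
                  rng: np.random.Generator,
                  _cache: dict | None = None) -> np.ndarray:
    """One Matérn field draw evaluated at the grid cell centres.

    Simulated on a mesh at the grid's own resolution, extended by twice the
    range so boundary inflation stays outside the domain.
    """
    key = (grid, params.range_km, params.sd)
    if _cache is not None and key in _cache:
        chol, proj = _cache[key]
    else:
        mesh = build_mesh(grid, max_edge_km=grid.cell_km,
                          min_spacing_km=grid.cell_km,
                          extension_km=2.0 * params.range_km)
        Q = matern_precision(mesh, HyperParams(params.sd, params.range_km))
        chol = SparseCholesky(Q.Q)
        proj = mesh.projector(grid.center_points())
        if _cache is not None:
            _cache[key] = (chol, proj)
    draw = chol.sample(rng, size=1)[0]
    return (proj @ draw).reshape(grid.shape)


def simulate_covariate_fields(grid: GridSpec, scm: ScmSpec) -> dict[str, Raster]:
    """Simulate all SCM covariate rasters in topological order.

    Each node's raster is the coefficient-weighted sum of its parents'
    rasters plus an independent Matérn noise field. Deterministic under
    ``scm.seed``.
    """
    rng = np.random.default_rng(scm.seed)
    order = list(nx.lexicographical_topological_sort(scm.dag.graph))
    cache: dict = {}
    out: dict[str, Raster] = {}
    for node in order:
        vals = _matern_noise(grid, scm.noise_for(node), rng, cache)
        for parent in scm.dag.graph.predecessors(node):
            vals = vals + scm.coef(parent, node) * out[parent].values
        out[node] = Raster(grid, vals, name=node)
    return out


def scm_total_effect(scm: ScmSpec, source: str, target: str) -> float:
    """Total causal effect of ``source`` on ``target``: the sum over all
    directed paths of the product of edge coefficients."""
    scm.dag.require(source, target)
    total = 0.0
    for path in nx.all_simple_paths(scm.dag.graph, source, target):
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= scm.coef(a, b)
        total += prod
    return total


def simulate_intensity(grid: GridSpec, covariates: dict[str, Raster],
                       model: TrueModel, seed: int) -> tuple[Raster, Raster]:
    """Draw the latent intensity surface λ and its spatial field ξ.

    log λ(s) = α + Σ β_k x_k(s) + ξ(s), with ξ a Matérn field draw
    (identically zero when ``field_sd`` is 0).
    """
    missing = set(model.beta) - set(covariates)
    if missing:
        raise KeyError(f"beta references unknown covariates: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    log_lam = np.full(grid.shape, model.alpha, dtype=float)
    for name, b in model.beta.items():
        log_lam = log_lam + b * covariates[name].values
    if model.field_sd > 0:
        xi = _matern_noise(grid, NoiseParams(model.field_sd, model.field_range), rng)
    else:
        xi = np.zeros(grid.shape)
    log_lam = log_lam + xi
    return (Raster(grid, np.exp(log_lam), name="lambda", units="points/km2"),
            Raster(grid, xi, name="xi"))


def simulate_pb_points(lam: Raster, bias: Raster | None,
                       seed: int) -> pd.DataFrame:
    """Presence-background points: a thinned Poisson draw from λ.

    ``bias``, if given, is a log-thinning surface added to log λ (an
    observation artefact, e.g. reporting effort), so per-cell counts are
    Poisson(exp(log λ + bias)·cell area) with points placed uniformly
    within their cell. Returns a DataFrame with columns x_km, y_km.
    """
    if (lam.values < 0).any():
        raise ValueError("intensity must be non-negative")
    grid = lam.grid
    rate = lam.values.copy()
    if bias is not None:
        if bias.grid != grid:
            raise ValueError("bias raster must share the intensity grid")
        rate = rate * np.exp(bias.values)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * grid.cell_area_km2)
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    rows = np.repeat(rows, reps)
    cols = np.repeat(cols, reps)
    n = len(rows)
    x0, y0 = grid.origin
    xs = x0 + (cols + rng.random(n)) * grid.cell_km
    ys = y0 + (rows + rng.random(n)) * grid.cell_km
    return pd.DataFrame({"x_km": xs, "y_km": ys})


def simulate_pa_surveys(lam: Raster, sites: np.ndarray, visits: np.ndarray,
                        e_vis: float, seed: int) -> pd.DataFrame:
    """Presence–absence survey table from repeat visits at fixed sites.

    A visit at site s detects at least one pest with probability
    p(s) = 1 − exp(−e_vis·λ(s)) (the cloglog link between a Poisson
    intensity and detection); detections are Binomial(visits, p).
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    visits = np.asarray(visits, dtype=int)
    if (visits < 1).any():
        raise ValueError("every site needs at least one visit")
    if len(visits) != len(sites):
        raise ValueError("sites and visits must have equal length")
    lam_s = lam.value_at(sites)  # raises if a site is outside the grid
    p = -np.expm1(-e_vis * lam_s)
    rng = np.random.default_rng(seed)
    det = rng.binomial(visits, p)
    return pd.DataFrame({
        "site_id": np.arange(len(sites)),
        "x_km": sites[:, 0],
        "y_km": sites[:, 1],
        "n_surveys": visits,
        "n_detections": det,
    })


def sample_sites(grid: GridSpec, n: int, seed: int) -> np.ndarray:
    """Uniformly random site locations within the grid."""
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = grid.extent
    return np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])


def sample_visit_counts(n_sites: int, mean: float = 1.5,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-truncated geometric visit counts per site.

    The default mean of 1.5 mimics the motivating inspection data: most
    sites are visited once (median 1), a few are visited many times.
    """
    if mean <= 1.0:
        raise ValueError("mean visit count must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # zero-truncated geometric with mean 1/p has support {1, 2, ...}
    return rng.geometric(p=1.0 / mean, size=n_sites)
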