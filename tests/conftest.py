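"""Shared fixtures and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

import pestscape as ps


@pytest.fixture(scope="session")
def small_grid() -> ps.GridSpec:
    return ps.GridSpec(20, 20, 1.0)


def make_integrated_dataset(seed: int, *, grid_size: int = 50, n_pa: int = 200,
                            alpha: float = -2.4,
                            beta: dict[str, float] | None = None,
                            field_sd: float = 0.5, field_range: float = 10.0,
                            pb_bias: ps.Raster | None = None):
    """Standard synthetic study: two independent covariates, a Matérn
    process field, ~500 PB points and 200 PA sites on a 50×50 km grid."""
    beta = {"x1": 1.0, "x2": -0.5} if beta is None else beta
    ss = np.random.SeedSequence(seed).generate_state(8)
    grid = ps.GridSpec(grid_size, grid_size, 1.0)
    scm = ps.ScmSpec(ps.parse_dag("node: " + ", ".join(sorted(beta))), {},
                     seed=int(ss[0]))
    covs = ps.stack_standardize(ps.simulate_covariate_fields(grid, scm))
    truth = ps.TrueModel(alpha=alpha, beta=beta, field_sd=field_sd,
                         field_range=field_range)
    lam, xi = ps.simulate_intensity(grid, covs, truth, int(ss[1]))
    pb = ps.simulate_pb_points(lam, pb_bias, int(ss[2]))
    sites = ps.sample_sites(grid, n_pa, int(ss[3]))
    visits = ps.sample_visit_counts(n_pa, seed=int(ss[4]))
    pa = ps.simulate_pa_surveys(lam, sites, visits, truth.e_vis, int(ss[5]))
    return grid, covs, pa, pb, truth


@pytest.fixture(scope="session")
def integrated_dataset():
    return make_integrated_dataset(2024)


@pytest.fixture(scope="session")
def integrated_fit(integrated_dataset):
    grid, covs, pa, pb, truth = integrated_dataset
    cfg = ps.IsdmConfig(covariates=("x1", "x2"), max_edge_km=5.0,
                        bias_field=False)
    return ps.fit_isdm(covs, pa, pb, cfg)


# ---------------------------------------------------------------------------
# independent d-separation oracle: explicit path enumeration

def _undirected_paths(edges: set[tuple[str, str]], src: str, dst: str):
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def walk(node, path):
        if node == dst:
            yield list(path)
            return
        for nxt in adj.get(node, ()):  # noqa: B007
            if nxt not in path:
                path.append(nxt)
                yield from walk(nxt, path)
                path.pop()

    yield from walk(src, [src])


def _descendants(edges: set[tuple[str, str]], node: str) -> set[str]:
    out = {node}
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for a, b in edges:
            if a == cur and b not in out:
                out.add(b)
                frontier.append(b)
    return out


def dsep_oracle(dag: "ps.Dag", X: set[str], Y: set[str], Z: set[str]) -> bool:
    """Brute-force d-separation: enumerate every undirected simple path and
    apply the blocking rules node by node."""
    edges = set(dag.edges)
    for x in X:
        for y in Y:
            for path in _undirected_paths(edges, x, y):
                blocked = False
                for i in range(1, len(path) - 1):
                    prev, node, nxt = path[i - 1], path[i], path[i + 1]
                    is_collider = (prev, node) in edges and (nxt, node) in edges
                    if is_collider:
                        if not (_descendants(edges, node) & Z):
                            blocked = True
                            break
                    elif node in Z:
                        blocked = True
                        break
                if not blocked:
                    return False
    return True


def adjustment_sets_oracle(dag: "ps.Dag", exposure: str, outcome: str):
    """Exhaustive-subset back-door oracle: scan every subset of observed
    non-descendants, keep the valid ones, filter to inclusion-minimal.
    Returns None when not even the full candidate set blocks all paths."""
    from itertools import combinations

    edges = set(dag.edges)
    desc = _descendants(edges, exposure)
    candidates = sorted(dag.observed - desc - {outcome})
    bd_edges = {(a, b) for a, b in edges if a != exposure}
    bd = ps.Dag(tuple(bd_edges), dag.latent,
                tuple(sorted(dag.nodes - {n for e in bd_edges for n in e})))
    valid = []
    for size in range(len(candidates) + 1):
        for combo in combinations(candidates, size):
            if dsep_oracle(bd, {exposure}, {outcome}, set(combo)):
                valid.append(frozenset(combo))
    if not valid:
        return None
    minimal = [s for s in valid if not any(o < s for o in valid)]
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))
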