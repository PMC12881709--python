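"""Graphical causal analysis: DAGs, d-separation, back-door adjustment sets.

The driver analysis treats the assumed data-generating process as a directed
acyclic graph over observed covariates, latent introduction/establishment
probabilities, and the pest/disease outcome. For each focal driver the total
causal effect is identified by adjusting for a minimal set of observed
variables satisfying the back-door criterion; robustness to the assumed graph
is probed by re-deriving adjustment sets along a sequence of nested DAGs.

DAG files are plain text: one ``A -> B`` edge per line, an optional
``latent: X, Y`` directive, ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from itertools import combinations

import networkx as nx

OUTCOME = "y"


class DagParseError(ValueError):
    """Malformed DAG text (reports the offending line number)."""


class CycleError(ValueError):
    """The edge list contains a directed cycle (reported in the message)."""


class IdentifiabilityError(Exception):
    """No observed adjustment set satisfies the back-door criterion."""


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph with observed and latent nodes."""

    edges: tuple[tuple[str, str], ...]
    latent: frozenset[str] = frozenset()
    isolated: tuple[str, ...] = ()  # nodes with no incident edges

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e in seen:
                raise ValueError(f"duplicate edge {e[0]} -> {e[1]}")
            if e[0] == e[1]:
                raise ValueError(f"self-loop on {e[0]}")
            seen.add(e)
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            path = " -> ".join([u for u, _ in cyc] + [cyc[0][0]])
            raise CycleError(f"graph contains a cycle: {path}")

    @cached_property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.isolated)
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def observed(self) -> frozenset[str]:
        return self.nodes - self.latent

    def require(self, *names: str) -> None:
        unknown = set(names) - self.nodes
        if unknown:
            raise KeyError(f"unknown node(s): {sorted(unknown)}")

    def induced(self, keep: set[str]) -> "Dag":
        keep = set(keep) & self.nodes
        edges = tuple(e for e in self.edges if e[0] in keep and e[1] in keep)
        used = {n for e in edges for n in e}
        return Dag(edges, self.latent & keep, tuple(sorted(keep - used)))


@dataclass(frozen=True)
class AdjustmentResult:
    """Minimal back-door adjustment sets for one exposure/outcome pair."""

    exposure: str
    outcome: str
    sets: tuple[frozenset[str], ...]
    criterion: str = "back-door, total effect"


def parse_dag(text: str) -> Dag:
    edges: list[tuple[str, str]] = []
    latent: set[str] = set()
    isolated: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("latent:"):
            latent.update(p.strip() for p in line.split(":", 1)[1].split(",") if p.strip())
            continue
        if line.lower().startswith("node:"):
            isolated.extend(p.strip() for p in line.split(":", 1)[1].split(",") if p.strip())
            continue
        if "->" not in line:
            raise DagParseError(f"line {lineno}: expected 'A -> B', got {raw!r}")
        left, _, right = line.partition("->")
        a, b = left.strip(), right.strip()
        if not a or not b:
            raise DagParseError(f"line {lineno}: expected 'A -> B', got {raw!r}")
        edges.append((a, b))
    return Dag(tuple(edges), frozenset(latent), tuple(isolated))


def serialize_dag(dag: Dag) -> str:
    lines = [f"{a} -> {b}" for a, b in dag.edges]
    iso = sorted(dag.nodes - {n for e in dag.edges for n in e})
    if iso:
        lines.append("node: " + ", ".join(iso))
    if dag.latent:
        lines.append("latent: " + ", ".join(sorted(dag.latent)))
    return "\n".join(lines) + "\n"


def load_maximal_dag() -> Dag:
    """The packaged maximal DAG over the GB pest/disease covariates.

    A synthetic reconstruction: the published graph is available only as a
    figure, so the shipped edge list is a plausible transcription and is
    meant to be edited. It is configuration, not a hard-coded model.
    """
    text = resources.files("pestscape.data").joinpath(
        "maximal_dag_synthetic.txt").read_text()
    return parse_dag(text)


def d_separated(dag: Dag, X: set[str], Y: set[str], Z: set[str]) -> bool:
    """True iff every path between X and Y is blocked given Z (d-separation)."""
    X, Y, Z = set(X), set(Y), set(Z)
    dag.require(*(X | Y | Z))
    if (X & Y) or (X & Z) or (Y & Z):
        raise ValueError("X, Y, Z must be disjoint")
    return nx.is_d_separator(dag.graph, X, Y, Z)


def _blocks_backdoor(dag: Dag, exposure: str, outcome: str,
                     Z: frozenset[str]) -> bool:
    g = dag.graph.copy()
    g.remove_edges_from(list(g.out_edges(exposure)))
    return nx.is_d_separator(g, {exposure}, {outcome}, set(Z))


def minimal_adjustment_sets(dag: Dag, exposure: str,
                            outcome: str = OUTCOME) -> AdjustmentResult:
    """All inclusion-minimal observed back-door adjustment sets.

    A candidate set contains only observed non-descendants of the exposure
    and must block every back-door path from exposure to outcome
    (d-separation in the graph with the exposure's outgoing edges removed).
    An empty-set result means the unadjusted estimate already identifies the
    total effect; if not even the full candidate set works, the effect is
    unidentifiable from observed covariates and an
    :class:`IdentifiabilityError` is raised.
    """
    dag.require(exposure, outcome)
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    if exposure in dag.latent or outcome in dag.latent:
        raise ValueError("exposure and outcome must be observed")
    desc = nx.descendants(dag.graph, exposure) | {exposure}
    candidates = sorted(dag.observed - desc - {outcome})

    # validity is not monotone in Z (conditioning can open colliders), so
    # every subset must be scanned; supersets of found minimal sets are
    # skipped because they are never inclusion-minimal
    minimal: list[frozenset[str]] = []
    for size in range(len(candidates) + 1):
        for combo in combinations(candidates, size):
            Z = frozenset(combo)
            if any(m <= Z for m in minimal):
                continue
            if _blocks_backdoor(dag, exposure, outcome, Z):
                minimal.append(Z)
    if not minimal:
        raise IdentifiabilityError(
            f"total effect of {exposure!r} on {outcome!r} is not identifiable "
            "by observed back-door adjustment (latent confounding)")
    minimal.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return AdjustmentResult(exposure, outcome, tuple(minimal))


def sensitivity_sequence(
    maximal: Dag,
    focal: str,
    order: list[str] | None = None,
    outcome: str = OUTCOME,
) -> list[tuple[Dag, AdjustmentResult]]:
    """Adjustment sets along a nested DAG sequence, from focal-only upward.

    Starting from the sub-DAG containing only the focal variable, the
    outcome, and the outcome's latent ancestors (the unadjusted estimate),
    observed variables are added one at a time in ``order`` (default:
    topological order of the maximal DAG) until the maximal DAG is reached;
    each induced sub-DAG contributes its minimal adjustment sets. Each
    distinct adjustment set across the sequence implies one model fit; use
    :func:`unique_adjustment_sets` to deduplicate.
    """
    maximal.require(focal, outcome)
    latent_anc = {n for n in nx.ancestors(maximal.graph, outcome)
                  if n in maximal.latent}
    remaining = sorted(maximal.observed - {focal, outcome})
    if order is None:
        topo = list(nx.topological_sort(maximal.graph))
        order = [n for n in topo if n in remaining]
    elif sorted(order) != remaining:
        raise ValueError("order must be a permutation of the remaining observed nodes")

    out: list[tuple[Dag, AdjustmentResult]] = []
    for k in range(len(order) + 1):
        keep = {focal, outcome} | latent_anc | set(order[:k])
        sub = maximal.induced(keep)
        out.append((sub, minimal_adjustment_sets(sub, focal, outcome)))
    return out


def unique_adjustment_sets(
    seq: list[tuple[Dag, AdjustmentResult]],
) -> list[frozenset[str]]:
    """Deduplicated adjustment sets across a sensitivity sequence, in first-seen order."""
    seen: list[frozenset[str]] = []
    for _, res in seq:
        for s in res.sets:
            if s not in seen:
                seen.append(s)
    return seen
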