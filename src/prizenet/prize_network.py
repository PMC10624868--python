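"""Single-cell-cluster-informed node prizes and edge-cost multipliers.

The integration scheme rewards proteins by how significantly they changed
(-log10 FDR-adjusted p) and by how broadly their transcript changed across
single-cell clusters (the ratio of a gene's DE-cluster count to the cohort
average), and cheapens interactome edges between genes with broad single-cell
evidence via a rank-based multiplier, before handing the instance to the PCSF
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
from scipy import stats

from .differential import ClusterCounts
from .errors import ParameterError
from .omics_io import Interactome, OmicsMeasurement

ROLE_PROTEOME = "terminal_proteome"
ROLE_UBIQUITINOME = "terminal_ubiquitinome"
ROLE_BOTH = "terminal_both"
ROLE_STEINER = "steiner"

Edge = tuple[str, str]


def _edge_key(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PCSFInstance:
    """Weighted graph with node prizes, final edge costs, beta and omega.

    ``graph`` carries the final cost on each edge (attribute ``cost``);
    ``prizes`` maps every prized node to a non-negative reward; ``beta``
    scales prizes in the objective and ``omega`` is the per-tree penalty.
    """

    graph: nx.Graph
    prizes: Mapping[str, float]
    beta: float = 1.0
    omega: float = 2.0
    node_roles: Mapping[str, str] = field(default_factory=dict)
    dropped_prizes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.omega <= 0:
            raise ParameterError("beta and omega must be positive")
        for v, p in self.prizes.items():
            if v not in self.graph:
                raise ParameterError(f"prized node {v} missing from graph")
            if p < 0:
                raise ParameterError(f"negative prize for {v}")
        for u, v, c in self.graph.edges(data="cost"):
            if c is None or c <= 0:
                raise ParameterError(f"edge ({u}, {v}) has non-positive cost")

    def cost(self, u: str, v: str) -> float:
        return self.graph[u][v]["cost"]

    def prize(self, v: str) -> float:
        return float(self.prizes.get(v, 0.0))


def _cluster_multiplier(
    gene: str, counts: ClusterCounts | None, absent_multiplier: float
) -> float:
    if counts is None or counts.mean_clusters <= 0.0:
        return 1.0
    if gene in counts:
        return counts.n_total(gene) / counts.mean_clusters
    return absent_multiplier


def compute_prizes(
    proteome: Sequence[OmicsMeasurement],
    ubiquitinome: Sequence[OmicsMeasurement],
    counts: ClusterCounts | None = None,
    absent_multiplier: float = 1.0,
) -> tuple[dict[str, float], dict[str, str]]:
    """Node prizes from retained proteome and collapsed ubiquitinome hits.

    prize(v) = (-log10 adj-p) * m(v), with m(v) the gene's DE-cluster count
    over the cohort average when the gene was measured in the single-cell
    data, and ``absent_multiplier`` (default 1: unmeasured is not unchanged)
    when it was not.  A node hit in both layers sums the two contributions
    and is tagged ``terminal_both``.
    """
    prizes: dict[str, float] = {}
    roles: dict[str, str] = {}
    for records, role in (
        (proteome, ROLE_PROTEOME),
        (ubiquitinome, ROLE_UBIQUITINOME),
    ):
        for m in records:
            if m.p_adjusted <= 0.0:
                raise ParameterError(
                    f"{m.feature_id}: adjusted p of 0 gives an infinite prize"
                )
            contribution = -math.log10(m.p_adjusted) * _cluster_multiplier(
                m.feature_id, counts, absent_multiplier
            )
            if m.feature_id in prizes:
                prizes[m.feature_id] += contribution
                if roles[m.feature_id] != role:
                    roles[m.feature_id] = ROLE_BOTH
            else:
                prizes[m.feature_id] = contribution
                roles[m.feature_id] = role
    return prizes, roles


def adjust_edge_costs(
    interactome: Interactome,
    counts: ClusterCounts | None = None,
    absent_multiplier: float = 0.0,
) -> dict[Edge, float]:
    """Rank-based edge-cost adjustment from single-cell cluster evidence.

    Each edge's ratio r(e) is the mean, over its two endpoints, of the gene's
    DE-cluster count divided by the cohort average (genes without single-cell
    data count 0).  Edges are ranked by r(e) descending (average ranks on
    ties) and the final cost is rank/|E| times the base cost, so edges between
    broadly differentially expressed genes become cheapest.  Without
    single-cell data the base costs are returned unchanged.
    """
    edges = interactome.edges
    if not edges:
        raise ParameterError("interactome has no edges")
    base = {e: interactome.base_cost(*e) for e in edges}
    if counts is None or counts.mean_clusters <= 0.0:
        return base
    cbar = counts.mean_clusters

    def node_count(g: str) -> float:
        return counts.n_total(g) if g in counts else absent_multiplier * cbar

    # rank on the count sums: same order as the ratios (they differ by the
    # positive constant 1/(2*cbar)) but with exact tie detection on integers
    sums = [node_count(u) + node_count(v) for u, v in edges]
    ranks = stats.rankdata([-s for s in sums], method="average")
    n_edges = len(edges)
    return {
        e: (rank / n_edges) * base[e] for e, rank in zip(edges, ranks)
    }


def assemble_instance(
    interactome: Interactome,
    prizes: Mapping[str, float],
    costs: Mapping[Edge, float] | None = None,
    beta: float = 1.0,
    omega: float = 2.0,
    roles: Mapping[str, str] | None = None,
) -> PCSFInstance:
    """Combine graph, prizes and costs into a solver-ready instance.

    Prize genes absent from the interactome are dropped (and recorded on the
    instance); nodes without a prize get 0.  Raises when no prize gene maps
    into the graph at all.
    """
    if beta <= 0 or omega <= 0:
        raise ParameterError("beta and omega must be positive")
    g = nx.Graph()
    g.add_nodes_from(interactome.nodes)
    for u, v in interactome.edges:
        cost = (
            costs[_edge_key(u, v)]
            if costs is not None
            else interactome.base_cost(u, v)
        )
        g.add_edge(u, v, cost=float(cost))
    present = {v: float(p) for v, p in prizes.items() if v in g}
    dropped = tuple(sorted(v for v in prizes if v not in g))
    if prizes and not present:
        raise ParameterError(
            "no prize gene maps into the interactome; nothing to recover"
        )
    roles = roles or {}
    node_roles = {v: roles.get(v, ROLE_PROTEOME) for v in present}
    return PCSFInstance(
        graph=g,
        prizes=present,
        beta=beta,
        omega=omega,
        node_roles=node_roles,
        dropped_prizes=dropped,
    )


def write_instance(instance: PCSFInstance, path_prefix: str | Path) -> None:
    """Serialize an instance as a TSV pair (nodes: id, prize; edges: u, v, cost)."""
    prefix = Path(path_prefix)
    node_lines = ["node\tprize"]
    for v in sorted(instance.graph.nodes):
        node_lines.append(f"{v}\t{instance.prize(v):.10g}")
    Path(str(prefix) + "_nodes.tsv").write_text(
        "\n".join(node_lines) + "\n", newline="\n"
    )
    edge_lines = ["node_a\tnode_b\tcost"]
    for u, v in sorted(tuple(sorted(e)) for e in instance.graph.edges):
        edge_lines.append(f"{u}\t{v}\t{instance.cost(u, v):.10g}")
    Path(str(prefix) + "_edges.tsv").write_text(
        "\n".join(edge_lines) + "\n", newline="\n"
    )


def read_instance(
    path_prefix: str | Path, beta: float = 1.0, omega: float = 2.0
) -> PCSFInstance:
    """Read the TSV pair written by :func:`write_instance`."""
    prefix = Path(path_prefix)
    g = nx.Graph()
    prizes: dict[str, float] = {}
    node_lines = (
        Path(str(prefix) + "_nodes.tsv").read_text().splitlines()[1:]
    )
    for line in node_lines:
        if not line.strip():
            continue
        v, p = line.split("\t")
        g.add_node(v)
        if float(p) > 0:
            prizes[v] = float(p)
    edge_lines = (
        Path(str(prefix) + "_edges.tsv").read_text().splitlines()[1:]
    )
    for line in edge_lines:
        if not line.strip():
            continue
        u, v, c = line.split("\t")
        g.add_edge(u, v, cost=float(c))
    return PCSFInstance(graph=g, prizes=prizes, beta=beta, omega=omega)
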