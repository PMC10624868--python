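"""Readers, writers and domain containers for every external format the pipeline touches.

Formats supported: tab-separated omics tables (feature, log2 fold change, raw and
FDR-adjusted p-value), a three-column interactome edge list with STRING-like
confidences, GMT gene-set libraries, a long-format per-cluster DE table, a
two-column identifier map, and GraphML/TSV network output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError

#: Minimum edge cost after the 1 - confidence transform; keeps PCSF non-degenerate.
COST_FLOOR = 0.01

#: Default column names for omics tables; all overridable per call.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "feature": "feature",
    "log2fc": "log2fc",
    "pval": "pval",
    "padj": "padj",
    "protein": "protein",
}


class Layer(str, Enum):
    """Omics layer a measurement belongs to."""

    TRANSCRIPT = "transcript"
    PROTEIN = "protein"
    UBIQUITIN_SITE = "ubiquitin_site"


@dataclass(frozen=True)
class OmicsMeasurement:
    """One feature's effect size and significance in one omics layer.

    ``log2_fold_change`` is mutant minus control in log2 units.  Both p-values
    must lie in (0, 1]; an adjusted p of exactly 0 would later produce an
    infinite node prize and is rejected at construction.  Ubiquitin-site
    records must name the protein the site maps to.
    """

    feature_id: str
    layer: Layer
    log2_fold_change: float
    p_raw: float
    p_adjusted: float
    parent_protein: str = ""

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise FormatError("feature_id must be nonempty")
        if not math.isfinite(self.log2_fold_change):
            raise FormatError(
                f"{self.feature_id}: log2_fold_change must be finite"
            )
        for name, p in (("p_raw", self.p_raw), ("p_adjusted", self.p_adjusted)):
            if not (0.0 < p <= 1.0):
                raise FormatError(
                    f"{self.feature_id}: {name}={p!r} outside (0, 1]"
                )
        if self.layer is Layer.UBIQUITIN_SITE and not self.parent_protein:
            raise FormatError(
                f"{self.feature_id}: ubiquitin_site record needs parent_protein"
            )


@dataclass(frozen=True)
class ClusterDEMatrix:
    """Per-gene, per-cluster differential-expression statistics.

    ``log2fc`` and ``padj`` are genes x clusters frames with identical shape
    and identical missingness pattern (NaN marks a gene not tested in a
    cluster).
    """

    log2fc: pd.DataFrame
    padj: pd.DataFrame

    def __post_init__(self) -> None:
        if self.log2fc.shape[1] < 1:
            raise FormatError("ClusterDEMatrix needs at least one cluster")
        if list(self.log2fc.index) != list(self.padj.index) or list(
            self.log2fc.columns
        ) != list(self.padj.columns):
            raise FormatError("log2fc and padj frames must share labels")
        if self.log2fc.index.has_duplicates or self.log2fc.columns.has_duplicates:
            raise FormatError("gene and cluster labels must be unique")
        if not (self.log2fc.isna() == self.padj.isna()).all().all():
            raise FormatError("every present cell needs both statistics")
        vals = self.padj.to_numpy(float)
        present = ~np.isnan(vals)
        if present.any() and not (
            (vals[present] > 0.0) & (vals[present] <= 1.0)
        ).all():
            raise FormatError("adjusted p-values must lie in (0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.log2fc.columns)

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "ClusterDEMatrix":
        """Build from a long table with columns gene, cluster, log2fc, padj."""
        for col in ("gene", "cluster", "log2fc", "padj"):
            if col not in table.columns:
                raise FormatError(f"missing required column '{col}'")
        fc = table.pivot(index="gene", columns="cluster", values="log2fc")
        padj = table.pivot(index="gene", columns="cluster", values="padj")
        return cls(fc.sort_index(), padj.sort_index())


class Interactome:
    """Simple undirected protein-protein interaction graph with confidences.

    Each edge carries ``confidence`` in (0, 1] and ``base_cost`` =
    max(1 - confidence, COST_FLOOR), so cost is strictly decreasing in
    confidence and never reaches zero.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        min_confidence: float = 0.0,
        isolated_nodes: Iterable[str] = (),
    ) -> "Interactome":
        if not (0.0 <= min_confidence < 1.0):
            raise FormatError("min_confidence must lie in [0, 1)")
        g = nx.Graph()
        for name in isolated_nodes:
            g.add_node(str(name))
        for u, v, conf in edges:
            conf = float(conf)
            if not (0.0 < conf <= 1.0):
                raise FormatError(
                    f"edge ({u}, {v}): confidence {conf!r} outside (0, 1]"
                )
            if u == v:
                continue  # self-loops dropped
            if conf <= min_confidence:
                continue
            u, v = str(u), str(v)
            if g.has_edge(u, v):
                conf = max(conf, g[u][v]["confidence"])
            g.add_edge(u, v, confidence=conf,
                       base_cost=max(1.0 - conf, COST_FLOOR))
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def confidence(self, u: str, v: str) -> float:
        return self._graph[u][v]["confidence"]

    def base_cost(self, u: str, v: str) -> float:
        return self._graph[u][v]["base_cost"]

    def __len__(self) -> int:
        return self._graph.number_of_nodes()


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named collection of term -> gene-identifier set."""

    sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set '{term}' is empty")

    @property
    def terms(self) -> list[str]:
        return sorted(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def __len__(self) -> int:
        return len(self.sets)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV identifier map (source id -> target id)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        mapping[parts[0]] = parts[1]
    return mapping


def _numeric_column(
    frame: pd.DataFrame, col: str, path: str | Path
) -> np.ndarray:
    values = pd.to_numeric(frame[col], errors="coerce")
    bad = values.isna() & frame[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header, one for 1-based numbering
        raise FormatError(
            f"{path}: non-numeric value {frame[col].iloc[row]!r} in column "
            f"'{col}' at line {row + 2}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise FormatError(
            f"{path}: missing value in column '{col}' at line {row + 2}"
        )
    return values.to_numpy(float)


def read_omics_table(
    path: str | Path,
    layer: Layer,
    columns: Mapping[str, str] | None = None,
    id_map: Mapping[str, str] | None = None,
) -> list[OmicsMeasurement]:
    """Read a TSV omics table into measurement records, preserving row order.

    ``columns`` overrides the default header names; ``id_map`` is applied to
    feature ids (and parent-protein ids) at read time, defaulting to identity.
    """
    layer = Layer(layer)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["feature", "log2fc", "pval", "padj"]
    if layer is Layer.UBIQUITIN_SITE:
        required.append("protein")
    for key in required:
        if cols[key] not in frame.columns:
            raise FormatError(
                f"{path}: missing required column '{cols[key]}'"
            )
    fc = _numeric_column(frame, cols["log2fc"], path)
    praw = _numeric_column(frame, cols["pval"], path)
    padj = _numeric_column(frame, cols["padj"], path)
    id_map = id_map or {}
    records = []
    for i in range(len(frame)):
        feature = str(frame[cols["feature"]].iloc[i])
        feature = id_map.get(feature, feature)
        parent = ""
        if layer is Layer.UBIQUITIN_SITE:
            parent = str(frame[cols["protein"]].iloc[i])
            parent = id_map.get(parent, parent)
        try:
            records.append(
                OmicsMeasurement(
                    feature_id=feature,
                    layer=layer,
                    log2_fold_change=float(fc[i]),
                    p_raw=float(praw[i]),
                    p_adjusted=float(padj[i]),
                    parent_protein=parent,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_cluster_matrix(path: str | Path) -> ClusterDEMatrix:
    """Read a long-format per-cluster DE table (gene, cluster, log2fc, padj)."""
    frame = pd.read_csv(path, sep="\t")
    return ClusterDEMatrix.from_long(frame)


def read_interactome(
    path: str | Path,
    min_confidence: float = 0.0,
    id_map: Mapping[str, str] | None = None,
) -> Interactome:
    """Read a three-column edge list (node, node, confidence in (0, 1]).

    Edges at or below ``min_confidence`` are dropped, duplicate pairs keep the
    maximum confidence, self-loops are discarded, and base costs are
    max(1 - confidence, COST_FLOOR).
    """
    id_map = id_map or {}
    edges = []
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected three columns")
        try:
            conf = float(parts[2])
        except ValueError as exc:
            if lineno == 1:
                continue  # header row
            raise FormatError(
                f"{path}:{lineno}: non-numeric confidence {parts[2]!r}"
            ) from exc
        u = id_map.get(parts[0], parts[0])
        v = id_map.get(parts[1], parts[1])
        edges.append((u, v, conf))
    try:
        return Interactome.from_edges(edges, min_confidence=min_confidence)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    """Write the edge list back out (node, node, confidence), sorted."""
    lines = ["node_a\tnode_b\tconfidence"]
    for u, v in interactome.edges:
        lines.append(f"{u}\t{v}\t{interactome.confidence(u, v):.6f}")
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_gene_sets(path: str | Path) -> GeneSetLibrary:
    """Read a GMT file: term, description, then gene ids, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs term, description and at "
                "least one gene"
            )
        term = parts[0]
        if term in sets:
            raise FormatError(f"{path}:{lineno}: duplicate term '{term}'")
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: term '{term}' has no genes")
        sets[term] = genes
    return GeneSetLibrary(sets)


def write_gene_sets(library: GeneSetLibrary, path: str | Path) -> None:
    lines = [
        "\t".join([term, term] + sorted(library[term]))
        for term in library.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def write_network(
    solution,
    instance,
    path_prefix: str | Path,
    partition: Mapping[str, int] | None = None,
) -> tuple[Path, Path]:
    """Serialize a forest solution as GraphML plus a flat TSV edge list.

    Node attributes: role, prize, module (empty string when unassigned); edge
    attribute: final cost.  Output bytes are identical across runs for
    identical inputs (nodes and edges are written sorted).
    """
    partition = partition or {}
    prefix = Path(path_prefix)
    g = nx.Graph()
    for node in sorted(solution.nodes):
        g.add_node(
            node,
            role=solution.node_roles.get(node, "steiner"),
            prize=float(instance.prizes.get(node, 0.0)),
            module="" if node not in partition else str(partition[node]),
        )
    for u, v in sorted(solution.edges):
        g.add_edge(u, v, cost=float(instance.graph[u][v]["cost"]))
    graphml_path = prefix.with_suffix(".graphml")
    text = "\n".join(nx.generate_graphml(g)) + "\n"
    graphml_path.write_text(text, newline="\n")

    tsv_path = prefix.with_suffix(".tsv")
    lines = [
        "node_a\tnode_b\tcost\trole_a\trole_b\tprize_a\tprize_b"
        "\tmodule_a\tmodule_b"
    ]
    for u, v in sorted(solution.edges):
        lines.append(
            "\t".join(
                [
                    u,
                    v,
                    f"{instance.graph[u][v]['cost']:.6g}",
                    g.nodes[u]["role"],
                    g.nodes[v]["role"],
                    f"{g.nodes[u]['prize']:.6g}",
                    f"{g.nodes[v]['prize']:.6g}",
                    g.nodes[u]["module"],
                    g.nodes[v]["module"],
                ]
            )
        )
    tsv_path.write_text("\n".join(lines) + "\n", newline="\n")
    return graphml_path, tsv_path
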