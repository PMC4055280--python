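"""Global and tissue interactomes, the core sub-network, and TS-PPIs.

The global interactome is the union of experimentally detected PPIs from
several source databases, stored as an undirected simple graph over opaque
gene identifiers. A tissue interactome keeps an edge only if both partners
are co-expressed in the same sample or tissue subpart at the lowest
hierarchy level (node-removal filtering); edges recovered in any subpart of
a tissue are united to form that tissue's interactome. The core sub-network
is the edge intersection of all tissue interactomes. An edge's breadth is
the number of tissues containing it; edges of breadth <= k_ts are
tissue-specific PPIs (TS-PPIs) of each tissue that contains them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError
from .expression import Expressome

logger = logging.getLogger(__name__)


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) representation of an undirected edge."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# readers


def read_edge_list(path, default_source: str | None = None) -> list[tuple[str, str, str]]:
    """Read a TSV edge list ``gene_a  gene_b  source`` (header required)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["gene_a", "gene_b"]:
            raise ParseError(f"bad header {header!r}, expected gene_a/gene_b[/source]", line=1)
        has_source = len(header) >= 3
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0] or not row[1]:
                raise ParseError(f"malformed edge row {row!r}", line=lineno)
            source = row[2] if has_source and len(row) > 2 and row[2] else (default_source or "unknown")
            rows.append((row[0], row[1], source))
    return rows


def read_psimitab(path, source: str | None = None) -> list[tuple[str, str, str]]:
    """Read a PSI-MI TAB 2.5 file using interactor columns 1-2 only.

    Identifiers are taken verbatim (database prefixes such as
    ``uniprotkb:`` included); organism filtering and identifier mapping are
    upstream data-preparation concerns.
    """
    rows = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"PSI-MI TAB row with {len(fields)} columns", line=lineno)
            rows.append((fields[0], fields[1], source or "psimitab"))
    return rows


# ---------------------------------------------------------------------------
# construction


def build_global_interactome(
    sources: Mapping[str, Iterable[tuple[str, str]]]
) -> nx.Graph:
    """Union of edge sources into one undirected simple graph.

    Duplicates and reversed duplicates collapse onto a single canonical
    edge; self-loops are dropped (with a logged count) because PPI degree
    counts *partners*. Source provenance is kept per edge in the ``sources``
    edge attribute.
    """
    g = nx.Graph(scope="global")
    dropped = 0
    for name in sorted(sources):
        for pair in sources[name]:
            u, v = pair[0], pair[1]
            if u == v:
                dropped += 1
                continue
            u, v = edge_key(u, v)
            if g.has_edge(u, v):
                g.edges[u, v]["sources"].add(name)
            else:
                g.add_edge(u, v, sources={name})
    g.graph["n_self_loops_dropped"] = dropped
    if dropped:
        logger.info("dropped %d self-loop edge rows at ingest", dropped)
    return g


def build_tissue_interactome(
    global_interactome: nx.Graph, expressome: Expressome, tissue: str
) -> nx.Graph:
    """Filter the global interactome down to one tissue.

    An edge is kept iff some (dataset, subpart) mapped to the tissue has
    BOTH endpoints in its expressed set -- co-expression within a single
    sample at the lowest hierarchy level. Edges recovered via different
    subparts of the tissue are united. Nodes are the endpoints of kept
    edges; expressed genes with no kept edge stay in the expressome only.
    """
    if tissue not in expressome.tissues:
        raise KeyError(f"unknown tissue: {tissue!r}")
    subpart_sets = [
        expressome.subpart_sets[key] for key in expressome.subparts_of(tissue)
    ]
    g = nx.Graph(scope=f"tissue:{tissue}")
    for u, v in global_interactome.edges:
        for genes in subpart_sets:
            if u in genes and v in genes:
                g.add_edge(*edge_key(u, v))
                break
    return g


def compute_core(tissue_interactomes: Mapping[str, nx.Graph]) -> nx.Graph:
    """Edge intersection of all tissue interactomes (the core sub-network)."""
    if not tissue_interactomes:
        raise ValueError("compute_core requires at least one tissue interactome")
    names = sorted(tissue_interactomes)
    core_edges = {edge_key(u, v) for u, v in tissue_interactomes[names[0]].edges}
    for name in names[1:]:
        edges = {edge_key(u, v) for u, v in tissue_interactomes[name].edges}
        core_edges &= edges
    g = nx.Graph(scope="core")
    g.add_edges_from(core_edges)
    return g


# ---------------------------------------------------------------------------
# edge breadth and TS-PPIs


@dataclass
class EdgeBreadth:
    """Per global edge: the set (and count) of tissues containing it."""

    tissues_per_edge: dict[tuple[str, str], frozenset[str]]
    n_tissues: int

    def count(self, u: str, v: str) -> int:
        return len(self.tissues_per_edge.get(edge_key(u, v), ()))

    def histogram(self) -> pd.Series:
        counts = pd.Series([len(t) for t in self.tissues_per_edge.values()], dtype=int)
        return counts.value_counts().reindex(range(0, self.n_tissues + 1), fill_value=0).sort_index()


def edge_breadth(
    global_interactome: nx.Graph, tissue_interactomes: Mapping[str, nx.Graph]
) -> EdgeBreadth:
    """Number of tissue interactomes containing each global edge (0..16)."""
    per_edge: dict[tuple[str, str], set[str]] = {
        edge_key(u, v): set() for u, v in global_interactome.edges
    }
    for tissue, g in tissue_interactomes.items():
        for u, v in g.edges:
            k = edge_key(u, v)
            if k not in per_edge:
                raise ValueError(f"tissue edge {k} absent from the global interactome")
            per_edge[k].add(tissue)
    frozen = {k: frozenset(v) for k, v in per_edge.items()}
    return EdgeBreadth(frozen, len(tissue_interactomes))


@dataclass
class TSPPISet:
    """Tissue-specific PPIs: per tissue, the edges of breadth <= k_ts there."""

    per_tissue: dict[str, frozenset[tuple[str, str]]]
    k_ts: int

    def count_for(self, gene: str, tissue: str) -> int:
        return sum(1 for e in self.per_tissue.get(tissue, ()) if gene in e)

    def partners_of(self, gene: str, tissue: str) -> list[str]:
        out = []
        for u, v in self.per_tissue.get(tissue, ()):
            if gene == u:
                out.append(v)
            elif gene == v:
                out.append(u)
        return sorted(out)

    def genes_with_tsppi(self) -> set[str]:
        out: set[str] = set()
        for edges in self.per_tissue.values():
            for u, v in edges:
                out.add(u)
                out.add(v)
        return out


def identify_ts_ppis(breadth: EdgeBreadth, k_ts: int = 3) -> TSPPISet:
    """Edges occurring in at most ``k_ts`` tissues, attributed to each of them.

    The specificity cutoff mirrors the gene-level tissue-specific class
    (expressed in 1-3 tissues); it is configurable because "almost
    exclusively" has no canonical numeric value.
    """
    if k_ts < 1:
        raise ValueError("k_ts must be >= 1")
    per_tissue: dict[str, set[tuple[str, str]]] = {}
    for edge, tissues in breadth.tissues_per_edge.items():
        if 1 <= len(tissues) <= k_ts:
            for t in tissues:
                per_tissue.setdefault(t, set()).add(edge)
    return TSPPISet({t: frozenset(e) for t, e in per_tissue.items()}, k_ts)


# ---------------------------------------------------------------------------
# writers


def write_edge_list(g: nx.Graph, path, source_attr: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "source"] if source_attr else ["gene_a", "gene_b"])
        for u, v in sorted(edge_key(*e) for e in g.edges):
            if source_attr:
                srcs = ",".join(sorted(g.edges[u, v].get("sources", ())))
                writer.writerow([u, v, srcs])
            else:
                writer.writerow([u, v])


def write_tsppi_table(tsppis: TSPPISet, breadth: EdgeBreadth, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["tissue", "gene_a", "gene_b", "breadth"])
        for tissue in sorted(tsppis.per_tissue):
            for u, v in sorted(tsppis.per_tissue[tissue]):
                writer.writerow([tissue, u, v, breadth.count(u, v)])
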