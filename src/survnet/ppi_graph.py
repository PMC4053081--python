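"""Protein-protein interaction network loading and topology queries.

The interaction network is an undirected, unweighted ``networkx.Graph`` whose
nodes are uppercase gene symbols.  Edges carry no weights: curated PPI flat
files (HPRD-style) record binary physical interactions only, so distances are
plain hop counts.  Self-loops are dropped on load and duplicate rows are
collapsed; the graph may be disconnected — seeds in small components simply
see small candidate pools.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

PPINetwork = nx.Graph
"""Alias documenting intent: an undirected gene-symbol interaction graph."""


def _normalize_symbol(sym: str) -> str:
    return sym.strip().upper()


def build_network(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build a validated PPI graph from (a, b) symbol pairs.

    Symbols are trimmed and uppercased; self-loops and duplicate edges
    (in either orientation) are removed, with counts logged.
    """
    net = nx.Graph()
    n_self = 0
    n_dup = 0
    for a, b in edges:
        a, b = _normalize_symbol(a), _normalize_symbol(b)
        if not a or not b:
            raise ValueError("empty gene symbol in edge list")
        if a == b:
            n_self += 1
            continue
        if net.has_edge(a, b):
            n_dup += 1
            continue
        net.add_edge(a, b)
    if n_self or n_dup:
        logger.info(
            "dropped %d self-loop and %d duplicate edge rows", n_self, n_dup
        )
    return net


def load_edge_list(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read an undirected interaction network from a flat file.

    Parameters
    ----------
    path
        Edge-list file.  ``tsv``: two whitespace/tab-separated symbol columns
        per row (extra columns ignored); lines starting with ``#`` are
        treated as headers/comments.  ``sif``: the three-column
        ``nodeA relation nodeB`` dialect.
    format
        ``"tsv"`` or ``"sif"``.

    Returns
    -------
    networkx.Graph
        Deduplicated, self-loop-free undirected network with uppercase,
        whitespace-trimmed gene symbols.

    Raises
    ------
    ValueError
        On an empty file, an unknown format, or a malformed row (too few
        columns) — the error names the offending line number.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f for f in fields if f.strip()]
            if format == "sif":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF row needs >=3 columns, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[2]))
            else:
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: edge row needs >=2 columns, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    return build_network(pairs)


def neighborhood(net: nx.Graph, seed: str, k: int) -> set[str]:
    """All nodes within unweighted shortest-path distance ``k`` of ``seed``.

    Includes the seed itself.  ``k`` must be >= 1.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = nx.single_source_shortest_path_length(net, seed, cutoff=k)
    return set(dist)


def induced_edges(net: nx.Graph, genes: Iterable[str]) -> set[frozenset[str]]:
    """Edges of ``net`` with both endpoints in ``genes``.

    Returned as frozensets so orientation never matters.
    """
    genes = set(genes)
    missing = genes - set(net.nodes)
    if missing:
        raise KeyError(f"genes not in network: {sorted(missing)[:5]}")
    return {
        frozenset((a, b)) for a, b in net.subgraph(genes).edges()
    }


def is_connected(net: nx.Graph, genes: Iterable[str]) -> bool:
    """True iff the subgraph induced by ``genes`` is connected."""
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = genes - set(net.nodes)
    if missing:
        raise KeyError(f"genes not in network: {sorted(missing)[:5]}")
    if len(genes) == 1:
        return True
    return nx.is_connected(net.subgraph(genes))
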