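"""Pipeline orchestration, module merging, table and network exports.

``run_pipeline`` wires the stages end to end (load -> preprocess -> search
-> univariate screen -> optional enrichment -> merge -> export) and leaves a
run log with the resolved configuration beside the outputs, so any results
directory is self-describing.

``merge_modules`` reproduces the figure-style summary in which top-ranked
subnetworks sharing proteins are collapsed into larger functional modules:
two subnetworks belong to the same module when they share at least one gene
(or, optionally, exceed a Jaccard threshold), and a module is the union of
its subnetworks' genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from survnet.cox import univariate_cox
from survnet.enrichment import hypergeom_enrich, load_gmt, select_survival_genes
from survnet.expression_io import (
    align_samples,
    collapse_probes,
    load_expression,
    load_survival,
    standardize,
)
from survnet.ppi_graph import load_edge_list
from survnet.search import SearchConfig, Subnetwork, search_all_seeds, subnetwork_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Module:
    """A merged functional module with provenance.

    ``genes`` is the union over member subnetworks; ``members`` identifies
    the contributing subnetworks by rank (or list position when unranked).
    """

    genes: frozenset[str]
    members: tuple[int, ...]


def merge_modules(
    subnets: list[Subnetwork] | list[set[str]] | list[frozenset[str]],
    jaccard_threshold: float | None = None,
) -> list[Module]:
    """Collapse subnetworks into modules by shared-gene connectivity.

    Accepts :class:`Subnetwork` objects or plain gene sets.  With the
    default ``jaccard_threshold=None`` any single shared gene links two
    subnetworks; a threshold in (0, 1] requires that Jaccard similarity
    instead.  Modules are connected components of the resulting relation,
    returned sorted by their smallest member id.
    """
    gene_sets: list[frozenset[str]] = []
    labels: list[int] = []
    for i, s in enumerate(subnets):
        if isinstance(s, Subnetwork):
            gene_sets.append(frozenset(s.genes))
            labels.append(s.rank if s.rank is not None else i + 1)
        else:
            gene_sets.append(frozenset(s))
            labels.append(i + 1)
    g = nx.Graph()
    g.add_nodes_from(range(len(gene_sets)))
    for i, j in combinations(range(len(gene_sets)), 2):
        inter = gene_sets[i] & gene_sets[j]
        if not inter:
            continue
        if jaccard_threshold is None:
            g.add_edge(i, j)
        else:
            union = gene_sets[i] | gene_sets[j]
            if len(inter) / len(union) >= jaccard_threshold:
                g.add_edge(i, j)
    modules = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(labels[i] for i in comp))
        genes = frozenset().union(*(gene_sets[i] for i in comp))
        modules.append(Module(genes=genes, members=members))
    modules.sort(key=lambda mod: mod.members)
    return modules


def _membership_labels(subnets: list[Subnetwork]) -> dict[str, list[str]]:
    labels: dict[str, list[str]] = {}
    for i, s in enumerate(subnets):
        tag = f"rank{s.rank}" if s.rank is not None else f"subnet{i + 1}"
        for gene in s.genes:
            labels.setdefault(gene, []).append(tag)
    return labels


def export_network(
    subnets: list[Subnetwork], path: str | Path, format: str = "sif"
) -> Path:
    """Write the union of subnetworks as SIF or GraphML.

    Nodes carry a ``subnetworks`` attribute listing every subnetwork (by
    rank) they belong to — a gene shared by several subnetworks lists them
    all.  Edges are the induced interaction edges.  Singleton subnetworks
    contribute isolated nodes.
    """
    if not subnets:
        raise ValueError("no subnetworks to export")
    path = Path(path)
    labels = _membership_labels(subnets)
    g = nx.Graph()
    for gene, tags in sorted(labels.items()):
        g.add_node(gene, subnetworks=",".join(tags))
    for s in subnets:
        for edge in sorted(map(sorted, s.edges)):
            g.add_edge(edge[0], edge[1])
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, g.edges())):
                fh.write(f"{a}\tpp\t{b}\n")
            for node in sorted(g.nodes):
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return path


def subnetworks_table(subnets: list[Subnetwork]) -> pd.DataFrame:
    """Tabular form of search results (one row per subnetwork)."""
    rows = []
    for i, s in enumerate(subnets):
        univ = ";".join(
            f"{g}={s.per_gene_univariate_p[g]:.6g}"
            for g in s.genes
            if g in s.per_gene_univariate_p
        )
        rows.append(
            {
                "rank": s.rank if s.rank is not None else i + 1,
                "seed": s.seed,
                "genes": ",".join(s.genes),
                "n_genes": s.n_genes,
                "n_edges": s.n_edges,
                "p_multivariate": s.p_multivariate,
                "p_adjusted": s.p_adjusted,
                "univariate_p": univ,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "seed",
            "genes",
            "n_genes",
            "n_edges",
            "p_multivariate",
            "p_adjusted",
            "univariate_p",
        ],
    )


def modules_table(modules: list[Module]) -> pd.DataFrame:
    rows = [
        {
            "module": i + 1,
            "n_genes": len(mod.genes),
            "member_subnetworks": ",".join(map(str, mod.members)),
            "genes": ",".join(sorted(mod.genes)),
        }
        for i, mod in enumerate(modules)
    ]
    return pd.DataFrame(
        rows, columns=["module", "n_genes", "member_subnetworks", "genes"]
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved inputs and options of one pipeline run."""

    edge_list: str
    expression: str
    survival: str
    outdir: str
    probe_map: str | None = None
    gmt: str | None = None
    edge_format: str = "tsv"
    log2: bool = False
    zscore: bool = True
    missing: str = "drop"
    alpha_univariate: float = 0.05
    search: SearchConfig = field(default_factory=SearchConfig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full discovery pipeline and write the result bundle.

    Writes ``subnetworks.tsv``, ``univariate.tsv``, ``modules.tsv``,
    ``enrichment.tsv`` (when a GMT is given), SIF/GraphML exports and
    ``run_log.json`` into ``cfg.outdir``.  Returns a summary dict.  Any
    stage failure is re-raised with the stage name attached.
    """
    for p in (cfg.edge_list, cfg.expression, cfg.survival, cfg.probe_map, cfg.gmt):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        net = load_edge_list(cfg.edge_list, format=cfg.edge_format)
        m = load_expression(cfg.expression, missing=cfg.missing)
        if cfg.probe_map is not None:
            pmap = pd.read_csv(
                cfg.probe_map, sep="\t", index_col=0, comment="#"
            ).iloc[:, 0]
            m = collapse_probes(m, pmap)
        surv = load_survival(cfg.survival)

        stage = "preprocess"
        if cfg.log2:
            if (m.to_numpy() < 0).any():
                raise ValueError("log2 transform requires non-negative values")
            m = np.log2(m + 1.0)
        if cfg.zscore:
            m = standardize(m)
        m, surv = align_samples(m, surv)

        stage = "search"
        results = search_all_seeds(net, m, surv, cfg.search)
        subnetworks_table(results).to_csv(
            outdir / "subnetworks.tsv", sep="\t", index=False
        )

        stage = "univariate"
        univ = univariate_cox(m, surv, ties=cfg.search.ties)
        univ.to_csv(outdir / "univariate.tsv", sep="\t")
        survival_genes = select_survival_genes(univ, alpha=cfg.alpha_univariate)

        stage = "enrichment"
        n_enriched = None
        if cfg.gmt is not None:
            collection = load_gmt(cfg.gmt, universe=map(str, m.index))
            enr = hypergeom_enrich(survival_genes, collection)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            n_enriched = int((enr["fdr"] <= 0.05).sum())

        stage = "report"
        modules = merge_modules(results)
        modules_table(modules).to_csv(outdir / "modules.tsv", sep="\t", index=False)
        if results:
            export_network(results, outdir / "subnetworks.sif", format="sif")
            export_network(results, outdir / "subnetworks.graphml", format="graphml")

        count, mean_genes, mean_edges = subnetwork_stats(results)
        summary = {
            "n_seeds": int(len(set(map(str, m.index)) & set(net.nodes))),
            "n_subnetworks": count,
            "mean_genes": mean_genes,
            "mean_edges": mean_edges,
            "n_modules": len(modules),
            "n_survival_genes": len(survival_genes),
            "n_enriched_sets_fdr05": n_enriched,
        }
        log = {
            "config": {**asdict(cfg), "search": asdict(cfg.search)},
            "summary": summary,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
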