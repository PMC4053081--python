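"""Univariate survival-gene selection and hypergeometric gene-set enrichment.

The comparator analysis: genes whose single-gene Cox model reaches P < 0.05
form the survival-gene list, and user-supplied gene-set collections (GMT
format, e.g. GO slims or pathway databases) are tested for over-representation
of that list with a one-sided hypergeometric test, BH-corrected across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from survnet.cox import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """A named collection of gene sets with an optional explicit universe.

    ``sets`` maps set_id -> (human-readable name, frozenset of gene symbols).
    When ``universe`` is None the effective universe is the union of all set
    members and the selected genes — a permissive default; supplying the
    full assayed gene list is the recommended choice.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def effective_universe(self, selected=()) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        u: set[str] = set(selected)
        for _, members in self.sets.values():
            u |= members
        return frozenset(u)


def load_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file: set_id TAB description TAB member genes..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs >=3 columns")
            sid, name = fields[0].strip(), fields[1].strip()
            members = frozenset(
                g.strip().upper() for g in fields[2:] if g.strip()
            )
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = (name, members)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    if universe is not None:
        universe = frozenset(str(g).upper() for g in universe) or None
    return GeneSetCollection(sets=sets, universe=universe)


def select_survival_genes(univariate: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes with univariate Cox P < alpha, sorted by P ascending.

    ``univariate`` is the table from :func:`survnet.cox.univariate_cox`
    (indexed by gene, with a ``p`` column), or any gene -> p mapping.
    """
    if not isinstance(univariate, pd.DataFrame):
        univariate = pd.DataFrame({"p": pd.Series(dict(univariate))})
    if univariate.empty:
        return []
    if ((univariate["p"] < 0) | (univariate["p"] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    hits = univariate[univariate["p"] < alpha].sort_values("p", kind="stable")
    return [str(g) for g in hits.index]


def hypergeom_enrich(
    selected: list[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided over-representation test for every set in the collection.

    For a universe of M genes, a set of K, and N selected genes with k in
    the set, the P value is P(X >= k) for X ~ Hypergeometric(M, K, N).
    Selected genes outside the universe are dropped (logged); set members
    outside an explicit universe are likewise ignored.  Returns a DataFrame
    indexed by set_id with columns name, set_size, overlap, p, fdr, sorted
    by p ascending.
    """
    universe = collection.effective_universe(selected)
    if not universe:
        raise ValueError("empty gene universe")
    sel = frozenset(g.upper() for g in selected)
    outside = sel - universe
    if outside:
        logger.info("dropping %d selected genes outside the universe", len(outside))
        sel = sel & universe
    M, N = len(universe), len(sel)
    rows = []
    for sid, (name, members) in collection.sets.items():
        members = members & universe
        K = len(members)
        k = len(members & sel)
        # P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((sid, name, K, k, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "set_size", "overlap", "p"]
    ).set_index("set_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set_id"], kind="stable")
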