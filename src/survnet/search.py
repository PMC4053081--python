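"""Seed-centred greedy search for survival-related subnetworks.

Every network protein with matched expression data acts as a seed.  Its
candidate pool is the set of expressed genes within shortest-path distance
``k`` of the seed (distances measured on the full interaction network, so a
non-expressed protein can still bridge two expressed ones).  Growth is
adjacency-constrained forward selection: starting from the seed alone, each
step fits a multivariate Cox model for every pool gene adjacent to the
current member set and adopts the candidate with the smallest global Wald P
value; growth stops when no candidate improves the P value, the pool is
exhausted, or the size cap is reached.  The member set with the minimum P
value anywhere along the growth path is reported for that seed — which by
construction is never worse than the seed-only model.

Per-seed minimum P values are then Benjamini-Hochberg adjusted across seeds
and thresholded.  The greedy min-P selection is anti-conservative (the same
data pick the model and score it); the FDR gate is applied to the selected
P values as-is, so downstream users should treat adjusted P values as a
ranking device rather than calibrated error rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from survnet.cox import CoxEngine, CoxFit, bh_adjust, univariate_cox
from survnet.expression_io import SurvivalData, align_samples
from survnet.ppi_graph import induced_edges, is_connected, neighborhood

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the subnetwork search.

    Attributes
    ----------
    k : int
        Maximum shortest-path distance from the seed (default 3).
    max_size : int
        Maximum genes per subnetwork (default 10).
    alpha_adjusted : float
        Reporting threshold on the BH-adjusted P value (default 0.001).
    min_improvement : float
        Required decrease in P to keep growing; 0 means any strict decrease.
    alpha_enter : float
        Stepwise entry significance: the adopted candidate's own coefficient
        must reach this per-coefficient Wald P (default 0.05, the classical
        variable-entry threshold).  Without an entry gate the greedy min-P
        rule accumulates noise covariates without bound under the null;
        set to 1.0 to disable.
    ties : str
        Tie handling for the Cox partial likelihood, breslow or efron.
    df_guard : float
        A candidate model with p covariates is skipped unless
        p < n_events * df_guard (default 1/3), avoiding near-saturated fits.
    random_seed : int
        Recorded for provenance; the search itself is deterministic (ties in
        P are broken by gene symbol after rounding to 12 significant digits).
    """

    k: int = 3
    max_size: int = 10
    alpha_adjusted: float = 0.001
    min_improvement: float = 0.0
    alpha_enter: float = 0.05
    ties: str = "breslow"
    df_guard: float = 1.0 / 3.0
    random_seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if not (0 < self.alpha_adjusted <= 1):
            raise ValueError("alpha_adjusted must lie in (0, 1]")


@dataclass(frozen=True)
class Subnetwork:
    """One reported survival-related subnetwork.

    ``genes`` are ordered by addition along the growth path (seed first);
    ``p_multivariate`` is the global Wald P of the reported member set and
    ``p_adjusted`` its BH-adjusted value across seeds (NaN until adjustment).
    """

    seed: str
    genes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    p_multivariate: float
    p_adjusted: float
    per_gene_univariate_p: dict[str, float] = field(repr=False)
    fit: CoxFit = field(repr=False)
    rank: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def candidate_pool(
    net: nx.Graph, m: pd.DataFrame, seed: str, k: int
) -> set[str]:
    """Expressed genes within distance ``k`` of ``seed``.

    Distances are computed on the full network before filtering by
    expression availability, so membership is restricted to measured genes
    but reachability is not.  Always contains the seed.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    if seed not in m.index:
        raise KeyError(f"seed {seed!r} has no expression row")
    ball = neighborhood(net, seed, k)
    expressed = set(map(str, m.index))
    return {g for g in ball if g in expressed} | {seed}


def _p_key(p: float) -> float:
    """P value rounded to 12 significant digits for tie detection.

    Rounding to significant digits (not decimal places) keeps very small P
    values distinguishable while making equality robust to last-bit
    floating-point noise; exact ties are then broken by gene symbol.
    """
    return float(f"{p:.12e}") if p > 0 else 0.0


def _univ_p_lookup(univ: pd.DataFrame | None, genes) -> dict[str, float]:
    if univ is None:
        return {}
    return {g: float(univ.loc[g, "p"]) for g in genes if g in univ.index}


def grow_subnetwork(
    seed: str,
    pool: set[str],
    net: nx.Graph,
    m: pd.DataFrame,
    surv: SurvivalData,
    cfg: SearchConfig = SearchConfig(),
    engine: CoxEngine | None = None,
    univ: pd.DataFrame | None = None,
) -> Subnetwork:
    """Greedy adjacency-constrained growth from one seed.

    Returns the member set attaining the minimum global Wald P anywhere
    along the growth path (not necessarily the final set).  Candidates whose
    fit does not converge, or whose covariate count would breach the
    events-per-covariate guard, are skipped.  A seed whose own model does
    not converge yields a flagged single-gene subnetwork with P = 1.
    """
    if seed not in pool:
        raise ValueError("seed must be a member of its own pool")
    if engine is None:
        m, surv = align_samples(m, surv)
        engine = CoxEngine(surv, ties=cfg.ties)
    if list(m.columns) != list(engine.surv.sample_ids):
        m = m[list(engine.surv.sample_ids)]

    row_of = {str(g): i for i, g in enumerate(m.index)}
    vals = m.to_numpy(float)
    max_df = engine.n_events * cfg.df_guard

    members = [seed]
    cur_X = vals[row_of[seed]][:, None]
    cur_fit = engine.fit(cur_X, gene_ids=(seed,))
    best_members, best_fit = list(members), cur_fit
    cur_p = cur_fit.p_value if cur_fit.converged else 1.0
    best_p = cur_p
    n_skipped = 0

    if cur_fit.converged:
        while len(members) < cfg.max_size:
            if len(members) + 1 >= max_df:
                n_skipped += 1
                break
            member_set = set(members)
            frontier = sorted(
                {
                    nb
                    for g in members
                    for nb in net.neighbors(g)
                    if nb in pool and nb not in member_set
                }
            )
            if not frontier:
                break
            step_best = None  # (p_rounded, gene, fit, X)
            for cand in frontier:
                X = np.hstack([cur_X, vals[row_of[cand]][:, None]])
                fit = engine.fit(
                    X,
                    gene_ids=tuple(members) + (cand,),
                    beta0=np.append(cur_fit.beta, 0.0),
                )
                if not fit.converged:
                    n_skipped += 1
                    continue
                key = _p_key(fit.p_value)
                if step_best is None or key < step_best[0]:
                    step_best = (key, cand, fit, X)
            if step_best is None:
                break
            _, cand, fit, X = step_best
            if not (fit.p_value < cur_p - cfg.min_improvement and fit.p_value < cur_p):
                break
            if fit.per_coef_p[-1] >= cfg.alpha_enter:
                break
            members.append(cand)
            cur_X, cur_fit, cur_p = X, fit, fit.p_value
            if cur_p < best_p:
                best_members, best_fit, best_p = list(members), cur_fit, cur_p

    if n_skipped:
        logger.debug("seed %s: skipped %d candidate fits", seed, n_skipped)
    return Subnetwork(
        seed=seed,
        genes=tuple(best_members),
        edges=frozenset(induced_edges(net, best_members)),
        p_multivariate=best_p,
        p_adjusted=float("nan"),
        per_gene_univariate_p=_univ_p_lookup(univ, best_members),
        fit=best_fit,
    )


def exhaustive_subnetwork(
    seed: str,
    pool: set[str],
    net: nx.Graph,
    m: pd.DataFrame,
    surv: SurvivalData,
    cfg: SearchConfig = SearchConfig(max_size=4),
) -> Subnetwork:
    """Minimum-P connected subnetwork by exhaustive enumeration.

    Enumerates every connected subset of the pool that contains the seed,
    up to ``cfg.max_size`` genes (capped at 5 — the count is exponential),
    fits each, and returns the minimum-P set.  Oracle companion to the
    greedy :func:`grow_subnetwork`.
    """
    if cfg.max_size > 5:
        raise ValueError("exhaustive enumeration is capped at max_size <= 5")
    m, surv = align_samples(m, surv)
    engine = CoxEngine(surv, ties=cfg.ties)
    row_of = {str(g): i for i, g in enumerate(m.index)}
    vals = m.to_numpy(float)

    best = None  # (p_rounded, genes, fit)
    others = sorted(pool - {seed})
    for size in range(0, cfg.max_size):
        for combo in combinations(others, size):
            genes = (seed,) + combo
            if len(genes) > 1 and not is_connected(net, genes):
                continue
            X = vals[[row_of[g] for g in genes]].T
            fit = engine.fit(X, gene_ids=genes)
            if not fit.converged:
                continue
            key = (_p_key(fit.p_value), genes)
            if best is None or key < (best[0], best[1]):
                best = (key[0], genes, fit)
    if best is None:
        return grow_subnetwork(seed, {seed}, net, m, surv, cfg)
    _, genes, fit = best
    return Subnetwork(
        seed=seed,
        genes=genes,
        edges=frozenset(induced_edges(net, genes)),
        p_multivariate=fit.p_value,
        p_adjusted=float("nan"),
        per_gene_univariate_p={},
        fit=fit,
    )


def search_all_seeds(
    net: nx.Graph,
    m: pd.DataFrame,
    surv: SurvivalData,
    cfg: SearchConfig = SearchConfig(),
) -> list[Subnetwork]:
    """Run the greedy search from every mappable seed and FDR-filter.

    Every node present in both the network and the expression matrix seeds
    one growth; the per-seed minimum P values are BH-adjusted across seeds,
    results are filtered to ``p_adjusted <= cfg.alpha_adjusted``, sorted by
    adjusted then raw P, and ranked from 1.
    """
    m, surv = align_samples(m, surv)
    m = m.loc[~m.index.duplicated()]
    seeds = sorted(set(map(str, m.index)) & set(net.nodes))
    if not seeds:
        raise ValueError("no network node has an expression row")
    engine = CoxEngine(surv, ties=cfg.ties)
    univ = univariate_cox(m.loc[sorted(set(map(str, m.index)) & set(net.nodes))], surv, ties=cfg.ties)

    results = []
    for seed in seeds:
        pool = candidate_pool(net, m, seed, cfg.k)
        results.append(
            grow_subnetwork(seed, pool, net, m, surv, cfg, engine=engine, univ=univ)
        )
    adj = bh_adjust([s.p_multivariate for s in results])
    kept = [
        Subnetwork(
            seed=s.seed,
            genes=s.genes,
            edges=s.edges,
            p_multivariate=s.p_multivariate,
            p_adjusted=float(a),
            per_gene_univariate_p=s.per_gene_univariate_p,
            fit=s.fit,
        )
        for s, a in zip(results, adj)
        if a <= cfg.alpha_adjusted
    ]
    kept.sort(key=lambda s: (s.p_adjusted, s.p_multivariate, s.seed))
    return [
        Subnetwork(
            seed=s.seed,
            genes=s.genes,
            edges=s.edges,
            p_multivariate=s.p_multivariate,
            p_adjusted=s.p_adjusted,
            per_gene_univariate_p=s.per_gene_univariate_p,
            fit=s.fit,
            rank=i + 1,
        )
        for i, s in enumerate(kept)
    ]


def subnetwork_stats(results: list[Subnetwork]) -> tuple[int, float, float]:
    """(count, mean genes per subnetwork, mean edges per subnetwork)."""
    if not results:
        return (0, 0.0, 0.0)
    return (
        len(results),
        float(np.mean([s.n_genes for s in results])),
        float(np.mean([s.n_edges for s in results])),
    )
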