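"""Geometric-mean consensus ranking across the three stability algorithms.

geNorm, NormFinder and BestKeeper measure different things and rarely agree
gene-for-gene; the comprehensive ranking aggregates them by (1) converting
each method's stability scores to *dense* ranks - tied scores share a rank
and the next distinct score takes the next consecutive integer (1,1,2,3,...)
- and (2) ordering genes by the geometric mean of their three ranks.  Dense
ranking matters because geNorm always ends with two jointly-ranked genes:
they both get rank 1 and the next gene rank 2, which is what makes the
geometric means of differently-tied methods comparable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .bestkeeper import BestkeeperResult
from .data_io import ConsensusRanking, ConsistencyError
from .genorm import GenormResult
from .normfinder import NormfinderResult


def dense_ranks(scores: Mapping[str, float], ascending: bool = True) -> dict[str, int]:
    """Dense ranks of a score map (ascending = lower score ranks first).

    Exactly equal scores share a rank; the next distinct score receives the
    next consecutive integer.
    """
    if not scores:
        raise ValueError("empty score map")
    distinct = sorted(set(scores.values()), reverse=not ascending)
    rank_of = {s: i + 1 for i, s in enumerate(distinct)}
    return {g: rank_of[s] for g, s in scores.items()}


def geometric_mean_ranking(
        per_method_ranks: Mapping[str, Mapping[str, int]],
        optimal_n: int | None = None,
        pairwise_variations: list[float] | None = None) -> ConsensusRanking:
    """Aggregate per-method ranks into the comprehensive ranking.

    All methods must cover the same gene set.  The final order is ascending
    by geometric-mean rank, ties broken lexicographically by gene id.
    """
    methods = list(per_method_ranks)
    if not methods:
        raise ValueError("no method rankings supplied")
    gene_set = set(per_method_ranks[methods[0]])
    for m in methods[1:]:
        if set(per_method_ranks[m]) != gene_set:
            raise ConsistencyError(f"gene set of method {m!r} differs")
    geomean = {}
    for g in gene_set:
        per = [per_method_ranks[m][g] for m in methods]
        gm = float(np.exp(np.mean(np.log(per))))
        # clamp float round-off so the min/max-rank envelope holds exactly
        geomean[g] = min(max(gm, float(min(per))), float(max(per)))
    order = sorted(gene_set, key=lambda g: (geomean[g], g))
    return ConsensusRanking(
        ranks={m: dict(per_method_ranks[m]) for m in methods},
        geomean=geomean, order=order, optimal_n=optimal_n,
        pairwise_variations=pairwise_variations)


def build_consensus(genorm: GenormResult,
                    nf: NormfinderResult,
                    bk: BestkeeperResult) -> ConsensusRanking:
    """Comprehensive ranking from the three method results.

    Rank sources: geNorm M at exclusion (the final pair ties at rank 1),
    NormFinder stability, BestKeeper SD of raw Ct.  The optimal reference-gene
    count from geNorm's pairwise-variation analysis is attached.
    """
    gene_set = set(genorm.m_at_exclusion)
    if set(nf.stability) != gene_set or set(bk.stats.index) != gene_set:
        raise ConsistencyError("the three results cover different gene sets")
    ranks = {
        "genorm": dense_ranks(genorm.m_at_exclusion),
        "normfinder": dense_ranks(nf.stability),
        "bestkeeper": dense_ranks({g: float(bk.stats.at[g, "sd"])
                                   for g in bk.stats.index}),
    }
    return geometric_mean_ranking(ranks, optimal_n=genorm.optimal_n,
                                  pairwise_variations=genorm.pairwise_variations)
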