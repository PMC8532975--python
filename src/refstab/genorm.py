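"""geNorm expression-stability analysis.

The geNorm measure rests on the observation that the expression *ratio* of
two ideal reference genes is constant across samples.  For genes j and k the
pairwise variation

    V_jk = SD over samples of log2(Q_j / Q_k)       (sample SD, n-1)

is zero when the two genes are perfectly co-regulated or both perfectly
stable.  The gene-stability measure M_j is the arithmetic mean of V_jk over
all other candidates k; low M means stable.  Ranking proceeds by stepwise
exclusion: the gene with the highest M is removed, M values are recomputed
on the remaining set, and so on until two genes remain.  Those two cannot be
distinguished further (their M values are identical by construction - both
equal V of the pair) and are ranked jointly first.

The number of reference genes needed is decided from normalization factors:
NF_n(s) is the geometric mean of the n top-ranked genes' quantities in
sample s, and V_n = SD over samples of log2(NF_n / NF_{n+1}).  The smallest
n whose V_n falls below a cutoff (conventionally 0.15) is the recommended
gene count: adding gene n+1 would no longer change the normalization factor
appreciably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import InsufficientDataError, StabilityTable
from .quantification import QuantityMatrix

log = logging.getLogger("refstab")

DEFAULT_V_CUTOFF = 0.15


@dataclass
class GenormResult:
    """Stepwise geNorm outcome.

    ``m_at_exclusion`` maps every gene to its M value at the step it was
    excluded; the two final genes share the final pair's M.  ``ranking``
    lists genes most-stable first, the tied final pair (lexicographic order)
    in positions 1-2.  ``pairwise_variations`` holds V_n for n = 2..G-1.
    """

    m_at_exclusion: dict[str, float]
    ranking: list[str]
    tied_pair: tuple[str, str]
    exclusion_order: list[str]
    pairwise_variations: list[float]
    optimal_n: int

    def table(self) -> StabilityTable:
        return StabilityTable(method="genorm", scores=dict(self.m_at_exclusion),
                              ranking=list(self.ranking))


def _log2_matrix(q: QuantityMatrix, genes: list[str]) -> pd.DataFrame:
    vals = q.values.loc[genes]
    return np.log2(vals)


def pairwise_gene_variation(q: QuantityMatrix, gene_j: str, gene_k: str) -> float:
    """SD over samples of log2(Q_j / Q_k); symmetric in its gene arguments.

    Samples where either gene is missing are dropped pairwise; fewer than two
    common samples is an error.
    """
    lj = np.log2(q.values.loc[gene_j])
    lk = np.log2(q.values.loc[gene_k])
    ratios = (lj - lk).dropna()
    if len(ratios) < 2:
        raise InsufficientDataError(
            f"genes {gene_j}/{gene_k}: fewer than 2 common samples")
    return float(ratios.std(ddof=1))


def m_values(q: QuantityMatrix, genes: list[str] | None = None) -> dict[str, float]:
    """Gene-stability measure M for each gene of the (sub)set.

    M_j is the mean of V_jk over all k != j; with exactly two genes both M
    values equal their pairwise variation.
    """
    genes = list(q.genes if genes is None else genes)
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    logs = _log2_matrix(q, genes)
    m: dict[str, float] = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = (logs.loc[j] - logs.loc[k]).dropna()
            if len(ratios) < 2:
                raise InsufficientDataError(
                    f"genes {j}/{k}: fewer than 2 common samples")
            vs.append(float(ratios.std(ddof=1)))
        m[j] = float(np.mean(vs))
    return m


def rank_genorm(q: QuantityMatrix,
                v_cutoff: float = DEFAULT_V_CUTOFF) -> GenormResult:
    """Full stepwise geNorm ranking plus the V_n/n+1 analysis.

    Ties at the maximum M are broken deterministically: the lexicographically
    smallest gene id among the tied genes is excluded first (and the tie is
    logged).  Requires at least three genes.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 genes")

    remaining = list(genes)
    m_at_exclusion: dict[str, float] = {}
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        m = m_values(q, remaining)
        worst_m = max(m.values())
        tied = sorted(g for g, v in m.items() if v == worst_m)
        if len(tied) > 1:
            log.info("geNorm tie at M=%.4f between %s; excluding %s",
                     worst_m, tied, tied[0])
        worst = tied[0]
        m_at_exclusion[worst] = worst_m
        exclusion_order.append(worst)
        remaining.remove(worst)

    final_m = m_values(q, remaining)
    pair = tuple(sorted(remaining))
    shared = final_m[pair[0]]            # both equal the pair's V by construction
    m_at_exclusion[pair[0]] = shared
    m_at_exclusion[pair[1]] = shared

    ranking = [pair[0], pair[1]] + list(reversed(exclusion_order))
    v = nf_pairwise_variation(q, ranking)
    return GenormResult(m_at_exclusion=m_at_exclusion, ranking=ranking,
                        tied_pair=pair, exclusion_order=exclusion_order,
                        pairwise_variations=v,
                        optimal_n=optimal_gene_count(v, cutoff=v_cutoff))


def nf_pairwise_variation(q: QuantityMatrix, ranking: list[str]) -> list[float]:
    """V_n = SD over samples of log2(NF_n / NF_{n+1}) for n = 2..G-1.

    NF_n(s) is the geometric mean of the top-n ranked genes' quantities in
    sample s.  Samples with a missing quantity among the genes involved are
    dropped for that comparison.
    """
    if len(ranking) < 3:
        raise ValueError("pairwise variation needs a ranking of >= 3 genes")
    logs = _log2_matrix(q, list(ranking))
    vs: list[float] = []
    for n in range(2, len(ranking)):
        log_nf_n = logs.iloc[:n].mean(axis=0)
        log_nf_n1 = logs.iloc[: n + 1].mean(axis=0)
        diff = (log_nf_n - log_nf_n1).dropna()
        if len(diff) < 2:
            raise InsufficientDataError(f"V_{n}/{n+1}: fewer than 2 usable samples")
        vs.append(float(diff.std(ddof=1)))
    return vs


def optimal_gene_count(v: list[float], cutoff: float = DEFAULT_V_CUTOFF) -> int:
    """Smallest n with V_n/n+1 below the cutoff; n_max with a warning if none.

    ``v[0]`` is V_2/3, so a first value below the cutoff recommends 2 genes.
    """
    if not v:
        raise ValueError("empty pairwise-variation sequence")
    for i, value in enumerate(v):
        if value < cutoff:
            return i + 2
    n_max = len(v) + 2
    log.warning("no V_n/n+1 below %.2f; recommending all %d genes", cutoff, n_max)
    return n_max
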