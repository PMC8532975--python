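"""Transcriptome-based screening of candidate reference genes.

A good reference gene is abundantly and, above all, *constantly* expressed
across the conditions of interest.  Screening therefore works on an RPKM
matrix over developmental stages and uses the coefficient of variation
(CV = SD / mean, sample SD with the n-1 denominator) as the constancy index:
genes with CV below a threshold (default 0.6) are retained and the top N by
mean RPKM become the qPCR candidates.

Relative expression profiles (RPKM divided by the gene's own mean across
stages) put all candidates on a common scale for plotting/eyeballing; each
gene's profile averages to exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import DomainError, ExpressionMatrix

log = logging.getLogger("refstab")


@dataclass
class ScreeningResult:
    """Outcome of CV-based candidate screening.

    ``stats``    per-gene mean, SD and CV of RPKM across stages.
    ``passing``  genes with CV below the threshold, ordered by descending
                 mean RPKM (ties: ascending CV, then gene id), truncated to
                 the requested top N.
    ``profiles`` per-gene relative expression (stage -> RPKM / gene mean).
    """

    stats: pd.DataFrame
    passing: list[str]
    profiles: pd.DataFrame
    cv_threshold: float
    undefined_cv: list[str] = field(default_factory=list)


def _stage_level(matrix: ExpressionMatrix,
                 stage_of: Mapping[str, str] | None) -> pd.DataFrame:
    """Collapse replicate-level columns to per-stage means if a mapping is given."""
    if stage_of is None:
        return matrix.values
    absent = [c for c in matrix.conditions if c not in stage_of]
    if absent:
        raise DomainError(f"conditions without a stage assignment: {absent}")
    return matrix.values.T.groupby([stage_of[c] for c in matrix.conditions],
                                   sort=False).mean().T


def compute_cv(matrix: ExpressionMatrix,
               stage_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1) and CV of expression across stages.

    Genes with zero mean have an undefined CV; they are reported with
    ``cv = NaN`` and a warning rather than raising, so that one silent gene
    cannot abort a screen.

    Returns a DataFrame indexed by gene with columns ``mean``, ``sd``, ``cv``.
    """
    values = _stage_level(matrix, stage_of)
    if values.shape[1] < 2:
        raise DomainError("CV needs at least two stages per gene")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    undefined = list(mean.index[~(mean > 0)])
    if undefined:
        log.warning("undefined CV (zero mean RPKM) for: %s", ", ".join(undefined))
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})


def relative_profile(matrix: ExpressionMatrix,
                     stage_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Each gene's RPKM divided by its own mean across stages (profile mean = 1).

    Zero-mean genes cannot be scaled and are skipped with a warning.
    """
    values = _stage_level(matrix, stage_of)
    mean = values.mean(axis=1)
    zero = list(mean.index[~(mean > 0)])
    if zero:
        log.warning("skipping zero-mean gene(s) in relative profile: %s",
                    ", ".join(zero))
    kept = values.drop(index=zero)
    return kept.div(mean.drop(index=zero), axis=0)


def screen_candidates(matrix: ExpressionMatrix,
                      cv_threshold: float = 0.6,
                      top_n: int = 18,
                      stage_of: Mapping[str, str] | None = None) -> ScreeningResult:
    """Keep genes with CV < ``cv_threshold``, then take the ``top_n`` by mean RPKM.

    Ordering of the passing list: descending mean RPKM, ties broken by
    ascending CV and then lexicographic gene id.  If fewer genes pass than
    ``top_n``, all passing genes are returned with a warning.
    """
    if cv_threshold <= 0:
        raise DomainError("cv_threshold must be positive")
    if top_n < 1:
        raise DomainError("top_n must be >= 1")
    stats = compute_cv(matrix, stage_of)
    ok = stats[stats["cv"] < cv_threshold]
    ordered = ok.assign(_gene=ok.index).sort_values(
        by=["mean", "cv", "_gene"], ascending=[False, True, True])
    passing = list(ordered.index[:top_n])
    if len(passing) < top_n:
        log.warning("only %d gene(s) pass CV < %g (requested top %d)",
                    len(passing), cv_threshold, top_n)
    profiles = relative_profile(matrix, stage_of)
    undefined = list(stats.index[stats["cv"].isna()])
    return ScreeningResult(stats=stats, passing=passing, profiles=profiles,
                           cv_threshold=cv_threshold, undefined_cv=undefined)
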