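"""Bundled published tables from the sugarcane female-gametophyte study.

Two small tables ship with the package so the worked examples and the
reproduction checks run without any download:

* ``sugarcane_candidates.tsv`` - the 18 candidate reference genes with their
  published per-stage RPKM mean, SD and CV, amplicon length, amplification
  efficiency and standard-curve R^2.
* ``sugarcane_stability.tsv`` - the published per-method stability columns
  (geNorm M, NormFinder stability, BestKeeper CV% and SD) in their published
  order, plus the published geometric-mean consensus column.

Gene-name note: the study's tables spell two genes inconsistently
(FAB2/FBA2 and TIC110/TIV110); the bundled files use the canonical FAB2 and
TIC110 throughout.  The Greek alpha in EF1a is transliterated.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .consensus import dense_ranks, geometric_mean_ranking
from .data_io import ConsensusRanking, ExpressionMatrix


def _load(name: str) -> pd.DataFrame:
    with resources.files("refstab.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_candidate_table() -> pd.DataFrame:
    """The published 18-gene candidate table, indexed by gene symbol."""
    return _load("sugarcane_candidates.tsv").set_index("gene")


def load_stability_table() -> pd.DataFrame:
    """Published per-method stability columns in long format.

    Columns: ``method`` (genorm / normfinder / bestkeeper / consensus),
    ``position`` (published row within the method's column), ``gene``,
    ``score`` (M, stability value, CV% or geomean) and, for BestKeeper only,
    ``sd`` of raw Ct.
    """
    return _load("sugarcane_stability.tsv")


def candidate_moment_matrix() -> ExpressionMatrix:
    """A two-condition expression matrix reproducing each candidate's
    published mean and SD exactly.

    The published table prints only per-gene moments (mean, SD) of RPKM
    across stages, not the stage values themselves.  For any mean m and
    sample SD s the pair (m - s/sqrt(2), m + s/sqrt(2)) has exactly those
    moments, which is all the CV statistic consumes - so CV screening can be
    validated against the published table without the underlying stage data.
    """
    tab = load_candidate_table()
    a = tab["mean_rpkm"] - tab["sd_rpkm"] / np.sqrt(2.0)
    b = tab["mean_rpkm"] + tab["sd_rpkm"] / np.sqrt(2.0)
    values = pd.DataFrame({"lo": a, "hi": b})
    return ExpressionMatrix(values)


def published_method_ranks() -> dict[str, dict[str, int]]:
    """Per-method gene ranks as used by the published consensus.

    geNorm ranks are dense ranks of the published M values: the stepwise
    procedure genuinely ties its final pair (both genes carry the pair's V
    as their M), so the two genes at 0.15 share rank 1 and the next gene
    gets rank 2.  NormFinder and BestKeeper scores are continuous and tie
    only through rounding in the published column (e.g. two genes print as
    0.10), so their ranks are the published column positions, which reflect
    the full-precision ordering.
    """
    tab = load_stability_table()
    ranks: dict[str, dict[str, int]] = {}
    gn = tab[tab["method"] == "genorm"]
    ranks["genorm"] = dense_ranks(dict(zip(gn["gene"], gn["score"])))
    for method in ("normfinder", "bestkeeper"):
        sub = tab[tab["method"] == method]
        ranks[method] = dict(zip(sub["gene"], sub["position"].astype(int)))
    return ranks


def published_consensus() -> ConsensusRanking:
    """Recompute the geometric-mean consensus from the published per-method
    columns (the published geomean column itself is *not* consulted)."""
    return geometric_mean_ranking(published_method_ranks())
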