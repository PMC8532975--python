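"""BestKeeper-style descriptive stability on raw Ct values.

Unlike geNorm and NormFinder, BestKeeper works directly on the raw Ct scale:
for each gene it reports the mean Ct, the dispersion of Ct across samples,
and the coefficient of variation CV% = 100 * dispersion / mean.  It also
builds the BestKeeper index - the per-sample geometric mean of Ct over all
candidates - and each gene's Pearson correlation with that index.  Genes are
ranked by ascending dispersion (ties broken by CV%, then gene id).

Dispersion defaults to the sample standard deviation (n-1); the classic
spreadsheet tool's mean absolute deviation from the mean is available via
``use_mad=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import CtMatrix, InsufficientDataError, StabilityTable

log = logging.getLogger("refstab")


@dataclass
class BestkeeperResult:
    """Per-gene descriptive statistics, the index, and the ranking."""

    stats: pd.DataFrame          # index gene; columns n, mean_ct, sd, cv_pct, r_with_index
    index: pd.Series             # per-sample geometric mean Ct
    ranking: list[str]
    use_mad: bool = False

    def table(self) -> StabilityTable:
        aux = {
            g: {"mean_ct": float(self.stats.at[g, "mean_ct"]),
                "sd": float(self.stats.at[g, "sd"]),
                "cv_pct": float(self.stats.at[g, "cv_pct"]),
                "r_with_index": float(self.stats.at[g, "r_with_index"])}
            for g in self.stats.index
        }
        return StabilityTable(method="bestkeeper",
                              scores={g: float(self.stats.at[g, "sd"])
                                      for g in self.stats.index},
                              ranking=list(self.ranking), aux=aux)


def bestkeeper_stats(ct: CtMatrix, use_mad: bool = False) -> BestkeeperResult:
    """Descriptive stability of every gene on the raw Ct scale.

    Genes with fewer than two finite Ct values cannot be scored and are
    excluded with a warning.
    """
    rows = {}
    for gene in ct.genes:
        vals = ct.values.loc[gene].dropna()
        if len(vals) < 2:
            log.warning("BestKeeper: excluding %s (<2 finite Ct values)", gene)
            continue
        mean = float(vals.mean())
        if use_mad:
            disp = float((vals - mean).abs().mean())
        else:
            disp = float(vals.std(ddof=1))
        rows[gene] = {"n": len(vals), "mean_ct": mean, "sd": disp,
                      "cv_pct": 100.0 * disp / mean}
    if len(rows) == 0:
        raise InsufficientDataError("no gene with >= 2 finite Ct values")
    stats = pd.DataFrame(rows).T.loc[list(rows)]
    stats["n"] = stats["n"].astype(int)

    retained = ct.values.loc[stats.index]
    index = np.exp(np.log(retained).mean(axis=0, skipna=True))
    index.name = "bestkeeper_index"

    r = {}
    for gene in stats.index:
        paired = pd.concat([retained.loc[gene], index], axis=1).dropna()
        if len(paired) < 3 or paired.iloc[:, 0].nunique() == 1:
            r[gene] = float("nan")
        else:
            r[gene] = float(sps.pearsonr(paired.iloc[:, 0], paired.iloc[:, 1])[0])
    stats["r_with_index"] = pd.Series(r)

    ranking = sorted(stats.index,
                     key=lambda g: (stats.at[g, "sd"], stats.at[g, "cv_pct"], g))
    return BestkeeperResult(stats=stats, index=index, ranking=ranking,
                            use_mad=use_mad)
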