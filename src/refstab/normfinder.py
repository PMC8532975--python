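"""NormFinder model-based stability estimation.

NormFinder models log-transformed relative quantities with a two-way layout
inside each sample group (here: developmental stage),

    z_igj = mu_ig + b_gj + eps_igj,      eps_igj ~ (0, sigma2_ig)

where i indexes genes, g groups and j samples.  Gene i's systematic
*intergroup* deviation in group g is the interaction contrast

    d_ig = mean(z_ig.) - mean(z_i..) - mean(z_.g.) + mean(z_...)

(a stable gene keeps d_ig ~ 0 in every group), while sigma2_ig is its
*intragroup* (replicate) variance.  Because the candidate panel is finite,
the naive residual variance is biased; an unbiased moment estimator with the
finite-panel correction is used and floored at zero.  The d_ig are shrunk
toward zero empirical-Bayes style by gamma2 / (gamma2 + sigma2_ig/n_g),
where gamma2 is the across-gene variance of the d's net of their sampling
noise.  The stability value of gene i is

    rho_i = mean over groups of ( |d~_ig| + sqrt(Var(d~_ig)) )

i.e. systematic bias plus uncertainty, averaged over groups; low rho is
stable.  All logs are base 2, so rho is commensurate with geNorm's M (both
are SD-like quantities on the log2 expression scale).

When groups are unavailable (or degenerate) the ungrouped variant scores a
gene by the spread of its sample-centred log quantities, again with the
finite-panel correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DomainError, StabilityTable
from .quantification import QuantityMatrix

log = logging.getLogger("refstab")


@dataclass
class NormfinderResult:
    """Per-gene stability values and the underlying variance decomposition.

    ``intergroup``  DataFrame gene x group of shrunk deviations d~_ig
                    (empty in ungrouped mode).
    ``intragroup``  DataFrame gene x group of variance estimates sigma2_ig.
    """

    stability: dict[str, float]
    ranking: list[str]
    grouped: bool
    intergroup: pd.DataFrame
    intragroup: pd.DataFrame

    def table(self) -> StabilityTable:
        return StabilityTable(method="normfinder", scores=dict(self.stability),
                              ranking=list(self.ranking))


def _log2_values(q: QuantityMatrix) -> pd.DataFrame:
    vals = q.values
    arr = vals.to_numpy()
    if not np.isfinite(arr).all():
        raise DomainError("NormFinder requires complete, finite quantities")
    if (arr <= 0).any():
        raise DomainError("NormFinder requires strictly positive quantities")
    return np.log2(vals)


def _rank(stability: dict[str, float]) -> list[str]:
    return sorted(stability, key=lambda g: (stability[g], g))


def normfinder_ungrouped(q: QuantityMatrix) -> NormfinderResult:
    """Stability without group structure.

    Each gene is scored by the SD of its residuals after removing the gene's
    own level and the per-sample across-gene mean, scaled by the finite-panel
    factor k/(k-1) on the variance.
    """
    z = _log2_values(q)
    k, n = z.shape
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    if n < 2:
        raise ValueError("NormFinder needs at least 2 samples")
    resid = z.sub(z.mean(axis=1), axis=0).sub(z.mean(axis=0), axis=1) + \
        float(z.to_numpy().mean())
    u = (resid ** 2).sum(axis=1) / (n - 1)
    var = np.maximum(u * k / (k - 1), 0.0)
    stability = {g: float(np.sqrt(var[g])) for g in z.index}
    empty = pd.DataFrame(index=z.index)
    return NormfinderResult(stability=stability, ranking=_rank(stability),
                            grouped=False, intergroup=empty,
                            intragroup=pd.DataFrame({"all": np.sqrt(var) ** 2}))


def normfinder_stability(q: QuantityMatrix,
                         groups: dict[str, str] | None = None) -> NormfinderResult:
    """Grouped NormFinder stability (the default mode).

    ``groups`` maps sample -> group label; defaults to the quantity matrix's
    own stage assignment.  Needs >= 3 genes and >= 2 groups of >= 2 samples;
    with a single usable group the function falls back to the ungrouped
    variant with a warning.
    """
    z = _log2_values(q)
    k = z.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    groups = dict(q.group_of) if groups is None else dict(groups)
    labels = [groups[s] for s in z.columns]
    by_group: dict[str, list[str]] = {}
    for s, g in zip(z.columns, labels):
        by_group.setdefault(g, []).append(s)

    usable = {g: ss for g, ss in by_group.items() if len(ss) >= 2}
    if len(usable) < 2 or len(usable) < len(by_group):
        log.warning("group structure unusable (%d group(s) with >= 2 samples); "
                    "falling back to ungrouped NormFinder", len(usable))
        return normfinder_ungrouped(q)

    grand = float(z.to_numpy().mean())
    gene_grand = z.mean(axis=1)

    group_names = list(usable)
    d = pd.DataFrame(index=z.index, columns=group_names, dtype=float)
    sigma2 = pd.DataFrame(index=z.index, columns=group_names, dtype=float)
    n_of: dict[str, int] = {}
    for g in group_names:
        zg = z[usable[g]]
        n_g = zg.shape[1]
        n_of[g] = n_g
        gene_mean = zg.mean(axis=1)
        sample_mean = zg.mean(axis=0)
        group_mean = float(zg.to_numpy().mean())
        resid = zg.sub(gene_mean, axis=0).sub(sample_mean, axis=1) + group_mean
        u = (resid ** 2).sum(axis=1) / (n_g - 1)
        if k > 2:
            est = (u - u.mean() / (k - 1)) * k / (k - 2)
        else:                                       # pragma: no cover - k >= 3
            est = u
        sigma2[g] = np.maximum(est, 0.0)
        d[g] = gene_mean - gene_grand - group_mean + grand

    # across-gene variance of the true intergroup deviations, net of the
    # sampling noise of each d_ig (d's sum to zero over genes within a group,
    # hence the k-1 denominator)
    noise = sigma2.div(pd.Series(n_of))
    gamma2 = float(np.mean((d ** 2).sum(axis=0) / (k - 1) - noise.mean(axis=0)))
    gamma2 = max(gamma2, 0.0)

    denom = gamma2 + noise
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = (gamma2 / denom).where(denom > 0, 0.0)
    d_shrunk = d * shrink
    var_shrunk = shrink * noise                      # posterior variance of d~

    per_group = d_shrunk.abs() + np.sqrt(var_shrunk)
    stability = {g: float(per_group.loc[g].mean()) for g in z.index}
    return NormfinderResult(stability=stability, ranking=_rank(stability),
                            grouped=True, intergroup=d_shrunk,
                            intragroup=sigma2)
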