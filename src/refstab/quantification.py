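"""qPCR quantification: standard curves, efficiencies, and relative quantities.

Amplification efficiency E is estimated from a 10-fold dilution series by
ordinary least squares of Ct on log10 template amount:

    E = 10^(-1/slope) - 1

so a perfect per-cycle doubling gives slope -1/log10(2) = -3.3219 and E = 1.

Raw Ct values are converted to relative quantities per gene as

    Q = (1 + E)^(-dCt),   dCt = Ct - min(Ct over samples of that gene)

which rescales every gene so its most abundant sample has Q = 1; this is the
conventional input to the stability algorithms.  Target-gene validation
divides the target's quantity by the geometric mean of the chosen reference
genes' quantities and rescales to a calibrator stage or sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import (
    CtMatrix,
    DomainError,
    InsufficientDataError,
    RefstabError,
)

log = logging.getLogger("refstab")


class InvalidAssayError(RefstabError):
    """Standard-curve slope is non-negative: not a valid qPCR assay."""


@dataclass
class StandardCurve:
    points: list[tuple[float, float]]    # (log10 dilution, Ct)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float                    # proportion; 1.0 = perfect doubling

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise InsufficientDataError("standard curve needs >= 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError("r_squared outside [0, 1]")
        expected = 10.0 ** (-1.0 / self.slope) - 1.0
        if abs(self.efficiency - expected) > 1e-9:
            raise DomainError("efficiency inconsistent with slope")


@dataclass
class QuantityMatrix:
    """Relative quantities Q in (0, 1], genes x samples, plus metadata."""

    values: pd.DataFrame
    efficiency_of: dict[str, float]
    group_of: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: Sequence[str]) -> "QuantityMatrix":
        return QuantityMatrix(self.values.loc[list(genes)],
                              dict(self.efficiency_of), dict(self.group_of))


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Ct ~ log10(dilution) by OLS and derive efficiency and R^2.

    ``points`` are (log10 relative template amount, Ct) pairs, e.g.
    (0, -1, -2, ...) for a 10-fold series.  The slope must be negative
    (more template -> earlier threshold crossing); otherwise the assay is
    rejected.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise InsufficientDataError("standard curve needs >= 3 dilution points")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(set(xs.tolist())) < 2:
        raise InsufficientDataError("dilution values must be distinct")
    fit = sps.linregress(xs, ys)
    if fit.slope >= 0:
        raise InvalidAssayError(
            f"standard-curve slope {fit.slope:.3f} >= 0: invalid assay")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(points=pts, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2,
                         efficiency=float(efficiency))


def ct_to_quantity(ct: CtMatrix,
                   efficiency_of: Mapping[str, float] | None = None,
                   default_efficiency: float = 1.0) -> QuantityMatrix:
    """Convert raw Ct values to per-gene relative quantities.

    Q_gs = (1 + E_g)^-(Ct_gs - min_s Ct_gs); the sample with the lowest Ct of
    each gene gets exactly Q = 1.  Genes without a single finite Ct are
    excluded with a warning; missing Ct values stay missing.
    """
    eff: dict[str, float] = {}
    for gene in ct.genes:
        e = default_efficiency if efficiency_of is None else \
            efficiency_of.get(gene, default_efficiency)
        if e <= 0:
            raise DomainError(f"{gene}: amplification efficiency must be > 0")
        eff[gene] = float(e)

    rows = {}
    kept_eff = {}
    for gene in ct.genes:
        row = ct.values.loc[gene]
        if not np.isfinite(row.to_numpy()).any():
            log.warning("excluding gene %s: no finite Ct value", gene)
            continue
        dct = row - row.min(skipna=True)
        rows[gene] = np.power(1.0 + eff[gene], -dct)
        kept_eff[gene] = eff[gene]
    if not rows:
        raise InsufficientDataError("no gene with a finite Ct value")
    values = pd.DataFrame(rows).T.loc[list(rows)]
    values.columns = ct.samples
    return QuantityMatrix(values=values, efficiency_of=kept_eff,
                          group_of=dict(ct.group_of))


@dataclass
class TargetExpression:
    """Normalized relative expression of one target gene."""

    target: str
    per_sample: pd.Series                  # calibrated ratio per sample
    per_stage: pd.DataFrame                # index stage; columns mean, se, n
    references: list[str]
    calibrator: str


def _geomean_rows(values: pd.DataFrame) -> pd.Series:
    logs = np.log(values)
    return np.exp(logs.mean(axis=0))


def normalize_target(target_ct: pd.Series,
                     target_efficiency: float,
                     references: QuantityMatrix,
                     calibrator: str,
                     target: str = "target") -> TargetExpression:
    """Efficiency-corrected relative expression of a target gene.

    Per sample s:  ratio_s = (1+E_t)^-(Ct_ts - min Ct_t) / NF_s, where NF_s is
    the geometric mean of the reference genes' quantities in s.  Ratios are
    rescaled so the calibrator's mean ratio is 1.  ``calibrator`` may be a
    stage label (mean over its samples) or a single sample identifier.
    With a single reference of equal efficiency this is exactly the classical
    ddCt method.
    """
    if target_efficiency <= 0:
        raise DomainError("target efficiency must be > 0")
    if len(references.genes) < 1:
        raise InsufficientDataError("need at least one reference gene")
    samples = [s for s in references.samples if s in target_ct.index]
    if not samples:
        raise InsufficientDataError("no common samples between target and references")

    t = target_ct.loc[samples].astype(float)
    q_t = np.power(1.0 + target_efficiency, -(t - t.min()))
    nf = _geomean_rows(references.values.loc[:, samples])
    ratio = q_t / nf

    stage_of = {s: references.group_of.get(s, s) for s in samples}
    if calibrator in set(stage_of.values()):
        cal_samples = [s for s in samples if stage_of[s] == calibrator]
    elif calibrator in samples:
        cal_samples = [calibrator]
    else:
        raise ValueError(f"calibrator {calibrator!r} is neither a stage nor a sample")
    ratio = ratio / ratio.loc[cal_samples].mean()

    groups = pd.Series(stage_of)
    per_stage = ratio.groupby(groups, sort=False).agg(["mean", "sem", "count"])
    per_stage.columns = ["mean", "se", "n"]
    per_stage.index.name = "stage"
    return TargetExpression(target=target, per_sample=ratio, per_stage=per_stage,
                            references=list(references.genes),
                            calibrator=calibrator)
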