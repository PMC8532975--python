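"""Synthetic qPCR and RNA-seq data with known ground truth.

Every pipeline stage can be exercised without any experimental download by
generating data that emulates the study design of the sugarcane
female-gametophyte series: five developmental stages (AC, MMC, Meiosis,
Mitosis, Mature), three biological replicates per stage, and a candidate
panel mixing stable and unstable genes.

Ct values follow the standard additive qPCR error model,

    Ct_gsr = baseline_g + effect_g(stage) + N(0, sd_g^2)

i.e. Gaussian replicate noise on the Ct scale (multiplicative on the
quantity scale).  "Stable" genes have |stage effect| <= 0.25 Ct and
replicate SD <= 0.3; "unstable" genes have a stage effect of at least 1.5 Ct
or replicate SD >= 1.0, which makes the two classes unambiguous for
recovery tests.  Baseline Ct values are drawn from U(18, 30), the range
typical of moderately expressed transcripts.

RPKM matrices plant genes with exact target coefficients of variation on
either side of the screening threshold; standard-curve series and target
genes with known fold-change profiles complete the four input kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import CtMatrix, DEFAULT_STAGES, ExpressionMatrix

STABLE_EFFECT_MAX = 0.25     # Ct; a stable gene's largest |stage effect|
STABLE_SD_MAX = 0.3          # Ct; a stable gene's largest replicate SD
UNSTABLE_EFFECT_MIN = 1.5    # Ct; an unstable gene's minimum max |stage effect| ...
UNSTABLE_SD_MIN = 1.0        # ... unless its replicate SD is at least this


@dataclass
class GeneTruth:
    baseline: float
    stage_effects: dict[str, float]
    replicate_sd: float
    efficiency: float
    label: str            # Ct genes: "stable" | "unstable"; also "target",
                          # and "low_cv" | "high_cv" for RPKM genes

    def __post_init__(self) -> None:
        if self.replicate_sd <= 0:
            raise ValueError("replicate SD must be positive")
        peak = max(abs(e) for e in self.stage_effects.values())
        if self.label == "stable" and (peak > STABLE_EFFECT_MAX
                                       or self.replicate_sd > STABLE_SD_MAX):
            raise ValueError("stable gene violates the stability envelope")
        if self.label == "unstable" and (peak < UNSTABLE_EFFECT_MIN
                                         and self.replicate_sd < UNSTABLE_SD_MIN):
            raise ValueError("unstable gene is not unstable enough")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset."""

    genes: dict[str, GeneTruth]
    stages: list[str]
    replicates: int
    seed: int
    fold_profile: dict[str, float] = field(default_factory=dict)
    cv_of: dict[str, float] = field(default_factory=dict)   # RPKM datasets

    def labelled(self, label: str) -> list[str]:
        return [g for g, t in self.genes.items() if t.label == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, t in self.genes.items():
            rows.append({"gene": g, "label": t.label, "baseline": t.baseline,
                         "replicate_sd": t.replicate_sd,
                         "efficiency": t.efficiency,
                         **{f"effect_{s}": t.stage_effects[s]
                            for s in self.stages}})
        return pd.DataFrame(rows).set_index("gene")


def _sample_names(stages: Sequence[str], replicates: int) -> list[str]:
    return [f"{s}_{r}" for s in stages for r in range(1, replicates + 1)]


def generate_ct_dataset(n_stable: int,
                        n_unstable: int,
                        stages: Sequence[str] = DEFAULT_STAGES,
                        replicates: int = 3,
                        seed: int = 0,
                        stable_sd: float = 0.2,
                        stable_effect_max: float = 0.2,
                        unstable_effect: float = 2.0,
                        unstable_sd: float = 0.3) -> tuple[CtMatrix, SyntheticTruth]:
    """Generate a Ct matrix with planted stable and unstable genes.

    Stable genes get stage effects drawn from U(-stable_effect_max,
    +stable_effect_max) and replicate SD ``stable_sd``; unstable genes get a
    stage-effect pattern rescaled to a peak of ``unstable_effect`` Ct.
    Deterministic for a fixed seed.
    """
    if n_stable < 2:
        raise ValueError("need >= 2 stable genes (geNorm requires a stable pair)")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per stage")
    if n_stable + n_unstable < 3:
        raise ValueError("stability methods need >= 3 genes in total")
    rng = np.random.default_rng(seed)
    stages = list(stages)

    truths: dict[str, GeneTruth] = {}
    for i in range(n_stable):
        effects = dict(zip(stages,
                           rng.uniform(-stable_effect_max, stable_effect_max,
                                       len(stages))))
        truths[f"STB{i + 1:02d}"] = GeneTruth(
            baseline=float(rng.uniform(18, 30)), stage_effects=effects,
            replicate_sd=stable_sd, efficiency=1.0, label="stable")
    for i in range(n_unstable):
        raw = rng.uniform(-1.0, 1.0, len(stages))
        raw = raw * (unstable_effect / np.max(np.abs(raw)))
        truths[f"UNS{i + 1:02d}"] = GeneTruth(
            baseline=float(rng.uniform(18, 30)),
            stage_effects=dict(zip(stages, raw)),
            replicate_sd=unstable_sd, efficiency=1.0, label="unstable")

    samples = _sample_names(stages, replicates)
    values = pd.DataFrame(index=list(truths), columns=samples, dtype=float)
    for gene, t in truths.items():
        for stage in stages:
            noise = rng.normal(0.0, t.replicate_sd, replicates)
            for r in range(replicates):
                values.at[gene, f"{stage}_{r + 1}"] = (
                    t.baseline + t.stage_effects[stage] + noise[r])
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    replicate_of = {s: int(s.rsplit("_", 1)[1]) for s in samples}
    truth = SyntheticTruth(genes=truths, stages=stages, replicates=replicates,
                           seed=seed)
    return CtMatrix(values, group_of, replicate_of), truth


def _solve_sigma(z: np.ndarray, target_cv: float) -> float:
    """Log-scale dispersion giving an *exact* sample CV for fixed draws z."""

    def realized(s: float) -> float:
        v = np.exp(s * (z - z.max()))           # shift-invariant, overflow-safe
        return float(np.std(v, ddof=1) / np.mean(v)) - target_cv

    return brentq(realized, 1e-12, 20.0)


def generate_rpkm_dataset(n_low_cv: int,
                          n_high_cv: int,
                          stages: Sequence[str] = DEFAULT_STAGES,
                          seed: int = 0,
                          low_cv_range: tuple[float, float] = (0.05, 0.35),
                          high_cv_range: tuple[float, float] = (0.9, 1.5),
                          ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """RPKM matrix with genes planted at exact CVs on both sides of 0.6.

    Per-stage values are log-normal around a gene-specific mean; the
    log-scale dispersion is solved numerically so each gene's realized
    sample CV equals a target drawn from its class range (low: CV < 0.4,
    high: CV > 0.8 by default).  Deterministic for a fixed seed.
    """
    if n_low_cv + n_high_cv < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    stages = list(stages)
    if len(stages) < 3:
        raise ValueError("need >= 3 stages for a meaningful CV")

    rows: dict[str, np.ndarray] = {}
    truths: dict[str, GeneTruth] = {}
    cv_of: dict[str, float] = {}
    specs = ([("LOW", low_cv_range, "low_cv")] * n_low_cv
             + [("HIGH", high_cv_range, "high_cv")] * n_high_cv)
    counters = {"LOW": 0, "HIGH": 0}
    for prefix, cv_range, label in specs:
        counters[prefix] += 1
        gene = f"{prefix}{counters[prefix]:02d}"
        mean_rpkm = float(np.exp(rng.normal(3.0, 0.8)))
        target_cv = float(rng.uniform(*cv_range))
        # redraw shapes whose attainable CV cannot reach the target (the CV
        # saturates when the largest deviations are nearly tied)
        z = rng.standard_normal(len(stages))
        v = np.exp(20.0 * (z - z.max()))
        while np.ptp(z) < 1e-6 or np.std(v, ddof=1) / np.mean(v) <= target_cv:
            z = rng.standard_normal(len(stages))
            v = np.exp(20.0 * (z - z.max()))
        sigma = _solve_sigma(z, target_cv)
        v = np.exp(sigma * z)
        rows[gene] = mean_rpkm * v / v.mean()       # exact mean, exact CV
        cv_of[gene] = target_cv
        truths[gene] = GeneTruth(baseline=mean_rpkm,
                                 stage_effects={s: 0.0 for s in stages},
                                 replicate_sd=max(sigma, 1e-9),
                                 efficiency=1.0, label=label)
    values = pd.DataFrame(rows).T.loc[list(rows)]
    values.columns = stages
    truth = SyntheticTruth(genes=truths, stages=stages, replicates=1,
                           seed=seed, cv_of=cv_of)
    return ExpressionMatrix(values), truth


def generate_standard_curve(true_efficiency: float,
                            intercept: float = 35.0,
                            n_dilutions: int = 5,
                            noise_sd: float = 0.0,
                            seed: int = 0) -> tuple[list[tuple[float, float]], dict]:
    """A 10-fold dilution series from a known efficiency.

    Ct at log10 dilution d is ``intercept - d / log10(1 + E)`` plus Gaussian
    noise; the true slope is therefore -1/log10(1+E) (-3.3219 for E = 1).
    """
    if true_efficiency <= 0:
        raise ValueError("efficiency must be positive")
    if n_dilutions < 3:
        raise ValueError("need >= 3 dilution points")
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + true_efficiency)
    points = []
    for i in range(n_dilutions):
        d = -float(i)                               # log10 relative amount
        ct = intercept + slope * d + rng.normal(0.0, noise_sd) if noise_sd > 0 \
            else intercept + slope * d
        points.append((d, float(ct)))
    truth = {"efficiency": true_efficiency, "slope": slope,
             "intercept": intercept, "noise_sd": noise_sd, "seed": seed}
    return points, truth


def generate_target_dataset(fold_profile: Mapping[str, float],
                            reference_truth: SyntheticTruth,
                            seed: int = 0,
                            baseline: float = 26.0,
                            replicate_sd: float = 0.15,
                            efficiency: float = 1.0) -> tuple[pd.Series, GeneTruth]:
    """Per-sample Ct values of a target gene with a planted fold-change profile.

    A fold change f at a stage shifts Ct by -log(f)/log(1+E) relative to the
    baseline stage (the first stage of the reference design), so the
    normalized expression recovered downstream should reproduce
    ``fold_profile`` up to replicate noise.
    """
    stages = reference_truth.stages
    missing = [s for s in stages if s not in fold_profile]
    if missing:
        raise ValueError(f"fold profile lacks stages: {missing}")
    if any(f <= 0 for f in fold_profile.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    shift = {s: -math.log(fold_profile[s]) / math.log(1.0 + efficiency)
             for s in stages}
    values = {}
    for s in stages:
        for r in range(1, reference_truth.replicates + 1):
            values[f"{s}_{r}"] = (baseline + shift[s]
                                  + float(rng.normal(0.0, replicate_sd)))
    truth = GeneTruth(baseline=baseline,
                      stage_effects=shift, replicate_sd=replicate_sd,
                      efficiency=efficiency, label="target")
    return pd.Series(values, name="target_ct"), truth
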