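"""Shared data model and tabular I/O for the reference-gene stability pipeline.

All pipeline stages exchange three kinds of tables:

* a Ct matrix (genes x samples of qPCR cycle-threshold values) with
  sample -> stage / replicate metadata,
* an expression matrix (genes x stages of RPKM/FPKM values) used for
  transcriptome-based candidate screening,
* per-method stability tables and the geometric-mean consensus ranking.

Files are plain CSV or TSV with a header row; the delimiter is auto-detected
from the header line.  Decimal separator is always ".".
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("refstab")

#: tokens treated as a missing Ct (e.g. no amplification within 40 cycles)
MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "-"}

#: stage labels of the female-gametophyte developmental series, in
#: developmental order (archesporial cell -> mature gametophyte)
DEFAULT_STAGES = ("AC", "MMC", "Meiosis", "Mitosis", "Mature")

STABILITY_METHODS = ("genorm", "normfinder", "bestkeeper")


class RefstabError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(RefstabError):
    """Duplicate identifiers or malformed table shape."""


class MetadataError(RefstabError):
    """Sample metadata missing or inconsistent with the matrix."""


class TableParseError(RefstabError):
    """A cell could not be parsed as a number."""


class DomainError(RefstabError):
    """A value violates a domain constraint (e.g. negative RPKM)."""


class ConsistencyError(RefstabError):
    """Gene sets of two results that must agree do not."""


class InsufficientDataError(RefstabError):
    """Too few observations for the requested statistic."""


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def detect_delimiter(path: str | Path) -> str:
    """Return the delimiter of a CSV/TSV file, sniffed from its header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_header_ids(path: str | Path, sep: str) -> list[str]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        row = next(csv.reader(fh, delimiter=sep))
    return [c.strip() for c in row[1:]]


def _read_numeric_table(path: str | Path, *, allow_missing: bool) -> pd.DataFrame:
    """Read a genes-x-samples table of floats, naming the offending cell on error."""
    path = Path(path)
    sep = detect_delimiter(path)
    header_ids = _read_header_ids(path, sep)
    if len(set(header_ids)) != len(header_ids):
        dupes = sorted({c for c in header_ids if header_ids.count(c) > 1})
        raise StructuralError(f"duplicate column identifiers in {path.name}: {dupes}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = [str(c).strip() for c in raw.columns]
    raw.index = [str(i).strip() for i in raw.index]
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise StructuralError(f"duplicate row identifiers in {path.name}: {dupes}")

    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for row in raw.index:
            cell = raw.at[row, col].strip()
            if cell in MISSING_TOKENS:
                if not allow_missing:
                    raise TableParseError(
                        f"missing value at row {row!r}, column {col!r} in {path.name}"
                    )
                continue
            try:
                values.at[row, col] = float(cell)
            except ValueError as exc:
                raise TableParseError(
                    f"non-numeric value {cell!r} at row {row!r}, column {col!r} "
                    f"in {path.name}"
                ) from exc
    return values


def _write_table(values: pd.DataFrame, path: str | Path, index_label: str) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    values.to_csv(path, sep=sep, index_label=index_label)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if list(ids).count(g) > 1})
        raise StructuralError(f"duplicate {what} identifiers: {dupes}")


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class CtMatrix:
    """Raw qPCR Ct values (genes x samples) with sample grouping metadata.

    Parameters
    ----------
    values
        Genes in rows, samples in columns.  ``NaN`` marks a missing Ct
        (no amplification); all finite values must be positive cycle numbers.
    group_of
        Maps every sample to its stage label (e.g. ``"AC"``, ``"MMC"``).
    replicate_of
        Maps samples to a biological-replicate index; optional.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    replicate_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        missing_meta = [s for s in self.values.columns if s not in self.group_of]
        if missing_meta:
            raise MetadataError(f"samples without a stage label: {missing_meta}")
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite <= 0).any():
            raise DomainError("Ct values must be positive cycle numbers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in order of first appearance across samples."""
        seen: list[str] = []
        for s in self.samples:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return seen

    def groups(self) -> pd.Series:
        return pd.Series({s: self.group_of[s] for s in self.samples}, name="stage")

    def n_missing(self) -> pd.Series:
        return self.values.isna().sum(axis=1)

    def drop_sparse_genes(self, max_missing_frac: float = 0.2) -> "CtMatrix":
        """Drop genes with more than ``max_missing_frac`` missing Ct values."""
        frac = self.values.isna().mean(axis=1)
        dropped = list(frac.index[frac > max_missing_frac])
        if dropped:
            log.warning(
                "excluding %d gene(s) with >%.0f%% missing Ct: %s",
                len(dropped), 100 * max_missing_frac, ", ".join(dropped),
            )
        return CtMatrix(self.values.drop(index=dropped),
                        dict(self.group_of), dict(self.replicate_of))

    def subset(self, genes: Iterable[str]) -> "CtMatrix":
        genes = list(genes)
        absent = [g for g in genes if g not in self.values.index]
        if absent:
            raise ConsistencyError(f"genes not in Ct matrix: {absent}")
        return CtMatrix(self.values.loc[genes], dict(self.group_of),
                        dict(self.replicate_of))


@dataclass
class ExpressionMatrix:
    """RPKM/FPKM expression values, genes x conditions (stage labels)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.shape[1] == 0:
            raise StructuralError("expression matrix has no conditions")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "condition")
        arr = self.values.to_numpy()
        if (arr[np.isfinite(arr)] < 0).any():
            raise DomainError("RPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneAssay:
    """Per-gene qPCR assay characteristics from a dilution-series standard curve."""

    gene: str
    efficiency: float           # amplification efficiency E as a proportion (~0.9-1.1)
    r_squared: float
    slope: float                # Ct per log10 dilution; negative for a valid assay

    def __post_init__(self) -> None:
        if self.efficiency <= 0:
            raise DomainError(f"{self.gene}: efficiency must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"{self.gene}: r_squared outside [0, 1]")


@dataclass
class StabilityTable:
    """Stability scores and ranking from one algorithm.

    ``scores`` maps each gene to the method's stability value (geNorm M at
    exclusion, NormFinder stability, BestKeeper SD of Ct); lower is always
    more stable.  ``aux`` holds method-specific extras (for BestKeeper:
    ``mean_ct``, ``sd``, ``cv_pct``, ``r_with_index``).
    """

    method: str
    scores: dict[str, float]
    ranking: list[str]
    aux: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in STABILITY_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if set(self.ranking) != set(self.scores):
            raise ConsistencyError("ranking is not a permutation of the scored genes")
        if self.method in ("genorm", "normfinder"):
            neg = [g for g, s in self.scores.items() if s < 0]
            if neg:
                raise DomainError(f"negative {self.method} stability for {neg}")
        if self.method == "bestkeeper":
            for g, stats in self.aux.items():
                sd, mean, cv = stats["sd"], stats["mean_ct"], stats["cv_pct"]
                if sd < 0:
                    raise DomainError(f"negative SD for {g}")
                if abs(cv - 100.0 * sd / mean) > 1e-9:
                    raise ConsistencyError(f"CV% inconsistent with 100*SD/mean for {g}")

    @property
    def genes(self) -> set[str]:
        return set(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, gene in enumerate(self.ranking, start=1):
            row = {"gene": gene, "score": self.scores[gene], "rank": rank}
            row.update(self.aux.get(gene, {}))
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene")


@dataclass
class ConsensusRanking:
    """Geometric-mean aggregation of the per-method rankings.

    ``ranks``  method -> gene -> dense rank (ties share a rank).
    ``geomean``  gene -> geometric mean of its per-method ranks.
    ``order``  genes sorted ascending by geometric mean (ties lexicographic).
    ``optimal_n``  recommended number of reference genes from the geNorm
    pairwise-variation analysis (``None`` if not computed).
    """

    ranks: dict[str, dict[str, int]]
    geomean: dict[str, float]
    order: list[str]
    optimal_n: int | None = None
    pairwise_variations: list[float] | None = None

    def __post_init__(self) -> None:
        for method, ranks in self.ranks.items():
            if set(ranks) != set(self.geomean):
                raise ConsistencyError(f"gene set of method {method!r} mismatches")
            lo = [ranks[g] for g in ranks]
            if any(r < 1 for r in lo):
                raise DomainError("ranks must be >= 1")
        for g, gm in self.geomean.items():
            per = [self.ranks[m][g] for m in self.ranks]
            if not (min(per) - 1e-9 <= gm <= max(per) + 1e-9):
                raise ConsistencyError(
                    f"geometric mean of {g} outside its per-method rank range")
        if self.optimal_n is not None and self.optimal_n < 2:
            raise DomainError("optimal_n must be >= 2")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "geomean": self.geomean[g],
             **{f"rank_{m}": self.ranks[m][g] for m in self.ranks}}
            for g in self.order
        ]
        return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read sample metadata (columns: sample, stage[, replicate])."""
    sep = detect_delimiter(path)
    meta = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in meta.columns}
    for required in ("sample", "stage"):
        if required not in cols:
            raise MetadataError(f"metadata file lacks a {required!r} column")
    samples = [s.strip() for s in meta[cols["sample"]]]
    _check_unique(samples, "metadata sample")
    group_of = dict(zip(samples, (s.strip() for s in meta[cols["stage"]])))
    replicate_of: dict[str, int] = {}
    if "replicate" in cols:
        replicate_of = {s: int(r) for s, r in zip(samples, meta[cols["replicate"]])}
    return group_of, replicate_of


def parse_sample_name(sample: str) -> tuple[str, int | None]:
    """Fallback ``"AC_1" -> ("AC", 1)`` parsing when no metadata file is given."""
    stem, _, suffix = sample.rpartition("_")
    if stem and suffix.isdigit():
        return stem, int(suffix)
    return sample, None


def read_ct_table(path: str | Path,
                  metadata_path: str | Path | None = None) -> CtMatrix:
    """Read a Ct matrix and its sample metadata.

    The matrix file has one header row of sample identifiers and one row per
    gene.  The metadata file is authoritative for stage/replicate assignment;
    without one, stage and replicate are parsed from ``<stage>_<rep>`` sample
    names.
    """
    values = _read_numeric_table(path, allow_missing=True)
    if metadata_path is not None:
        group_of, replicate_of = read_sample_metadata(metadata_path)
        absent = [s for s in values.columns if s not in group_of]
        if absent:
            raise MetadataError(f"samples missing from metadata: {absent}")
    else:
        group_of, replicate_of = {}, {}
        for s in values.columns:
            stage, rep = parse_sample_name(s)
            group_of[s] = stage
            if rep is not None:
                replicate_of[s] = rep
    return CtMatrix(values, group_of, replicate_of)


def write_ct_table(ct: CtMatrix, path: str | Path,
                   metadata_path: str | Path | None = None) -> None:
    _write_table(ct.values, path, index_label="gene")
    if metadata_path is not None:
        meta = pd.DataFrame({
            "sample": ct.samples,
            "stage": [ct.group_of[s] for s in ct.samples],
            "replicate": [ct.replicate_of.get(s, 1) for s in ct.samples],
        })
        sep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
        meta.to_csv(metadata_path, sep=sep, index=False)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an RPKM matrix (header = stage labels, one row per gene)."""
    values = _read_numeric_table(path, allow_missing=True)
    return ExpressionMatrix(values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    _write_table(matrix.values, path, index_label="gene")


def write_ranking_report(consensus: ConsensusRanking,
                         tables: Sequence[StabilityTable],
                         path: str | Path) -> None:
    """Write the combined report: one row per rank position, one gene+score
    column pair per method, then the consensus gene and its geometric mean.

    All tables and the consensus must cover the same gene set.
    """
    gene_set = set(consensus.geomean)
    for t in tables:
        if t.genes != gene_set:
            raise ConsistencyError(
                f"gene set of {t.method} table does not match consensus")
    rows = []
    for i, gene in enumerate(consensus.order):
        row: dict[str, object] = {"rank": i + 1}
        for t in tables:
            g = t.ranking[i]
            row[f"{t.method}_gene"] = g
            if t.method == "bestkeeper":
                row[f"{t.method}_score"] = (
                    f"{t.aux[g]['cv_pct']:.2f} +/- {t.aux[g]['sd']:.2f}")
            else:
                row[f"{t.method}_score"] = f"{t.scores[g]:.2f}"
        row["consensus_gene"] = gene
        row["geomean"] = f"{consensus.geomean[gene]:.2f}"
        rows.append(row)
    report = pd.DataFrame(rows)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    report.to_csv(path, sep=sep, index=False)
    if consensus.optimal_n is not None:
        with open(path, "a", encoding="utf-8") as fh:
            fh.write(f"# optimal_n{sep}{consensus.optimal_n}\n")


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean of positive numbers."""
    vals = np.asarray(list(values), dtype=float)
    if (vals <= 0).any():
        raise DomainError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(vals))))
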