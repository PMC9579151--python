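"""Domain types, coordinate conventions and flat-file readers/writers.

Conventions used throughout the package:

* All genomic intervals are BED-style: 0-based, half-open ``[start, end)``.
* A peak's *center* is ``floor((start + end) / 2)``.
* The TSS of a plus-strand gene is its annotation ``start``; for a
  minus-strand gene it is ``end - 1`` (the last covered base of the
  half-open interval).
* Peak–gene distances are unsigned center-to-TSS distances and are
  undefined across chromosomes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hiftargets")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A flat file could not be parsed (message names the offending line)."""


class ValidationError(PipelineError):
    """An in-memory object violates one of its invariants."""


class BoundsError(ValidationError):
    """A genomic coordinate falls outside its chromosome."""


class SizingError(PipelineError):
    """A simulation request is infeasible for the given sizes."""


class DegenerateDataError(PipelineError):
    """The input data admit no meaningful statistic (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """An ordered reference coordinate space: (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        if not self.chromosomes:
            raise ValidationError("genome has no chromosomes")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length_of(self, chromosome: str) -> int:
        try:
            return self.lengths[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in genome") from None

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Genome":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, ["chromosome", "length"], path)
        return cls(tuple(zip(df["chromosome"].astype(str), df["length"].astype(int))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.chromosomes, columns=["chromosome", "length"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak interval; the unit of binding evidence."""

    peak_id: str
    chromosome: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_against(self, genome: Genome) -> None:
        if self.end > genome.length_of(self.chromosome):
            raise BoundsError(
                f"peak {self.peak_id!r} extends past the end of {self.chromosome}"
            )


def load_peaks(path: str | Path, genome: Genome) -> list[Peak]:
    """Read a BED3+ file into validated :class:`Peak` records.

    Order is preserved; ids are auto-assigned (``peak_1``, ...) when the
    name column is absent.  Malformed lines and out-of-genome intervals
    raise errors naming the line number.  An empty file yields an empty
    list.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"peak_{len(peaks) + 1}"
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            try:
                peak = Peak(name, chrom, start, end, score)
                peak.validate_against(genome)
            except (BoundsError, KeyError) as exc:
                raise BoundsError(f"{path}:{lineno}: {exc}") from None
            peaks.append(peak)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6-minus-strand (chrom, start, end, name, score)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\n")


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    tss: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.tss < 0:
            raise BoundsError(f"gene {self.gene_id!r}: negative TSS")


def load_genes(path: str | Path, genome: Optional[Genome] = None) -> list[GeneModel]:
    """Read a gene-annotation TSV (gene_id, chromosome, start, end, strand).

    The annotation interval is 0-based half-open; the TSS is ``start`` for
    plus-strand genes and ``end - 1`` for minus-strand genes.  Genes on
    chromosomes absent from ``genome`` are dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    _require_columns(df, ["gene_id", "chromosome", "start", "end", "strand"], path)
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene_id(s) in {path}: {dupes[:5]}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(
            f"{path}: unknown strand symbol(s) {sorted(df.loc[bad, 'strand'].unique())}"
        )
    genes: list[GeneModel] = []
    dropped = 0
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        if genome is not None:
            if row.chromosome not in genome.lengths:
                dropped += 1
                continue
            if not (0 <= tss < genome.length_of(row.chromosome)):
                raise BoundsError(f"gene {row.gene_id!r}: TSS {tss} outside {row.chromosome}")
        name = getattr(row, "name", None)
        genes.append(GeneModel(str(row.gene_id), str(row.chromosome), row.strand, tss, name))
    if dropped:
        logger.warning("load_genes: dropped %d gene(s) on chromosomes absent from genome", dropped)
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path, body_bp: int = 1000) -> None:
    """Write genes as the annotation TSV ``load_genes`` reads.

    Gene bodies are emitted as nominal ``body_bp`` intervals oriented so
    that the TSS round-trips exactly under the strand convention.
    """
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, g.tss + body_bp
        else:
            start, end = max(0, g.tss + 1 - body_bp), g.tss + 1
        rows.append((g.gene_id, g.chromosome, start, end, g.strand))
    pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------


@dataclass
class DifferentialComparison:
    """Per-gene log2FC / raw p / FDR for one pairwise contrast."""

    label: str
    records: pd.DataFrame  # columns: gene_id, log2fc, raw_p, fdr

    def __post_init__(self) -> None:
        df = self.records
        _require_columns(df, ["gene_id", "log2fc", "raw_p", "fdr"], self.label)
        if df["gene_id"].duplicated().any():
            raise ValidationError(f"comparison {self.label!r}: duplicate gene_ids")
        for col in ("raw_p", "fdr"):
            vals = df[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"comparison {self.label!r}: {col} outside [0, 1]")

    @property
    def gene_ids(self) -> pd.Series:
        return self.records["gene_id"]

    def to_tsv(self, path: str | Path) -> None:
        # %.17g keeps the write/read round trip bit-exact for float64
        self.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_comparison(path: str | Path, label: str) -> DifferentialComparison:
    """Read a DE TSV (gene_id, log2fc, raw_p[, fdr]).

    When the ``fdr`` column is absent it is filled by Benjamini–Hochberg
    adjustment of the raw p-values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    _require_columns(df, ["gene_id", "log2fc", "raw_p"], path)
    if "fdr" not in df.columns:
        from .loa import benjamini_hochberg

        df = df.copy()
        df["fdr"] = benjamini_hochberg(df["raw_p"].to_numpy(dtype=float))
    return DifferentialComparison(label, df[["gene_id", "log2fc", "raw_p", "fdr"]].copy())


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Every analysis threshold in one validated record.

    Defaults are the study settings: FDR 0.01, 15 kb TSS window, 400 bp
    co-binding radius, HOT bound of 15 factors, 1e5 bootstrap replicates,
    +/-100 bp motif windows, one-tailed KS cutoff 0.01, and the
    meta-analysis thresholds (q < 0.05 in >= 15 studies, expressed in
    >= 15 studies).
    """

    alpha: float = 0.01
    window_bp: int = 15_000
    cobind_radius_bp: int = 400
    hot_threshold: int = 15
    n_boot: int = 100_000
    motif_flank_bp: int = 100
    ks_cutoff: float = 0.01
    q_threshold_meta: float = 0.05
    min_consistent_studies: int = 15
    min_expressed_studies: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_bp", "cobind_radius_bp", "hot_threshold", "n_boot",
                     "motif_flank_bp", "min_consistent_studies", "min_expressed_studies"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be > 0")
        for name in ("alpha", "ks_cutoff", "q_threshold_meta"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"config: {name} must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def distance_center_to_tss(peak: Peak, gene: GeneModel) -> Optional[int]:
    """Unsigned center-to-TSS distance in bp, or None across chromosomes."""
    if peak.chromosome != gene.chromosome:
        return None
    return abs(peak.center - gene.tss)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], source) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing required column(s) {missing}")
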