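"""Cross-study consistency meta-analysis for ortholog sets.

A gene is *consistently upregulated* across a panel of independent
differential-expression studies iff it is up (log2FC > 0) with q below a
threshold in at least ``min_studies`` studies.  Comparing the consistent
fraction among putative orthologs of the direct-target set against the
rest of the gene universe with a two-proportion chi-square test (Yates
continuity correction, one-sided toward enrichment) quantifies
cross-species conservation of the regulatory program.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

STUDY_COLUMNS = ["gene_id", "log2fc", "q", "expressed"]


@dataclass
class StudyPanel:
    """Per-study DE tables with per-gene expression flags.

    Each table has columns gene_id, log2fc, q, expressed; unexpressed
    genes carry NaN statistics.
    """

    studies: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValidationError("StudyPanel: no studies")
        for sid, df in self.studies.items():
            missing = [c for c in STUDY_COLUMNS if c not in df.columns]
            if missing:
                raise ValidationError(f"study {sid!r}: missing column(s) {missing}")
            q = df.loc[df["expressed"].astype(bool), "q"].to_numpy(dtype=float)
            if ((q < 0) | (q > 1)).any():
                raise ValidationError(f"study {sid!r}: q outside [0, 1]")

    @property
    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for df in self.studies.values():
            out.update(df["gene_id"])
        return out

    @classmethod
    def from_dir(cls, directory: str | Path) -> "StudyPanel":
        directory = Path(directory)
        studies = {
            p.stem: pd.read_csv(p, sep="\t", dtype={"gene_id": str})
            for p in sorted(directory.glob("*.tsv"))
        }
        return cls(studies)

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sid, df in self.studies.items():
            df.to_csv(directory / f"{sid}.tsv", sep="\t", index=False)


def _per_gene_counts(panel: StudyPanel, predicate) -> pd.Series:
    counts: pd.Series | None = None
    for df in panel.studies.values():
        flags = predicate(df)
        s = pd.Series(flags.to_numpy(dtype=int), index=df["gene_id"])
        counts = s if counts is None else counts.add(s, fill_value=0)
    return counts.fillna(0)


def consistency_calls(
    panel: StudyPanel, q_threshold: float = 0.05, min_studies: int = 15
) -> set[str]:
    """Genes upregulated with q < threshold in >= min_studies studies."""
    counts = _per_gene_counts(
        panel,
        lambda df: df["expressed"].astype(bool)
        & (df["log2fc"] > 0)
        & (df["q"] < q_threshold),
    )
    return set(counts.index[counts >= min_studies])


def expression_filter(panel: StudyPanel, min_expressed: int = 15) -> set[str]:
    """Genes flagged expressed in >= min_expressed studies (inclusive)."""
    counts = _per_gene_counts(panel, lambda df: df["expressed"].astype(bool))
    return set(counts.index[counts >= min_expressed])


@dataclass
class EnrichmentReport:
    n_background: int
    n_background_consistent: int
    n_orthologs: int
    n_orthologs_consistent: int
    prop_background: float
    prop_orthologs: float
    fold: float
    p: float
    degenerate: bool = False
    fold_infinite: bool = False

    def to_dict(self) -> dict:
        return {
            "n_background": self.n_background,
            "n_background_consistent": self.n_background_consistent,
            "n_orthologs": self.n_orthologs,
            "n_orthologs_consistent": self.n_orthologs_consistent,
            "prop_background": self.prop_background,
            "prop_orthologs": self.prop_orthologs,
            "fold": self.fold,
            "p": self.p,
            "degenerate": self.degenerate,
            "fold_infinite": self.fold_infinite,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def enrichment_proportion_test(
    consistent: set[str],
    orthologs: set[str],
    universe: set[str],
    include_orthologs_in_background: bool = False,
) -> EnrichmentReport:
    """Two-proportion test of consistency among orthologs vs background.

    The background is the universe excluding the orthologs (inclusive
    backgrounds available via flag).  The chi-square uses Yates continuity
    correction; the p-value is one-sided toward enrichment.  A zero
    background proportion reports an infinite fold with a flag; an empty
    consistent set is flagged degenerate.
    """
    if not universe:
        raise ValidationError("enrichment_proportion_test: empty universe")
    if not orthologs <= universe:
        raise ValidationError("enrichment_proportion_test: orthologs not a subset of universe")
    background = universe if include_orthologs_in_background else universe - orthologs
    n_orth = len(orthologs)
    n_bg = len(background)
    k_orth = len(consistent & orthologs)
    k_bg = len(consistent & background)
    prop_orth = k_orth / n_orth if n_orth else 0.0
    prop_bg = k_bg / n_bg if n_bg else 0.0

    degenerate = (k_orth + k_bg) == 0 or n_orth == 0 or n_bg == 0
    fold_infinite = False
    if degenerate:
        fold, p = 0.0, 1.0
    elif prop_bg == 0:
        fold, fold_infinite = float("inf"), True
        p = _one_sided_prop_p(k_orth, n_orth, k_bg, n_bg)
    else:
        fold = prop_orth / prop_bg
        p = _one_sided_prop_p(k_orth, n_orth, k_bg, n_bg)
    return EnrichmentReport(
        n_background=n_bg,
        n_background_consistent=k_bg,
        n_orthologs=n_orth,
        n_orthologs_consistent=k_orth,
        prop_background=prop_bg,
        prop_orthologs=prop_orth,
        fold=fold,
        p=float(p),
        degenerate=degenerate,
        fold_infinite=fold_infinite,
    )


def _one_sided_prop_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided (group 1 enriched) p from the Yates-corrected 2x2 chi-square."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    chi2, p_two, _, _ = stats.chi2_contingency(table, correction=True)
    if k1 / n1 >= k2 / n2:
        return p_two / 2
    return 1 - p_two / 2
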