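"""Two-condition metabolite differential abundance and the
enzyme<->metabolite pathway join.

Abundances are log2-transformed (after optional per-metabolite minimum
imputation of missing values, the common practice for untargeted LC-MS
panels) and tested per metabolite with Welch's unequal-variance t test;
BH adjustment is applied across metabolites.  Counts at both raw p < 0.05
and FDR < 0.05 are reported.  The pathway join places each reaction's
enzymes (with their transcriptional fold-changes and direct-target flags)
next to its substrate/product metabolites (with their abundance
fold-changes), one output row per (reaction, enzyme, metabolite) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateDataError, DifferentialComparison, ValidationError
from .loa import benjamini_hochberg


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch–Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t: each group needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateDataError("welch_t: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class MetaboliteStat:
    metabolite_id: str
    log2_fold: float
    t: float
    df: float
    raw_p: float
    fdr: float


def metabolite_differential(
    matrix: pd.DataFrame,
    design: Sequence[str],
    log_transform: bool = True,
    impute_min: bool = True,
) -> tuple[list[MetaboliteStat], dict[str, int]]:
    """Per-metabolite Welch tests between the two design conditions.

    ``matrix`` is metabolites x samples; ``design`` labels each column
    with one of exactly two conditions.  ``log2_fold`` is the difference
    of condition means on the log2 scale (condition 2 minus condition 1,
    in the order labels first appear).  Returns the per-metabolite stats
    and the counts at raw p < 0.05 and FDR < 0.05.
    """
    labels = list(design)
    if len(labels) != matrix.shape[1]:
        raise ValidationError("metabolite_differential: design length != number of samples")
    conditions = list(dict.fromkeys(labels))
    if len(conditions) != 2:
        raise ValidationError("metabolite_differential: design must name exactly 2 conditions")
    mask1 = np.array([l == conditions[0] for l in labels])
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValidationError("metabolite_differential: >= 2 samples per condition required")

    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_min:
            raise ValidationError("metabolite_differential: missing values present")
        row_min = np.nanmin(values, axis=1)
        if np.isnan(row_min).any():
            raise ValidationError("metabolite_differential: a metabolite has no observed value")
        values = np.where(np.isnan(values), row_min[:, None], values)
    if log_transform:
        if (values <= 0).any():
            raise ValidationError("metabolite_differential: non-positive abundance under log transform")
        values = np.log2(values)

    stats_rows = []
    for i, mid in enumerate(matrix.index):
        t, df, p = welch_t(values[i, mask2], values[i, mask1])
        lfc = float(values[i, mask2].mean() - values[i, mask1].mean())
        stats_rows.append((str(mid), lfc, t, df, p))
    fdrs = benjamini_hochberg([r[4] for r in stats_rows])
    out = [
        MetaboliteStat(mid, lfc, t, df, p, float(q))
        for (mid, lfc, t, df, p), q in zip(stats_rows, fdrs)
    ]
    counts = {
        "raw_p_lt_0.05": int(sum(s.raw_p < 0.05 for s in out)),
        "fdr_lt_0.05": int(sum(s.fdr < 0.05 for s in out)),
    }
    return out, counts


def stats_to_frame(stats_list: Sequence[MetaboliteStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"metabolite_id": s.metabolite_id, "log2_fold": s.log2_fold, "t": s.t,
             "df": s.df, "raw_p": s.raw_p, "fdr": s.fdr}
            for s in stats_list
        ]
    )


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrate_metabolite_ids: tuple[str, ...]
    product_metabolite_ids: tuple[str, ...]
    enzyme_gene_ids: tuple[str, ...]
    pathway_name: str

    def __post_init__(self) -> None:
        if not self.enzyme_gene_ids:
            raise ValidationError(f"reaction {self.reaction_id!r}: no enzymes")
        if not (self.substrate_metabolite_ids or self.product_metabolite_ids):
            raise ValidationError(f"reaction {self.reaction_id!r}: no metabolites")


@dataclass
class PathwayMap:
    reactions: list[Reaction]

    @classmethod
    def from_tsv(cls, path) -> "PathwayMap":
        """Columns: reaction_id, pathway, enzymes, substrates, products
        (comma-separated id lists)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        reactions = [
            Reaction(
                row.reaction_id,
                tuple(filter(None, row.substrates.split(","))),
                tuple(filter(None, row.products.split(","))),
                tuple(filter(None, row.enzymes.split(","))),
                row.pathway,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(reactions)


def pathway_join(
    pathway_map: PathwayMap,
    enzyme_deg: DifferentialComparison,
    metab_stats: Sequence[MetaboliteStat],
    direct_target_ids: set[str],
) -> pd.DataFrame:
    """Join enzyme expression changes to metabolite abundance changes.

    One row per (reaction, enzyme, metabolite); enzymes or metabolites
    missing from the stats tables carry NaN fold-changes.
    """
    enz = enzyme_deg.records.set_index("gene_id")["log2fc"]
    met = {s.metabolite_id: s.log2_fold for s in metab_stats}
    rows = []
    for r in pathway_map.reactions:
        metabolites = list(r.substrate_metabolite_ids) + list(r.product_metabolite_ids)
        for e in r.enzyme_gene_ids:
            for m in metabolites:
                rows.append(
                    {
                        "reaction_id": r.reaction_id,
                        "pathway": r.pathway_name,
                        "enzyme_id": e,
                        "enzyme_log2fc": float(enz[e]) if e in enz.index else np.nan,
                        "enzyme_flag_direct": e in direct_target_ids,
                        "metabolite_id": m,
                        "metabolite_log2fold": met.get(m, np.nan),
                    }
                )
    columns = ["reaction_id", "pathway", "enzyme_id", "enzyme_log2fc",
               "enzyme_flag_direct", "metabolite_id", "metabolite_log2fold"]
    return pd.DataFrame(rows, columns=columns)
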