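"""Conditional overlap analysis of paired differential-expression comparisons.

The overlap of independently thresholded DE lists underestimates the true
overlap because each list pays the full multiple-testing price.  The
conditional procedure implemented here (overlap analysis in the style of
Luperchio et al.) instead uses the calls of a *first* comparison to
stratify the genes of a *second* comparison: BH adjustment is re-applied
to the second comparison's raw p-values separately within the stratum of
genes already called in the first comparison and within its complement.
Only the informed stratum is harvested.  Because that stratum is small
and enriched for true effects, its re-adjusted q-values are far less
penalised than a genome-wide adjustment, enlarging the overlap list at
the same nominal FDR.

Two such combos (each pairing a transgene-free comparison with its
transgene-carrying counterpart) are intersected to give the final
high-confidence DE gene list; the naive four-way intersection at the same
threshold serves as the stringent baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import DifferentialComparison, ValidationError

logger = logging.getLogger("hiftargets")

FINAL_DEG_COLUMNS = ["gene_id", "direction", "log2fc", "fdr"]


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    Adjusted values are monotone-enforced and clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("benjamini_hochberg: empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("benjamini_hochberg: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LoaResult:
    """Genes harvested from one conditional combo."""

    combo_label: str
    genes: pd.DataFrame  # gene_id, direction, log2fc_A, log2fc_B, conditional_fdr_B, fdr_A

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes["gene_id"])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def loa_combine(
    comp_A: DifferentialComparison,
    comp_B: DifferentialComparison,
    alpha: float = 0.01,
    combo_label: str = "LOA Combo",
) -> LoaResult:
    """Conditional overlap of two comparisons sharing a gene universe.

    Stratum 1 holds genes with ``fdr_A <= alpha``; BH is re-applied to
    comparison B's raw p-values within each stratum separately.  A gene is
    a member iff it sits in stratum 1, its within-stratum adjusted p is
    <= alpha, and its fold-change signs agree between the two comparisons.
    An empty stratum 1 yields an empty result with a warning.
    """
    a = comp_A.records.set_index("gene_id")
    b = comp_B.records.set_index("gene_id")
    shared = a.index.intersection(b.index)
    dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if dropped:
        logger.warning(
            "loa_combine(%s): %d record(s) outside the shared gene universe dropped",
            combo_label, dropped,
        )
    a, b = a.loc[shared], b.loc[shared]

    in_stratum1 = a["fdr"].to_numpy() <= alpha
    empty = _empty_loa(combo_label)
    if not in_stratum1.any():
        logger.warning("loa_combine(%s): stratum 1 is empty", combo_label)
        return empty

    cond_fdr = np.full(len(shared), np.nan)
    for mask in (in_stratum1, ~in_stratum1):
        if mask.any():
            cond_fdr[mask] = benjamini_hochberg(b["raw_p"].to_numpy()[mask])

    sign_a = np.sign(a["log2fc"].to_numpy())
    sign_b = np.sign(b["log2fc"].to_numpy())
    member = in_stratum1 & (cond_fdr <= alpha) & (sign_a == sign_b) & (sign_a != 0)
    if not member.any():
        return empty

    out = pd.DataFrame(
        {
            "gene_id": shared[member],
            "direction": np.where(sign_a[member] > 0, "up", "down"),
            "log2fc_A": a["log2fc"].to_numpy()[member],
            "log2fc_B": b["log2fc"].to_numpy()[member],
            "conditional_fdr_B": cond_fdr[member],
            "fdr_A": a["fdr"].to_numpy()[member],
        }
    ).sort_values("gene_id", ignore_index=True)
    return LoaResult(combo_label, out)


def _empty_loa(label: str) -> LoaResult:
    cols = ["gene_id", "direction", "log2fc_A", "log2fc_B", "conditional_fdr_B", "fdr_A"]
    return LoaResult(label, pd.DataFrame(columns=cols))


def intersect_combos(combo1: LoaResult, combo2: LoaResult) -> pd.DataFrame:
    """Direction-matched intersection of two combos.

    The reported log2fc/fdr are taken from combo 1's first (A)
    comparison — the mutant-versus-wild-type contrast of the study design.
    """
    merged = combo1.genes.merge(
        combo2.genes[["gene_id", "direction"]], on=["gene_id", "direction"], how="inner"
    )
    out = merged[["gene_id", "direction", "log2fc_A", "fdr_A"]].rename(
        columns={"log2fc_A": "log2fc", "fdr_A": "fdr"}
    )
    return out.sort_values("gene_id", ignore_index=True)


def naive_intersection(
    comparisons: Sequence[DifferentialComparison], alpha: float = 0.01
) -> pd.DataFrame:
    """Genes passing ``fdr <= alpha`` with one common sign in all four
    comparisons — the stringent intersection baseline.

    Reported log2fc/fdr come from the first comparison supplied.
    """
    if len(comparisons) != 4:
        raise ValidationError(
            f"naive_intersection: expected 4 comparisons, got {len(comparisons)}"
        )
    frames = [c.records.set_index("gene_id") for c in comparisons]
    shared = frames[0].index
    for f in frames[1:]:
        shared = shared.intersection(f.index)
    frames = [f.loc[shared] for f in frames]

    sig = np.ones(len(shared), dtype=bool)
    for f in frames:
        sig &= f["fdr"].to_numpy() <= alpha
    signs = np.stack([np.sign(f["log2fc"].to_numpy()) for f in frames])
    concordant = (np.abs(signs.sum(axis=0)) == len(frames)) & (signs[0] != 0)
    member = sig & concordant
    out = pd.DataFrame(
        {
            "gene_id": shared[member],
            "direction": np.where(signs[0][member] > 0, "up", "down"),
            "log2fc": frames[0]["log2fc"].to_numpy()[member],
            "fdr": frames[0]["fdr"].to_numpy()[member],
        }
    )
    return out.sort_values("gene_id", ignore_index=True)
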