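"""Binding/expression integration: regulatory-potential scoring, rank
products, one-tailed KS activator/repressor inference, and direct-target
calling with peak assignment.

A gene's regulatory potential (RP) sums distance-decayed contributions of
all peaks whose centers fall within ``window_bp`` of its TSS:

    S = sum_i exp(-(0.5 + 4 * d_i / window_bp)),   d_i <= window_bp

so a peak at the TSS contributes exp(-0.5) and a peak at the window edge
exp(-4.5).  Normalising the decay by the configured window keeps the
score scale window-invariant.  A gene is called a direct target iff it is
in the final DE gene list and has at least one peak within the window;
each qualifying peak is assigned to its nearest qualifying gene, so the
assignment is a partition (many peaks may map to one gene, never the
reverse).  Whether the factor activates or represses is inferred by
one-tailed two-sample KS tests comparing the RP distribution of the up-
and down-regulated groups against the non-DE background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, GeneModel, Peak, ValidationError

logger = logging.getLogger("hiftargets")


def regulatory_potential(gene: GeneModel, peaks: Sequence[Peak], window_bp: int) -> float:
    """Distance-decayed binding score S for one gene (0 if no peak in window)."""
    if window_bp <= 0:
        raise ValidationError("regulatory_potential: window_bp must be > 0")
    s = 0.0
    for p in peaks:
        if p.chromosome != gene.chromosome:
            continue
        d = abs(p.center - gene.tss)
        if d <= window_bp:
            s += math.exp(-(0.5 + 4.0 * d / window_bp))
    return s


def regulatory_potential_table(
    genes: Sequence[GeneModel], peaks: Sequence[Peak], window_bp: int
) -> pd.Series:
    """Vectorised RP for every gene, indexed by gene_id."""
    if window_bp <= 0:
        raise ValidationError("regulatory_potential: window_bp must be > 0")
    centers_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.chromosome for p in peaks}:
        centers_by_chrom[chrom] = np.sort(
            np.array([p.center for p in peaks if p.chromosome == chrom])
        )
    out = {}
    for g in genes:
        centers = centers_by_chrom.get(g.chromosome)
        if centers is None:
            out[g.gene_id] = 0.0
            continue
        lo = np.searchsorted(centers, g.tss - window_bp, side="left")
        hi = np.searchsorted(centers, g.tss + window_bp, side="right")
        d = np.abs(centers[lo:hi] - g.tss)
        out[g.gene_id] = float(np.exp(-(0.5 + 4.0 * d / window_bp)).sum())
    return pd.Series(out, name="rp")


def rank_targets(rp: pd.Series, deg_table: pd.DataFrame) -> pd.DataFrame:
    """Rank-product prioritisation of DE genes by binding and expression.

    ``rp_rank`` ranks RP descending (ties averaged); ``de_rank`` ranks FDR
    ascending with |log2fc| descending as tiebreak; ``rank_product`` is
    the product of the two normalised ranks, in (0, 1].
    """
    missing = set(deg_table["gene_id"]) - set(rp.index)
    if missing:
        raise ValidationError(f"rank_targets: genes missing from RP table: {sorted(missing)[:5]}")
    df = deg_table.copy()
    n = len(df)
    df["rp"] = rp.loc[df["gene_id"]].to_numpy()
    df["rp_rank"] = stats.rankdata(-df["rp"].to_numpy(), method="average")
    # lexicographic (fdr asc, |log2fc| desc) via dense composite key
    fdr_r = stats.rankdata(df["fdr"].to_numpy(), method="dense")
    fc_r = stats.rankdata(-np.abs(df["log2fc"].to_numpy()), method="dense")
    df["de_rank"] = stats.rankdata(fdr_r * (n + 1) + fc_r, method="average")
    df["rank_product"] = (df["rp_rank"] / n) * (df["de_rank"] / n)
    return df


@dataclass
class RegulationVerdict:
    """One-tailed KS evidence for activation and/or repression."""

    up_ks_stat: float
    up_p: float
    down_ks_stat: float
    down_p: float
    verdict: str  # activator | repressor | both | none

    def to_dict(self) -> dict:
        return {
            "up_ks_stat": self.up_ks_stat,
            "up_p": self.up_p,
            "down_ks_stat": self.down_ks_stat,
            "down_p": self.down_p,
            "verdict": self.verdict,
        }


def _one_sided_ks(group: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    """One-tailed two-sample KS: alternative = group shifted to higher values.

    Exact p by enumeration (scipy's exact method) when both samples have
    <= 10 tie-free observations; asymptotic otherwise.
    """
    if group.size == 0:
        return 0.0, 1.0
    pooled = np.concatenate([group, background])
    small = group.size <= 10 and background.size <= 10
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (small and tie_free) else "asymp"
    res = stats.ks_2samp(group, background, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_regulation_test(
    up_rp: Sequence[float],
    down_rp: Sequence[float],
    static_rp: Sequence[float],
    ks_cutoff: float = 0.01,
) -> RegulationVerdict:
    """Compare RP distributions of DE groups against the non-DE background.

    An empty DE group scores p = 1 for that side; the verdict names the
    side(s) with p <= ks_cutoff.
    """
    static = np.asarray(static_rp, dtype=float)
    if static.size == 0:
        raise ValidationError("ks_regulation_test: static background is empty")
    up_stat, up_p = _one_sided_ks(np.asarray(up_rp, dtype=float), static)
    down_stat, down_p = _one_sided_ks(np.asarray(down_rp, dtype=float), static)
    act, rep = up_p <= ks_cutoff, down_p <= ks_cutoff
    verdict = {(True, True): "both", (True, False): "activator",
               (False, True): "repressor", (False, False): "none"}[(act, rep)]
    return RegulationVerdict(up_stat, up_p, down_stat, down_p, verdict)


@dataclass
class TargetCall:
    """A gene judged a direct functional target."""

    gene_id: str
    direction: str
    peak_ids: list[str]
    rp: float
    log2fc: float
    fdr: float

    @property
    def n_sites(self) -> int:
        return len(self.peak_ids)


def call_direct_targets(
    hif_peaks: Sequence[Peak],
    final_deg_table: pd.DataFrame,
    genes: Sequence[GeneModel],
    config: AnalysisConfig,
) -> tuple[list[TargetCall], RegulationVerdict]:
    """Call direct targets and assign peaks.

    A gene qualifies iff it appears in ``final_deg_table`` at
    ``fdr <= alpha`` and has >= 1 peak center within ``window_bp`` of its
    TSS.  Each peak within the window of any qualifying gene is assigned
    to the nearest such gene (ties broken by lexicographic gene_id).  The
    activator/repressor verdict comes from the KS test of DE-group RP
    against the non-DE background.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    unknown = set(final_deg_table["gene_id"]) - set(gene_by_id)
    if unknown:
        logger.warning("call_direct_targets: %d DE gene(s) missing from annotation", len(unknown))
    deg = final_deg_table[
        (final_deg_table["fdr"] <= config.alpha)
        & final_deg_table["gene_id"].isin(gene_by_id)
    ]

    rp = regulatory_potential_table(genes, hif_peaks, config.window_bp)

    deg_genes = [gene_by_id[g] for g in deg["gene_id"]]
    qualifying = [g for g in deg_genes if rp[g.gene_id] > 0]
    assignment: dict[str, str] = {}
    if qualifying:
        q_sorted = sorted(qualifying, key=lambda g: g.gene_id)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in q_sorted:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for p in hif_peaks:
            cands = by_chrom.get(p.chromosome, [])
            best: Optional[str] = None
            best_d = config.window_bp + 1
            for g in cands:  # lexicographic order => ties keep first
                d = abs(p.center - g.tss)
                if d <= config.window_bp and d < best_d:
                    best, best_d = g.gene_id, d
            if best is not None:
                assignment[p.peak_id] = best

    peaks_by_gene: dict[str, list[str]] = {}
    for pid, gid in assignment.items():
        peaks_by_gene.setdefault(gid, []).append(pid)

    deg_idx = deg.set_index("gene_id")
    calls = [
        TargetCall(
            gene_id=gid,
            direction="up" if deg_idx.loc[gid, "log2fc"] > 0 else "down",
            peak_ids=sorted(pids),
            rp=float(rp[gid]),
            log2fc=float(deg_idx.loc[gid, "log2fc"]),
            fdr=float(deg_idx.loc[gid, "fdr"]),
        )
        for gid, pids in sorted(peaks_by_gene.items())
    ]
    if not calls:
        logger.warning("call_direct_targets: no genes qualify")

    deg_ids = set(deg["gene_id"])
    up_rp = [rp[g] for g in deg_ids if deg_idx.loc[g, "log2fc"] > 0]
    down_rp = [rp[g] for g in deg_ids if deg_idx.loc[g, "log2fc"] < 0]
    static_rp = [rp[g.gene_id] for g in genes if g.gene_id not in deg_ids]
    verdict = ks_regulation_test(up_rp, down_rp, static_rp, config.ks_cutoff)
    return calls, verdict


def sites_per_target_summary(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Histogram of binding sites per called target (n_sites, count, fraction)."""
    if not calls:
        return pd.DataFrame(columns=["n_sites", "count", "fraction"])
    counts = pd.Series([c.n_sites for c in calls]).value_counts().sort_index()
    return pd.DataFrame(
        {"n_sites": counts.index, "count": counts.to_numpy(),
         "fraction": counts.to_numpy() / counts.sum()}
    ).reset_index(drop=True)


def calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "n_sites": c.n_sites,
                "peak_ids": ",".join(c.peak_ids),
                "rp": c.rp,
                "log2fc": c.log2fc,
                "fdr": c.fdr,
            }
            for c in calls
        ],
        columns=["gene_id", "direction", "n_sites", "peak_ids", "rp", "log2fc", "fdr"],
    )
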