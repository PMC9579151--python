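"""Transcription-factor co-occupancy around anchor peaks.

HOT ("high occupancy target") loci are genomic regions bound by many
distinct factors in ChIP-seq — often sticky, artifact-prone chromatin
rather than sequence-specific regulation.  This module counts, for each
anchor peak, how many distinct other factors have a peak center within a
radius of the anchor's center (400 bp by default), flags anchors near
>= 15 other factors as HOT, tests per-factor enrichment against a
bootstrap null that repositions the anchor set uniformly at random, and
compares occupancy distributions between site sets with the
Kruskal–Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, Genome, Peak, ValidationError
from .loa import benjamini_hochberg


@dataclass(frozen=True)
class CobindProfile:
    peak_id: str
    n_tfs: int
    is_hot: bool


def _centers_by_chrom(peaks: Sequence[Peak]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for p in peaks:
        out.setdefault(p.chromosome, []).append(p.center)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _within_radius(
    centers: np.ndarray, positions: np.ndarray, radius: int
) -> np.ndarray:
    """Boolean: does any value of sorted ``centers`` lie within radius of each position."""
    if centers.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    idx = np.searchsorted(centers, positions)
    right = np.where(idx < centers.size, centers[np.minimum(idx, centers.size - 1)] - positions, np.iinfo(np.int64).max)
    left = np.where(idx > 0, positions - centers[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    return np.minimum(right, left) <= radius


def cobinding_counts(
    anchor_peaks: Sequence[Peak],
    tf_atlas: Mapping[str, Sequence[Peak]],
    radius_bp: int,
    hot_threshold: int = 15,
) -> list[CobindProfile]:
    """Distinct co-binding factor count per anchor; HOT iff count >= threshold.

    A factor co-binds an anchor iff one of its peak centers lies within
    ``radius_bp`` of the anchor center on the same chromosome.
    """
    if radius_bp <= 0:
        raise ValidationError("cobinding_counts: radius_bp must be > 0")
    atlas_centers = {tf: _centers_by_chrom(peaks) for tf, peaks in tf_atlas.items()}
    chroms = sorted({p.chromosome for p in anchor_peaks})
    counts = np.zeros(len(anchor_peaks), dtype=int)
    for chrom in chroms:
        rows = np.array([i for i, p in enumerate(anchor_peaks) if p.chromosome == chrom])
        pos = np.array([anchor_peaks[i].center for i in rows], dtype=np.int64)
        for per_chrom in atlas_centers.values():
            centers = per_chrom.get(chrom)
            if centers is not None:
                counts[rows] += _within_radius(centers, pos, radius_bp)
    return [
        CobindProfile(p.peak_id, int(c), bool(c >= hot_threshold))
        for p, c in zip(anchor_peaks, counts)
    ]


@dataclass(frozen=True)
class TfEnrichment:
    tf_name: str
    observed: int
    boot_mean: float
    log2_fold: float
    p: float
    direction: str  # "enriched" | "depleted"
    fdr: float


def bootstrap_tf_enrichment(
    anchor_peaks: Sequence[Peak],
    tf_atlas: Mapping[str, Sequence[Peak]],
    genome: Genome,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> list[TfEnrichment]:
    """Per-factor co-binding enrichment against a repositioned-anchor null.

    Each of ``n_boot`` replicates repositions every anchor peak uniformly
    at random (chromosome with probability proportional to length,
    position uniform, interval length preserved) and recounts how many
    repositioned anchors each factor co-binds.  One-sided add-one
    p-values are computed for enrichment and depletion; the smaller side
    is reported with its direction, and BH adjustment is applied across
    factors.  ``log2_fold = log2((observed + 1) / (boot_mean + 1))``.
    """
    if config.n_boot < 1:
        raise ValidationError("bootstrap_tf_enrichment: n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(anchor_peaks)
    B = config.n_boot
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    anchor_len = np.array([p.length for p in anchor_peaks], dtype=np.int64)
    if (anchor_len > lengths.max()).any():
        raise ValidationError("bootstrap_tf_enrichment: an anchor exceeds every chromosome")

    chrom_idx = rng.choice(len(lengths), size=(B, n), p=lengths / lengths.sum())
    span = lengths[chrom_idx] - anchor_len[None, :]
    if (span < 0).any():
        raise ValidationError("bootstrap_tf_enrichment: genome shorter than an anchor interval")
    start = (rng.random(size=(B, n)) * (span + 1)).astype(np.int64)
    boot_center = start + anchor_len[None, :] // 2

    obs_pos = {  # anchor centers grouped by chromosome index
        ci: np.array([p.center for p in anchor_peaks if p.chromosome == genome.names[ci]],
                     dtype=np.int64)
    for ci in range(len(lengths))}

    # flatten replicate positions grouped by chromosome once, shared by all TFs
    flat_chrom = chrom_idx.ravel()
    flat_center = boot_center.ravel()
    flat_rep = np.repeat(np.arange(B), n)
    by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ci in range(len(lengths)):
        sel = flat_chrom == ci
        if sel.any():
            by_chrom[ci] = (flat_center[sel], flat_rep[sel])

    radius = config.cobind_radius_bp
    tf_names = sorted(tf_atlas)
    pvals, rows = [], []
    for tf in tf_names:
        per_chrom = _centers_by_chrom(tf_atlas[tf])
        observed = 0
        boot_counts = np.zeros(B, dtype=np.int64)
        for ci, cname in enumerate(genome.names):
            centers = per_chrom.get(cname)
            if centers is None or centers.size == 0:
                continue
            if obs_pos[ci].size:
                observed += int(_within_radius(centers, obs_pos[ci], radius).sum())
            if ci in by_chrom:
                pos, rep = by_chrom[ci]
                hits = _within_radius(centers, pos, radius)
                boot_counts += np.bincount(rep[hits], minlength=B)
        boot_mean = float(boot_counts.mean())
        p_enrich = (1 + int((boot_counts >= observed).sum())) / (B + 1)
        p_deplete = (1 + int((boot_counts <= observed).sum())) / (B + 1)
        if p_enrich <= p_deplete:
            p, direction = p_enrich, "enriched"
        else:
            p, direction = p_deplete, "depleted"
        log2_fold = float(np.log2((observed + 1) / (boot_mean + 1)))
        pvals.append(p)
        rows.append((tf, observed, boot_mean, log2_fold, p, direction))
    fdrs = benjamini_hochberg(pvals)
    return [
        TfEnrichment(tf, obs, bm, lf, p, d, float(q))
        for (tf, obs, bm, lf, p, d), q in zip(rows, fdrs)
    ]


def enrichment_to_frame(enrichments: Sequence[TfEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tf_name": e.tf_name, "observed": e.observed, "boot_mean": e.boot_mean,
             "log2_fold": e.log2_fold, "p": e.p, "direction": e.direction, "fdr": e.fdr}
            for e in enrichments
        ]
    )


def compare_occupancy_distributions(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) across named occupancy groups."""
    if len(groups) < 2:
        raise ValidationError("compare_occupancy_distributions: need >= 2 groups")
    arrays = []
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"compare_occupancy_distributions: group {name!r} is empty")
        arrays.append(arr)
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        return 0.0, 1.0  # identical groups; H is exactly 0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_occupancy_tests(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Post-hoc pairwise rank-sum (Mann–Whitney) tests with BH correction."""
    names = sorted(groups)
    rows, pvals = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append((a, b, float(res.statistic)))
            pvals.append(float(res.pvalue))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic"])
    out["p"] = pvals
    out["fdr"] = benjamini_hochberg(pvals) if pvals else []
    return out
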