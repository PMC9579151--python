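"""Synthetic regulomes with planted ground truth.

The generators emulate the statistical structure the analysis assumes: a
small genome with annotated TSSs; an anchor-factor peak set in which each
planted direct target receives 1–5 target-proximal peaks (59% of targets
carry a single site) and the remaining peaks are decoys, most stacked at
HOT loci where many atlas factors co-bind; four pairwise DE comparisons
sharing per-gene planted effects; peak-window sequences with an RCGTG
core planted preferentially in functional windows; a two-condition
metabolite matrix; and a multi-study human DE panel in which a planted
fraction of ortholog genes is consistently upregulated.

Every generator is a pure function of (params, seed): each draws from its
own named substream of the top-level seed, so outputs are reproducible
individually and jointly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DifferentialComparison,
    GeneModel,
    Genome,
    Peak,
    SizingError,
    ValidationError,
)
from .loa import benjamini_hochberg
from .orthologs import StudyPanel

# Named substreams: every generator derives its RNG from
# SeedSequence(seed, spawn_key=(stream,)) so modules are independent.
_STREAMS = {"regulome": 0, "deg": 1, "sequences": 2, "metabolome": 3, "orthologs": 4}

COMPARISON_LABELS = (
    "egl9_vs_wt",          # mutant (factor stabilised) vs wild type
    "egl9_vs_egl9hif1",    # mutant vs mutant lacking the factor
    "tg_egl9_vs_wt",       # transgene-rescued comparison, vs wild type
    "tg_egl9_vs_egl9hif1", # transgene-rescued comparison, vs factor-null
)
# LOA pairing: each combo conditions its second (transgene) comparison on
# its first.
COMBO_PAIRING = ((0, 2), (1, 3))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationParams:
    """Study-scale generator settings (a ~5x scaled-down nematode genome).

    Defaults encode the study conditions: 59% of targets carry a single
    binding site, nine metabolite replicates, 31 DE studies in the
    meta-analysis panel, planted consistent fractions 6.8% (orthologs)
    vs 0.3% (background), and a metabolite effect fraction chosen so the
    expected raw p<0.05 count is ~175 of 558.
    """

    n_chromosomes: int = 6
    chromosome_length_bp: int = 3_000_000
    n_genes: int = 2000
    n_direct_targets: int = 20
    sites_per_target_distribution: tuple[float, ...] = (0.59, 0.205, 0.10, 0.07, 0.035)
    target_peak_max_offset_bp: int = 10_000
    peak_width_bp: int = 200
    n_decoy_peaks: int = 75
    n_hot_loci: int = 25
    hot_decoy_fraction: float = 0.8
    n_tfs: int = 30
    hot_tf_count_at_hot_loci: int = 20
    tf_peaks_per_tf: int = 150
    hot_jitter_bp: int = 100
    hot_exclusion_bp: int = 16_000  # keep HOT loci outside target peak-to-gene windows
    cobind_tf_fraction: float = 0.0
    effect_mean_log2fc: float = 4.0
    effect_sd: float = 0.5
    de_noise_sd: float = 0.5
    effect_direction: str = "up"  # "up" | "mixed"
    motif_plant_prob_functional: float = 1.0
    motif_plant_prob_decoy: float = 0.05
    motif_flank_bp: int = 100
    metab_n: int = 558
    metab_replicates: int = 9
    metab_effect_fraction: float = 0.28
    metab_effect_log2: float = 1.0
    metab_noise_sd: float = 0.5
    n_studies: int = 31
    meta_n_genes: int = 20_000
    meta_n_orthologs: int = 1000
    ortholog_fraction_consistent: float = 0.068
    background_fraction_consistent: float = 0.003
    consistent_up_study_prob: float = 0.95
    base_up_study_prob: float = 0.10
    expression_prob_high: float = 0.95
    expression_prob_low: float = 0.30
    low_expression_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length_bp", "n_genes", "peak_width_bp",
                     "n_tfs", "n_studies", "meta_n_genes", "metab_n", "metab_replicates"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"params: {name} must be > 0")
        for name in ("n_direct_targets", "n_decoy_peaks", "n_hot_loci", "tf_peaks_per_tf",
                     "meta_n_orthologs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"params: {name} must be >= 0")
        for name in ("hot_decoy_fraction", "cobind_tf_fraction",
                     "motif_plant_prob_functional", "motif_plant_prob_decoy",
                     "metab_effect_fraction", "ortholog_fraction_consistent",
                     "background_fraction_consistent", "consistent_up_study_prob",
                     "base_up_study_prob", "expression_prob_high", "expression_prob_low",
                     "low_expression_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"params: {name} must be in [0, 1]")
        if self.n_direct_targets > self.n_genes:
            raise ValidationError("params: n_direct_targets > n_genes")
        if abs(sum(self.sites_per_target_distribution) - 1.0) > 1e-9:
            raise ValidationError("params: sites_per_target_distribution must sum to 1")
        if self.ortholog_fraction_consistent < self.background_fraction_consistent:
            raise ValidationError(
                "params: ortholog_fraction_consistent < background_fraction_consistent"
            )
        if self.effect_direction not in ("up", "mixed"):
            raise ValidationError("params: effect_direction must be 'up' or 'mixed'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"params: unknown keys {sorted(unknown)}")
        if "sites_per_target_distribution" in d:
            d = dict(d, sites_per_target_distribution=tuple(d["sites_per_target_distribution"]))
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites_per_target_distribution"] = list(self.sites_per_target_distribution)
        return d


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic regulome, verifiable by inspection."""

    direct_targets: dict[str, str]            # gene_id -> direction
    peak_assignment: dict[str, str]           # peak_id -> gene_id or "decoy"
    hot_loci: list[tuple[str, int]]
    motif_planted: set[str] = field(default_factory=set)
    sites_per_target: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assigned = [g for g in self.peak_assignment.values() if g != "decoy"]
        if not set(assigned) <= set(self.direct_targets):
            raise ValidationError("truth: an assigned peak's gene is not a direct target")
        if self.sites_per_target and sum(self.sites_per_target.values()) != len(assigned):
            raise ValidationError("truth: sites_per_target does not sum to assigned peaks")

    @property
    def functional_peak_ids(self) -> set[str]:
        return {p for p, g in self.peak_assignment.items() if g != "decoy"}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "note": "synthetic planted ground truth; all distributions are stand-ins",
                    "direct_targets": self.direct_targets,
                    "peak_assignment": self.peak_assignment,
                    "hot_loci": [[c, int(p)] for c, p in self.hot_loci],
                    "motif_planted": sorted(self.motif_planted),
                    "sites_per_target": self.sites_per_target,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            direct_targets=d["direct_targets"],
            peak_assignment=d["peak_assignment"],
            hot_loci=[(c, int(p)) for c, p in d["hot_loci"]],
            motif_planted=set(d["motif_planted"]),
            sites_per_target={k: int(v) for k, v in d["sites_per_target"].items()},
        )


def make_regulome(
    params: SimulationParams,
) -> tuple[Genome, list[GeneModel], list[Peak], dict[str, list[Peak]], PlantedTruth]:
    """Genome, genes, anchor peaks, TF atlas and planted truth.

    Direct targets receive 1–5 peaks with centers within
    ``target_peak_max_offset_bp`` of their TSS; HOT loci are kept away
    from target TSSs so functional sites sit in low-occupancy chromatin;
    a configured fraction of decoys stacks at HOT loci, where
    ``hot_tf_count_at_hot_loci`` atlas factors also place peaks.
    """
    rng = _rng(params.seed, "regulome")
    margin = params.target_peak_max_offset_bp + params.peak_width_bp
    L = params.chromosome_length_bp
    if 2 * margin >= L:
        raise SizingError("chromosome too short for the requested peak offsets")
    genome = Genome(tuple((f"chr{i + 1}", L) for i in range(params.n_chromosomes)))
    if params.n_genes * 100 > genome.total_length:
        raise SizingError("gene spacing infeasible: fewer than 100 bp per gene")

    n_digits = len(str(params.n_genes))
    gene_ids = [f"g{str(i + 1).zfill(n_digits)}" for i in range(params.n_genes)]
    chrom_of = rng.integers(0, params.n_chromosomes, size=params.n_genes)
    tss = rng.integers(margin, L - margin, size=params.n_genes)
    strands = rng.choice(["+", "-"], size=params.n_genes)
    genes = [
        GeneModel(gid, f"chr{c + 1}", s, int(t))
        for gid, c, t, s in zip(gene_ids, chrom_of, tss, strands)
    ]

    target_idx = np.sort(rng.choice(params.n_genes, size=params.n_direct_targets, replace=False))
    if params.effect_direction == "up":
        directions = ["up"] * params.n_direct_targets
    else:
        directions = list(rng.choice(["up", "down"], size=params.n_direct_targets))
    direct_targets = {gene_ids[i]: d for i, d in zip(target_idx, directions)}

    # Anchor peaks: planted target-proximal sites first, then decoys.
    width = params.peak_width_bp
    hif_peaks: list[Peak] = []
    assignment: dict[str, str] = {}
    sites_per_target: dict[str, int] = {}
    site_counts = 1 + rng.choice(
        len(params.sites_per_target_distribution),
        size=params.n_direct_targets,
        p=np.array(params.sites_per_target_distribution),
    )
    for i, k in zip(target_idx, site_counts):
        g = genes[i]
        sites_per_target[g.gene_id] = int(k)
        for _ in range(int(k)):
            offset = int(rng.integers(0, params.target_peak_max_offset_bp + 1))
            sign = -1 if rng.random() < 0.5 else 1
            center = int(np.clip(g.tss + sign * offset, width, L - width))
            pid = f"hifp_{len(hif_peaks) + 1}"
            hif_peaks.append(Peak(pid, g.chromosome, center - width // 2, center + width // 2))
            assignment[pid] = g.gene_id

    # HOT loci, kept clear of target TSS neighbourhoods.
    target_tss = {(genes[i].chromosome, genes[i].tss) for i in target_idx}
    exclusion = params.hot_exclusion_bp
    hot_loci: list[tuple[str, int]] = []
    attempts = 0
    while len(hot_loci) < params.n_hot_loci:
        attempts += 1
        if attempts > 100 * max(1, params.n_hot_loci):
            raise SizingError("could not place HOT loci away from target TSSs")
        c = int(rng.integers(0, params.n_chromosomes))
        pos = int(rng.integers(margin, L - margin))
        chrom = f"chr{c + 1}"
        if all(ch != chrom or abs(pos - t) > exclusion for ch, t in target_tss):
            hot_loci.append((chrom, pos))

    n_hot_decoys = int(round(params.hot_decoy_fraction * params.n_decoy_peaks)) if hot_loci else 0
    for j in range(params.n_decoy_peaks):
        if j < n_hot_decoys:
            chrom, pos = hot_loci[j % len(hot_loci)]
            center = pos + int(rng.integers(-params.hot_jitter_bp, params.hot_jitter_bp + 1))
        else:
            chrom = f"chr{int(rng.integers(0, params.n_chromosomes)) + 1}"
            center = int(rng.integers(margin, L - margin))
        pid = f"hifp_{len(hif_peaks) + 1}"
        hif_peaks.append(Peak(pid, chrom, center - width // 2, center + width // 2))
        assignment[pid] = "decoy"

    # Atlas: per-factor background peaks plus stacks at HOT loci.
    tf_atlas: dict[str, list[Peak]] = {}
    tf_names = [f"TF_{str(i + 1).zfill(2)}" for i in range(params.n_tfs)]
    for tf in tf_names:
        peaks = []
        for k in range(params.tf_peaks_per_tf):
            chrom = f"chr{int(rng.integers(0, params.n_chromosomes)) + 1}"
            center = int(rng.integers(width, L - width))
            peaks.append(Peak(f"{tf}_p{k + 1}", chrom, center - width // 2, center + width // 2))
        tf_atlas[tf] = peaks
    hot_tf_n = min(params.hot_tf_count_at_hot_loci, params.n_tfs)
    for h, (chrom, pos) in enumerate(hot_loci):
        chosen = rng.choice(params.n_tfs, size=hot_tf_n, replace=False)
        for t in chosen:
            tf = tf_names[int(t)]
            center = pos + int(rng.integers(-params.hot_jitter_bp, params.hot_jitter_bp + 1))
            tf_atlas[tf].append(
                Peak(f"{tf}_hot{h + 1}", chrom, center - width // 2, center + width // 2)
            )

    if params.cobind_tf_fraction > 0 and hif_peaks:
        n_cobind = int(round(params.cobind_tf_fraction * len(hif_peaks)))
        chosen = rng.choice(len(hif_peaks), size=n_cobind, replace=False)
        peaks = []
        for j, idx in enumerate(np.sort(chosen)):
            anchor = hif_peaks[int(idx)]
            center = anchor.center + int(rng.integers(-200, 201))
            center = int(np.clip(center, width, L - width))
            peaks.append(
                Peak(f"TF_planted_p{j + 1}", anchor.chromosome, center - width // 2, center + width // 2)
            )
        tf_atlas["TF_planted"] = peaks

    truth = PlantedTruth(
        direct_targets=direct_targets,
        peak_assignment=assignment,
        hot_loci=hot_loci,
        sites_per_target=sites_per_target,
    )
    return genome, genes, hif_peaks, tf_atlas, truth


def simulate_deg_tables(
    truth: PlantedTruth, genes: Sequence[GeneModel], params: SimulationParams
) -> list[DifferentialComparison]:
    """Four pairwise DE comparisons sharing planted per-gene effects.

    Each direct target draws one gene-level log2FC effect, re-noised per
    comparison; z = log2fc / noise_sd gives two-sided p-values that are
    exactly Uniform(0, 1) for null genes.  FDR by BH within each
    comparison.
    """
    rng = _rng(params.seed, "deg")
    gene_ids = [g.gene_id for g in genes]
    unknown = set(truth.direct_targets) - set(gene_ids)
    if unknown:
        raise ValidationError(f"simulate_deg_tables: truth genes not in gene set: {sorted(unknown)[:5]}")
    effect = np.zeros(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        d = truth.direct_targets.get(gid)
        if d is not None:
            e = rng.normal(params.effect_mean_log2fc, params.effect_sd)
            effect[i] = abs(e) if d == "up" else -abs(e)

    comparisons = []
    for label in COMPARISON_LABELS:
        obs = effect + rng.normal(0.0, params.de_noise_sd, size=len(gene_ids))
        z = obs / params.de_noise_sd
        raw_p = 2 * stats.norm.sf(np.abs(z))
        df = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": obs, "raw_p": raw_p,
             "fdr": benjamini_hochberg(raw_p)}
        )
        comparisons.append(DifferentialComparison(label, df))
    return comparisons


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_peak_sequences(
    hif_peaks: Sequence[Peak], truth: PlantedTruth, params: SimulationParams
) -> dict[str, str]:
    """Per-peak windows of length 2*flank+1 with planted RCGTG cores.

    Background is i.i.d. uniform A/C/G/T.  A consensus instance (ACGTG or
    GCGTG, on a random strand) is planted at a random offset with
    probability ``motif_plant_prob_functional`` for truth-assigned peaks
    and ``motif_plant_prob_decoy`` otherwise; planted peak ids are
    recorded in ``truth.motif_planted``.
    """
    if params.motif_flank_bp < 3:
        raise SizingError("motif_flank_bp < 3: the 5-bp core cannot fit")
    rng = _rng(params.seed, "sequences")
    width = 2 * params.motif_flank_bp + 1
    functional = truth.functional_peak_ids
    out: dict[str, str] = {}
    for p in hif_peaks:
        seq = _BASES[rng.integers(0, 4, size=width)].tobytes().decode()
        prob = (
            params.motif_plant_prob_functional
            if p.peak_id in functional
            else params.motif_plant_prob_decoy
        )
        if rng.random() < prob:
            core = ("A" if rng.random() < 0.5 else "G") + "CGTG"
            if rng.random() < 0.5:  # random strand
                core = core.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            off = int(rng.integers(0, width - len(core) + 1))
            seq = seq[:off] + core + seq[off + len(core):]
            truth.motif_planted.add(p.peak_id)
        out[p.peak_id] = seq
    return out


def simulate_metabolome(
    params: SimulationParams,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-condition log-normal abundance matrix with a perturbed subset.

    Returns (matrix, design labels, perturbed metabolite ids); the matrix
    is metab_n rows by 2*metab_replicates columns.
    """
    rng = _rng(params.seed, "metabolome")
    n, r = params.metab_n, params.metab_replicates
    mids = [f"m{str(i + 1).zfill(len(str(n)))}" for i in range(n)]
    base = rng.normal(10.0, 2.0, size=n)
    log2_ab = base[:, None] + rng.normal(0.0, params.metab_noise_sd, size=(n, 2 * r))
    n_perturbed = int(round(params.metab_effect_fraction * n))
    perturbed_idx = np.sort(rng.choice(n, size=n_perturbed, replace=False))
    signs = np.where(rng.random(n_perturbed) < 0.5, 1.0, -1.0)
    log2_ab[perturbed_idx, r:] += signs[:, None] * params.metab_effect_log2
    columns = [f"cond1_r{j + 1}" for j in range(r)] + [f"cond2_r{j + 1}" for j in range(r)]
    matrix = pd.DataFrame(np.exp2(log2_ab), index=mids, columns=columns)
    design = ["cond1"] * r + ["cond2"] * r
    return matrix, design, [mids[i] for i in perturbed_idx]


def simulate_ortholog_studies(
    params: SimulationParams,
) -> tuple[StudyPanel, set[str], set[str]]:
    """Multi-study human DE panel with planted consistent genes.

    Returns (panel, ortholog gene set, truth consistent set).  Consistent
    genes are upregulated with q < 0.05 in nearly every study in which
    they are expressed; a fraction of genes is lowly expressed so the
    expressed-in->=15-studies filter is exercised.  Consistent fractions
    default to 6.8% of orthologs and 0.3% of the background.
    """
    rng = _rng(params.seed, "orthologs")
    n = params.meta_n_genes
    gene_ids = np.array([f"h{str(i + 1).zfill(len(str(n)))}" for i in range(n)])
    orth_idx = np.sort(rng.choice(n, size=params.meta_n_orthologs, replace=False))
    is_orth = np.zeros(n, dtype=bool)
    is_orth[orth_idx] = True

    n_orth_cons = int(round(params.ortholog_fraction_consistent * params.meta_n_orthologs))
    bg_idx = np.nonzero(~is_orth)[0]
    n_bg_cons = int(round(params.background_fraction_consistent * bg_idx.size))
    cons_idx = np.concatenate(
        [
            rng.choice(orth_idx, size=n_orth_cons, replace=False),
            rng.choice(bg_idx, size=n_bg_cons, replace=False),
        ]
    )
    is_cons = np.zeros(n, dtype=bool)
    is_cons[cons_idx] = True

    # consistent genes keep high expression probability so they stay
    # observable in enough studies
    low_expr = (rng.random(n) < params.low_expression_fraction) & ~is_cons
    p_expr = np.where(low_expr, params.expression_prob_low, params.expression_prob_high)

    studies: dict[str, pd.DataFrame] = {}
    for s in range(params.n_studies):
        expressed = rng.random(n) < p_expr
        up_sig = rng.random(n) < np.where(
            is_cons, params.consistent_up_study_prob, params.base_up_study_prob
        )
        log2fc = np.where(up_sig, np.abs(rng.normal(2.0, 0.5, size=n)), rng.normal(0.0, 1.0, size=n))
        q = np.where(
            up_sig,
            rng.uniform(0.0, 0.8 * 0.05, size=n),
            rng.uniform(0.0, 1.0, size=n),
        )
        # non-significant draws may still land under the threshold by
        # chance; push genuinely-null small-q genes to negative or weak
        # fold changes with the Uniform draw above (no adjustment needed:
        # base_up_study_prob covers the by-chance rate)
        df = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": np.where(expressed, log2fc, np.nan),
                "q": np.where(expressed, q, np.nan),
                "expressed": expressed,
            }
        )
        studies[f"study_{str(s + 1).zfill(2)}"] = df
    panel = StudyPanel(studies)
    return panel, set(gene_ids[is_orth]), set(gene_ids[is_cons])
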