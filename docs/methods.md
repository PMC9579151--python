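# Methods

This note documents the statistical procedures implemented in
`hiftargets`, the synthetic-data model used to exercise them, the
numerical choices made where the design was genuinely open, and the
limits of what the synthetic tests demonstrate.

## Coordinate conventions

All intervals are BED-style 0-based half-open. A peak's center is
`floor((start + end) / 2)`; the TSS of a minus-strand gene is `end − 1`
(the last covered base). Peak–gene distance is the unsigned
center-to-TSS distance and is undefined across chromosomes; the 15 kb
window is therefore symmetric around the TSS rather than strand-signed —
with a symmetric placement model the unsigned choice loses no
information and avoids a strand-dependent off-by-one class.

## Conditional overlap (LOA)

Given comparisons A and B over a shared gene universe and level α
(default 0.01):

1. Stratum 1 = genes with `fdr_A ≤ α` (A's own genome-wide BH values);
   stratum 2 = the rest.
2. BH is re-applied to B's **raw** p-values within each stratum
   separately.
3. Members are the stratum-1 genes with within-stratum q ≤ α and
   `sign(log2FC_A) = sign(log2FC_B) ≠ 0`. Stratum 2 is never harvested.

The power gain is structural: stratum 1 is small and effect-enriched, so
its re-adjusted q-values pay almost no multiplicity price. The final
list intersects Combo 1 (mutant-vs-wild-type pairing) and Combo 2
(factor-null pairing) on gene and direction; its reported log2FC/FDR
come from Combo 1's first comparison, the mutant-versus-wild-type
contrast, which is the natural reporting axis for a stabilised-factor
design. Genes absent from either comparison are dropped (logged) before
stratification. The stratified re-adjustment is the module's main
interpretive choice: the procedure is specified here as the minimal
conditional scheme with both-comparison significance and sign
concordance; local-FDR or empirical-Bayes variants are out of scope.

The naive baseline is the four-way intersection of genes at
`fdr ≤ α` with one common sign in all four comparisons.

## Regulatory potential and target calling

`S_g = Σ exp(−(0.5 + 4 d_i/w))` over peaks with `d_i ≤ w`, `w` the
configured window (15 kb default). The decay is normalised by `w`, not
by a fixed genomic constant, so the score spans (e^−0.5 … e^−4.5] across
the window at any window size; this keeps the ranking scale
window-invariant. Rank products (binding rank × DE rank, each
normalised) are reported for prioritisation but are not an additional
filter: the target definition is `fdr ≤ α` plus ≥ 1 peak in the window.

Peaks within the window of at least one qualifying gene are assigned to
the nearest qualifying TSS, ties broken by lexicographic gene id. This
makes site assignment a partition — many sites may map to one target,
never the reverse — which is what a sites-per-target histogram requires.

The activator/repressor verdict uses one-tailed two-sample KS tests
(alternative: the DE group's S distribution is shifted high relative to
the non-DE background), cutoff 0.01. The p-value is computed by exact
enumeration (no ties, both samples ≤ 10) and asymptotically otherwise;
an empty DE group scores p = 1.

## Co-occupancy and the bootstrap null

A factor co-binds an anchor iff one of its peak centers is within the
radius (400 bp) of the anchor center on the same chromosome;
center-to-center distance is used for both sides (the
interval-overlap alternative is not exposed because peak widths are an
upstream artifact of the caller, not a binding property). Anchors with
≥ 15 distinct co-binding factors are HOT, boundary inclusive.

The null repositions the **anchor** set — chromosome chosen with
probability proportional to length, start uniform, interval length
preserved — and recounts all factors once per replicate, so per-factor
counts share replicates exactly as the observed counts share anchors.
Repositioning anchors rather than the atlas keeps the atlas (a fixed
public resource) intact. Enrichment and depletion p-values use the
add-one rule `p = (1 + #{boot ≥ obs}) / (B + 1)` (mirrored for
depletion); the smaller side is reported with its direction and BH is
applied across factors. The reported raw p is therefore up to 2×
anti-conservative under the null; calibration is controlled at the BH
level, which is what the package's own calibration check measures.
`log2_fold = log2((obs+1)/(boot_mean+1))` with add-one smoothing to
avoid zeros. The default B = 10^5 matches the study setting; the
package's own checks use B = 500–2000, which bounds attainable p at
1/(B+1) but leaves fold ranks and calibration unchanged.

Occupancy distributions between site sets are compared with
tie-corrected Kruskal–Wallis (chi-square p on k−1 df), with pairwise
Mann–Whitney/BH post-hocs exposed separately.

## Motif scanning

The scanner counts all, possibly overlapping, matches of an IUPAC
consensus (default RCGTG, the mammalian HRE core) on both strands of
±100 bp peak-center windows; N never matches. Enrichment uses
per-window mononucleotide shuffles (base composition preserved exactly)
and the add-one p-value. Mononucleotide rather than dinucleotide
shuffling is a deliberate simplification — the windows this package
scans are short and, in the synthetic setting, compositionally uniform —
and is a known limitation for real genomic sequence. Uniform background
implies a high chance rate for a 5-bp degenerate core (≈1.5 expected
matches per 201-bp window across both strands), so enrichment is
informative for bound-window sets, not single windows.

## Metabolome

Abundances are log2-transformed after per-metabolite minimum imputation
of missing values (standard practice for untargeted LC-MS panels;
configurable off). Welch's t with Welch–Satterthwaite df per
metabolite, BH across metabolites; both the raw p < 0.05 and FDR < 0.05
counts are reported because platform conventions differ on which count
is quoted. The pathway join emits one row per (reaction, enzyme,
metabolite) with NaN markers for ids absent from the stats tables and a
flag for enzymes in the direct-target set.

## Ortholog meta-analysis

A gene is consistent iff upregulated with q < 0.05 in ≥ 15 studies
(counted only where the gene is expressed); genes expressed in < 15
studies are removable by the expression filter. Enrichment compares the
consistent fraction among orthologs against the universe *excluding*
orthologs (exclusive background avoids double-counting; at 20 000 genes
vs 1000 orthologs the inclusive alternative, available by flag, differs
negligibly). "Proportion test" is implemented as the 2×2 chi-square
with Yates continuity correction, one-sided toward enrichment. A zero
background proportion yields an infinite fold with a flag; an empty
consistent set is flagged degenerate.

## Synthetic-data model

The generator emulates the statistical structure the analysis assumes,
at roughly 1/5 genome scale:

* **Genome/genes** — 6 chromosomes × 3 Mb; 2000 genes at uniform
  positions, random strand.
* **Anchor peaks** — 20 direct targets receive k ∈ 1..5 sites
  (probabilities 0.59, 0.205, 0.10, 0.07, 0.035; the 0.59 single-site
  mass is the observed study condition) with centers within 10 kb of the
  TSS; 75 decoy peaks give a total peak density of ≈6 per Mb, matching
  the study's peak count per genome length. 80% of decoys stack at 25
  HOT loci (most observed binding sites sat in or near HOT regions),
  where 20 of 30 atlas factors also place peaks; HOT loci are kept
  ≥ 16 kb from target TSSs so functional sites occupy low-occupancy
  chromatin, which is the structure the occupancy-shift analysis
  detects. An optional planted co-binder places peaks beside a
  configurable fraction of anchors for enrichment-recovery checks.
* **DE tables** — each target draws one gene-level log2FC effect
  ~ N(4, 0.5) (upregulated only by default, mirroring the exclusively
  activating program; a mixed mode exists for the repressor branch),
  re-noised per comparison with sd 0.5; z = log2FC/0.5 gives two-sided
  p-values that are exactly Uniform(0,1) for null genes. P-values are
  generated directly from this z model rather than by simulating counts
  through a DE fitter, because the pipeline consumes DE tables and the
  upstream count model is out of scope. The default effect size is
  deliberately strong (z ≈ 8): it encodes the regime in which the
  direct-target program is unambiguous, as for the strongly induced
  flagship targets of the hypoxia response.
* **Sequences** — i.i.d. uniform A/C/G/T windows of 201 bp; an RCGTG
  instance planted on a random strand with probability 1.0 (functional)
  / 0.05 (decoy).
* **Metabolome** — 558 metabolites × 9 replicates per arm (the study's
  panel size), log-normal abundances, 28% perturbed by 1.0 log2 units —
  the fraction at which the expected raw p < 0.05 count reproduces the
  observed ≈175 of 558.
* **Ortholog panel** — 31 studies × 20 000 genes with 1000 orthologs;
  planted consistent fractions 6.8% / 0.3% (exactly 68 and 57 genes at
  these sizes, making the planted fold 22.67 — the printed 23-fold after
  rounding); 10% of genes are lowly expressed to exercise the
  expression filter.

Every generator is a pure function of (params, seed) through named RNG
substreams, so each module's data is reproducible independently.

**What the synthetic tests do not show.** The generators omit read-level
noise, realistic base composition, peak-width variation, mappability
structure, correlated replicate noise, and any linkage between
metabolite and gene effects. Passing tests therefore demonstrate the
correctness and calibration of the *procedures* under their stated
assumptions, not recovery performance on real sequencing data.

## Problem sizes and numerics

The package's acceptance checks use 10–200 simulation seeds per property
and bootstrap depths of 500–2000 — sizes chosen so each property is
measured with binomial standard errors comfortably inside its decision
band. Degenerate inputs are errors, not silent answers: both-constant
Welch groups, empty KS backgrounds, empty Kruskal–Wallis groups, zero
p-value lists, and anchors longer than every chromosome all raise typed
exceptions. Ties: RP ranks average; peak-assignment ties break
lexicographically; the KS test falls back to the asymptotic p when ties
make exact enumeration invalid. TSV writers use `%.17g` and readers
round-trip float parsing, so write→read→write is bit-stable and a
completed synthetic run replayed in real-input mode reproduces the same
target list.

## Known limitations

* The LOA mechanics are specified here as stratified BH re-adjustment;
  other conditional FDR estimators would satisfy the same verbal
  description and may differ at the margin.
* The regulatory-potential decay normalisation (by the configured
  window) is one of two defensible readings of a 15 kb cutoff applied
  to a distance-decay score; the alternative (a fixed large-scale decay
  truncated at 15 kb) concentrates weight near the TSS.
* The bootstrap null is uniform over the genome: it does not match
  mappability, accessibility or blacklist structure of real data.
* The single-site fraction recovered from calls runs slightly below the
  planted 0.59 because decoy peaks landing inside a target's window add
  apparent sites — a real phenomenon of window-based assignment, not an
  implementation artifact.
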