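# Methods

## Data model

All stages operate on a `BetaMatrix`: a probes × samples table of
methylation fractions β ∈ [0, 1] with NA support, validated at construction
and at every file boundary (TSV/CSV, probes as rows, header = sample IDs;
empty cells, `NA`, `NaN` are missing, anything else non-numeric is a loud
error). Genomic coordinates are 0-based half-open everywhere; manifests from
1-based sources are converted when read.

Replicate probes (same genomic CpG, shared ID prefix) are collapsed by the
mean of non-NA replicate betas. Intensity-based most-robust-replicate
selection is the alternative at the raw-signal level; it is not available
from beta values, so collapsing is mean-only here. The replicate-SD profile
reports, per group, the within-sample sample SD (n−1) averaged over samples,
against a contrast distribution from randomly paired non-replicate probes.

Probe designability QC flags a probe when its 50-mer contains more than six
additional CG dinucleotides (sliding-window count, excluding the assayed
site — neighboring variable CpGs interfere with hybridization), or when a
known SNP lies within 5 nt of the 3′ terminus (offset 1 = terminal base),
which compromises single-base extension. Both reasons can co-occur; the
decision never depends on betas.

## Ternary decomposition

With matched total-modification (5modC, bisulfite) and 5hmC (APOBEC-based)
betas, 5mC = 5modC − 5hmC and C = 1 − 5modC. Independent measurement noise
can drive 5modC − 5hmC negative; such cells are clamped to 0 and flagged in
a mask rather than renormalized, preserving the 5hmC reading as measured and
keeping the violation auditable. On clamped cells, C is set to 1 − 5hmC so
the ternary closure (components sum to 1 within 1e-9, all non-negative)
holds for every non-NA cell — the closure invariant takes precedence over
the literal C = 1 − 5modC formula, which cannot hold simultaneously with it
once 5mC is clamped. NA in either input propagates to all three components.
Summaries: per-group component means, and the mean 5mC/(5mC + C) ratio in
left-closed bins of 5hmC (last bin closed; cells with 5mC + C = 0 excluded).

## Marker discovery

One-vs-rest contrasts use the two-sided Wilcoxon rank-sum test with
midranks: exact null distribution when both groups have ≤ 10 observations
and no ties occur, otherwise the normal approximation with tie and
continuity corrections. AUC = U/(n₁n₂) (probability of superiority;
> 0.5 means the target runs higher), Δβ is the difference of group means.
Selection keeps CpGs with AUC ≥ `min_auc` or ≤ 1 − `min_auc` (distance from
0.5, so hypomethylated markers qualify symmetrically) and |Δβ| ≥
`min_delta`; CpGs with NA in > 10% of the target group or > 50% of the
out-group are dropped first. Under a per-contrast cap, candidates are
ordered by (|AUC − 0.5| desc, |Δβ| desc, probe_id) and hyper/hypo directions
alternate while both lists are non-empty, making capped selection
deterministic and balanced. The same machinery applies to arbitrary numeric
feature tables (e.g. genes × tissues TPM, delta on the table's own scale,
one observation per group allowed), and hierarchically: at each node of a
label hierarchy the contrast is restricted to that node's siblings.

Screens: constitutive (every non-NA β < 0.2, or > 0.8), intermediate
(required fraction of non-NA betas strictly inside (0.3, 0.7); a
design-time variant thresholds an absolute sample count, e.g. 140 of 180),
and variability ranking by sample SD with an optional autosome filter.

The continuity correction makes asymptotic null p-values slightly
conservative in the far tail; calibration tests therefore check type-I
error at several α levels against binomial confidence bounds rather than a
continuous-uniform KS statistic, which flags exactly that deliberate
conservatism on thousands of discrete p-values.

## Deconvolution

A reference panel holds mean betas of the union of marker CpGs per cell
type. Proportions are estimated per sample by robust linear regression of
bulk betas on the panel columns — iteratively reweighted least squares with
Huber weights, tuning constant 1.345 (95% Gaussian efficiency), no
intercept, pairwise-complete NA handling — followed by truncation of
negative coefficients to zero and renormalization to sum 1 (the
robust-partial-correlations contract). Betas live on a common [0, 1] scale
and the reference spans the mixture space, hence no intercept. On exactly
consistent systems the IRLS scale estimate degenerates, so a perfect
ordinary-least-squares fit (relative residual < 1e-9) is used directly.
Non-negative least squares provides the independent cross-check solver;
rank-deficient panels fail loudly naming the collinear cell types.

## Imputation

For each query site absent from the condensed platform, the nearest
retained site by Euclidean distance across the reference-sample vectors is
recorded (per-probe mean imputation completes NA cells first — the NA
policy changes neighbors, so it is fixed and documented), with ties broken
by higher Pearson r, then probe ID. The search is exhaustive over retained
sites, which is exactly equivalent to (and replaces) a k-NN graph query
followed by a lowest-distance pick; exhaustive search at these scales is
cheap and removes an approximation layer. A neighbor substitutes for a
missing legacy probe only when its cross-sample Pearson r exceeds 0.5
(strict). Pass-through applies when the wanted probe is literally present;
unmappable probes surface as NA with a tally. Final distances are
recomputed directly per chosen pair because the expanded-norm identity
loses ~1e-8 to cancellation on exact copies.

## Enrichment statistics

Probe-set enrichment is the one-sided hypergeometric upper tail on the
2×2 overlap table against a stated universe (all array probes by default),
with Benjamini–Hochberg correction within each annotation family. The odds
ratio uses a 0.5 continuity correction only when a zero cell occurs; fully
degenerate margins (annotation or query covering all or none of the
universe) report OR = 1 by convention since no association is estimable.
Interval colocalization expands both sides symmetrically (default ±5000 bp,
starts clamped at 0) and counts any shared base under half-open semantics.

Ranked set enrichment uses the unweighted Kolmogorov–Smirnov running sum
(+1/|Q| at hits, −1/(N−|Q|) at misses; ES = signed maximum deviation) with
a membership-permutation null and p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1),
which is super-uniform by construction. The weight-0 statistic and this
exact null are fixed here for reproducibility among the family of GSEA-like
variants.

Tissue rank context: per trait CpG, samples are ranked by beta (midranks);
per-tissue mean ranks pooled across CpGs form per-tissue distributions,
compared by tie-corrected Kruskal–Wallis with Dunn's rank-sum z post hoc
(BH-adjusted — matching the global FDR convention). CpG–gene links connect
a probe to every gene interval overlapping its ±window expansion
(many-to-many); per-pair Pearson correlations across tissues require ≥ 3
complete points and non-zero variance, else NA.

## EWAS and clocks

The EWAS fits per-CpG ordinary least squares of β on Age + Sex + Tissue
(dummy coding, first level as reference; no interactions), with two-sided
t-tests and BH q-values per coefficient family. Probes are grouped by NA
pattern so each distinct design solve is vectorized. CpGs with fewer than
rank + 2 usable samples return NA rows. Zero residual variance is split: a
perfect fit with non-zero coefficient is infinitely significant (p = 0),
while a constant row (0/0) carries no inference (p = NA). Collinear designs
fail naming the aliased columns.

Clocks are trained by leave-one-out cross-validation with feature selection
strictly inside each fold: an EWAS on the n−1 training samples picks the
`n_features` (default 50) CpGs with the smallest age p-values (ties by
probe ID), and an elastic net (mixing parameter 0.5; penalty by 10-fold
inner cross-validation minimizing squared error, minimum-mean-error choice;
predictors standardized internally, coefficients reported back on the beta
scale) predicts the held-out age from CpG betas alone — sex and tissue act
only in selection. Inner-fold RNG is seeded per held-out sample ID and the
training samples are put in canonical (sorted) order, so results are
invariant to cohort ordering and bit-reproducible per seed. Selecting
features outside the folds leaks the held-out sample into selection and
produces optimistic errors; the test suite demonstrates this with a
deliberately leaky variant on null data. The final model is retrained on
all samples by the same recipe and serializes as a weights CSV plus a YAML
header (intercept, training means, metadata); response transforms are
treated as opaque user-supplied invertible functions.

The sex score is mean β over male-hyper CpGs minus mean β over male-hypo
CpGs; predicted male iff score > 0 strictly (a score exactly at the
threshold is called female, documented as the tie rule).

## Synthetic data

The generator produces the statistical structure the stages assume, with
complete ground truth. Background probes sit at a bimodal baseline (modes
0.1/0.9, probe-level logit jitter shared across cell types, so non-markers
carry no contrast). Each cell type gets planted hyper/hypo markers at an
exact one-vs-rest Δβ (default 0.4 — comfortably above the 0.2 selection
threshold, as sorted-cell references show). Noise is Gaussian on the logit
scale, β′ = logistic(logit(β) + ε) (default sd 0.5), which preserves [0, 1]
without clamping and mimics the heteroskedastic error of array betas;
values at 0/1 are nudged by 1e-6 first. Missingness is injected completely
at random (default 1%).

Cohorts add: linear age effects (slopes 0.003–0.005 β/yr on ~2% of
low-background CpGs — the magnitude at which ~50 years of age span moves a
beta by ~0.2), sex effects (±0.5 β at 20 CpGs, split hyper/hypo so the
difference score separates at zero), imprinted-like loci fixed at 0.5 in
all samples (~1% of probes), and a 5hmC layer defined as a per-probe
fraction of total modification — high (0.25) on methylated background, low
(0.02) elsewhere, scaled per sample by a "proliferation" scalar in
[0.3, 1]. The bound 0 ≤ 5hmC ≤ 5modC therefore holds exactly before noise;
the two matrices are then noised independently, deliberately allowing
violations that exercise the ternary clamping path. Mixtures are convex
combinations of archetypes with Dirichlet(α = 1) proportions by default.
Two-platform splits generate each query site as a noisy copy of a random
retained site with noise calibrated to a target cross-sample correlation
(exact copy at ρ = 1, independent redraw at ρ = 0). Annotation sets plant
one probe set at a chosen odds ratio against a designated query via
inside/outside membership odds; other sets sit at OR = 1.

What the generator does **not** emulate: probe-level technical structure
(type I/II chemistry, dye bias, batch effects), spatial correlation along
the genome, realistic age/tissue interaction, non-linear age trajectories,
cell-composition confounding of the EWAS, or 5hmC's genic enrichment
beyond the binary high/low grouping. Passing recovery tests therefore show
the estimators are correct under their stated model, not that real-array
noise is fully captured.

## Problem sizes and numerics

Default verification scales: 5,000 × 40 cohort for closure; all group sizes
n₁, n₂ ≤ 6 against exact enumeration; 3,000 probes / 5 types / 10
samples-per-type for marker recovery; 200 markers / 50 bulks for
deconvolution; 2,000 query sites for the neighbor map; every universe size
up to 200 for the hypergeometric oracle; 1,000 null queries for set-
enrichment calibration; 2,000 null CpGs and 500 slope replicates for EWAS
calibration; n = 40 / 500 probes (100 informative) for the clock; 200
samples for sex scoring. These sizes make each property measurable with
tight Monte-Carlo error while keeping a full run in minutes on one CPU.

Fixed numerical choices: exact-vs-asymptotic Wilcoxon switch at group size
10 with no ties; Huber constant 1.345 with IRLS tolerance 1e-6 and the
consistent-system OLS shortcut; strict r > 0.5 imputation gate with
(distance, −r, probe_id) tie order; BH everywhere a family of tests is
corrected; elastic-net path of 60 penalties with 10 inner folds; seeds
propagate from a single integer through labelled crc32-derived sub-seeds
(< 2³¹), so every stage is independently reproducible.
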