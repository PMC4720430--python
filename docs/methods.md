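# Methods

This note documents the models behind `confounderscan`, the choices made
where the published workflow left details open, what the synthetic
generator does and does not emulate, and the problem sizes used by the
validation suite.

## Design and data model

The design is the wild-type arm of a repeated-biopsy experiment: four
groups of mice — (early series, high dose, treated), (early, untreated),
(late, low dose, treated), (late, untreated) — with 6 biopsies per early
mouse at recovery times {0,1,2,3,4,5} h and 5 per late mouse at
{0,7.5,9,10.5,12} h. With the default 16 mice this gives 88 samples. The
expression substrate is an already-normalized log2 matrix (genes ×
samples); raw two-channel normalization is upstream of this package.

Biopsy order: early t0..t5 → b1..b6. The late sequence is assumed to
restart at 7.5 h (the animal has recovered from its t0 biopsy by then), so
both t0 and t7.5 carry order b1, then t9 → b2, t10.5 → b3, t12 → b4. The
five-times/four-labels ambiguity admits a second reading — drop the late
t0 samples — available as `late_b1_includes_t0=False`.

## Synthetic generator

Per sample *s* of individual *i* at recovery time *t* with biopsy order
*b* (0-based step), gene values are:

| class       | model                                                          |
|-------------|----------------------------------------------------------------|
| null        | μ_g + ε                                                        |
| composition | log2( Σ_c f_{c,s} · 2^{a_{g,c}} ) + ε                          |
| circadian   | μ_g + A sin(2π (t + t₀ + φ_i) / 24) + ε                        |
| handling    | μ_g + slope · b + ε                                            |
| individual  | μ_g + m_{g,i} + ε,  m ~ N(0, σ_m²)                             |
| treatment   | μ_g + m_{g,i} + δ·1[treated, t>0] + ε                          |

with ε ~ N(0, σ_e²) i.i.d. Mixing of cell populations happens on the
intensity scale (2^x) and is logged afterwards — RNA mass is additive,
log2 expression is not. Cell fractions f are Dirichlet draws
(concentration 3) around a per-mouse mean composition, itself Dirichlet
(concentration 6); the result is substantial biopsy-to-biopsy
fluctuation around a mouse-specific composition, keeping most mice off
the saturating extremes of the log-mixture response — this reproduces
the observed phenomenon that marker-gene profiles are nearly identical
within a mouse and unrelated between mice. Recovery time is fed directly
into the circadian phase (all series start at the same clock hour, at the
rising zero-crossing of the oscillation), deliberately reproducing the
recovery-time ≈ time-of-day confounding of the original design.

Defaults (log2 units): baseline μ_g ~ N(8, 1.5²); σ_e = 0.2; circadian
amplitude A = 1.5 with per-mouse phase SD 0.5 h (entrained animals);
handling slope 0.4 per biopsy step; σ_m = 0.8; marker spread ±2 (16-fold
between own and other cell types); treatment shift δ = 1 at all
post-exposure times (restrictable to chosen times). Effect sizes are
chosen to sit clearly above, but within reach of, the workflow's
published selection thresholds (fold change 2, coefficient 0.5).

Treatment genes carry an individual intercept by default
(`sigma_m_treatment`, defaulting to σ_m): genes that truly respond to an
exposure still differ between animals, and this is precisely what makes
the individual random term matter in DEG scans. The circadian and
handling classes are pure mechanisms by default; optional overlays
(`sigma_m_circadian`, `sigma_m_handling`) add per-mouse intercepts for
scenarios that need individual effects on contrast-responsive genes —
real time-of-day gene groups show exactly such offsets.

Null genes carry no individual term. Planting σ_m-sized intercepts on
null genes would make them indistinguishable from the individual class
and would contradict the individual-effect selection rule's false-positive
expectation, so "null" means measurement noise only.

Reproducibility: every gene draws from a seed-sequence substream keyed by
the gene index, and sample-level structure (phases, compositions,
fractions) from substreams keyed by individual/sample index. Changing one
class count never reshuffles another gene's noise; the same seed gives
bit-identical matrices.

## Clustering and PCA

Gene profiles are centered and scaled to unit SD before clustering — the
workflow compares profile *shapes*. Distances are Euclidean; Ward linkage
heights are reported as the increase in within-cluster sum of squares
(ΔSSE; the backend's √(2·ΔSSE) convention is converted). Leaf order puts,
at every internal node, the child with the smaller mean (unscaled)
expression first; ties everywhere break by gene-ID lexicographic order,
making the dendrogram bit-reproducible. Seeded extraction returns the
lowest node containing all seed genes (a single seed returns its first
merge partner set), flagged oversize beyond `max_size` rather than
truncated. Marker panels of ~5 genes per suspected cell type are
recommended: a 2-gene panel can share a deep ancestor and truncate the
cluster.

PCA treats genes as observations and samples as variables (columns
centered over the gene subset). Component signs are fixed by forcing each
component's largest-magnitude loading positive; subsets are defined by
explicit score-threshold rules rather than manual gating of the score
plot.

## SOM and coherence

The per-mouse 2×2 self-organizing map uses the batch Kohonen algorithm:
codebook initialized from the first two principal components of the scaled
profiles, Gaussian neighborhood with radius decaying linearly 1 → 0 over
20 epochs (the final epochs are batch k-means), constant profiles excluded
with a count. None of these hyperparameters is stated in the original
workflow; they are declared here for determinism.

Coherence quantifies the map's visual argument: within-mouse coherence is
the mean pairwise Pearson correlation of member-gene profiles per mouse;
between-mouse coherence is the mean pairwise correlation of per-mouse mean
scaled profiles, computed only across mice sharing a sampling grid (early
and late series are never mixed). The composition signature is
within ≥ 0.8 and between ≤ 0.3 (both configurable). The pipeline judges
coherence over the full design rather than only untreated mice:
composition variation is treatment-independent, and 16 mice give a
between-mouse estimate stable enough for the 0.3 cut (with 8 mice the
estimate's sampling noise alone produces occasional false negatives).

## Mixed model

Per gene: y = Xβ + Zu + e, with a single random intercept per mouse,
u ~ N(0, σ_u² I), e ~ N(0, σ_e² I). Fixed effects are either the biopsy
levels or a group-means parameterization of the series × treatment × time
cells. Estimation is REML, profiled over θ = σ_u²/σ_e²: for one random
intercept, V⁻¹ reduces to per-block corrections (Sherman–Morrison), so
each evaluation costs O(n·p²). θ is found by a coarse log grid plus
golden-section refinement (tolerance 1e-11), truncated at 0; balanced
one-way layouts use the exact ANOVA/REML closed form. Near the optimum the
REML objective is flat to double precision, which bounds any iterative
optimizer at ~1e-7 relative accuracy in θ — the closed-form branch is
exact. Predicted individual effects are BLUPs, û_i = c_i (t_i − s_iᵀβ̂)
with c_i = θ/(1+n_iθ); on balanced designs they sum to zero, making the
|coefficient| > 0.5 selection rule scale-comparable across genes. The fit
was validated against lme4 (REML fixed effects, variance components and
BLUPs to ~1e-7 on a frozen fixture).

## Permutation Fs test

Fs_g = (contrast mean square)_g / σ̃²_g. The shrunken variance σ̃² comes
from James–Stein shrinkage of log residual variances toward their
across-gene mean: X_g = ln σ̂²_g is de-biased by the χ² log-variance bias
(digamma(d/2) − ln(d/2)), shrunk with positive-part factor
1 − (G−3)·trigamma(d/2)/Σ(X−X̄)², and re-biased — so the constant cancels
and equal-variance inputs are returned unchanged.

The individual term enters the test in one of two ways:

* **within-individual contrasts** (biopsy levels, time-vs-t0 within an
  arm): per-mouse means are projected out exactly (the θ → ∞ limit of the
  random intercept). This makes the statistic exactly invariant to adding
  any constant per mouse, and is cheaper than REML.
* **between-individual contrasts** (treated vs time-matched untreated):
  between-mouse information is required, so the REML random intercept is
  used, with per-gene θ estimated once on the observed data and held fixed
  across permutations — a permutation null does not need re-estimated
  variance ratios, and refitting REML G × n_perm times would be wasted
  computation.

Null distribution: condition labels are permuted within each mouse
(preserving the repeated-measures blocking); factors constant within a
mouse (the arm) are permuted across mice within a series. Permuted Fs
values are pooled across genes (per-gene nulls are available via
`pool=False`), and p_g = (1 + #{pooled Fs ≥ Fs_g}) / (1 + G·n_perm).
Individuals lacking a contrast level are dropped with a warning; if that
would drop everyone the contrast is between-individual and all samples are
kept.

## q-values

π̂₀(λ) = #{p > λ}/(m(1−λ)) on λ ∈ {0, 0.05, …, 0.90}; a cubic
least-squares smooth is evaluated at the largest λ and clipped to
(1/m, 1]. q-values are the step-up monotonized π̂₀·m·p_(j)/j. Forcing
π₀ = 1 reproduces Benjamini–Hochberg exactly (a frozen test asserts the
printed 4-value example). DEG cut: q ≤ 0.05.

## ANOVA decomposition

Y = μ + (individual effect) + (dose×time effect) + residual, fitted by
backfitting with both effect blocks re-centered to sum-to-zero every
sweep (tolerance 1e-12). The residual is defined as Y minus the assembled
components, so the decomposition reproduces Y exactly by construction.
Because individuals are nested in arms, arm-level means are aliased
between the two blocks; the zero-mean convention picks one member of the
aliased family deterministically. On designs where individuals are fully
crossed with the cells the decomposition is unique and recovers planted
structure exactly.

## Overlap, enrichment, recovery

Overlap cells are 100·|DEG ∩ set|/|DEG| (exact fractions kept internally,
display rounded half-up; empty DEG rows render as "-"). The "All" column
uses the union of the confounder sets. Enrichment is the upper-tail
hypergeometric probability P(X ≥ k) against the whole expression matrix
as background, computed with the standard numerically stable survival
function and cross-checked against exhaustive draw enumeration. Raw
per-cell probabilities are reported with α = 0.05; no across-cell
correction is applied, matching the original table convention. Recovery
metrics are per-class precision/recall/F1 of called sets against the
generator's truth; an empty call reports recall 0 and missing precision.

## Pipeline order

Variance screen → seeded clusters + coherence (SC) → FC screen + variance
tail (TD) → relabel + biopsy Fs tests + SD filter (HS) → individual
coefficients (IM, excluding SC/TD/HS) → DEG scans → overlap/enrichment.
The order is forced by IM's definition (it may not overlap any earlier
set).

Two thresholds are data-dependent by nature and deserve emphasis. The
published handling-stress SD cut (0.32) and variance-tail sizes (277/93)
were calibrated on the original array data; they remain the config
defaults, but on synthetic data the SD cut must clear the planted
handling genes themselves: a slope-0.4 gene spans 0–2 log2 units over the
b1..b6/b1..b4 grids, giving SD ≈ 0.68 over the untreated samples, so the
synthetic scenarios use 0.8 (above the handling class, below the
composition class at ≳1). This value follows analytically from the
generator parameters, not from fitting. The tail size is a quantile
(default 0.8 of the candidates) with absolute-k overrides.

## Validation scenarios and problem sizes

The acceptance suite (tests/test_acceptance.py, scripts/acceptance.py)
simulates the 16-mouse design throughout, at desk-scale sizes chosen so
the whole run takes on the order of a minute on one CPU:

* null calibration: 2,000 null genes, 300 permutations, b1-vs-b2;
* q-value checks: the 4-value BH example and 10,000 uniform p-values;
* hypergeometric: all (N ≤ 12, K, n, k) cases by draw enumeration plus
  the N=20 closed-form example;
* REML recovery: 500 genes, 16 mice × 6 replicates, σ_u² = 0.25,
  σ_e² = 0.04 (median within 20%; closed-form agreement to 1e-8);
* composition: 6,000 genes, 150 planted markers in 2 cell types, top-5,000
  screen, 5-gene seed panels;
* circadian: 2,000 genes, 50 planted (A = 1.5);
* handling: 2,000 genes, 60 planted (slope 0.4), 300 permutations;
* individual: 2,000 genes, 100 planted (σ_m = 0.8), full scan with
  SC/TD/HS exclusion;
* model comparison: 600 genes with circadian/handling/individual/treatment
  plants (overlays on), all 18 within-arm contrasts, both models;
* determinism: every stochastic stage run twice at a fixed seed.

## What passing tests do and do not show

The generator produces Gaussian noise, a single compound-symmetric
individual effect, sinusoidal circadian signal with intercept-only
between-mouse variation, and linear handling trends. Real data add
heavy-tailed noise, probe-level artifacts, correlated gene modules beyond
the planted classes, amplitude (not just phase) circadian variation,
nonlinear stress kinetics, and composition changes entangled with
treatment. Recovery rates measured here therefore demonstrate that the
implementation performs its stated computations correctly and that the
selection rules work under their own assumptions — not that the published
thresholds are optimal, or that recovery on real biopsy data will be as
clean. The permutation test's calibration, the q-value and hypergeometric
oracles, and the REML closed-form agreements are assumption-light and
transfer directly.

## Known limitations

* Only a single random intercept is modeled; no random slopes, no
  gene–gene covariance, no empirical-Bayes moderated-t alternative.
* The SOM is fixed at 2×2; larger grids are out of scope.
* The late-series relabeling keeps both t0 and t7.5 at b1; whether the
  original analysis did the same cannot be confirmed from its text, and
  the alternative is provided behind a switch.
* The strict ">" reading of the 0.5 individual-coefficient rule is used
  (the source states both ">" and "≥" in different places); "≥" is a flag.
* Between-arm permutations exchange whole mice within a series, which
  assumes exchangeability of animals across arms under the null.
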