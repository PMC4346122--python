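# Methods

## The problem

Corticobasal syndrome (CBS) has heterogeneous underlying pathology:
frontotemporal lobar degeneration (FTLD) spectrum pathologies in the
majority, Alzheimer's disease (AD) in roughly a quarter of patients.
Amyloid PET (Pittsburgh compound B, PIB) serves as the in-vivo reference
standard for AD pathology. The package operationalizes and evaluates
predictors of PIB status that are available without amyloid imaging:
rule-based clinical variants, visual imaging reads (treated as input label
columns), and quantitative FDG-PET measures.

## Clinical variant engine

Core screening requires a progressive course, at least three of five core
features (parkinsonism, dystonia, myoclonus, impaired voluntary limb
control, cortical sensory deficit) and the absence of all six exclusion
features (visual hallucinations, RBD, cerebellar ataxia, prominent
autonomic dysfunction, fluctuating alertness, prominent rest tremor). Each
variant is met when at least one of its features is present: four frontal
(fv) features and three temporoparietal (tpv) features, of which the two
relative cognitive-profile indicators (executive-predominant vs
memory/visuospatial-predominant) are mutually exclusive by construction
and enforced at load time — conflicting input is a hard error, never a
silent repair. No neuropsychological thresholds are applied; the relative
impairment indicators are inputs.

Patients meeting both variants are adjudicated deterministically — where a
human rater would have used overall clinical impression, this engine uses
an explicit precedence so every call is reproducible and traceable:

1. **cognitive dominance** — if exactly one of the two cognitive-profile
   indicators is set, its variant wins. The cognitive profile is the
   dominant tie-breaker because it is the one feature class with
   individually predictive value for amyloid status (executive-predominant
   toward fv/amyloid-negative, memory/visuospatial-predominant toward
   tpv/amyloid-positive).
2. **count majority** — otherwise the variant with more met features wins.
3. **frontal default** — a residual tie defaults to fv, since non-AD
   pathology is the prior majority in CBS (~75%).

Confidence maps from the adjudication path onto the 1 (confident fv) … 5
(confident tpv) scale: an unopposed variant gives 1/5, a tie resolved by
either rule gives 2/4, the residual default gives 3. This is a stated
replacement for unblindable human impression, not a reconstruction of any
particular rater's behavior, and published per-rater splits are therefore
not reproduction targets.

Properties verified exhaustively over all admissible variant-feature
vectors: determinism, totality (every core-eligible patient with ≥ 1
variant feature receives a call), monotonicity (adding a concordant
feature never flips a label), and the dominance of the cognitive
tie-breaker.

## Quantitative FDG-PET

Regional uptake enters as mean activity per ROI (frontal, temporoparietal,
and the peri-rolandic "common" region shared across variants; left and
right separately) and is normalized to mean pons activity to give SUVR.
Z-scores are computed against a normal-control cohort per ROI and side
(sample SD, ddof = 1, so the control cohort Z-scored against itself has
mean 0 and SD 1 exactly); hypometabolism is negative and "lowest Z" means
most negative. Classification uses bilateral (hemisphere-averaged)
composites of the frontal and temporoparietal ROIs only: tpv iff
Z_temporoparietal < Z_frontal. The "common" ROI is profiled but excluded
from the decision, being by definition non-discriminating. An exact Z tie
resolves to fv, consistent with the clinical engine's default; ties have
measure zero on real data. Classification is invariant to any common
positive rescaling of raw uptakes (SUVR units cancel).

The Z-difference Z_frontal − Z_temporoparietal is reported per patient
(positive = temporoparietal-predominant hypometabolism). Hemispheric
asymmetry is the lateralization index LI = |R/L − 1| × 100 per ROI. The
formula is left-anchored: LI(R, L) ≠ LI(L, R) in general (1.1/1.0 → 10.0
but 1.0/1.1 → 9.09), a property the tests assert rather than hide. The
symmetric alternative |max/min − 1| was not adopted because published
group LI values cannot adjudicate the parenthesization without
patient-level data; the absolute value is required since a signed R/L − 1
would be negative for left-lateralized patients, incompatible with
strictly positive group LI summaries.

SUVR, Z and DVR are carried at full floating precision; rounding (Z and LI
to 2 decimals, sensitivity/specificity to whole percents half-up, accuracy
and kappa to 2 decimals) happens only at report time.

## Logan graphical DVR

For a reversible tracer with a reference-tissue input function, the plot
of y(T) = ∫₀ᵀC_target dt / C_target(T) against
x(T) = ∫₀ᵀC_ref dt / C_target(T) becomes linear after an equilibration
time t\*, with slope equal to the distribution volume ratio (DVR).
Implementation choices: cumulative trapezoidal integration anchored at an
implicit (0, 0) point; ordinary least squares over frames with mid-time
≥ t\*; t\* defaults to 35 min (CLI-overridable) — the pure reference-ratio
form without a k2′ perfusion correction term. Because none of t\*, the
integration rule, or a k2′ term is pinned by any published protocol the
package targets, DVR validation is property-based (recovery on simulated
kinetics), not value reproduction. Guards: ≥ 3 fit frames, shared frame
grids, strictly positive target activity in the window. Amyloid
positivity from a global DVR uses the inclusive threshold DVR ≥ 1.20.

## Diagnostic performance

Per-modality 2×2 tables take a tpv call (or marker presence) as the
positive prediction and PIB+ as the positive reference. Sensitivity,
specificity, PPV, NPV and accuracy are observed proportions with
Clopper–Pearson exact 95% CIs — chosen over Wald for validity at
denominators of order 10–25 (Wald is available behind a flag). A statistic
with an empty denominator is undefined (NaN + flag), never 0. Odds ratios
use the cross-product with a Woolf log-normal CI; the Haldane–Anscombe
+0.5 correction is applied to all cells iff any cell is zero. The
two-sided Fisher exact p follows the probability-mass convention (sum of
hypergeometric probabilities of tables no more probable than the observed
one) — stated explicitly because several two-sided conventions exist;
it matches naive exact-rational enumeration to < 1e-12 for all tables with
total ≤ 30. Pearson chi-square is computed without continuity correction
and is undefined on zero margins. Cohen's kappa exposes the observed and
chance-agreement components; pe = 1 with imperfect agreement is
unreachable for product marginals (Cauchy–Schwarz), so kappa is 1 on
identical constant ratings and finite everywhere else. Patients missing a
modality are excluded pairwise for that modality, with a logged count —
never imputed. The report writer can emit the contributing patient ids per
cell (audit mode), so every number is traceable.

Predictor combination uses conjunction (positive iff both inputs positive),
which can only reduce the positive count; combined odds ratios are
produced but not pinned to any published value, the underlying combined
tables never having been printed.

## Synthetic cohorts

The generator's defaults are the study conditions the analysis assumes:
11 amyloid-positive patients, 14 amyloid-negative, 26 controls, and
group-level ROI Z means/SDs taken from published FDG ROI comparisons
(PIB+: frontal −1.26 ± 0.91, temporoparietal −2.76 ± 1.65, common
−1.89 ± 0.81; PIB−: frontal −1.06 ± 1.61, temporoparietal −0.93 ± 1.65,
common −1.69 ± 1.37; controls 0 ± 1 by construction). Patient Z-scores are
drawn directly in control-SD units and inverted to uptakes against the
*generated* control reference — matching how the group statistics are
expressed and avoiding any commitment to unobserved raw-SUVR scales — so
re-running the quantification pipeline recovers the drawn Z exactly.
Draws are independent across ROIs (no between-ROI covariance has been
published; a documented limitation). Asymmetry is injected by splitting
each bilateral SUVR into left/right at a half-normal percent magnitude
(means per group/ROI from the published LI summaries) with a random
lateralized side, preserving the bilateral mean exactly. Control SUVR
scale (cortical/pons ≈ 1.4–1.5, SD 0.10) and the raw pons level are
synthetic choices that cancel in SUVR.

Clinical-feature prevalences are explicitly synthetic (no per-criterion
rates have been published): the memory/visuospatial-predominant profile is
enriched in the amyloid-positive group and the executive-predominant
profile in the amyloid-negative group, so the criteria engine's
discrimination is exercised. The two cognitive indicators come from a
single three-way categorical (enforcing exclusivity); vectors meeting
neither variant are rejection-sampled away, matching a cohort in which
every patient met one variant; every patient is core-eligible by
construction. Exclusion features are absent.

Because ROI draws are independent, the quantitative classifier's expected
sensitivity has the closed form Φ((μ_f − μ_tp)/√(σ_f² + σ_tp²)) =
Φ(1.50/1.884) ≈ 0.787 under the default PIB+ parameters, which the
end-to-end acceptance test verifies at n = 500/500 within 3 Monte-Carlo
standard errors. What passing these tests does *not* show: real FDG data
have spatially correlated, non-Gaussian ROI profiles, correlated
clinical–imaging features, and rater noise in the input label columns —
none of which the generator emulates.

Time–activity curves come from a one-tissue compartment model
dC_t/dt = K₁C_ref − k₂C_t driven by a bi-exponential reference curve and
solved in closed form, giving an exactly linear Logan plot with slope
K₁/k₂ = DVR and intercept −1/k₂ — an analytic ground truth with no ODE
solver error. Frame boundaries are quadratically spaced (short early
frames while the input function changes fast), after which noise-free
trapezoidal recovery error is below 0.1% at 30 frames / 90 min. Additive
Gaussian noise is optional; at the 2%-of-late-frame-activity level used
in the tests the estimator is unbiased within Monte-Carlo error over 100
seeds (larger noise would induce the well-known negative Logan bias from
noise in the denominator).

## Reference fixtures

Group-level results that the validation suite reproduces exactly — the
per-modality contingency counts against PIB status in a 25-patient cohort,
APOE-ε4 carrier counts (6/10 vs 1/10), and the eight-patient pathology
subset — ship as counts in `cbsamyloid.datasets`. Per-patient call vectors
are reconstructed deterministically from the counts; within each amyloid
stratum the assignment is exchangeable, so every downstream statistic is
invariant to which reconstruction is chosen. One published inconsistency
is reproduced as-counted rather than as-quoted: the quantitative-FDG
column's counts give 9/10 = 90% sensitivity although the prose rounds it
with the visual read to "91%"; the package reports 90.

## Problem sizes and runtime choices

Exhaustive checks run over all 96 admissible variant-feature vectors and
all 46,375 2×2 tables with total ≤ 30; coverage sweeps use 2,000
replicates per (n, p) cell; end-to-end simulation uses 500 patients per
group with 26 controls; kinetic validation uses 30-frame, 90-minute
curves and 100 noise seeds. These sizes make every Monte-Carlo tolerance
(3 SEs) small relative to the effects checked while keeping the full
suite fast to run routinely.

## Known limitations

* The adjudication rule is a principled replacement for human impression;
  published per-patient variant resolutions cannot be reconstructed.
* No between-ROI covariance, spatial noise, or visual-rating simulation.
* Logan estimation omits k2′ correction; at high noise the slope estimator
  is biased low, as for all Logan-type methods.
* MRI and visual FDG/PIB reads are input label columns, never computed.
* Voxel-level processing (image registration, atlas extraction, voxel-wise
  statistics) is out of scope; ROI means are inputs.
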