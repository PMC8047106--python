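# Methods and design notes

## Model

Two-sample MR treats each genetic variant *j* as an instrument for the
exposure. With exposure association γ̂_j ~ N(γ_j, σ²_xj) and outcome
association Γ̂_j ~ N(βγ_j + α_j, σ²_yj) estimated in non-overlapping
samples, β is the causal log-odds effect per SD of exposure and α_j is the
variant's direct (pleiotropic) effect on the outcome. Valid instruments
have α_j = 0; the estimators differ in what they assume about the α_j:

| estimator | assumption on α_j |
|---|---|
| IVW (fixed/random) | all zero (random effects absorb balanced spread) |
| maximum likelihood | all zero; models error on both sides |
| MR-Egger | common mean α, independent of instrument strength (InSIDE) |
| simple/weighted median | under half the instruments (weight) invalid |
| simple/weighted mode | the largest ratio cluster is valid (ZEMPA) |

All pooled estimates are reported on the log-odds scale with normal or
t-based CIs and converted to odds ratios with the fixed 97.5% quantile
1.959964 at the default 95% level.

## Numerical choices

* **Wald ratio SE** uses the first-order delta method, σ_yj/|γ̂_j|,
  ignoring exposure-side error. This keeps IVW exactly equal to the
  weighted-least-squares-through-origin solve with weights 1/σ²_yj, which
  the tests exploit as an independent oracle. The exposure-side error is
  instead handled explicitly by the maximum-likelihood estimator.
* **Random-effects IVW** is multiplicative: SE_random = SE_fixed ·
  max(1, √(Q/(J−1))). Truncation at 1 (no "benefit" from under-dispersion)
  follows the dominant implementation convention; it is configurable
  (`truncate_underdispersion=False`). Consequence: under a homogeneous
  null the truncated interval is mildly conservative (empirical type-I
  error ≈ 0.038 at the 0.05 level, coverage ≈ 0.96–0.97), while the
  fixed-effects interval is exactly calibrated. Calibration checks in the
  acceptance suite therefore use the fixed-effects variant, which is the
  correctly specified model in the homogeneous no-pleiotropy regime;
  both variants share one point estimate, so bias statements are
  unaffected.
* **MR-Egger** orients instruments to positive exposure effects, fits a
  weighted line (weights 1/σ²_yj) via `statsmodels` WLS, scales both SEs
  by max(1, residual scale) and uses t(J−2) p-values. With the default
  truncation a perfectly fitting line keeps the weight-implied SE floor;
  the untruncated option lets an exact fit drive the intercept p to 0.
* **Maximum likelihood** profiles out the per-variant true exposure
  effects analytically, leaving the 1-d objective
  Σ(Γ̂_j − βγ̂_j)²/(σ²_yj + β²σ²_xj), minimized by Nelder-Mead from the
  fixed-effects IVW start; the SE comes from the numerical curvature of
  the profile (observed information). Non-convergence raises with the
  optimizer trace attached.
* **Median**: ratios sorted ascending; cumulative weight
  s_j = (Σ_{i≤j}w_i − w_j/2)/Σw; linear interpolation at s = 0.5
  (`np.interp`, which clamps at the extremes for J = 2 edge cases).
* **Mode**: normal-kernel density with bandwidth
  h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5) evaluated on a 512-point grid
  spanning the ratio range extended by 3h per side. When the MAD is zero
  but the SD is not (a clustered majority plus outliers), the bandwidth
  falls back to the SD term rather than collapsing to zero; identical
  ratios return the common value directly. A refinement test checks the
  grid argmax against a 10× finer grid.
* **Bootstrap SEs** (median, mode): parametric — both effect sides are
  resampled from normals at their reported SEs, the point estimate
  recomputed, and the SD over 1,000 (default) replicates taken. A seed is
  required in the CLI whenever bootstrap methods run.
* **Cochran's Q** always uses fixed-effects weights about the
  fixed-effects estimate, making the link to the random-effects
  dispersion exact (φ̂² = Q/(J−1)); the Egger variant uses residuals about
  the fitted line with J−2 df.
* **LD pruning** is greedy by ascending p-value (clumping convention),
  ties broken by input order; pairs absent from the LD table are assumed
  independent and the assumption is logged. The source analysis named
  only the threshold and the excluded variants, not the ranking rule.
* **Palindromic variants** (A/T, C/G) are kept only when both
  effect-allele frequencies are known, both fall outside 0.5 ± 0.08
  (configurable) and lie on the same side of 0.5; otherwise dropped as
  ambiguous. Strand complementing is attempted only for non-palindromic
  variants. The original analysis did not state its palindrome policy;
  dropping ambiguous variants is the cautious default.
* **Leave-one-out influence**: a variant is flagged when its exclusion
  moves the pooled estimate by more than one pooled SE or flips
  significance at the configured α. The criterion used by the motivating
  analysis was unstated; this flag is a documented stand-in, not a claim
  of equivalence.
* **Pleiotropy screen**: default flags instruments whose trait-association
  p < 0.05 (`association_p`); a `wald_p` criterion recomputing per-variant
  ratio p-values is also implemented (the two coincide when trait tables
  carry normal-approximation p-values). No multiplicity correction across
  the 16 screened traits by default, matching common practice; a
  Bonferroni flag is available. "Influencer" status is purely a
  significance-status comparison between the full-set and retained-set
  runs at the configured α.

## Synthetic study conditions

The generator's defaults mirror the motivating homocysteine panel: J = 13
instruments, total exposure R² = 0.059, exposure n = 44,147 (continuous,
SD units), outcome n = 440,328 with case fraction 0.0122 (binary,
log-odds), causal effect β = 0.3. Per-variant SEs use the standard GWAS
approximations σ_x = 1/√(2p(1−p)n) and σ_y = 1/√(2p(1−p)·n·v(1−v)), which
puts outcome SEs on the ~0.02 scale of the bundled tables and the
instrument F at ≈ 213. Effect-allele frequencies are uniform on
(0.1, 0.9); true effects are uniform draws rescaled so the variance
explained hits the target exactly. Direct effects α_j are
N(μ_α, σ_α²) with optional correlation to γ_j (a nonzero value violates
InSIDE). A quarter of outcome rows are emitted with swapped allele labels
by default so harmonization is always exercised; palindromic emission is
off by default to keep the harmonized instrument count fixed.

For robustness scenarios, `simulate_invalid_subset` plants a constant
direct effect in a fixed-size subset drawn uniformly among subsets
carrying under half the total instrument weight — the regime in which the
weighted median's validity condition holds. Arbitrary subsets of a
13-variant panel exceed half the weight in roughly 10% of draws, where no
majority-valid estimator can be expected to win. Trait tables for the
screen plant effects of 5×SE (power ≈ 0.999 at α = 0.05) on a chosen
subset and pure noise elsewhere.

What the generator does **not** emulate: LD between instruments (LD enters
only through the user-supplied pairwise table), heavy-tailed effect-size
distributions with a single dominant locus, sample overlap between the two
studies, and winner's-curse bias in instrument selection. Passing tests
therefore demonstrate correctness of the estimators and workflow under
idealized two-sample conditions, not robustness to those real-data
complications.

## Problem sizes

Simulation-based checks use 1,000 replicates for bias/coverage, 5,000 for
type-I error, 2,000 each for the Q null distribution and the
Egger-intercept size, and 500 each for the robustness-ordering and
screening scenarios — sizes at which Monte-Carlo error is small relative
to the asserted bounds while the whole battery runs in under a minute on
one CPU.

## Bundled data and known limitations

The bundled tables transcribe published per-variant odds ratios of the 13
homocysteine instruments against ten outcomes; ORs/CIs are converted to
log-odds on load, "NA" rows (variant absent from an outcome dataset) are
omitted and logged, and proxy variants used for MS/FTD are recorded. Two
caveats are preserved rather than resolved: the source prints two
different 95% CIs for its pooled small-artery-occlusion estimate (the
provenance string flags both), and the TIA rows are published as
1.00 (1.00–1.00) — effects rounded away on that scale — which convert to
beta 0, SE 0; they are retained so record counts match the source, and
estimators reject zero-SE instruments explicitly. The exposure-side
per-variant effects (variant → homocysteine) were published only in a
supplementary file and are not redistributed, so pooled estimates for the
bundled outcomes cannot be recomputed from package data alone; the
bundled tables chiefly exercise I/O, conversion and single-variant
diagnostics, and serve users who supply their own exposure-side table.
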