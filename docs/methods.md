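# Methods

This note documents the models and procedures `nirseed` implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the design choices made where the design was genuinely open.

## Spectral model and preprocessing

Spectra are stored as absorbance-like log(1/R) on a strictly increasing
wavenumber grid (4000–10000 cm⁻¹; the default generator uses the 8 cm⁻¹
spacing typical of FT-NIR instruments). Whether reflectance data have been
converted to log(1/R) is the caller's responsibility; the package assumes
they have.

**MSC.** Each spectrum *s* is regressed on a reference spectrum *m* by
ordinary least squares, s = a + b·m, and corrected to (s − a)/b. The
reference is the pointwise mean of the calibration set and is *stored with
the model*: a prediction-time sample is always corrected against the
calibration mean, never against its own batch, so predictions are a pure
function of (model, spectrum). A fitted slope b ≤ 0 (or |b| below 1e-8)
raises a correction error — such a spectrum is not an affine distortion of
the reference and MSC is meaningless for it.

**Gap-segment first derivative.** Points are first smoothed by a centered
moving average over `segment` points (default 5, must be odd), then
differenced across a gap: D(i) = (ŝ(i+gap) − ŝ(i−gap)) / (2·gap·Δ), with
`gap` = 5 points and Δ the nominal grid spacing. Segment and gap are
counted in points, the common vendor convention. Edge points without full
support are dropped; the output grid records the survivors. The exact
vendor variant of the "Norris filter" is unpublished; this
smooth-then-gap-difference form is the standard published one and is an
approximation to whatever the instrument software does. The operator is
linear and exact on affine spectra.

**Windows.** Closed intervals 4100–4940, 5390–6690, 6900–7130 and
7185–9000 cm⁻¹ by default — the organic-signature regions, excluding water
bands. The pipeline order is fixed: MSC → derivative → windows. MSC first
matches the order in which the pretreatments are conventionally described;
windows last so derivative edge-trimming consumes points outside the
windows, not chemical-band interiors. Both choices are configurable
per-stage via `PreprocessConfig`.

## PLS calibration and factor selection

PLS1 (one response per model; oil, protein, carbon and nitrogen each get
their own model) is implemented as NIPALS with X-deflation: per factor the
weight vector is the normalized covariance direction X'y, scores t = Xw,
loadings p = X't/t't, q = y't/t't, then X ← X − tp'. For a single response
this is fully deterministic — no iteration, no random initialization. The
regression vector is B = W(P'W)⁻¹q. At full rank PLS1 reproduces ordinary
least squares (a test asserts this to 1e-8), and its coefficients match
scikit-learn's `PLSRegression` to machine precision (used as an independent
cross-check only, never as the implementation).

**Leave-one-out PRESS.** For every held-out sample, the MSC reference, the
derivative/window pipeline, and the centering are all refit on the n−1
retained samples before the PLS fit, so cross-validated residuals carry no
leakage from the held-out sample and SECV is honest. PRESS(k) = Σ squared
held-out errors at k factors, k = 1..max_factors (default cap 10).

**Factor count.** The PRESS curve of a well-behaved calibration drops
steeply and then flattens; on the flat tail the curve fluctuates at the
sub-percent level and its literal global minimum is effectively a random
draw among the large-k values — selecting it inflates the factor count
without improving predictions. `select_factors` therefore defaults to the
parsimonious Haaland–Thomas rule: the smallest k whose PRESS is not
significantly above the curve minimum by an F-ratio test
(PRESS(k)/PRESS(k_min) < F₁₋α(n, n), α = 0.25). The literal rule remains
available as `method="global_min"`; exact ties always resolve to the
smaller k.

## Validation statistics

With e the residuals (reference − predicted):

- SEC = √(Σe²/(n−k−1)) on the calibration fit, k = PLS factors;
- SECV = √(Σe²/n) over leave-one-out residuals;
- SEP = √(Σ(e−ē)²/(n−1)) on the external validation set, with the bias ē
  reported separately (bias-corrected convention; `convention="rmsep"`
  switches to √(mean e²) — the two conventions coexist in vendor software
  and the difference matters when predictions are systematically offset);
- r² = squared Pearson correlation between predicted and reference (the
  chemometrics convention; 1 − SSE/SST is available as
  `convention="explained"`). A negative predicted-vs-reference slope is
  flagged in the report since squared correlation alone would hide it;
- RPD = SD of the *calibration-set* reference values divided by SEP. The
  calibration-set SD (not the validation-set SD) is the convention that
  reproduces the published arithmetic this package checks itself against
  (3.88/0.505 = 7.68, 3.39/1.228 = 2.76). Bands: ≥ 2.5 screening, ≥ 5
  quality control, ≥ 8 process control (AACC Method 39-00.01), half-open
  upward.

## Calibration-set design

The historical selection of diverse samples from a PC1/PC3 score plot was a
visual, unrecorded step; as a reproducible surrogate the package uses
greedy max–min selection (Kennard–Stone restricted to the two named axes):
start from the point farthest from the centroid, repeatedly add the point
maximizing its minimum distance to the selected set, ids sorted before
index tie-breaks so the result is input-order invariant. PCA for selection
runs on MSC-corrected, *non*-derivative spectra. A preliminary PLS model
fit on the diverse samples predicts the whole pool, and the ⌈n/2⌉ highest
plus ⌊n/2⌋ lowest predictions (even split assumed; the historical split is
unstated) extend the concentration range. The combined set is rank-split
3:1: sorted ascending by reference value, every 4th rank goes to
validation, except that both endpoints stay in calibration (if the top rank
lands on a validation slot it swaps with its lower neighbour). Consequence,
asserted as an invariant: the validation range is always contained in the
calibration range, so external validation never extrapolates.

## Variance decomposition

`variance_components` fits a two-way crossed fixed-effects ANOVA
(value ~ genotype + culture + genotype:culture) on replicate-level data and
reports each term's **sequential** sum of squares (genotype entered first;
the historical order of terms is unstated) as a percentage of the total SS.
Sequential SS makes the four percentages sum to exactly 100. REML variance
components would be the choice for unbalanced mixed models, but
percent-of-variation-explained from an ANOVA is what the workflow reports,
so that is what is implemented; unbalanced designs run through the same
decomposition with a warning once cell counts are > 10 % imbalanced. The
fit itself is delegated to statsmodels (`anova_lm`, type I), cross-checked
against hand-computed sums of squares on a balanced 2×2×2 fixture.

## RIL genetics and QTL mapping

**Genotype model.** RILs are fully homozygous; genotypes are coded A
(Col-0-like) / B (Ct-1-like), internally 0/1, with missing allowed.
Genotype coding for effects is x ∈ {−1, +1}, so a reported additive effect
is the mean change in the trait from replacing the A allele by the B allele
at the locus.

**Simulation.** Genotypes follow a Markov chain along each chromosome: the
first marker is A/B with probability ½, and the genotype switches between
adjacent markers with probability R = 2r/(1+2r), where
r = (1 − e^(−2d/100))/2 is the Haldane recombination fraction for the cM
interval d — the observed recombinant fraction between selfed-RIL
genotypes (map expansion). This is marginally equivalent to iterating
selfing generations and far cheaper; its one inaccuracy is that the chain's
composed two-locus probabilities across several intervals slightly exceed
the true non-Markov RIL values (the adjacent-interval law is exact).
Chromosomes segregate independently. The default map — 5 chromosomes of
87 cM with markers every 3 cM — is a synthetic stand-in; the marker density
of the emulated population is not published.

**Interval mapping.** Haley–Knott regression: at every pseudomarker (1 cM
step plus all marker positions) the phenotype is regressed on
E[x] = 2·P(B) − 1, with P(B) from the two-locus RIL transition algebra
conditional on the nearest observed flanking markers (missing genotypes are
conditioned around; chromosome ends condition on the single available
flank). LOD = (n/2)·log₁₀(RSS₀/RSS₁), which for a single regressor equals
−(n/2)·log₁₀(1−r²); RSS ratios are floored at 1e-12 so perfect fits yield
a large finite LOD. Haley–Knott rather than EM interval mapping because
homozygous-RIL genotype probabilities make the regression approximation
nearly exact, and it is deterministic.

**Significance.** Genome-wide thresholds come from permuting phenotypes
over lines (default n = 1000, seeded) and taking the empirical 95th
percentile of the genome-wide maximum LOD. The threshold is invariant to
monotone linear transforms of the phenotype (LOD depends only on
correlations).

**Multiple-QTL scan.** The closest marker to each interval-mapping peak
becomes a cofactor; at each test position the model includes all cofactors
except those within 10 cM (configurable) of the test position on the same
chromosome — preventing the scan from conditioning on itself — and the LOD
compares models with and without the test-position term. Exactly collinear
cofactors are dropped with a warning.

**Peaks and intervals.** Local maxima above threshold count as distinct
QTL when ≥ 2× the cofactor window apart or separated by a valley dropping
≥ 1.5 LOD below the lower peak. Support intervals are the contiguous
region within 1.5 LOD of the peak (the community-default drop rule;
configurable), clipped at the valley between adjacent peaks so intervals on
one chromosome never overlap. Effects and per-QTL R² (drop-one SS / total
SS × 100) come from the joint additive model at the final positions; the
summary table appends a per-trait R² totals row.

Estimating the effect *at the detected peak* carries a mild winner's-curse
upward bias (~5 % of the effect size at the simulated study's power); the
acceptance study measures and bounds it rather than hiding it.

## Synthetic study generator

What it emulates: (a) reference concentrations with the published
calibration-set statistics — oil 38.78 ± 3.88 % (18.70–46.90), protein
19.99 ± 3.39 % (11.89–27.73), carbon 57.39 ± 1.25 % (51.41–60.69) — drawn
from truncated (bivariate) normals with an oil–protein correlation of −0.7
by default; (b) nitrogen as protein divided by the conventional 6.25
conversion factor plus N(0, 0.05) noise, mirroring the biochemical
protein–nitrogen coupling — note this puts the simulated nitrogen level
near 3.2 %, below the published nitrogen mean of 4.34 %, because the
emulated study's protein assay was not nitrogen-based and its printed
protein/nitrogen ratio is ≈ 4.6, not 6.25; the factor is configurable and
no test depends on the nitrogen level; (c) spectra as linear mixtures of
Gaussian-band component signatures (bands deliberately overlapping between
components, so single-wavelength regression cannot work and multivariate
calibration is genuinely exercised) on a shared smooth baseline, distorted
per sample by a multiplicative slope m ~ N(1, 0.10) truncated positive and
an additive offset a ~ N(0, 0.05) — the artifacts MSC removes — plus white
channel noise of SD 5e-4 AU, a quiet-FT-instrument figure.

What it does not emulate: real seed component spectra (the signatures are
invented stand-ins), wavelength-dependent scatter (EMSC territory),
instrument drift, nonlinear detector response, epistasis, or QTL ×
environment interaction. Passing tests therefore demonstrate that the
*workflow* is implemented correctly and recovers truth under its own
modeling assumptions — not that any particular real instrument or
population would achieve the same statistics.

All generators are deterministic under a fixed seed; the pipeline derives
per-stage seeds by hashing "seed:stage-name" (kept below 2³¹), so stages
can be rerun in isolation and full runs are hash-identical.

## Problem sizes

The acceptance study uses a 500-sample spectral pool (design selects 100
diverse + 48 extremes, rank-split to ≈ 111 calibration / 37 validation
samples, mirroring the emulated study's 112/36) and, for QTL recovery, 50
replicates of 164 RILs with 1000-permutation thresholds — sizes chosen to
match the emulated study while keeping a full run around one minute on one
CPU. Unit tests use smaller fixtures (n ≤ 12 for oracle equivalences,
n = 2000 lines only for recombination-fraction checks).

## Known limitations

- The Markov RIL simulation slightly inflates multi-interval recombination
  (see above); negligible at 3 cM marker spacing.
- Sequential-SS percentages depend on term order in unbalanced designs;
  genotype-first is a documented convention, not an inference procedure.
- MQM here is the described cofactor scheme, not composite interval
  mapping with model selection; support intervals are LOD-drop, not
  Bayesian credible intervals.
- `select_extremes` assumes the preliminary model is good enough to rank
  the tails; a badly biased preliminary model would propagate its bias into
  the design.
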