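# Methods

## Scope and model

`nmrmetab` implements the serum ¹H-NMR metabonomic discrimination workflow:
bucketed spectra → latent-variable class models → correlation-loading
extraction of differential metabolites → pathway over-representation. It
operates on already-processed frequency-domain spectra; pulse-sequence
physics, apodization, Fourier transformation, phasing and baseline
correction are upstream of the package and out of scope.

## Synthetic cohort generator

Because no public spectra accompany the workflow it targets, the package
ships a first-class simulator whose defaults define the study conditions
used throughout the tests.

**Design.** Three xenograft-style groups — Panc-1 (n = 12), BxPC-3 (n = 13),
SW1990 (n = 11), i.e. poor, poor-to-moderate and moderate-to-well
differentiated grades. Per-group log2 effects are derived from the bundled
reference coefficient table: every non-masked signed coefficient contributes
the constraint `level(second) − level(first) = ±1` (one 2-fold step) and
every masked entry an equality constraint; the three group levels per
metabolite are solved by least squares with a sum-to-zero anchor. A few
sign triangles in the table are internally inconsistent (e.g. glutamate,
trimethylamine); least squares softens these into intermediate effects
(±0.67 log2), which the ground-truth API exposes so that recovery metrics
can classify metabolites by realized effect size (≥1 log2 counts as truly
differential, exactly 0 as null, intermediates excluded). The direction
convention — glycolysis/glutaminolysis participants and amino acids elevated
in SW1990, choline species in Panc-1 — is switchable
(`default_design(convention="results")` flips every direction) because the
two readings of the source material disagree; the default follows the
abstract/discussion reading.

**Concentrations.** Per-sample concentrations are log-normal around the
group mean: `c = base · 2^(effect + N(0, σ))` with σ = 0.2 log2 units
(~15 % biological CV, typical for serum metabolites). Base levels are fixed
at realistic CPMG-serum relative shares: glucose dominates (~40 % of the
retained integral), lactate ~13 %, lipoprotein signals deliberately modest
(L1 + L2 + L3 ≈ 11 %) because the 70-ms CPMG echo strongly attenuates
macromolecule signal, and the remaining metabolites 0.3–5 % each.

**Spectra.** Each metabolite contributes unit-area Lorentzian multiplets at
its library shifts: default FWHM 0.004 ppm (≈2 Hz at 500 MHz: natural width
plus 1-Hz line broadening), J = 7 Hz (0.014 ppm) between adjacent lines of
s/d/t/q patterns, a second 3-Hz coupling for dd, and single broadened lines
for m (×2.5) and br (×6) — the br widths emulate CPMG attenuation of
lipid/glycoprotein signal without time-domain modelling. Per-peak shift
jitter (σ = 0.001 ppm) emulates pH/ionic-strength variation; a per-sample
global offset (σ = 0.003 ppm) emulates mis-referencing and is what the
lactate-referencing step removes; additive Gaussian noise σ = 0.05 intensity
units (peak SNR roughly 15–600 across the library); polynomial baseline
amplitude defaults to 0 (baseline correction is assumed done upstream). The
rendering is exactly linear in concentrations, and all randomness flows from
one seed, so cohorts are byte-reproducible.

**What the simulator does not emulate.** Water-suppression artefacts,
phase/baseline errors, peak-shape asymmetry, ridges/t1 noise,
concentration-dependent shift drift (e.g. citrate), and inter-metabolite
correlation structure beyond the designed group effects. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
statistical calibration under clean, known-truth conditions — not robustness
to every artefact of real instruments.

## Preprocessing

- **Referencing:** the midpoint of the two tallest local maxima within
  δ1.33 ± 0.05 is shifted to 1.33 (the endogenous lactate doublet); with
  fewer than two maxima the single tallest point is used and a warning
  logged.
- **Bucketing:** 0.002-ppm buckets over δ9.0–0.5 (4250 raw), dropping
  buckets wholly inside δ6.40–5.50 (water, 450) and δ5.19–4.36 (urea, 415),
  leaving 3385. Bucket value = **sum** of intensity samples in the half-open
  interval `[left, right)`; with a uniform acquisition grid the sum is
  proportional to the integral and the constant cancels under total-sum
  normalization. Half-open buckets make exclusion endpoints unambiguous (an
  intensity sample exactly on a boundary belongs to the higher-ppm bucket);
  all stated boundaries are multiples of the width and land exactly on
  edges. Empty buckets (possible only for axes coarser than 0.002 ppm) are
  filled by interpolation at the bucket centre with a warning.
- **Normalization:** after exclusion, each row is divided by its own sum, so
  profiles are invariant to per-sample global intensity scale. This
  introduces the usual closure (compositional) coupling: a large real change
  in one metabolite shifts every normalized bucket slightly. With the
  default design the group-wise closure shift is ≤0.12 log2 — visible in the
  tails of the null-coefficient distribution but below the significance
  cutoff in expectation.

## Latent-variable models

- **Scaling:** PCA uses mean-centring; PLS-DA/OPLS-DA use Pareto scaling
  `(x − mean)/√sd` with the **sample** (n−1) standard deviation. Constant
  columns are left unscaled and flagged.
- **PCA** via SVD; component signs fixed so each component's
  largest-magnitude loading is positive.
- **PLS-DA** by NIPALS with per-component predictor deflation; two classes
  use one centred −1/+1 column (first class by order of appearance = −1),
  more classes centred one-hot columns.
- **OPLS-DA** (pairwise only): predictive weight w ∝ X'y; each orthogonal
  component takes the part of the current loading orthogonal to w, deflates
  X, and by construction has exactly zero sample correlation with y. One
  predictive + one orthogonal component is the shipped default; with zero
  orthogonal components the model reduces identically to one-component PLS.
  The predictive score is sign-fixed to correlate positively with the
  +1-coded class, which fixes the sign convention of every downstream
  coefficient.
- **Q²** = 1 − PRESS/SS with PRESS pooled over stratified k-fold CV (k = 10)
  against the globally centred response SS; scaling parameters are
  re-estimated inside each training fold (no leakage); folds are stratified
  by class, shuffled deterministically from the seed.
- **Permutation test** (n = 200): labels permuted, R²Y refit and Q²
  re-cross-validated each time; p(Q²) = (1 + #{perm ≥ observed})/(n + 1).
  The R² and Q² intercepts at zero label correlation are reported from a
  least-squares line over the permuted points plus the observed point, but
  no intercept threshold is enforced — p(Q²) is the decision statistic.
- **CV-ANOVA:** F = ((SS − PRESS)/d1)/(PRESS/d2) with d1 = number of fitted
  latent components (predictive + orthogonal, 2 by default) and
  d2 = N − 1 − d1, referred to F(d1, d2); PRESS ≥ SS clamps F to 0, p to 1.
  This is the pragmatic Eriksson-style bookkeeping; other df conventions
  exist and the model df is overridable.

## Differential metabolites

Per-bucket coefficient r = Pearson correlation between the raw bucket values
and the predictive score (scale-invariant, hence computed on the
back-calculated footing); the covariance with the score is exported for
colour-coded loading plots. The significance cutoff is analytic:
r_crit = t/√(t² + df) at two-tailed α; the shipped defaults (α = 0.05,
df = 10) give 0.576. df is deliberately a configuration constant rather
than derived from sample counts, reproducing the reference cutoff exactly.

Buckets are assigned to every non-marker library peak within 0.01 ppm.
Residual water (HOD, 4.76) and urea (5.80) ride in the library as region
markers that can never be assignment candidates — their shifts fall inside
the excluded windows. Per metabolite, the maximum-|r| assigned bucket is
reported; if that bucket is shared between candidates the call is flagged
`ambiguous` (lactate/threonine at δ1.33 being the canonical case). Max-|r|
was chosen for sensitivity and transparency; it slightly inflates the false
flag probability of multi-peak metabolites, which the ambiguity flag and the
recovery tests quantify. Insignificant entries are rendered masked ("-") in
the report tables.

## Pathway over-representation

Upper-tail hypergeometric p per pathway with ≥1 hit: k hits of a K-member
pathway in an n-metabolite query from an N-metabolite universe. The universe
defaults to all annotated metabolites of the bundled map (34 of the 45) and
is configurable. The bundled map is a small curated annotation of
KEGG-style pathway names to library abbreviations — a synthetic stand-in,
not a database export; with such a compact universe only selective queries
(e.g. an amino-acid signature) can reach p < 0.01, and saturated queries
correctly cannot. Raw p < 0.01 is the headline filter; BH-FDR is emitted
alongside but not used for filtering.

## Numerical and design notes

- Degenerate inputs: constant buckets get r = 0 and zero covariance;
  non-positive row sums, inverted windows, inconsistent counts and
  too-large component counts raise informative errors; binning widths must
  divide the region exactly (tolerance 1e-9).
- All stochastic procedures (sampling, folds, permutations) are
  deterministic given (seed, n); sample order does not affect Q² beyond the
  seeded stratified fold assignment.
- Problem sizes used in the validation suite: the default 36-sample cohort
  at 12 288 axis points; 50 seeded cohorts for the recovery study; 100
  replicates at 50 permutations each for the null-calibration study. These
  sizes make the whole suite run in a few minutes while keeping the
  binomial uncertainty of the recovery rates well inside the asserted
  margins.
- Known limitations: single predictive component only for OPLS-DA (use
  PLS-DA for >2 classes); no probabilistic-quotient or vector normalization
  alternatives; no peak alignment beyond global referencing (the 0.002-ppm
  buckets absorb the default jitter); enrichment p-values depend strongly on
  the chosen universe.
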