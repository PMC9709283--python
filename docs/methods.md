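# Methods

## Scope and data model

The pipeline operates on a processed feature table: `p` molecular features
(accurate mass m/z in Da, retention time in min) × `n` injections with
non-negative relative intensities, plus injection metadata (subject,
timepoint pre/mid/post/rebound, dialysate arm AD/CD, sample type
study/qc/blank, injection order). Raw spectra, peak picking and retention
alignment are upstream concerns and out of scope; zeros encode
below-detection values. Four comparisons ship as presets: pre vs post within
each arm, and AD vs CD at post and at rebound. Pairing is strict — a subject
must contribute exactly one injection per group; extras are an error (the
crossover design has one sampled midweek session per arm), and subjects
missing one side are dropped and logged.

## Normalization

**medFC.** The reference profile is the feature-wise median over study
injections. Each injection's scale factor is the median, over features
positive in both the injection and the reference, of intensity/reference;
all columns (study, QC, blank) are divided by their factor. With
multiplicative (log-normal) intensities this removes per-sample dilution
exactly in expectation. medFC is idempotent only up to the stability of the
median reference profile; with a few hundred features the second-pass
factors sit within a few percent of 1, which is what the idempotence test
asserts.

**QC-LOESS (QC-RLSC).** Per feature, a LOESS curve (local-linear,
default span 0.75, configurable; the published workflow states no span) is
fitted to pooled-QC intensity versus injection order, evaluated at every
injection by linear interpolation between QC orders and clamped outside,
and divided out after rescaling by the median QC intensity. Correction is
per-feature, the standard QC-RLSC formulation; whether the original analysis
corrected per feature or globally is not stated in its methods, so this is a
documented choice, not an inference. Features whose QC values are all zero
pass through unchanged and are logged. medFC runs before LOESS so that gross
dilution does not masquerade as instrument drift.

## Quality assurance

CV is 100·SD/mean with the n−1 denominator (unstated upstream; sample SD is
the convention). Boundaries are strict per the published wording: a feature
needs QC CV **< 30%** (exactly 30% is removed) and a zero-percentage over
study injections **≤ 60%** (exactly 60% is retained, "greater than 60%"
being the removal rule). An undefined CV (all-zero QC) fails the CV rule.
Blanks are excluded from all statistics.

## Volcano pre-selection

Fold change is the ratio of paired-group arithmetic means of normalized
intensities (post over pre); zeros are imputed per feature by half the
minimum positive value (unit offset available). The paired differences (on
the normalized intensity scale) are routed by Shapiro–Wilk at α = 0.05 to a
paired t-test or a Wilcoxon signed-rank test (exact distribution up to
n = 25 without ties, normal approximation with continuity correction
otherwise). Benjamini–Hochberg step-up adjustment runs across features, and
selection is strict: |log₂FC| > 1 and adjusted p < 0.05 (the adjusted-p
reading is the stricter interpretation of the published criterion and is
config-switchable to raw p). Degenerate cases have fixed conventions:
identical pairs give p = 1, a constant non-zero difference gives p → 0 with
the t-test, all-zero features are excluded and flagged.

## Multivariate modeling

Features are unit-variance scaled by default (the convention of the
chemometrics software the field uses; Pareto and center-only available).
PCA is computed by SVD with a deterministic sign convention
(largest-magnitude loading element positive). OPLS-DA codes the two classes
as a centered ±1 dummy and follows the single-response O-PLS algorithm:
w ∝ Xᵀy normalized; per orthogonal component p = Xᵀt/(tᵀt),
w_o ∝ p − (wᵀp)w, t_o = Xw_o, deflation X ← X − t_o p_oᵀ; the predictive
component is fit on the deflated matrix. The orthogonal-component count is
the smallest value in 0..3 maximizing cross-validated Q² (forward
selection); one predictive component always, the response being binary.

Validation: Q² = 1 − PRESS/SS_tot under seeded, stratified 7-fold
cross-validation (each fold refits on training rows re-centered on training
means; fold count is clamped when a class is too small to stratify);
CV-ANOVA with F = ((SS_tot − PRESS)/d₁)/(PRESS/d₂), d₁ = components + 1,
d₂ = N − d₁ − 1 (Eriksson's CV-ANOVA formulation; the exact d₁ convention is
covered by a size simulation rather than claimed bit-exact to any vendor
tool); and a label-permutation test with p = (1 + #{perm ≥ obs})/(1 + n_iter)
for both R²Y and Q², 1,000 iterations by default. A model is "valid" when
Q² > 0.5, CV-ANOVA p < 0.05, and both permutation p-values are < 0.05.

## Variable selection

VIP is normalized so Σ VIP² equals the number of model variables. In the
default "total" mode the predictive component is weighted by the y sum of
squares it explains and orthogonal components by the X sum of squares they
capture (the OPLS total-VIP form); a predictive-only variant is available.
Jack-knife intervals use Martens' estimator over the cross-validation
sub-models, centered on the full-model VIP, with a t critical value at
G − 1 degrees of freedom. The cascade ranks by VIP descending (feature id
breaking ties), cuts to the top 30 *before* thresholding, then keeps
variables with VIP > 1, a CI strictly excluding zero (a degenerate [0, 0]
interval counts as including it), and max(FC, 1/FC) > 1.2 — the two-sided
reading, since clearance effects have FC well below 1. Peak verification is
deliberately a manual-review checklist (feature keys plus the QC intensity
profile in injection order), not an automated classifier.

**A structural property worth knowing.** When the volcano stage passes
*only* truly affected features of similar effect size, the model contains no
uninformative variables, the VIP normalization centers every score at 1, and
the strict VIP > 1 cut retains roughly half of them. On simulations with 20
equal-fold-change effects among 500 features (21 subjects), the cascade's
recall is therefore ~0.4 even though its false-selection proportion is 0.
VIP thresholds measure *relative* importance within the modeled variables;
with heterogeneous real-data effect sizes the cut behaves as intended, but a
homogeneous selected set halves it. This is a property of the published
cascade itself, not of this implementation.

## Annotation

Monoisotopic masses use IUPAC/CODATA atomic masses; adduct shifts follow the
charged-species convention (proton mass, electron-corrected): +1.00727647
(M+H), +22.98922070 (M+Na), −17.00328823 (M+H−H₂O). The hydrogen-atom
convention differs by ~0.5 mDa; both keep every packaged reference mass
within the 10 ppm window. The ppm window is applied to the adduct m/z (the
query is on observed m/z), every (compound, adduct) candidate within
tolerance is reported sorted by |ppm error| — no winner-takes-all — and MSI
levels come from evidence flags: standard-confirmed → 1, MS/MS match → 2,
mass-only → 3, no hit → 4. Two published reference rows do not reproduce
under any neutral-adduct convention and are excluded from the packaged
fixture: one whose printed formula is already the intact cation (off by
~1 Da under M+H), and one alkane M+Na row that computes to −10.07 ppm,
marginally outside the window at the printed precision.

## Synthetic data

The generator emulates the crossover design: intensity(f, i) =
exp(baseline_f + subject_{f,s} + effect_f·1[post] + ε) · drift(order_i),
with log-normal baselines (log-mean 10, log-SD 1 — conventions for relative
plasma LC-MS intensities, not fits), between-subject log-SD 0.3, replicate
noise log-SD 0.2, a smooth sinusoid-plus-trend drift whose peak-to-trough
ratio is exactly 1 + amplitude (default 0.3), QC pools carrying the pooled
baseline with replicate noise, 5 leading QCs plus one QC per 6 study
injections, and terminal blanks at trace level. Zero-censoring (default rate
0.05) applies to study injections only — pooled QCs essentially never drop
to zero in practice, and the QA stage needs estimable QC CVs. Effects are
multiplicative at the post timepoint; clearance corresponds to fold change
below 1. The generator does not simulate isotope patterns, correlated
feature blocks (adducts/fragments of one metabolite), heteroscedastic noise,
or retention-time instability, so passing tests demonstrate correctness of
the statistical machinery on a clean multiplicative model, not robustness to
every artifact of real spectra.

## Problem sizes and numerics

Simulation-based tests run at 21 subjects × 200–500 features, the
false-discovery check at 100 null datasets, and parameter recovery at 20
seeds — sizes chosen so the full suite completes in a few minutes while
Monte-Carlo error stays well inside the asserted tolerances. Seeds are fixed
everywhere; permutation and cross-validation randomness derive from a single
config seed. LOESS fitted values are floored at a tiny positive multiple of
the median QC intensity to avoid division blow-ups; OPLS deflation stops
early (with a warning) when the residual loading becomes collinear with w;
zero-variance columns are dropped before scaling and logged.

## Known limitations

- Multivariate modeling treats paired samples as independent observations,
  as the standard OPLS-DA workflow does; the pairing informs only the
  univariate stage.
- No inter-batch correction (single-batch designs only).
- MS/MS spectral matching is reduced to boolean evidence flags; the package
  does not score spectra.
- The bundled compound library is a small curated set for demonstration and
  testing; real annotation requires a full HMDB/METLIN-scale library in the
  same delimited format.
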