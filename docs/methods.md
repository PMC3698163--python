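# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `specfinger`, and what the synthetic
cohort does and does not establish about measured data.

## Pipeline model and assumptions

The pipeline treats disease classification from mid-IR plasma spectra
as a two-class problem on a fixed wavenumber grid.  Its stages and the
assumptions each one makes:

**Vector normalization** removes per-sample optical-path and
concentration scale: each spectrum is centred and scaled to unit
Euclidean norm.  Assumes the informative signal is the *shape* of the
spectrum, not its absolute intensity.

**Savitzky–Golay derivative** (window 9 points, polynomial order 3,
second derivative by default) sharpens overlapping bands and removes
smooth baselines.  The window length is the classical nine-point
smoothing choice for this application; the polynomial order is the
common chemometrics default for second derivatives and is configurable
(`PreprocessConfig.sg_polyorder`).  Derivatives are taken with respect
to wavenumber in physical units (per (cm⁻¹)^order); because grids are
stored descending, odd derivative orders flip sign relative to the
array axis and the implementation corrects for this.  Edge points use
the polynomial fit of the terminal windows (`mode="interp"`).  Requires
a uniform grid.

**Region extraction** keeps the closed intervals 3150–2750 cm⁻¹
(CH-stretch region) and 1850–750 cm⁻¹ (fingerprint region), excluding
the water band near 3350 cm⁻¹ and CO₂ near 2200 cm⁻¹ purely by region
choice.  On the default 4 cm⁻¹ grid the gridpoints are multiples of
4 cm⁻¹, so the two windows retain 100 and 275 points (375 feature
columns): interval endpoints that are not multiples of 4 fall off-grid.

**Region standardization** scales each region to zero mean, unit
variance.  Two readings of "normalized to zero mean and variance 1"
are implemented: per spectrum and region (default — each sample's
segment standardized independently, population n-denominator variance,
no cross-sample coupling, hence no leakage by construction) and per
wavenumber over the cohort (column statistics fitted on a training set
and applied elsewhere).  The per-spectrum default was chosen because
the sentence describes normalizing *regions* and because it removes
sample-level intensity nuisance.

**Bhattacharyya feature selection.**  The score is the Bhattacharyya
*distance* between per-class univariate Gaussians; field usage often
says "coefficient", but the coefficient (overlap integral e^(−D)) is
largest for *identical* classes, and only the distance orientation
makes a keep-the-largest 5%-of-maximum rule select separable
wavenumbers.  The threshold is strict (score > 0.05·max); the arg-max
is always kept.  Class standard deviations use the sample (n−1)
convention and are floored at 1e-9 × the global intensity scale so a
perfectly separated zero-variance column ranks top instead of
producing infinity.  Scoring is performed once on the full cohort by
default, mirroring a single published feature list; this is
optimistically biased relative to per-session selection (the shuffled
null quantifies the optimism), and leakage-safe per-split scoring is
available by calling `score_wavenumbers` on a training subset.

**Ensemble.**  67 sessions; per session a 70/15/15 split (train size =
round(0.70·n); the remainder halved, validation taking the odd extra
sample), stratified per class by default (the unstratified mode
reproduces a literal pooled draw; the cohort is near-balanced so the
difference is one sample here or there).  The session network is one
hidden layer of 3 logistic units and a logistic output trained on
log-loss with Adam (step 0.003, minibatch 32) for at most 500 epochs,
stopping when validation loss has not improved for 10 epochs and
restoring the best-validation weights.  The step size was chosen small
enough that the validation-loss trace is smooth on cohorts of this
size; with a noisier trace a 10-epoch patience fires long before
convergence.  All session randomness (splits, initialisation) derives
from `(master_seed, session_index)`, so the run is reproducible and
any single session can be re-run in isolation.

**Aggregation and the reject rule.**  Per sample: mean and standard
deviation (sample convention; defined as 0 below two appearances,
flagged low-coverage) of its test-set soft outputs.  Undefined iff
|mean − 0.5| ≤ std (ties reject).  Sensitivity/specificity are computed
over reliable calls; their ± uncertainty is a bootstrap over sessions
(sessions resampled with replacement, aggregation and rule re-applied,
sd over 50 replicates), since aggregate metrics have no closed-form
error under the reject rule.

**PCA diagnostics.**  Covariance PCA on the already-standardized
region features, centred per block.  Intra-class: eigenvectors per
class and region (4 components), all samples projected on every block
(2 regions × 2 classes × 4 = 16 coordinates); inter-class: one pooled
basis per region.  The fingerprint region is reported first because it
separates the classes best.  Eigenvectors are sign-fixed
(largest-magnitude loading positive) for reproducible orientation.
Multimodality is quantified by comparing BIC of 1- vs 2-component
Gaussian mixtures on a PC1 coordinate.

## Synthetic cohort design

No real spectra ship with the package; the generator emulates the
statistical structure such plasma studies report, at the study
conditions used throughout the tests:

* 192 positive vs 202 negative samples on a 4000–400 cm⁻¹ grid at
  4 cm⁻¹ (901 points — typical FT-IR resolution; the span is the
  instrument range, the step a desk-scale choice);
* absorbance built from 9 Gaussian bands at standard plasma
  assignments (CH stretches 2960/2925/2850; lipid ester 1750; Amide I
  1650 — dominant; Amide II 1550; 1400; carbohydrate 1155/1030 cm⁻¹).
  Relative amplitudes are generator inputs, not spectroscopic claims;
* the class effect is a multiplicative amplitude excess of the
  negative (control) class confined to 1750–1600 cm⁻¹ (default 15%,
  logistic edges of 8 cm⁻¹), so both classes follow the same wave
  pattern elsewhere;
* two subclusters per class (weights 0.8/0.2) whose band-offset
  signatures (per-band multiplicative offsets, sd 0.10) are *shared*
  between the classes; class information is carried entirely by how
  strongly each mode expresses the effect — main modes at 1.0/0.0,
  minor modes at 0.7/0.3.  The minor modes therefore straddle the
  midpoint: an overlapping mode that produces borderline samples,
  rejected calls and intra-class bimodality.  Sharing the signatures
  also makes `effect_size=0` a genuine null (classes exchangeable);
* per-sample nuisance: band-amplitude jitter (sd 0.03), a global
  log-normal intensity factor (sd 0.03, removed by vector
  normalization), smooth correlated noise (sd 0.006, correlation
  length 16 cm⁻¹) and white noise (sd 0.003), all relative to the unit
  Amide I amplitude; 2% outliers receive one large smooth perturbation
  (sd 0.30, 60 cm⁻¹);
* randomness flows from one seed through named per-sample streams
  (`SeedSequence([seed, class, index])`), so enlarging a cohort never
  reshuffles existing samples.

The within-window noise scales were fixed once so that the default
cohort reproduces the operating regime these pipelines report on real
plasma — per-session accuracy in the mid-90s, reliable-call
sensitivity/specificity of 95–98%, and a few percent of rejected
samples — and then left alone.  At the verification seed the full
pipeline yields sensitivity 98.4%, specificity 97.0%, 2.0% undefined.

**What passing tests show — and do not.**  The synthetic cohort
demonstrates that the pipeline recovers a known class effect of
plausible size under realistic nuisance structure, rejects ambiguous
samples rather than guessing, returns to chance under label shuffling,
and degrades monotonically as the effect shrinks.  It does not emulate
instrument artefacts (atmospheric lines, detector drift, scattering),
batch effects between collection sites, age/gender covariates, or the
true biological covariance of plasma composition; performance numbers
on the synthetic cohort are properties of the generator's conditions,
not predictions for any measured cohort.

## Numerical choices and degenerate inputs

* Grid uniformity tolerance: 1e-6 relative; region boundaries are
  closed on both ends (published ranges are written as closed
  intervals).
* Constant spectra (vector normalization), zero-variance segments or
  columns (standardization), all-zero score vectors (selection), a
  class with every call undefined (evaluation) raise typed errors that
  name the offending sample or wavenumber.
* Samples never landing in any test set are excluded from aggregation
  (with few sessions this is expected; at 67 sessions every sample is
  tested ~10 times).
* European number formats ("1.850" for 1850, decimal commas) are
  normalized when parsing wavenumber headers and config values;
  intensity cells are read as plain machine floats first.
* Metrics JSON is written with sorted keys so identical configurations
  produce byte-identical files.

## Known limitations

* The per-session trainer relies on a general-purpose Adam/MLP
  implementation; with very small training sets (tens of samples) the
  validation trace is noisy and early stopping can truncate training —
  the defaults are tuned for cohorts of a few hundred samples.
* Whole-cohort feature selection (the default, matching the published
  single feature list) is optimistic; the label-shuffled null in the
  test suite shows reliable-call accuracy staying at chance, but
  per-class rates under the null can be pushed off-centre by
  majority-class bias, which is why null behaviour is asserted on
  accuracy rather than per-class rates.
* No baseline correction, scatter correction (EMSC) or water-vapour
  compensation beyond region choice; spectra on unequal grids are not
  interpolated — resample upstream.
* The JCAMP-DX reader covers the plain AFFN `(X++(Y..Y))` layout only;
  compressed encodings (SQZ/DIF/DUP) are out of scope.
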