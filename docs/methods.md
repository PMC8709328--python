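# Methods

## Washout model and fitting

Each late-phase TIC (lesion or parenchyma ROI) is summarised by
`F(t) = A·exp(−k·(t − t_start)) + B` with `k ≥ 0`.  The clock is re-zeroed at
the window's start frame and the raw samples are fitted directly (no
smoothing) by trust-region nonlinear least squares from a deterministic
start (`A₀ = first − last`, `B₀ = last`, `k₀ = 2/T`, capped at `k ≤ 10 s⁻¹`),
tolerances 10⁻¹² on objective and step; no random restarts, so fits are
reproducible bit for bit.  The constant model `A = 0` is nested in the family
and is always evaluated as a fallback, which guarantees the fitted MSE never
exceeds the sample variance; an exactly flat series is reported as
`A = 0, k = 0` (the rate is unidentifiable there, and 0 is the tie-break).
An optimiser failure returns the start values with `converged = false`.

**AREA.** The statistic is the time-averaged deviation of the fitted curve
from its own start-frame value, `AREA = A·[(1 − e^{−kT})/(kT) − 1]`, in dB.
Time-averaging (rather than the raw dB·s integral) makes the statistic
comparable across window lengths and puts it on the same scale as the
−19.3 dB operating cutoff and the class means used throughout; the
unnormalized integral and a raw-sample (trapezoid) variant are available as
options.  The washout flag is `AREA ≤ −19.3 dB`, boundary inclusive: washout
means falling intensity, so the malignancy-suggestive side is the more
negative one.

**Known estimator bias.** Nonlinear least squares has an O(σ²) finite-sample
bias.  At the noise levels used in the tests (σ = 0.5 dB over 121 frames) the
median bias of `A` is ≈ 0.008 dB against a Monte-Carlo resolution of
≈ 0.012 dB at 500 replicates, i.e. negligible but measurable; at much larger
σ the bias becomes resolvable and the "unbiasedness" check would rightly
fail.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* **Census** (defaults): 91 lesions — 34 HCC, 13 metastases, 7 haemangiomas,
  7 regenerative nodules, 5 focal fatty alterations, 3 fatty-free areas,
  4 cholangiocarcinomas, 2 abscesses, 5 adenomas, 4 complex biliary cysts,
  5 parenchymal infarctions, 2 vascular abnormalities.  Counts are exact
  (count mode); probability mode draws a multinomial for arbitrary n.
* **Malignancy map**: HCC, metastasis and cholangiocarcinoma malignant
  (51/91); adenoma and the remaining categories benign.  Per-type overrides
  exist because published malignant/benign totals in this field are often
  internally inconsistent (55 vs 51 here, depending on the paragraph).
* **Fibrosis**: exactly `round(n·34/91)` lesions cirrhotic, selected by
  weighted sampling without replacement with 5:1 odds for HCC and
  regenerative nodules — both arise almost exclusively in cirrhotic livers.
  Fibrosis is a binary F4 flag; the pipeline never uses the kPa scale.
* **AREA structure**: the parenchyma AREA is drawn first from its marginal
  (mean −7.0, scale 42.6 dB), independently of class; the lesion AREA is
  drawn around the linear link `y = −12.21 + 0.16·x` plus a class shift
  calibrated so the malignant/benign means equal −25.08 / −7.08 dB exactly
  in expectation.  All AREA draws are upper-truncated at +30 dB (echo
  intensities cannot rise without bound in the late phase) using
  *mean-matched* truncated normals: the location is solved by Newton
  iteration so the post-truncation mean equals the target.  Without
  mean-matching the truncation would drag the class means several dB down
  and break the generator's own calibration guarantees.  One consequence of
  the published numbers being mutually inconsistent (the class means, their
  mixture, and the regression line cannot all hold at once) is that the
  class shifts do not average to zero: under the defaults the cohort-wide
  OLS *slope* is unbiased (parenchyma AREA ⊥ class) but the pooled intercept
  is offset by the mean shift (≈ −3.8 dB).  Parameter-recovery checks
  therefore use `consistent_regression_config()`, which places both class
  means on the configured line — the generator's own model with the shifts
  switched off.
* **TIC synthesis**: grid 120–300 s at 1 Hz (the late phase begins at 120 s;
  1 Hz is a typical cine rate), `k = 0.02 s⁻¹` (late-phase washout evolves
  over minutes), `B = −57.3 dB` (the observed asymptotic lesion intensity
  scale), amplitude `A` solved analytically from the drawn AREA, plus
  i.i.d. Gaussian noise of 0.5–1 dB (default 1.0) — log-compressed,
  ROI-averaged intensities are approximately Gaussian in dB.  Simulated
  curves therefore round-trip: refitting recovers the drawn AREA up to
  noise.
* **Patterns**: each diagnosis has a canonical arterial pattern (the five
  categories without a textbook row get the clinically nearest one: adenoma
  → hyper, complex cyst → septated peripheral, infarction → rim-like with
  central hypo, vascular abnormality → centrifugal, regenerative nodule and
  both fat pseudo-lesions → iso).  With probability
  `pattern_confusion_rate` (default 0.5) the recorded pattern is replaced by
  a uniformly random *other* pattern: these are lesions selected precisely
  because CEUS was inconclusive, so a large fraction of unreadable or
  atypical patterns is the realistic regime.

All draws flow from one `numpy.random.Generator` seeded by the config, so
cohorts are byte-identical under a fixed seed after serialization.

**What the generator does not emulate:** wash-in/bolus-arrival kinetics,
motion and depth-dependent attenuation artefacts, correlated (speckle)
noise, operator variability in ROI placement, and any dependence of the TIC
shape on lesion type beyond the AREA value.  Passing tests on synthetic
cohorts therefore demonstrate that the machinery is correct and calibrated,
not that the clinical performance figures would replicate on real patients.

## Decision tree

The rule table maps (cirrhotic, washout, pattern) to a lesion type and is
injected as data (JSON-serialisable); the default reconstruction routes
hyper-enhancement with washout to HCC in both fibrosis states, rim to
metastasis, rim-with-central-hypo to cholangiocarcinoma, and on the
no-washout side peripheral-nodular to haemangioma, centrifugal to FNH,
septated-peripheral to abscess, and iso to regenerative nodule (cirrhotic)
or focal fatty change (non-cirrhotic).  A bundled alternative table
(`rules_hyper_washout_adenoma.json`) routes non-cirrhotic hyper+washout to
adenoma instead, since that branch is clinically arguable.  Missing keys and
missing patterns yield type "indeterminate"; malignancy is still called from
the washout flag alone.  The "focal fatty change" call is scored correct for
both fat-distribution pseudo-lesions (deposition and sparing are the same
imaging entity).  FNH can be predicted but never occurs as a truth label in
the default census, so centrifugal-pattern truth types are never typeable —
a faithful property of the rule set, not a bug.

## Evaluation layer

* Confusion metrics use the standard definitions; undefined ratios are
  reported as missing rather than zero.
* AUROC is the pairwise-concordance (Mann–Whitney) estimator with ties
  counted ½, identical to trapezoidal integration of the empirical ROC; the
  default orientation treats more-negative AREA as more malignant.
* The Youden cutoff maximises Se + Sp − 1 over observed thresholds, ties
  broken toward higher sensitivity.  Note the empirical argmax is an
  n^{−1/3}-rate estimator: on two heavily overlapping Gaussians its spread
  is several dB even at n = 10⁴, so tests check the *median* over
  replicates against the closed-form density-crossing boundary.
* Group comparison gates on Shapiro–Wilk normality (α = 0.05 per group):
  Student's t when both pass, otherwise Mann–Whitney (exact for small
  tie-free samples).  Groups of fewer than three observations cannot be
  normality-tested and go to the rank branch.
* The two-proportion test is the pooled-variance z (chi-square without
  continuity correction); Fisher's exact test is an option.
* Detection rate = correctly typed / correctly classified, reported as an
  exact fraction plus an integer-rounded percent.
* Report JSON stores every proportion as an exact fraction alongside a
  printed-style string (percentages to one decimal, p-values to two), so
  downstream rounding is unambiguous.

## Pipeline sizes and determinism

The default end-to-end run fits 182 curves of 181 frames (< 1 s); the
calibration and recovery checks use 10⁴-lesion cohorts drawn without TIC
synthesis (the drawn AREA values are the generator's ground truth), and the
fit-bias study uses 500 replicates at σ = 0.5 dB.  `run_pipeline` quantifies
from the *serialized* TIC file and parameter table, so the staged CLI
(`simulate → quantify → classify → evaluate`) reproduces the monolithic run
byte for byte.  The run log records the seed, config hash, rule-table hash,
cutoff and AREA-normalisation mode.

## Known limitations

* The exponential model cannot represent non-monotone late-phase kinetics;
  the constant fallback bounds the damage but `t_to_peak` is the only
  non-monotone summary retained.
* The tree cannot type adenomas, complex cysts, infarctions or vascular
  abnormalities (no unique pattern row); they are scored as malignancy
  errors or indeterminate types, matching binary clinical scoring.
* Class-conditional AREA spreads are scale parameters of truncated
  distributions; realized standard deviations are smaller than the nominal
  37.98/42.6 dB because of the +30 dB bound.
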