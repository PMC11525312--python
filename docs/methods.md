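# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and image processing

A plate image is reduced to one chromatogram per track: 8-bit grey
conversion (ITU-R BT.601 weights 0.299/0.587/0.114 for colour input,
rounded to the nearest integer), arithmetic mean over the central 50 % of
the application band (all pixel columns within a quarter band-width of the
track centre — an odd count for integral centres), then a single
Savitzky–Golay pass with polyorder 2 and window 111 samples. Smoothing
happens once, after averaging and before any peak work; all fitting and
integration operate on the smoothed profile. Positions are 0-based samples
from the application origin toward the solvent front; the retention factor
of a plate-axis position is `(position − origin) / (front − origin)`.

## Peaks, baselines, integrals

Quantification happens inside a user-chosen peak window. The baseline is
the straight line through the profile's intensities at the window bounds;
integrals use the trapezoidal rule on the sampling grid. The net integral
is raw minus baseline and is invariant under adding a constant to both.

For fitted model curves the base integral is restricted to the span
between the outermost model/baseline crossings (piecewise-linear
intersection of the sampled curves) whenever the model properly crosses
the baseline inside the window; this prevents overestimating the
background under the model's flanks. Tangency does not count as a
crossing. A model entirely below the baseline is flagged and its net
integral reported as zero.

Ring signals are detected as double peaks: local maxima on the smoothed
profile with a minimum prominence of 2 grey values (a threshold that
suppresses residual noise maxima; the choice is ours), the two highest
being the halo shoulders, ties broken toward the widest-separated pair —
halo shoulders are far apart. The outer legs run from each shoulder apex
outward to the window edge, apexes included. When fewer than two maxima
are found the legs must be supplied manually; that fallback is part of the
supported workflow, not an error path.

Leg trimming for the sensitivity analysis orders each leg from the apex
outward, locates the inflection point as the steepest-slope sample
(central differences), and keeps `ceil(coverage × leg length)` samples
from the inflection outward. This removes the flat transition next to the
apex, which carries little information about the width and steepness of
the underlying peak. Coverage 1.0 means the whole leg, untrimmed.

## Peak functions and fitting

The four evaluators implement their printed algebraic forms exactly,
including the Gaussian's `σ²` denominator (a flag restores the
conventional `2σ²`) and the log-normal's idiosyncratic inner term. The
log-normal is zero outside its admissible support and its least-squares
fits frequently fail to converge; such failures are recorded outcomes
(`status='failed'`), never exceptions, and failed fits are excluded from
study means but counted.

Fits minimize the unweighted sum of squared residuals on the raw grey
values. The functions carry no offset term, so on data with a background
plateau the fit absorbs the background — the Lorentzian does this
particularly well through its heavy tails, which is consistent with its
superior integral ratios in the validation study. For this reason the
parameter bounds are generous (amplitude-equivalent height ≤ 3× the data
maximum, scale ≤ 10× the window length, centre within the window ± one
window length); clamping the scale to the window length would forbid the
background-absorbing solutions. Initialization is moment-based: amplitude
from the maximum, centre from the argmax, scale from the empirical
half-maximum width. Optimizer: SciPy trust-region reflective with
parameter tolerance 1e-8 and at most 10⁴ evaluations.

Masked-peak extrapolation fits the chosen function to the concatenated
outer-leg samples only, samples the model over the whole window, and
integrates with the intersection-restricted base integral.

## The simulated cytotoxic mask

A double peak is manufactured from an ideal peak by subtracting an
printed-form Gaussian (σ² denominator) from the central two thirds of the
window: amplitude
half the window's maximum intensity, centre at the window midpoint, scale
one fifth of the window's sample count ("thinner than the ideal peak").
Outside the central region the data are untouched; masked values are
floored (default 0, the 8-bit physical floor; the dose-series generator
floors at the background level, since a dead spot centre retains the
plate's background fluorescence). The window midpoint is used for the mask
centre; the alternative reading (the intensity at the midpoint) mixes
axes and was rejected.

A geometric consequence worth stating: with the mask amplitude tied to
half the data maximum, the two highest maxima of the masked curve sit at
the last untouched samples flanking the masked region whenever the peak is
wide relative to the window or rides on a sizeable background. In that
regime the outer legs are exactly the unaffected data. The exact-recovery
oracle (`exact_recovery_ratio`) exploits this: a noiseless,
background-free peak with width 1.5× the window is masked and refit from
its legs, and the fitted integral must reproduce the original to within
the optimizer tolerance. This holds for the Gaussian, Lorentzian and
(apex-centred) EMG kinds; the printed log-normal form has no comparably
stable parameterization and is excluded from the oracle.

## Synthetic validation study

The study stands in for a laboratory set of 42 ideal effect peaks, which
is not publicly available; its conditions are fixed in `FixtureSpec` and
emulate an 8-bit fluorescence readout:

- 42 peaks, alternating Lorentzian- and Gaussian-shaped (50/50 mix);
- apex amplitudes uniform in 60–220 grey values over a background plateau
  of 50 grey values (typical plate autofluorescence);
- width parameters uniform in 30–80 samples (Lorentzian FWHM, Gaussian
  printed-form σ);
- additive camera noise with sd 1–2 grey values, 8-bit quantization,
  Savitzky–Golay smoothing (2/111) on a 601-sample track;
- analysis window of one width parameter centred on the apex — the
  signal-zone interval within which the halo maxima delimit the unaffected
  flanks.

Step 1 fits each function to the full windowed peak and reports the
fit/measured net-integral ratio; step 2 masks each peak, detects the
double peak, extrapolates from the legs, and compares against the
original (unmasked) integral. Summaries per function: mean ratio, mean
|ratio − 1|, quartiles, Hampel outlier count; across functions:
Kruskal–Wallis and Dunn's post-hoc on the converged ratios; per fit: a χ²
goodness-of-fit p-value. The acceptance thresholds are the published
validation bounds: mean |ratio − 1| ≤ 3 % for step 1 and ≤ 9 % for step 2
(Lorentzian). These are bounds on our synthetic replication, not attempts
to reproduce laboratory ratio statistics, which depend on unpublished
chromatograms.

What the generator does not emulate: plate-to-plate illumination drift,
spatially correlated background structure, track warping, and analyte
diffusion physics. Passing thresholds on this synthetic study therefore
demonstrates the correctness and stability of the numerical pipeline
under controlled conditions, not assay-level performance on real plates.

The sensitivity analysis reruns step 2 with leg coverages 0.1–1.0 on the
same study. On 30–80-sample-wide peaks, low coverages often leave too few
leg samples to support a fit; those peaks are recorded as failures and the
low-coverage columns summarize correspondingly fewer peaks. The reported
qualitative behaviour — the interquartile range of the ratios does not
shrink as coverage falls — is asserted at 20 % versus 100 % coverage.

## Dose–response

Replicate net integrals are normalized to the global maximum across all
replicates and doses, averaged per dose (t-based 95 % CI of the mean), and
the means fitted with the five-parameter logistic. Initialization from the
data (d = min, a = max, w = dose nearest the half-range response, slope
sign from the log-dose trend, f = 1); bounds keep w and f positive. ED_x
solves the model in closed form, `ED_x = w ((100/x)^{1/f} − 1)^{1/b}`,
which is independent of the plateaus because the target is defined
relative to them. Confidence intervals are delta-method intervals on the
log-dose scale with a t critical value at the fit's residual degrees of
freedom — dose series are short (10 doses, 5 parameters), and the normal
quantile understates the uncertainty there. Intervals are pointwise, not
simultaneous.

The synthetic dose series mirrors a 10-step 1:2 dilution experiment
(doses 10–5120 units) with 5PL truth (a = 1, d = 0, w = 320, b = −2,
f = 1), four replicates, additive replicate noise of sd 0.05 on the
normalized response (not censored at zero: baseline-corrected net
integrals are real-valued), and simulated masking applied to doses above
640 units. Dose spots are quantified over a window of twice the width
parameter: halo signals keep most of their flank area, and the wider
window keeps the plainly-integrated ("unmodelled") integrals positive but
depressed, as observed for real ring signals. The package produces
modelled and unmodelled dose–response fits side by side; on the synthetic
series the extrapolated integrals give an ED50 much closer to the
generating value than the masked ones, though the leg-extrapolated
integrals retain a shape-dependent bias of order 10–15 % at fully masked
doses — plain CI coverage of the truth is therefore asserted for the
unmasked study, and the masked comparison is asserted directionally.

## Statistics toolbox

Shapiro–Wilk, Levene (median-centred, i.e. Brown–Forsythe — the centring
is unstated in the procedure this replicates and the median variant is the
robust default), and Kruskal–Wallis (tie-corrected, χ² p-value) wrap
SciPy. Dunn's post-hoc test is implemented here: pairwise z statistics on
pooled mean ranks with tie correction `Σ(t³−t)/(12(N−1))`, two-sided
normal p-values, optionally Holm-adjusted (default unadjusted). Hampel's
outlier rule flags values beyond the median ± 3 × 1.4826 × MAD; a zero MAD
with non-constant data falls back to flagging values off the median. The
χ² goodness-of-fit statistic is `Σ(obs − fit)²/fit` with df = n − number
of fitted parameters (the denominator and df convention are ours); p in
[0.05, 0.95] counts as a sufficient fit, p nearest 0.5 as best balanced.

## Degenerate inputs and tie-breaks

- Windows must cover ≥ 2 samples; masking needs ≥ 9.
- Equal-height shoulder candidates: widest-separated pair wins.
- Valley of a double peak: minimum strictly between the two maxima
  (plateau valleys resolve to the leftmost interior minimum).
- Legs shorter than 5 samples cannot be trimmed (no reliable inflection).
- A fit whose curve never exceeds 5 % of the data maximum is reported as
  failed ("no peak"), as is any non-finite or non-positive fitted curve.

## Problem sizes

Default sizes were chosen so the whole suite runs comfortably on one CPU:
the validation study uses 42 peaks on 601-sample tracks, the sensitivity
analysis 10 coverages × 42 peaks, and the ED50 coverage study 200 seeded
repetitions of a 10-dose × 4-replicate series.
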