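# Methods

This note records the models implemented in `skintrib`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Friction extraction

The instantaneous coefficient of friction is `|F_lateral| / F_normal` per
sample. Samples with normal force below `min_normal` (default 0.2 N) are
masked as `low-normal-force` rather than divided through: between strokes
the finger can partially unload and the ratio becomes unstable. Masked
samples are excluded from all statistics; no valid COF value is ever
discarded as an outlier (box-plot summaries report outliers beyond the
1.5 × IQR fences but keep them in every computation).

**Stroke segmentation** uses the sign of the lateral force, debounced by
a Schmitt trigger with a ±0.05 N hysteresis band: the direction state
only flips when the force crosses the opposite threshold, which
suppresses zero-crossing chatter at direction reversals. Runs shorter
than 0.25 s (10 samples at 40 Hz) are dropped and logged; adjacent
same-direction runs are merged. Indices are 0-based half-open spans
everywhere.

**Static/dynamic split.** Within a stroke, the static region runs from
the stroke start to the first sample attaining the stroke's maximum COF;
the dynamic region is the remainder minus a trailing 5 % trim covering
the deceleration into the reversal. This operationalizes the classic
morphology of a sliding stroke — static friction manifests as the initial
force peak, kinetic friction as the following plateau. Where the split
leaves fewer than 4 valid samples or an empty dynamic region, the stroke
is flagged unusable and logged, never silently filled. The summary
statistics are the 95th percentile of the static region and the median of
the dynamic region; the percentile convention is linear interpolation
between closest order statistics, applied identically everywhere a
percentile or quartile is taken, and oracle-tested against an independent
sort-and-interpolate implementation.

A declared convention, not a measurement: whether the static region
should begin at the force reversal or at motion onset is ambiguous in
this kind of experiment; the first-peak rule above is the package's
definition, chosen because it is deterministic and recovers the planted
ramp boundary of synthetic strokes to within 2 samples.

## Acoustic-emission features

**Spectra.** `compute_fft_spectrum` returns the one-sided amplitude
spectrum of the full record, scaled so a unit sinusoid at a bin frequency
has magnitude 1 (Parseval-consistent; checked to 1e-9 relative).
Spectral cleaning removes *singular* peaks — narrow spikes caused by
direction-reversal transients — detected on the peak-normalized scale
(record maximum = 1) with all three criteria: prominence within
0.01–0.1, height above 0.015, and a minimum separation between retained
peaks. The separation is stored in hertz (default 1.67 kHz, the value
that 50,000 bins correspond to for a 30 s record at 2 MSa/s) and
converted to bins per record, so the same physical criterion applies to
records of any length; a `min_distance_bins` override restores literal
bin-count behaviour. Removed peaks are filled by linear interpolation
between their prominence bases, clamped to the distance parameter and
never above the original magnitude, so all bins farther than the
distance parameter from a removed peak are returned bit-unchanged.
Normalizing the thresholds to the record's peak magnitude is itself a
design decision: the thresholds presuppose a scale, and the
peak-normalized scale is the only one that transfers across record
lengths and sensor gains. Raw-scale magnitudes are retained for
cross-record comparison; the band feature below is computed on the raw
scale.

**Band percentile.** The frequency-domain summary is the 90th percentile
of spectral magnitude in the closed 120–160 kHz band (at least 10 bins
required). For tones this feature responds through spectral leakage, so
it tracks amplitude linearly while remaining insensitive to single local
maxima.

**RMS envelope.** `x_RMS = sqrt(Σ x² / n)` over non-overlapping windows
aligned to sample 0, default 20,000 samples (0.01 s at 2 MSa/s); a
trailing partial window is dropped and logged. The profile is segmented
into strokes either by *transfer* (force-domain stroke boundaries
rescaled from force-sample to RMS-window indices; both streams are
assumed to start at t = 0 of the trial, with no cross-correlation
alignment) or *self* mode: stroke boundaries are local minima of the
5-window moving-average-smoothed envelope falling below 20 % of the
profile's 95th percentile. Profiles without such valley structure — the
behaviour of smooth planar substrates, where the sliding movements cannot
be separated — raise an explicit not-segmentable error. Self mode needs
strokes of roughly 0.75 s or longer for the inter-stroke valleys to
survive the window averaging; the transfer mode has no such floor. The
static/dynamic split and statistics are the same as for friction.

## Statistical layer

**PCA** is the eigendecomposition of the sample covariance matrix
(`ddof = 1`) of an observations × variables table; correlation mode
standardizes variables first and rejects constant variables by name.
Covariance mode on the raw 1–10 ratings is the default for sensory data:
the attributes share one scale, and the eigenvalues then carry squared
rating units (a six-attribute panel table yields eigenvalue sums far
above 6, which is how one can tell a covariance PCA from a correlation
PCA in a published variance table). Components are sign-fixed so each
component's largest-magnitude loading is positive, making outputs
deterministic. Observations are individual panellist × material
responses; material ellipsoids group the scores by material.

**Concentration ellipsoids** default to the population data-ellipse
convention: the group score covariance scaled by the chi-square quantile
at the 0.95 level — the region expected to contain 95 % of the group's
distribution, which is what "a confidence interval of the distribution
around the averaged point" describes. The F-based confidence region for
the group *mean* (a much smaller ellipsoid) is also implemented
(`scaling="f"`). Groups with fewer than `dims + 1` points or singular
covariance carry a degenerate flag.

**Tukey–Kramer.** Pooled within-group mean square across all groups;
pairwise `q = |m_i − m_j| / sqrt((MSE/2)(1/n_i + 1/n_j))`; p-values from
`scipy.stats.studentized_range` (numerical integration) with k groups and
N − k degrees of freedom; significance at p < α, default α = 0.05.
With equal group sizes this reduces exactly to the classical Tukey HSD
(cross-checked against an independent implementation to 1e-8 on q, and
against `scipy.stats.tukey_hsd` on p). When every group has zero
variance but means differ, p is reported at the numerical floor. The
family-wise error is controlled within one feature family at a time (one
panel per feature); no additional correction is applied across families.
The Monte-Carlo calibration helper decides significance by comparing the
maximum q against one precomputed critical value — the identical decision
rule, precomputed because per-pair numerical integration across thousands
of replicates would dominate the runtime.

**Combined tribology–sensory PCA** runs on the four tribological
variables (mean static/dynamic COF and AE RMS per material ×
participant) in correlation mode, since the variables carry different
units. Sensory attributes are overlaid as supplementary vectors — the
correlation of each attribute with each component's scores — so
perception is displayed against the physical axes without influencing
the decomposition. An attribute identical to an active variable
therefore points along that variable's biplot arrow (loading scaled by
the square root of the eigenvalue). Signed correlations are labelled
near-zero below |r| = 0.2.

## Synthetic-data generator

The generator emulates the study conditions: reciprocating strokes at a
target load of 2/3/4 N, 30 s recordings, 3 repeats, force channels at
40 Hz, AE at 2 MSa/s, 8 panellists. Values the study design leaves open
were fixed once as follows.

* **Stroke schedule**: uniform tiling of the trial duration with
  alternating directions; default 10 strokes per 30 s (3 s per stroke,
  ~3 cm/s over a 10 cm track — a plausible steady exploratory speed).
  Stroke count and velocity are fixture choices.
* **Stroke envelope**: linear ramp to the static peak
  `mu_static × load` over the first 20 % of the stroke (the peak is
  attained exactly at the last ramp sample), kinetic plateau
  `mu_dynamic × load`, linear decay to zero over the final 5 %.
* **Stick–slip** (planar presets): sinusoidal modulation of the plateau
  at 8 Hz with amplitude `stick_slip_amplitude ×` plateau.
* **Load tracking**: per-sample Gaussian error with sd 5 % of the target
  load plus a sinusoidal drift at 0.1 Hz with 5 % amplitude — imperfect
  manual load control. Additive lateral sensor noise has sd 0.02 N,
  below the segmentation hysteresis band.
* **AE synthesis**: white Gaussian noise restricted to 120–160 kHz by
  frequency-domain masking (constructed spectrally, which is
  distributionally identical and much cheaper), amplitude-modulated by
  the stroke envelope and scaled by `ae_band_level`; an unmodulated
  broadband floor of amplitude `ae_out_of_band_level` on top. Fabric
  presets have low floors, so their RMS envelopes show deep inter-stroke
  valleys; planar presets have floors comparable to their in-band level,
  reproducing the non-friction-like RMS profiles of smooth substrates.
* **Material presets**: six materials with dynamic-COF medians ordered
  PET film > enamel > PTFE ≈ terry > knit ≈ woven (all fabrics below
  0.5) and in-band AE levels ordered inversely. Knit and woven share
  `mu_dynamic` exactly: a pair that friction genuinely cannot separate,
  while their AE levels differ by 50 %. The exact numbers are fixture
  choices, not measured values. Sensory profiles plant the headline
  correlations (roughness with COF, pleasantness and slipperiness
  inversely with AE RMS).
* **Questionnaires**: planted material mean + Gaussian panellist noise
  (sd 0.8 rating units for untrained panellists), then an affine —
  hence rank-preserving — per-panellist-per-attribute rescale so the
  extreme grades 1 and 10 are each used at least once, matching the
  anchoring instruction; clipped to [1, 10].
* **Randomness**: one integer seed per trial; all draws from a single
  generator stream per trial.

What the generator does **not** emulate: finger contact mechanics and
skin hydration, acoustic propagation and sensor coupling physics,
audible-range (< 20 kHz) content, direction-asymmetric friction,
panellist idiosyncrasies beyond i.i.d. noise, and real inter-channel
clock skew. Passing recovery tests therefore demonstrates that the
extraction chain is correct and well-calibrated on signals with the
assumed morphology — not that it is robust to every artefact of real
recordings.

## Problem sizes and determinism

The default end-to-end report is desk-scale so a full study runs in
minutes on one CPU: 6 s trials with 8 strokes, AE at 0.4 MSa/s (the
120–160 kHz band stays below the 0.2 MHz Nyquist limit; RMS windows stay
at 0.01 s by using 4,000-sample windows), 3 simulated participants with
multiplicative friction (sd 5 %) and AE output (sd 10 %) effects, 3
loads × 3 repeats, 8 panellists. `TrialPlan` defaults remain at the full
study conditions (30 s, 2 MSa/s). All randomness flows from one root
seed through spawned per-trial sequences, so a report is bit-reproducible
from its resolved configuration.

The headline "inverse trend" check compares the material ordering of AE
band percentiles against the dynamic-COF ordering over the pairs whose
COF difference is statistically significant; the knit/woven pair is
planted as indistinguishable in friction, so its observed COF order is
noise and carries no ordering information — demanding a strict six-way
reversal there would test the random number generator, not the method.

## Known limitations

* Static-COF estimates ride on the declared first-peak split; traces
  whose true static peak is eroded by heavy filtering or very low
  sampling rates will bias it toward the plateau.
* Self-mode RMS segmentation requires valley dwell times longer than the
  smoothing span (≳ 3 windows); very fast strokes need transfer mode.
* The studentized-range p-values are accurate to the tolerance of
  `scipy.stats.studentized_range` (~1e-6 here); extremely large q report
  the numerical floor rather than exact zeros.
* Sensory ratings are modelled as continuous; ordinal-scale effects
  (category clumping) are not simulated.
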