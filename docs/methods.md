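# Methods

`jvmag` implements a noninvasive jugular-venous-pressure (JVP) video
pipeline: a neck video is segmented to a skin region, a video
photoplethysmogram (vPPG) extracted from that region fixes the cardiac
frequency band, jugular pulsations are amplified by phase-based Eulerian
motion magnification in that band, and paired JVP/right-atrial-pressure
(RAP) measurement tables are compared with categorical agreement
statistics. This note records the models, the parameters that matter, and
the design choices made where more than one defensible option existed.

## Imaging model and phantom

Real neck video shows two cardiac-synchronous signals: a subpixel
mechanical displacement of the skin over the internal jugular vein, and a
much weaker global color modulation of the skin (the photoplethysmographic
pulse). The synthetic phantom reproduces exactly these two signals and
nothing else: a skin-colored rectangle (70% of each frame dimension,
centered) on a contrasting background, containing a darker vertical stripe
whose two edges translate as `x(t) = x0 + delta * sin(2*pi*f*t)`, plus a
multiplicative sinusoid on the skin region, plus i.i.d. Gaussian sensor
noise, clipped to [0, 1].

Edges are rendered by integrating an error-function profile (scale 1 px by
default) across each pixel, so a displacement of 0.01 px changes pixel
values smoothly — the signal subpixel motion magnification feeds on.
Defaults: 96 x 72 px, 30 fps, 10 s, stripe width 8 px, `delta` = 0.1 px at
1.2 Hz (72 bpm), color-pulse amplitude 2% of channel range at the same
frequency. The jugular displacement amplitude of real skin is not an
established number; sub-0.5 px defaults are a modeling choice representing
"invisible to the naked eye".

What the phantom does *not* model: neck anatomy and texture, respiration
and swallowing motion, carotid-vs-jugular waveform morphology, specular
lighting, camera shake, compression artifacts. Passing phantom tests
therefore demonstrates correctness of the signal-processing chain, not
clinical performance on real video.

The measurement simulator draws one true RAP per participant from
`Normal(rap_mean, rap_sd)` (floored at 0, defaults 8.6 +/- 5.0 cm H2O,
matching a catheterization cohort with moderately elevated right-sided
pressures), and generates per-rater noninvasive values
`RAP + bias_modality + Normal(0, noise_sd)`. Noninvasive values are
deliberately *not* floored at zero so that the paired-difference model
`value - RAP = bias + noise` holds exactly; with the default geometry a few
tenths of a percent of simulated values can be slightly negative, which the
classification layer (correctly) refuses — analyses that classify simulated
values should use noise/bias settings that keep pressures positive.
Default rater counts are 2 (bedside) and 9 (each video modality).

## Segmentation

Per-pixel features are the two chroma coordinates (I, Q) of the YIQ
transform of the temporal median frame; luma is excluded to make the
clustering robust to illumination and shading. A Gaussian mixture with
K = 3 components (skin / background / shadowed or vessel skin) is fitted by
weighted EM, where each pixel's weight is an isotropic Gaussian spatial
prior centered on the frame (sigma = 0.35 * min(H, W)), encoding the
acquisition convention that the neck is framed centrally.

Weighted EM: responsibilities are the standard posteriors; M-step sufficient
statistics use `w_n * r_nk`. Uniform weights reduce exactly to standard EM
(tested against scikit-learn's `GaussianMixture` from the same
initialization). Initialization is weighted k-means++ refined by 10 Lloyd
iterations, with 3 seeded restarts keeping the best final weighted
log-likelihood; covariance eigenvalues are floored at 1e-6 to prevent
collapse. The weighted log-likelihood is non-decreasing across iterations
(asserted in tests).

Skin selection: every component whose mean chroma lies within 0.12 (I-Q
Euclidean distance) of a configurable skin reference (default (0.18, 0.05),
the chroma of a mid-tone skin color) is labeled skin. The distance rule —
rather than "nearest component only" — matters because shadowed or
vessel-darkened skin keeps its hue at lower saturation and clusters
separately; selecting only the nearest component can split the skin region
in two. The summed posterior is thresholded at 0.5, closed with a disk
whose radius scales with frame width (5 px at 1920), and the largest
connected component is kept (ties broken by lowest (row, column) anchor).
Segmentation yields one static mask per video: the tripod-stabilized,
near-static scene makes per-frame masks unnecessary, and a static mask
avoids mask-flicker in the vPPG. A mask covering under 1% of the frame is
treated as failure; callers fall back to a full-frame mask or supply one.

## vPPG and frequency band

The vPPG is the spatial mean of the green channel over the mask, linearly
detrended and demeaned; green carries the strongest photoplethysmographic
contrast in the remote-PPG literature. The heart rate is the peak of a
Welch periodogram (Hann window, ~20 s segments, 50% overlap — variance
reduction for ~60 s clips while retaining 0.05 Hz resolution) within a
physiologic search band of 0.7-3.0 Hz (42-180 bpm, comfortably bracketing
resting cardiology-clinic heart rates). The reported SNR is the peak-to-
median power ratio inside the search band, in dB; below `min_snr_db`
(default 3 dB) a no-periodicity error is raised and the pipeline falls
back to a configurable default band (0.9-1.5 Hz) with a warning. The
magnification band is `f_HR +/- 0.3 Hz` by default (absolute half-width;
a fractional mode is available), clipped inside (0, Nyquist).

## Complex steerable pyramid and magnification

The pyramid is built in the 2-D DFT domain with polar-separable filters:
raised-cosine log-radial windows in octave (default) or half-octave
spacing, times `cos^(K-1)` angular windows (K = 4 orientations default)
restricted to a half-plane, making subband coefficients complex (analytic)
with local amplitude and phase. Subbands are kept at full frame resolution
(no decimation): memory is affordable at the resolutions processed here,
and avoiding resampling keeps the per-coefficient temporal series exactly
aligned across frames.

Synthesis multiplies each subband spectrum by its analysis mask again,
adds the residuals, and divides by the numerically computed frame-energy
map `T(w) = (M(w) + M(-w))/2`, `M = H0^2 + sum A^2 + L^2`. Dividing by the
measured `T` rather than relying on an analytic tight-frame constant makes
reconstruction of an unmodified pyramid exact to floating point, so the
40 dB reconstruction requirement is met with orders of magnitude to spare
and `alpha = 0` is the identity up to single-precision arithmetic.

Magnification (per luma subband coefficient): phase differences against
frame 0 are unwrapped along time, band-pass filtered (brick-wall DFT mask
by default; order-2 zero-phase Butterworth available), optionally smoothed
spatially with an amplitude-weighted Gaussian, scaled by `alpha`, and added
back as `C * exp(i * alpha * filtered)`. Chroma passes through untouched
unless `chroma_attenuation > 0`. In-band motion of amplitude `delta` in
the oriented bands emerges with amplitude `(1 + alpha) * delta`; out-of-band
motion is untouched by construction of the temporal filter.

Pyramid depth default: the deepest octave pyramid whose coarsest band
still spans 4 px. Depth is the dominant accuracy parameter: structure
coarser than the deepest band falls into the (unamplified) lowpass
residual, and its motion is silently not magnified. With a 16 px floor the
measured gain on the standard phantom is ~25% short of `1 + alpha`; at the
4 px floor it is within ~10%. Videos are processed in 50%-overlapping
temporal chunks (default 1024 frames) blended with a linear cross-fade, in
single precision, so 60 s clips do not require whole-video FFTs in memory.
No hard cap is placed on `alpha`; a warning is emitted when amplified
phases are likely to exceed the finest band's quarter-wavelength support
(ringing regime).

Displacement measurement (the verification oracle, not part of the
enhancement path): a tracked patch is median-subtracted, tapered with a
flat-topped Tukey window (the taper suppresses the spurious static edge a
periodic DFT sees at the patch boundary; the flat top avoids amplitude
bias as long as the feature stays in the central ~70% of the patch), and
registered to frame 0 by phase correlation — an integer-resolution pass
followed by upsampled-DFT subpixel refinement of the re-aligned patch. The
reported amplitude is half the peak-to-peak excursion of the principal-axis
projection, optionally band-limited. On noiseless phantoms the oracle is
accurate to ~4% down to 0.01 px.

## Agreement statistics

Pressures are in cm H2O throughout. Rater assessments are averaged per
participant within modality; categories are boundary-inclusive: normal
(<= 7), borderline (> 7 and <= 10), elevated (> 10). Agreement with the
catheterization category is the absolute ordinal distance (0/1/2). The
category counts are tested with Pearson's chi-square against a uniform
expectation (total/3 per cell, df = 2). The paired pressures are summarized
by the mean difference with a Student-t 95% CI (the CI construction is an
assumption — the comparison scheme this reproduces does not state one) and
a two-sided Wilcoxon signed-rank test: zeros dropped, midranks for ties;
the exact null distribution is computed by convolution over sign
assignments for up to 25 nonzero differences (verified against exhaustive
enumeration for n <= 10 and against scipy's exact mode), and the normal
approximation with continuity and tie correction is used beyond.

## Problem sizes used in verification

The standard magnification check runs on a 128 x 128 px, 30 fps, 20 s
phantom (`delta` = 0.05 px at 1.2 Hz, `alpha` = 9, auto-band) — large
enough for a 5-octave pyramid and a 0.05 Hz-resolution spectrum while a
full run stays in the tens of seconds on one core. Heart-rate robustness
uses one hundred 32 x 24 px, 60 s phantoms at ~10 dB in-band spectral SNR.
Bias recovery uses one hundred simulated 48-participant tables with
modality biases (-2.9, -1.8, -0.8) cm H2O and 2 cm H2O rater noise,
checking ~95% CI coverage.

## Known limitations

- The magnification gain `(1 + alpha)` is accurate only for features whose
  spectral energy lies in the oriented bands; very coarse, low-contrast
  structure moves less than nominally magnified motion.
- Large amplified motions (beyond the finest band's quarter wavelength)
  produce ringing rather than clean translation; the tool warns but does
  not clip.
- The chroma-based segmentation assumes the skin region is the chroma
  cluster nearest a configured reference; strongly tinted lighting or
  backgrounds with skin-like chroma defeat it (supply a mask instead).
- Video I/O is restricted to lossless paths (PNG/TIFF directories,
  multi-page TIFF); compressed containers are out of scope.
- The measurement simulator models rater noise as i.i.d. Gaussian with a
  shared per-modality bias; it does not model rater-specific bias,
  value rounding, or censoring at high JVP ("above the earlobe").
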