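# jvmag

Noninvasive jugular venous pressure (JVP) from video: phase-based Eulerian
motion magnification of neck recordings, plus the agreement statistics for
validating noninvasive JVP estimates against invasive right-atrial
pressure (RAP).

## The problem

The height of the jugular venous pulsation column is the bedside proxy for
right-atrial pressure — the central measure of volume status in heart
failure — but the pulsation is a subtle, often invisible skin motion, and
bedside reads are unreliable. `jvmag` makes the pulsation visible: it
amplifies subpixel skin motion at the cardiac frequency so a clinician
(e.g., over a telehealth video link) can read the JVP from the enhanced
clip, and it provides the statistical machinery to compare such readings
against catheterization.

## The method

For a video `I(x, t)` the pipeline runs four stages:

1. **Neck segmentation** — chroma features of the temporal median frame are
   clustered by a *weighted* Gaussian-mixture EM (pixel weights from a
   centered spatial prior); the components nearest a skin-tone chroma
   reference, thresholded and cleaned morphologically, form a static skin
   mask.
2. **vPPG / heart rate** — the green channel averaged over the mask is a
   video photoplethysmogram; the peak of its Welch periodogram in
   0.7–3.0 Hz gives the heart rate f_HR, and the band of interest is
   [f_HR − Δ, f_HR + Δ] (Δ = 0.3 Hz default).
3. **Phase-based magnification** — each luma frame is decomposed into a
   complex steerable pyramid (octave radial bands × cos^(K−1) orientation
   windows). For each subband coefficient, the temporal phase signal
   φ(t) − φ(0) is band-passed to the cardiac band and amplified:

       C'(t) = C(t) · exp( i · α · B{φ(t) − φ(0)} )

   so in-band motion of amplitude δ is reconstructed with amplitude
   (1 + α)·δ while out-of-band motion passes unchanged.
4. **Agreement statistics** — rater-averaged pressures (cm H2O) are
   classified as normal (≤ 7), borderline (> 7, ≤ 10) or elevated (> 10);
   categories are compared with the catheterization category
   (agree / disagree-by-1 / disagree-by-2), tested by Pearson χ² against a
   uniform expectation, and paired values summarized by the mean
   difference, Student-t 95% CI and Wilcoxon signed-rank test.

A synthetic phantom generator (skin-toned region, vessel stripe with known
subpixel sinusoidal motion, weak color pulse, sensor noise) provides ground
truth for every stage; a phase-correlation displacement oracle measures
actual motion amplitudes in rendered video.

## Worked example

```bash
# render a phantom: 0.1 px vessel motion at 1.2 Hz, 72 bpm color pulse
jvmag phantom --out demo/phantom --duration 10 --seed 2

# end-to-end: segment -> vPPG -> band -> magnify (alpha defaults to 9)
jvmag run --input demo/phantom --out demo/out
```

which logs

```
band [0.900, 1.500] Hz, mask coverage 49.2% -> demo/out
```

— the vPPG found the 72 bpm pulse (1.2 Hz) and centered a ±0.3 Hz band on
it; the skin mask covers the phantom's skin rectangle. `demo/out/` holds
the magnified frames, the mask PNG and a `provenance.json` with every
stage's parameters and timings. Measuring the result from Python:

```python
from jvmag.video_io import read_frames
from jvmag.magnify import measure_displacement
from jvmag.vppg import FrequencyBand

band = FrequencyBand(0.9, 1.5)
before = read_frames("demo/phantom")
after = read_frames("demo/out/magnified")
roi = (24, 48, 34, 62)  # patch around the vessel stripe
print(measure_displacement(before, roi, band=band).amplitude)  # 0.1009 px
print(measure_displacement(after, roi, band=band).amplitude)   # 0.8756 px
```

the 0.1 px input motion leaves the magnified clip at ~0.88 px — a measured
gain of 8.7 against the nominal 1 + α = 10 (the shortfall is coarse stripe
energy living in the pyramid's unamplified lowpass residual; see
`docs/methods.md`).

The statistics stage runs on a measurement CSV
(`participant_id, modality, rater_id, value_cmH2O` with modalities
`bedside | unamplified | amplified | rhc`):

```bash
jvmag stats --input measurements.csv --out report/
```

writing per-modality descriptives, paired summaries and agreement tables
(`tables3_4.csv`, `summary.txt`).

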