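"""Synthetic video phantoms and simulated measurement tables.

The imaging phantom emulates what a neck video contributes to the pipeline:
a skin-toned region containing a vertical vessel-like stripe whose edges
oscillate with subpixel amplitude at a cardiac frequency, a weak global
color pulsation of the skin (the photoplethysmographic signal), and i.i.d.
sensor noise.  Edges are rendered by integrating an error-function profile
over each pixel, so fractional displacements change pixel intensities
continuously — the property subpixel motion magnification relies on.

The measurement simulator emulates paired jugular-venous-pressure readings:
one true right-atrial pressure per participant, plus modality-specific bias
and rater noise, in cm H2O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .video_io import FrameSequence

__all__ = [
    "PhantomSpec",
    "MeasurementTableSpec",
    "render_phantom",
    "simulate_measurements",
]

MODALITIES = ("bedside", "unamplified", "amplified")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic neck-video phantom.

    Defaults describe a small, well-conditioned scene: a centered skin patch
    with chroma well separated from the background, a 1.2 Hz (72 bpm)
    subpixel vessel oscillation, and a weak 1.2 Hz color pulse.
    """

    width: int = 96
    height: int = 72
    fps: float = 30.0
    duration: float = 10.0
    vessel_column: float = 48.0
    vessel_width: float = 8.0
    motion_amplitude: float = 0.1  # pixels, peak
    motion_frequency: float = 1.2  # Hz
    color_pulse_amplitude: float = 0.02  # fraction of channel range
    color_pulse_frequency: float = 1.2  # Hz
    skin_color: tuple[float, float, float] = (0.80, 0.55, 0.45)
    background_color: tuple[float, float, float] = (0.15, 0.25, 0.40)
    noise_sigma: float = 0.0
    seed: int = 0
    edge_softness: float = 1.0  # pixels; erf edge scale
    vessel_contrast: float = 0.4  # fractional darkening of the stripe
    quantize_8bit: bool = False

    def validate(self) -> None:
        nyq = self.fps / 2.0
        if max(self.motion_frequency, self.color_pulse_frequency) >= nyq:
            raise ValueError(
                "Nyquist violation: fps must exceed twice the motion and "
                f"color-pulse frequencies (fps={self.fps}, "
                f"f_motion={self.motion_frequency}, "
                f"f_color={self.color_pulse_frequency})"
            )
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        for name in ("skin_color", "background_color"):
            col = getattr(self, name)
            if not all(0.0 <= c <= 1.0 for c in col):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.width < 8 or self.height < 8:
            raise ValueError("phantom must be at least 8 x 8 pixels")


def _skin_mask(spec: PhantomSpec) -> np.ndarray:
    """Centered rectangular skin patch covering ~70% of each dimension."""
    h, w = spec.height, spec.width
    r0, r1 = int(round(0.15 * h)), int(round(0.85 * h))
    c0, c1 = int(round(0.15 * w)), int(round(0.85 * w))
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def _stripe_profile(x: np.ndarray, center: float, width: float, soft: float) -> np.ndarray:
    """Soft-edged box profile: 1 inside the stripe, 0 outside.

    Pixel-integrated erf edges so a fractional shift of `center` moves
    intensity smoothly.
    """
    left = center - width / 2.0
    right = center + width / 2.0
    s = soft * np.sqrt(2.0)
    return 0.5 * (erf((x - left) / s) - erf((x - right) / s))


def render_phantom(spec: PhantomSpec) -> tuple[FrameSequence, dict]:
    """Render the phantom and return it with its ground truth.

    Returns
    -------
    seq : FrameSequence
        ``duration * fps`` RGB frames in [0, 1].
    truth : dict
        ``delta`` (motion amplitude, px), ``f`` (motion frequency, Hz),
        ``f_color`` (color-pulse frequency, Hz), ``mask`` (boolean skin
        mask), ``vessel_column``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps))
    h, w = spec.height, spec.width
    skin = _skin_mask(spec)

    x = np.arange(w, dtype=np.float64)
    t = np.arange(n_frames, dtype=np.float64)
    centers = spec.vessel_column + spec.motion_amplitude * np.sin(
        2.0 * np.pi * spec.motion_frequency * t / spec.fps
    )
    pulse = 1.0 + spec.color_pulse_amplitude * np.sin(
        2.0 * np.pi * spec.color_pulse_frequency * t / spec.fps
    )

    skin_col = np.asarray(spec.skin_color)
    bg_col = np.asarray(spec.background_color)
    base = np.where(skin[..., None], skin_col, bg_col)  # H x W x 3

    frames = np.empty((n_frames, h, w, 3), dtype=np.float64)
    for i in range(n_frames):
        stripe = _stripe_profile(x, centers[i], spec.vessel_width, spec.edge_softness)
        # stripe darkens the skin only; background is static
        shade = 1.0 - spec.vessel_contrast * stripe[None, :] * skin
        frame = base * shade[..., None]
        gain = np.where(skin, pulse[i], 1.0)
        frames[i] = frame * gain[..., None]
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)
    if spec.quantize_8bit:
        frames = np.rint(frames * 255.0) / 255.0

    seq = FrameSequence(frames=frames, fps=spec.fps, colorspace="RGB",
                        source_bit_depth=8 if spec.quantize_8bit else 0)
    truth = {
        "delta": spec.motion_amplitude,
        "f": spec.motion_frequency,
        "f_color": spec.color_pulse_frequency,
        "mask": skin,
        "vessel_column": spec.vessel_column,
    }
    return seq, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Write the phantom ground truth as a JSON sidecar (mask as row runs)."""
    payload = {k: v for k, v in truth.items() if k != "mask"}
    payload["mask_shape"] = list(truth["mask"].shape)
    payload["mask_true_rows"] = [
        [int(a) for a in np.flatnonzero(row)[[0, -1]]] if row.any() else None
        for row in truth["mask"]
    ]
    Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class MeasurementTableSpec:
    """Parameters of the paired-measurement simulator.

    One latent right-atrial pressure (RAP) is drawn per participant from
    ``Normal(rap_mean, rap_sd)`` (clipped at 0).  Each noninvasive modality
    observes RAP plus a fixed bias plus per-rater Gaussian noise; the
    invasive catheterization row records the RAP itself.  Defaults follow a
    48-participant cohort with RAP 8.6 +/- 5 cm H2O and the bedside/
    unamplified/amplified biases -2.9 / -1.8 / -0.8 cm H2O.
    """

    n_participants: int = 48
    rap_mean: float = 8.6
    rap_sd: float = 5.0
    bias: dict = field(
        default_factory=lambda: {"bedside": -2.9, "unamplified": -1.8, "amplified": -0.8}
    )
    noise_sd: dict = field(
        default_factory=lambda: {"bedside": 2.0, "unamplified": 2.0, "amplified": 2.0}
    )
    n_raters: dict = field(
        default_factory=lambda: {"bedside": 2, "unamplified": 9, "amplified": 9}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for m in MODALITIES:
            if m not in self.bias or m not in self.noise_sd or m not in self.n_raters:
                raise ValueError(f"modality {m!r} missing from bias/noise_sd/n_raters")
            if self.noise_sd[m] < 0:
                raise ValueError("noise_sd must be >= 0")
            if self.n_raters[m] < 1:
                raise ValueError("n_raters must be >= 1")


def simulate_measurements(spec: MeasurementTableSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a paired JVP/RHC measurement table.

    Returns the long-format table with columns ``participant_id, modality,
    rater_id, value_cmH2O`` (one ``rhc`` row per participant plus
    ``n_raters`` rows per noninvasive modality) and the injected
    per-modality biases as ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rap = rng.normal(spec.rap_mean, spec.rap_sd, size=spec.n_participants)
    rap = np.clip(rap, 0.0, None)

    rows = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        rows.append((pid, "rhc", "cath_lab", rap[i]))
        for m in MODALITIES:
            noise = rng.normal(0.0, spec.noise_sd[m], size=spec.n_raters[m])
            for r in range(spec.n_raters[m]):
                # values deliberately not floored at 0: the paired-difference
                # model value - RAP = bias + noise must hold exactly
                value = rap[i] + spec.bias[m] + noise[r]
                rows.append((pid, m, f"{m}_r{r + 1}", value))
    table = pd.DataFrame(
        rows, columns=["participant_id", "modality", "rater_id", "value_cmH2O"]
    )
    return table, {"bias": dict(spec.bias), "rap": rap}
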