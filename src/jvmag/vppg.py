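"""Video photoplethysmography: pulse signal, heart rate, frequency band.

The vPPG is the spatial mean of the green channel over the segmented skin
region, per frame — the channel with the strongest photoplethysmographic
contrast.  The heart rate is the peak of a Welch-averaged periodogram
within a physiologic search band, and the magnification band of interest
is a window around that peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .video_io import FrameSequence

__all__ = [
    "FrequencyBand",
    "PpgSignal",
    "HeartRateEstimate",
    "NoPeriodicityError",
    "extract_vppg",
    "estimate_heart_rate",
    "band_from_hr",
    "DEFAULT_SEARCH_BAND",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A temporal frequency interval [lo, hi] in Hz."""

    lo: float
    hi: float

    def validate(self, fps: float | None = None) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band [{self.lo}, {self.hi}] Hz")
        if fps is not None and self.hi >= fps / 2:
            raise ValueError(
                f"band upper edge {self.hi} Hz at or above Nyquist ({fps / 2} Hz)"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: physiologic resting heart rates, 42-180 bpm
DEFAULT_SEARCH_BAND = FrequencyBand(0.7, 3.0)


class NoPeriodicityError(RuntimeError):
    """Raised when no sufficiently strong spectral peak is found."""


@dataclass
class PpgSignal:
    """Zero-mean detrended pulse waveform sampled at the video frame rate."""

    samples: np.ndarray
    fps: float

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class HeartRateEstimate:
    f_hr: float  # Hz
    snr_db: float  # peak power over median in-band power
    bin_width: float  # Hz

    @property
    def bpm(self) -> float:
        return self.f_hr * 60.0


def extract_vppg(
    seq: FrameSequence, mask: np.ndarray, channel: str = "green"
) -> PpgSignal:
    """Average the chosen channel over the masked region, detrend, demean."""
    if seq.n_frames < 2:
        raise ValueError("vPPG extraction needs at least 2 frames")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != seq.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {seq.frame_shape}"
        )
    if not mask.any():
        raise ValueError("empty mask: no pixels to average")

    if channel == "green":
        if seq.colorspace != "RGB":
            raise ValueError("green-channel extraction requires an RGB sequence")
        plane = seq.frames[..., 1]
    elif channel == "luma":
        if seq.colorspace == "RGB":
            plane = seq.frames @ np.array([0.299, 0.587, 0.114])
        else:
            plane = seq.frames[..., 0]
    else:
        raise ValueError(f"unknown vPPG channel {channel!r}")

    raw = plane[:, mask].mean(axis=1)
    detrended = _signal.detrend(raw, type="linear")
    return PpgSignal(samples=detrended - detrended.mean(), fps=seq.fps)


def periodogram(
    ppg: PpgSignal, segment_seconds: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged periodogram (50% overlap, ~20 s segments)."""
    nperseg = min(ppg.n, int(round(segment_seconds * ppg.fps)))
    nperseg = max(nperseg, 8)
    freqs, power = _signal.welch(
        ppg.samples, fs=ppg.fps, nperseg=nperseg, noverlap=nperseg // 2,
        window="hann", detrend=False,
    )
    return freqs, power


def estimate_heart_rate(
    ppg: PpgSignal,
    search_band: FrequencyBand = DEFAULT_SEARCH_BAND,
    min_snr_db: float = 3.0,
    segment_seconds: float = 20.0,
) -> HeartRateEstimate:
    """Locate the cardiac peak of the vPPG spectrum.

    Raises :class:`NoPeriodicityError` when the peak-to-median spectral
    ratio inside the search band falls below ``min_snr_db``.
    """
    search_band.validate(ppg.fps)
    if ppg.samples.std() < 1e-10:
        raise NoPeriodicityError("vPPG is constant: no cardiac signal present")
    freqs, power = periodogram(ppg, segment_seconds)
    bin_width = freqs[1] - freqs[0]
    in_band = (freqs >= search_band.lo) & (freqs <= search_band.hi)
    if in_band.sum() < 2:
        raise ValueError(
            "search band too narrow for the spectral resolution "
            f"({bin_width:.4f} Hz bins)"
        )
    band_power = power[in_band]
    peak_idx = int(np.argmax(band_power))
    peak = band_power[peak_idx]
    median = float(np.median(band_power))
    if median <= 0 or peak <= 0:
        raise NoPeriodicityError("vPPG spectrum is empty in the search band")
    snr_db = 10.0 * np.log10(peak / median)
    if snr_db < min_snr_db:
        raise NoPeriodicityError(
            f"no periodicity: in-band spectral SNR {snr_db:.1f} dB "
            f"below threshold {min_snr_db:.1f} dB"
        )
    f_hr = float(freqs[in_band][peak_idx])
    return HeartRateEstimate(f_hr=f_hr, snr_db=float(snr_db), bin_width=float(bin_width))


def band_from_hr(
    hr: HeartRateEstimate,
    fps: float,
    half_width_mode: str = "absolute",
    half_width_value: float = 0.3,
) -> FrequencyBand:
    """Window the magnification band around the estimated heart rate.

    ``half_width_mode='absolute'`` uses ``half_width_value`` Hz on each
    side; ``'fractional'`` uses ``half_width_value * f_hr``.  The band is
    clipped to the open interval (0, fps/2).
    """
    if half_width_mode == "absolute":
        delta = half_width_value
    elif half_width_mode == "fractional":
        delta = half_width_value * hr.f_hr
    else:
        raise ValueError(f"unknown half_width_mode {half_width_mode!r}")
    eps = 1e-6
    lo = max(hr.f_hr - delta, eps)
    hi = min(hr.f_hr + delta, fps / 2 - eps)
    if lo >= hi:
        raise ValueError(
            f"frequency band collapsed around f_hr={hr.f_hr} Hz "
            f"(delta={delta}, fps={fps})"
        )
    return FrequencyBand(lo, hi)
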