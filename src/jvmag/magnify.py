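"""Phase-based Eulerian motion magnification.

Each luma frame is decomposed into a complex steerable pyramid; per
subband coefficient, the temporal series of local phase (unwrapped relative
to the first frame) is band-pass filtered in the cardiac frequency band,
multiplied by the magnification factor ``alpha``, and added back before
frame reconstruction.  Motions whose temporal frequency falls inside the
band are amplified roughly ``(1 + alpha)``-fold while out-of-band motion
passes through unchanged; color is carried in the chroma channels and is
not amplified by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as _fft
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter
from skimage.registration import phase_cross_correlation

from .pyramid import build_filter_bank, max_feasible_scales
from .video_io import FrameSequence, from_luma_chroma, to_luma_chroma
from .vppg import FrequencyBand

__all__ = [
    "MagnificationConfig",
    "DisplacementTrace",
    "temporal_bandpass",
    "magnify_video",
    "measure_displacement",
]


@dataclass(frozen=True)
class MagnificationConfig:
    """Parameters of the magnification stage.

    alpha : dimensionless gain applied to the band-passed phase; the
        amplitude of in-band motion grows by about ``1 + alpha``.
    band : temporal frequency band of interest, Hz.
    n_scales : pyramid depth; ``None`` picks the deepest octave pyramid
        whose coarsest band spans at least 4 px (coarser structure falls
        into the lowpass residual, whose motion is not amplified).
    n_orientations : angular bands per scale.
    chroma_attenuation : fraction of ``alpha`` applied to the chroma
        channels (0 leaves color untouched).
    phase_smoothing_sigma : amplitude-weighted Gaussian smoothing of the
        filtered phase, in pixels; 0 disables.
    temporal_filter : ``"ideal-fft"`` (brick-wall DFT mask) or
        ``"iir-butterworth"`` (order-2 zero-phase Butterworth).
    chunk_size : frames per processing chunk; longer videos are processed
        in 50%-overlapping chunks blended with a linear cross-fade.
    """

    alpha: float = 9.0
    band: FrequencyBand = field(default_factory=lambda: FrequencyBand(0.9, 1.5))
    n_scales: int | None = None
    n_orientations: int = 4
    half_octave: bool = False
    chroma_attenuation: float = 0.0
    phase_smoothing_sigma: float = 0.0
    temporal_filter: str = "ideal-fft"
    chunk_size: int = 1024

    def validate(self, fps: float) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.band.validate(fps)
        if self.temporal_filter not in ("ideal-fft", "iir-butterworth"):
            raise ValueError(f"unknown temporal_filter {self.temporal_filter!r}")
        if not 0.0 <= self.chroma_attenuation <= 1.0:
            raise ValueError("chroma_attenuation must lie in [0, 1]")
        if self.chunk_size < 16:
            raise ValueError("chunk_size must be >= 16")


@dataclass
class DisplacementTrace:
    """Subpixel displacement of a tracked patch, per frame.

    ``shifts`` holds the (row, col) shift of each frame relative to frame 0;
    ``projected`` is the trace projected on the principal motion axis;
    ``amplitude`` is half the peak-to-peak excursion of the (optionally
    band-limited) projected trace, in pixels.
    """

    shifts: np.ndarray  # (T, 2)
    projected: np.ndarray  # (T,)
    amplitude: float


def temporal_bandpass(
    series: np.ndarray,
    band: FrequencyBand,
    fps: float,
    mode: str = "ideal-fft",
    axis: int = 0,
) -> np.ndarray:
    """Band-pass filter a time series along ``axis``.

    ``ideal-fft`` zeroes every DFT bin whose frequency lies outside
    ``[lo, hi]`` (band edges inclusive); ``iir-butterworth`` applies an
    order-2 Butterworth band-pass forward and backward (zero phase).
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[axis]
    if n < 8:
        raise ValueError("temporal filtering needs at least 8 samples")
    band.validate(fps)
    if mode == "ideal-fft":
        spec = np.fft.rfft(series, axis=axis)
        freqs = np.fft.rfftfreq(n, d=1.0 / fps)
        keep = (freqs >= band.lo) & (freqs <= band.hi)
        shape = [1] * series.ndim
        shape[axis] = len(freqs)
        spec *= keep.reshape(shape)
        return np.fft.irfft(spec, n=n, axis=axis)
    if mode == "iir-butterworth":
        sos = _signal.butter(
            2, [band.lo, band.hi], btype="bandpass", fs=fps, output="sos"
        )
        return _signal.sosfiltfilt(sos, series, axis=axis)
    raise ValueError(f"unknown temporal filter mode {mode!r}")


def _amplitude_weighted_smooth(
    phase: np.ndarray, amplitude: np.ndarray, sigma: float
) -> np.ndarray:
    """Spatially smooth filtered phases, weighting by coefficient amplitude."""
    num = gaussian_filter(phase * amplitude, sigma=(0, sigma, sigma))
    den = gaussian_filter(amplitude, sigma=(0, sigma, sigma))
    return num / np.maximum(den, 1e-12)


def _magnify_channel(
    frames: np.ndarray,
    fps: float,
    alpha: float,
    cfg: MagnificationConfig,
    n_scales: int,
) -> np.ndarray:
    """Phase-magnify a single (T, H, W) channel, processing band by band."""
    n_frames, h, w = frames.shape
    bank = build_filter_bank((h, w), n_scales, cfg.n_orientations, cfg.half_octave)

    # single precision: per-frame quantization is 8-16 bit anyway, and the
    # stack of per-band coefficient time series dominates memory
    spectra = _fft.fft2(frames.astype(np.float32), axes=(-2, -1))
    out_spec = spectra * (bank.highpass**2 + bank.lowpass**2).astype(np.float32)
    for mask in bank.band_masks.values():
        mask32 = mask.astype(np.float32)
        coeff = _fft.ifft2(spectra * mask32, axes=(-2, -1))
        if alpha > 0:
            delta = np.angle(coeff * np.conj(coeff[0]))
            delta = np.unwrap(delta, axis=0).astype(np.float32)
            filtered = temporal_bandpass(
                delta, cfg.band, fps, mode=cfg.temporal_filter, axis=0
            ).astype(np.float32)
            if cfg.phase_smoothing_sigma > 0:
                filtered = _amplitude_weighted_smooth(
                    filtered, np.abs(coeff), cfg.phase_smoothing_sigma
                ).astype(np.float32)
            coeff = coeff * np.exp(1j * alpha * filtered)
        out_spec += _fft.fft2(coeff, axes=(-2, -1)) * mask32
    out = _fft.ifft2(out_spec / bank.norm.astype(np.float32), axes=(-2, -1))
    return out.real.astype(np.float64)


def _chunked(frames: np.ndarray, chunk: int, fn) -> np.ndarray:
    """Apply ``fn`` over 50%-overlapping chunks with linear cross-fade."""
    n = frames.shape[0]
    if n <= chunk:
        return fn(frames)
    hop = chunk // 2
    out = np.zeros_like(frames)
    weight = np.zeros(n)
    ramp = np.minimum(np.arange(1, chunk + 1), np.arange(chunk, 0, -1)).astype(float)
    start = 0
    while start < n:
        stop = min(start + chunk, n)
        if stop - start < 16:  # tail too short to filter; fold into previous
            break
        piece = fn(frames[start:stop])
        wpiece = ramp[: stop - start]
        out[start:stop] += piece * wpiece[:, None, None]
        weight[start:stop] += wpiece
        if stop == n:
            break
        start += hop
    return out / weight[:, None, None]


def magnify_video(seq: FrameSequence, config: MagnificationConfig) -> FrameSequence:
    """Magnify motion in the configured frequency band.

    The sequence is converted to luma/chroma; the luma channel is
    phase-magnified (chroma too, at ``alpha * chroma_attenuation``, when
    attenuation is nonzero); frames are reconstructed, converted back to
    RGB and clipped to [0, 1].
    """
    if seq.n_frames < 16:
        raise ValueError("magnification needs at least 16 frames")
    config.validate(seq.fps)
    n_scales = config.n_scales
    if n_scales is None:
        n_scales = max_feasible_scales(seq.frame_shape)

    _warn_if_overdriven(config, n_scales)

    was_rgb = seq.colorspace == "RGB"
    yiq = to_luma_chroma(seq) if was_rgb else seq
    out = np.empty_like(yiq.frames)

    def run(alpha):
        return lambda stack: _magnify_channel(stack, seq.fps, alpha, config, n_scales)

    out[..., 0] = _chunked(yiq.frames[..., 0], config.chunk_size, run(config.alpha))
    chroma_alpha = config.alpha * config.chroma_attenuation
    for c in (1, 2):
        if chroma_alpha > 0:
            out[..., c] = _chunked(yiq.frames[..., c], config.chunk_size, run(chroma_alpha))
        else:
            out[..., c] = yiq.frames[..., c]

    result = replace(yiq, frames=out)
    if was_rgb:
        result = from_luma_chroma(result)
        result = replace(result, frames=np.clip(result.frames, 0.0, 1.0))
    return result


def _warn_if_overdriven(config: MagnificationConfig, n_scales: int) -> None:
    """Warn when alpha may push phases beyond the finest band's support.

    The finest octave band spans quarter-cycle phase shifts of about
    ``pi / 2`` at its center frequency (~``pi / 2`` rad/px); amplified
    phase excursions beyond ~``pi`` produce ringing artifacts.
    """
    if config.alpha > 0:
        # quarter-wavelength displacement bound of the finest band
        max_disp = 2.0 / (1.0 + config.alpha)
        if config.alpha > 25:
            warnings.warn(
                f"alpha={config.alpha:g} amplifies motions above "
                f"~{max_disp:.2f} px past the finest band's phase support; "
                "expect ringing for larger motions",
                stacklevel=3,
            )


def measure_displacement(
    seq: FrameSequence,
    roi: tuple[int, int, int, int],
    band: FrequencyBand | None = None,
    upsample_factor: int = 100,
) -> DisplacementTrace:
    """Track a patch's subpixel translation against frame 0.

    ``roi`` is ``(row0, row1, col0, col1)``.  Each frame's shift is found
    by phase correlation with subpixel (upsampled-DFT) peak interpolation.
    The per-frame shifts are projected on their principal axis; the
    reported amplitude is half the peak-to-peak excursion of that trace
    after optional band-limiting.
    """
    if seq.n_frames < 8:
        raise ValueError("displacement measurement needs at least 8 frames")
    r0, r1, c0, c1 = roi
    h, w = seq.frame_shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"roi {roi} outside frame of shape {(h, w)}")

    if seq.colorspace == "RGB":
        luma = seq.frames @ np.array([0.299, 0.587, 0.114])
    else:
        luma = seq.frames[..., 0]
    patches = luma[:, r0:r1, c0:c1]
    if patches[0].std() < 1e-9:
        warnings.warn("featureless ROI: displacement estimate is unreliable")

    # Median subtraction zeroes flat surround; the flat-topped Tukey taper
    # then kills the spurious static edge the periodic DFT sees at the patch
    # boundary without modulating (and thus biasing) the moving structure,
    # provided the tracked feature sits in the central ~70% of the patch.
    window = np.outer(
        _signal.windows.tukey(r1 - r0, 0.3), _signal.windows.tukey(c1 - c0, 0.3)
    )
    patches = patches - np.median(patches, axis=(1, 2), keepdims=True)
    ref = patches[0] * window

    shifts = np.zeros((seq.n_frames, 2))
    with warnings.catch_warnings():
        # our own featureless-ROI warning above covers the empty-patch case
        warnings.filterwarnings(
            "ignore", message="Could not determine RMS error"
        )
        for t in range(1, seq.n_frames):
            # integer stage first (peak location is robust under the
            # window), then windowed subpixel refinement on the re-aligned
            # patch, which keeps the window from modulating a largely
            # displaced feature
            coarse, _, _ = phase_cross_correlation(
                ref, patches[t] * window, upsample_factor=1, normalization=None
            )
            moved = np.roll(
                patches[t], (int(coarse[0]), int(coarse[1])), axis=(0, 1)
            )
            fine, _, _ = phase_cross_correlation(
                ref, moved * window, upsample_factor=upsample_factor,
                normalization=None,
            )
            shifts[t] = -(coarse + fine)  # displacement of frame t vs frame 0

    centered = shifts - shifts.mean(axis=0)
    if np.allclose(centered, 0):
        projected = np.zeros(seq.n_frames)
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        projected = centered @ vt[0]
    if band is not None:
        projected = temporal_bandpass(projected, band, seq.fps, mode="ideal-fft")
    amplitude = float(projected.max() - projected.min()) / 2.0
    return DisplacementTrace(shifts=shifts, projected=projected, amplitude=amplitude)
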