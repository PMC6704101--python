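"""Complex steerable pyramid in the frequency domain.

A single-scale-stack ("non-decimated") implementation: every oriented
subband is stored at full frame resolution.  Filters are polar-separable in
the 2-D DFT plane — raised-cosine log-radial windows with octave or
half-octave spacing, times ``cos^(K-1)`` angular windows restricted to a
half-plane, which makes the subband coefficients complex-valued (analytic)
with a meaningful local amplitude and phase.  Subpixel translation of image
content appears as a proportional shift of the local phase, which is what
the magnification stage amplifies.

Synthesis divides the accumulated spectrum by the numerically computed
frame-energy map ``T(w) = (M(w) + M(-w)) / 2`` with
``M = H0^2 + sum A^2 + L^2``, so reconstruction of an unmodified pyramid is
exact to floating-point precision rather than merely tight up to a filter
normalization constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "SteerablePyramid",
    "FilterBank",
    "build_filter_bank",
    "build_pyramid",
    "reconstruct_pyramid",
    "max_feasible_scales",
]

#: smallest acceptable extent (pixels) of the coarsest oriented band.
#: Depth matters: structure coarser than the deepest band falls into the
#: unamplified lowpass residual and its motion is not magnified, so the
#: default errs toward deep pyramids.
MIN_COARSE_SIZE = 4


def max_feasible_scales(shape: tuple[int, int]) -> int:
    """Largest octave depth whose coarsest band still spans >= 4 px."""
    return max(1, int(np.floor(np.log2(min(shape) / MIN_COARSE_SIZE))))


def _raised_cosine_lowpass(r: np.ndarray, cutoff: float) -> np.ndarray:
    """1 below cutoff/2, raised-cosine ramp to 0 at cutoff (log-radial)."""
    out = np.zeros_like(r)
    out[r <= cutoff / 2] = 1.0
    ramp = (r > cutoff / 2) & (r < cutoff)
    with np.errstate(divide="ignore"):
        out[ramp] = np.cos(np.pi / 2 * np.log2(2.0 * r[ramp] / cutoff))
    return out


@dataclass(frozen=True)
class FilterBank:
    """DFT-domain masks for one frame geometry.

    ``band_masks[(s, k)]`` is the half-plane (analytic) mask of scale ``s``,
    orientation ``k``; ``highpass`` / ``lowpass`` are the real residual
    masks; ``norm`` is the synthesis normalization map ``T``.
    """

    shape: tuple[int, int]
    n_scales: int
    n_orientations: int
    half_octave: bool
    highpass: np.ndarray
    lowpass: np.ndarray
    band_masks: dict
    norm: np.ndarray


@lru_cache(maxsize=8)
def build_filter_bank(
    shape: tuple[int, int],
    n_scales: int,
    n_orientations: int,
    half_octave: bool = False,
) -> FilterBank:
    """Construct the polar-separable mask bank for a frame shape.

    Raises ``ValueError`` (quoting the maximum feasible depth) if the frame
    is too small for the requested number of octaves.
    """
    h, w = shape
    feasible = max_feasible_scales(shape)
    if n_scales > feasible:
        raise ValueError(
            f"frame {shape} too small for {n_scales} scales; "
            f"maximum feasible depth is {feasible}"
        )
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")

    wy = 2 * np.pi * np.fft.fftfreq(h)[:, None]
    wx = 2 * np.pi * np.fft.fftfreq(w)[None, :]
    r = np.hypot(wy, wx)
    phi = np.arctan2(wy, wx)

    # telescoping radial decomposition: H0^2 + sum(band^2) + L^2 == 1
    step = 0.5 if half_octave else 1.0
    cutoffs = np.pi * 2.0 ** (-step * np.arange(0, n_scales + 1))
    lo_prev = _raised_cosine_lowpass(r, np.pi)
    highpass = np.sqrt(np.clip(1.0 - lo_prev**2, 0.0, None))
    radial = []
    for s in range(n_scales):
        lo_s = _raised_cosine_lowpass(r, cutoffs[s + 1])
        hi_s = np.sqrt(np.clip(1.0 - lo_s**2, 0.0, None))
        radial.append(lo_prev * hi_s)
        lo_prev = lo_prev * lo_s
    lowpass = lo_prev

    K = n_orientations
    band_masks = {}
    for k in range(K):
        theta = np.pi * k / K
        d = np.mod(phi - theta + np.pi, 2 * np.pi) - np.pi
        ang = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** max(K - 1, 0), 0.0)
        for s in range(n_scales):
            band_masks[(s, k)] = (radial[s] * ang).astype(np.float64)

    energy = highpass**2 + lowpass**2
    for m in band_masks.values():
        energy = energy + m**2
    # fold the conjugate half-plane in: real output sees (M(w)+M(-w))/2
    norm = 0.5 * (energy + energy[np.ix_(-np.arange(h) % h, -np.arange(w) % w)])
    if not (norm > 1e-12).all():
        raise RuntimeError("filter bank does not cover the frequency plane")
    return FilterBank(
        shape=shape,
        n_scales=n_scales,
        n_orientations=n_orientations,
        half_octave=half_octave,
        highpass=highpass,
        lowpass=lowpass,
        band_masks=band_masks,
        norm=norm,
    )


@dataclass
class SteerablePyramid:
    """Complex steerable decomposition of one frame."""

    levels: dict  # (scale, orientation) -> complex HxW array
    highpass_residual: np.ndarray
    lowpass_residual: np.ndarray
    n_scales: int
    n_orientations: int
    frame_shape: tuple[int, int]
    half_octave: bool = False


def build_pyramid(
    frame: np.ndarray,
    n_scales: int | None = None,
    n_orientations: int = 4,
    half_octave: bool = False,
) -> SteerablePyramid:
    """Decompose a 2-D (luma) frame into complex oriented subbands."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    if n_scales is None:
        n_scales = max_feasible_scales(frame.shape)
    bank = build_filter_bank(frame.shape, n_scales, n_orientations, half_octave)

    spectrum = np.fft.fft2(frame)
    levels = {
        key: np.fft.ifft2(spectrum * mask) for key, mask in bank.band_masks.items()
    }
    return SteerablePyramid(
        levels=levels,
        highpass_residual=np.fft.ifft2(spectrum * bank.highpass).real,
        lowpass_residual=np.fft.ifft2(spectrum * bank.lowpass).real,
        n_scales=n_scales,
        n_orientations=n_orientations,
        frame_shape=frame.shape,
        half_octave=half_octave,
    )


def reconstruct_pyramid(pyr: SteerablePyramid) -> np.ndarray:
    """Invert :func:`build_pyramid` (exact for an unmodified pyramid)."""
    bank = build_filter_bank(
        pyr.frame_shape, pyr.n_scales, pyr.n_orientations, pyr.half_octave
    )
    shape = pyr.frame_shape
    accum = np.zeros(shape, dtype=np.complex128)
    for key, mask in bank.band_masks.items():
        coeff = pyr.levels.get(key)
        if coeff is None or coeff.shape != shape:
            raise ValueError(f"pyramid level {key} missing or of wrong shape")
        accum += np.fft.fft2(coeff) * mask
    if pyr.highpass_residual.shape != shape or pyr.lowpass_residual.shape != shape:
        raise ValueError("residual shape does not match the frame shape")
    accum += np.fft.fft2(pyr.highpass_residual) * bank.highpass
    accum += np.fft.fft2(pyr.lowpass_residual) * bank.lowpass
    return np.fft.ifft2(accum / bank.norm).real
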