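"""Temporal filtering, magnification gain, and the displacement oracle."""

import numpy as np
import pytest

from conftest import psnr
from jvmag.magnify import (
    MagnificationConfig,
    magnify_video,
    measure_displacement,
    temporal_bandpass,
)
from jvmag.phantom import PhantomSpec, render_phantom
from jvmag.video_io import FrameSequence
from jvmag.vppg import FrequencyBand

BAND = FrequencyBand(0.9, 1.5)


class TestTemporalBandpass:
    fps = 30.0
    t = np.arange(300) / 30.0

    def test_in_band_tone_passes_unchanged(self):
        x = np.sin(2 * np.pi * 1.2 * self.t)
        y = temporal_bandpass(x, BAND, self.fps, "ideal-fft")
        assert np.abs(y - x).max() < 1e-6

    def test_out_of_band_tone_blocked(self):
        x = np.sin(2 * np.pi * 3.0 * self.t)
        y = temporal_bandpass(x, BAND, self.fps, "ideal-fft")
        assert np.abs(y).max() < 1e-6

    def test_superposition_keeps_only_in_band_tone(self):
        tone_in = np.sin(2 * np.pi * 1.2 * self.t)
        tone_out = 0.7 * np.sin(2 * np.pi * 4.0 * self.t)
        y = temporal_bandpass(tone_in + tone_out, BAND, self.fps, "ideal-fft")
        assert np.abs(y - tone_in).max() < 1e-6

    def test_butterworth_mode_selects_band(self):
        tone_in = np.sin(2 * np.pi * 1.2 * self.t)
        tone_out = np.sin(2 * np.pi * 6.0 * self.t)
        y = temporal_bandpass(tone_in + tone_out, BAND, self.fps, "iir-butterworth")
        # zero-phase IIR: in-band tone mostly preserved, far tone crushed
        assert np.corrcoef(y, tone_in)[0, 1] > 0.98
        out_residual = temporal_bandpass(
            np.sin(2 * np.pi * 6.0 * self.t), BAND, self.fps, "iir-butterworth"
        )
        # ignore filtfilt edge transients: check the interior
        assert np.abs(out_residual[60:-60]).max() < 0.05

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            temporal_bandpass(np.zeros(64), FrequencyBand(10.0, 20.0), self.fps)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_bandpass(np.zeros(4), BAND, self.fps)


@pytest.fixture(scope="module")
def moving_phantom():
    spec = PhantomSpec(width=96, height=96, fps=30, duration=10, vessel_column=48,
                       vessel_width=5, motion_amplitude=0.05, motion_frequency=1.2,
                       color_pulse_amplitude=0.0, noise_sigma=0.0, seed=21)
    return render_phantom(spec)[0]


ROI = (30, 66, 32, 64)


def test_alpha_zero_is_identity(moving_phantom):
    out = magnify_video(moving_phantom, MagnificationConfig(alpha=0.0, band=BAND))
    assert psnr(out.frames, moving_phantom.frames) >= 40


def test_magnification_is_deterministic(moving_phantom):
    cfg = MagnificationConfig(alpha=5.0, band=BAND)
    a = magnify_video(moving_phantom, cfg)
    b = magnify_video(moving_phantom, cfg)
    assert np.array_equal(a.frames, b.frames)


@pytest.mark.parametrize("alpha", [2.0, 9.0])
def test_in_band_gain_tracks_one_plus_alpha(moving_phantom, alpha):
    a_in = measure_displacement(moving_phantom, ROI, band=BAND).amplitude
    out = magnify_video(moving_phantom, MagnificationConfig(alpha=alpha, band=BAND))
    a_out = measure_displacement(out, ROI, band=BAND).amplitude
    assert a_out / a_in == pytest.approx(1 + alpha, rel=0.2)


def test_out_of_band_motion_not_amplified():
    spec = PhantomSpec(width=96, height=96, fps=30, duration=10, vessel_column=48,
                       vessel_width=5, motion_amplitude=0.05, motion_frequency=0.3,
                       color_pulse_amplitude=0.0, noise_sigma=0.0, seed=22)
    seq, _ = render_phantom(spec)
    slow = FrequencyBand(0.25, 0.35)
    a_in = measure_displacement(seq, ROI, band=slow).amplitude
    out = magnify_video(seq, MagnificationConfig(alpha=9.0, band=BAND))
    a_out = measure_displacement(out, ROI, band=slow).amplitude
    assert a_out / a_in <= 1.2


def test_chunked_processing_matches_band_behavior(moving_phantom):
    """50%-overlap chunking still amplifies the in-band motion."""
    cfg = MagnificationConfig(alpha=5.0, band=BAND, chunk_size=128)
    out = magnify_video(moving_phantom, cfg)
    a_in = measure_displacement(moving_phantom, ROI, band=BAND).amplitude
    a_out = measure_displacement(out, ROI, band=BAND).amplitude
    assert a_out / a_in == pytest.approx(6.0, rel=0.3)


def test_invalid_configs_rejected(moving_phantom):
    with pytest.raises(ValueError):
        magnify_video(moving_phantom, MagnificationConfig(alpha=-1.0, band=BAND))
    with pytest.raises(ValueError):
        magnify_video(
            moving_phantom,
            MagnificationConfig(band=FrequencyBand(10.0, 16.0)),
        )
    short = FrameSequence(frames=moving_phantom.frames[:8], fps=30.0)
    with pytest.raises(ValueError, match="16 frames"):
        magnify_video(short, MagnificationConfig(band=BAND))


class TestMeasureDisplacement:
    roi = (14, 34, 20, 44)  # stripe-centered patch of the 64x48 still phantom

    def test_static_video_has_zero_amplitude(self, still_frames):
        trace = measure_displacement(still_frames, self.roi)
        assert trace.amplitude <= 1e-3

    def test_integer_shift_recovered_exactly(self, still_frames):
        frames = np.repeat(still_frames.frames[:1], 8, axis=0)
        frames[1:] = np.roll(frames[1:], 3, axis=2)  # 3 px to the right
        seq = FrameSequence(frames=frames, fps=30.0)
        trace = measure_displacement(seq, (4, 44, 4, 60))
        assert trace.shifts[1, 1] == pytest.approx(3.0, abs=0.05)

    def test_moderate_amplitude_recovered(self):
        spec = PhantomSpec(width=64, height=48, fps=30, duration=10,
                           vessel_column=32, vessel_width=6,
                           motion_amplitude=0.3, motion_frequency=1.2,
                           color_pulse_amplitude=0.0, noise_sigma=0.0, seed=23)
        seq, _ = render_phantom(spec)
        trace = measure_displacement(seq, self.roi, band=BAND)
        assert trace.amplitude == pytest.approx(0.3, abs=0.03)

    def test_featureless_roi_warns(self, still_frames):
        with pytest.warns(UserWarning, match="featureless"):
            measure_displacement(still_frames, (0, 10, 0, 10))  # flat corner

    def test_roi_outside_frame_rejected(self, still_frames):
        with pytest.raises(ValueError, match="roi"):
            measure_displacement(still_frames, (0, 100, 0, 10))
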