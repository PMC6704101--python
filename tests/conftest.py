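import numpy as np
import pytest

from jvmag.phantom import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 64x48 phantom with 0.1 px motion at 1.2 Hz."""
    spec = PhantomSpec(
        width=64, height=48, fps=30, duration=10, vessel_column=32,
        vessel_width=6, motion_amplitude=0.1, motion_frequency=1.2,
        color_pulse_amplitude=0.02, color_pulse_frequency=1.2,
        noise_sigma=0.0, seed=11,
    )
    return render_phantom(spec)


@pytest.fixture(scope="session")
def still_frames():
    """A static, noiseless phantom sequence (no motion, no color pulse)."""
    spec = PhantomSpec(
        width=64, height=48, fps=30, duration=2, motion_amplitude=0.0,
        color_pulse_amplitude=0.0, noise_sigma=0.0, seed=5,
    )
    return render_phantom(spec)[0]


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    mse = np.mean((np.asarray(a) - np.asarray(b)) ** 2)
    if mse == 0:
        return np.inf
    return 10.0 * np.log10(peak**2 / mse)
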