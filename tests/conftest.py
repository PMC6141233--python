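import numpy as np
import pytest

from flymech.nyquist import NyquistFit
from flymech.sinusoidal import ComplexModulusSpectrum, LengthForceTrace


@pytest.fixture
def control_model() -> NyquistFit:
    """Three-process model with control-fiber amplitudes and rate constants
    (apparent rates 2*pi*b = 1036 s^-1, 2*pi*c = 5376 s^-1)."""
    return NyquistFit(A=339.0, k=0.12, alpha=1.0,
                      B=741.0, b=1036.0 / (2 * np.pi),
                      C=923.0, c=5376.0 / (2 * np.pi))


@pytest.fixture
def sweep_frequencies() -> np.ndarray:
    """The standard 50-point log-spaced sweep, 0.5-650 Hz."""
    return np.logspace(np.log10(0.5), np.log10(650.0), 50)


def spectrum_from_model(model: NyquistFit, freqs,
                        amplitude: float = 0.00125) -> ComplexModulusSpectrum:
    from flymech.nyquist import eval_model
    y = eval_model(model, np.asarray(freqs, dtype=float))
    return ComplexModulusSpectrum(np.asarray(freqs, dtype=float),
                                  y.real, y.imag, amplitude=amplitude)


def sinusoid_trace(e_elastic: float, e_viscous: float, frequency: float = 100.0,
                   amplitude: float = 0.00125, n_cycles: int = 10,
                   sample_rate: float = 20000.0, noise_sd: float = 0.0,
                   seed: int | None = None, offset: float = 0.0) -> LengthForceTrace:
    """Directly synthesized linear-response trace with known moduli."""
    n = int(np.ceil(n_cycles / frequency * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    w = 2 * np.pi * frequency
    strain = amplitude * np.sin(w * t)
    stress = offset + amplitude * (e_elastic * np.sin(w * t)
                                   + e_viscous * np.cos(w * t))
    if noise_sd:
        rng = np.random.default_rng(seed)
        amp = amplitude * float(np.hypot(e_elastic, e_viscous))
        stress = stress + rng.normal(0.0, noise_sd * amp, size=n)
    return LengthForceTrace(time=t, strain=strain, stress=stress,
                            drive_frequency=frequency, amplitude=amplitude)
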