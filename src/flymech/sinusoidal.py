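"""Small-amplitude sinusoidal analysis of skinned muscle fibers.

An active fiber is driven with a small (0.125% muscle length) sinusoidal
length change at a series of frequencies while force is recorded.  The
complex modulus Y(f) = E'(f) + i E''(f) is the stress/strain transfer
function at the drive frequency: E' (elastic modulus) is the in-phase
component, E'' (viscous modulus) the quadrature component.  For a muscle
doing net work on the apparatus E'' < 0, and the work per cycle per unit
volume is W(f) = -pi * eps0^2 * E''(f) with power P(f) = W(f) * f.

Moduli are handled in kN/m^2 (= kPa); strain is a dimensionless fraction
of muscle length; work and power come out in J/m^3 and W/m^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: conversion of (dimensionless strain)^2 * (kN/m^2) products to J/m^3
KPA_TO_J_PER_M3 = 1000.0

#: default number of initial drive cycles dropped as transient settling
DEFAULT_DROP_CYCLES = 2

#: relative residual of the strain fit above which the trace is flagged
HARMONIC_DISTORTION_LIMIT = 0.10


@dataclass(frozen=True)
class FiberGeometry:
    """Mounted fiber dimensions used to normalize force and length.

    Parameters
    ----------
    length : float
        Fiber length between the clips, m.
    cross_sectional_area : float
        Cross-sectional area from width/height measurement, m^2.
    """

    length: float
    cross_sectional_area: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.cross_sectional_area <= 0:
            raise ValueError("fiber length and cross-sectional area must be positive")

    @property
    def volume(self) -> float:
        """Fiber volume in m^3."""
        return self.length * self.cross_sectional_area

    def stretched(self, offset_pct: float) -> "FiberGeometry":
        """Geometry after stretching by ``offset_pct`` percent of muscle length."""
        return FiberGeometry(self.length * (1.0 + offset_pct / 100.0),
                             self.cross_sectional_area)


@dataclass
class LengthForceTrace:
    """Sampled strain and stress of one fiber under one drive protocol.

    ``strain`` is the imposed length change as a fraction of muscle length,
    ``stress`` the force per cross-sectional area in kN/m^2, both on the
    uniform time grid ``time`` (s).  ``amplitude`` is the strain amplitude
    eps0 (half the peak-to-peak excursion).  ``condition`` records the
    bathing solution (pCa, ATP and Pi in mM).  ``metadata`` may carry
    generator ground truth.
    """

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    drive_frequency: float
    amplitude: float
    condition: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if not (self.time.shape == self.strain.shape == self.stress.shape):
            raise ValueError("time, strain and stress must have equal length")
        if self.time.size < 4:
            raise ValueError("trace too short")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace must be uniformly sampled")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def n_cycles(self) -> int:
        """Number of complete drive cycles contained in the trace."""
        span = self.time[-1] - self.time[0]
        # guard against span = k/f - eps from float rounding
        return int(np.floor(span * self.drive_frequency + 1e-9))

    def check_amplitude(self, rtol: float = 0.05) -> None:
        """Verify the recorded strain excursion matches the stated amplitude."""
        if self.amplitude == 0:
            return
        half_pp = 0.5 * (self.strain.max() - self.strain.min())
        if abs(half_pp - self.amplitude) > rtol * self.amplitude:
            raise ValueError(
                f"strain excursion {half_pp:.4g} inconsistent with stated "
                f"amplitude {self.amplitude:.4g}"
            )


@dataclass
class ComplexModulusSpectrum:
    """Per-frequency elastic and viscous moduli at one drive amplitude."""

    frequencies: np.ndarray
    elastic_modulus: np.ndarray
    viscous_modulus: np.ndarray
    amplitude: float
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.elastic_modulus = np.asarray(self.elastic_modulus, dtype=float)
        self.viscous_modulus = np.asarray(self.viscous_modulus, dtype=float)
        if not (self.frequencies.shape == self.elastic_modulus.shape
                == self.viscous_modulus.shape):
            raise ValueError("spectrum arrays must have equal length")
        if self.frequencies.size and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def complex_modulus(self) -> np.ndarray:
        return self.elastic_modulus + 1j * self.viscous_modulus


class ModulusEstimate(NamedTuple):
    elastic: float
    viscous: float


@dataclass(frozen=True)
class TensionMeasurement:
    """Passive (pCa 8), active (pCa 5) and net isometric tension, kN/m^2."""

    passive_P0: float
    active_A0: float

    @property
    def net_F0(self) -> float:
        return self.active_A0 - self.passive_P0


@dataclass
class SpectrumSummary:
    """Scalar summary of a modulus spectrum."""

    f_max: float          # Hz, frequency of maximum power
    power_max: float      # W/m^3
    f_wmax: float         # Hz, frequency of maximum work
    work_max: float       # J/m^3
    stiffness_500hz: float  # kN/m^2, E' at the grid point nearest 500 Hz
    boundary_flag: bool = False   # optimum sits on the edge of the grid


def _phasor(time: np.ndarray, signal: np.ndarray, frequency: float) -> tuple[complex, float, float]:
    """Least-squares projection of ``signal`` onto {1, sin, cos} at ``frequency``.

    Returns (phasor, offset, relative residual).  The phasor convention is
    p + i q for signal p*sin(w t) + q*cos(w t), so a pure sine maps to a
    positive real number.
    """
    w = 2.0 * np.pi * frequency
    design = np.column_stack([np.ones_like(time), np.sin(w * time), np.cos(w * time)])
    coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
    offset, p, q = coef
    resid = signal - design @ coef
    amp = np.hypot(p, q)
    rel = np.sqrt(np.mean(resid**2)) / amp if amp > 0 else np.inf
    return complex(p, q), float(offset), float(rel)


def analysis_window(trace: LengthForceTrace,
                    drop_cycles: int = DEFAULT_DROP_CYCLES) -> slice:
    """Window of whole drive cycles at the end of the trace.

    The first ``drop_cycles`` cycles are discarded as transient settling;
    the window is trimmed to an integer number of cycles so that the sin
    and cos regressors stay orthogonal.
    """
    n = trace.n_cycles
    keep = n - drop_cycles
    if keep < 2:
        raise ValueError(
            f"need at least {drop_cycles + 2} complete cycles, trace has {n}"
        )
    period = 1.0 / trace.drive_frequency
    t_end = trace.time[0] + n * period
    t_start = t_end - keep * period
    i0 = int(np.searchsorted(trace.time, t_start - 1e-12))
    i1 = int(np.searchsorted(trace.time, t_end + 1e-12))
    return slice(i0, min(i1, trace.time.size))


def extract_complex_modulus(trace: LengthForceTrace,
                            drop_cycles: int = DEFAULT_DROP_CYCLES) -> ModulusEstimate:
    """Elastic and viscous moduli at the drive frequency.

    Both strain and stress are projected onto {1, sin, cos} at the drive
    frequency over the analysis window; the modulus is the ratio of the
    stress and strain phasors, so the estimate is insensitive to the phase
    origin of the time axis.  A strain residual above 10% of the strain
    amplitude raises a harmonic-distortion warning.
    """
    win = analysis_window(trace, drop_cycles)
    t = trace.time[win]
    f = trace.drive_frequency
    z_strain, _, strain_resid = _phasor(t, trace.strain[win], f)
    z_stress, _, _ = _phasor(t, trace.stress[win], f)
    if strain_resid > HARMONIC_DISTORTION_LIMIT:
        warnings.warn(
            f"strain harmonic distortion {strain_resid:.1%} exceeds "
            f"{HARMONIC_DISTORTION_LIMIT:.0%}; modulus estimate may be biased",
            stacklevel=2,
        )
    if abs(z_strain) == 0:
        raise ValueError("strain carries no power at the drive frequency")
    y = z_stress / z_strain
    return ModulusEstimate(elastic=float(y.real), viscous=float(y.imag))


def sweep_spectrum(traces: Sequence[LengthForceTrace],
                   drop_cycles: int = DEFAULT_DROP_CYCLES) -> ComplexModulusSpectrum:
    """Assemble a frequency sweep from one trace per drive frequency."""
    if not traces:
        raise ValueError("no traces given")
    amp = traces[0].amplitude
    cond = traces[0].condition
    freqs = [tr.drive_frequency for tr in traces]
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate drive frequencies in sweep")
    for tr in traces:
        if not np.isclose(tr.amplitude, amp, rtol=1e-6):
            raise ValueError("mixed drive amplitudes in sweep")
        if tr.condition != cond:
            raise ValueError("mixed solution conditions in sweep")
    order = np.argsort(freqs)
    est = [extract_complex_modulus(traces[i], drop_cycles) for i in order]
    return ComplexModulusSpectrum(
        frequencies=np.asarray(freqs)[order],
        elastic_modulus=np.array([e.elastic for e in est]),
        viscous_modulus=np.array([e.viscous for e in est]),
        amplitude=amp,
        condition=dict(cond),
    )


def work_and_power(spectrum: ComplexModulusSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency net work (J/m^3) and power (W/m^3) from the moduli.

    W(f) = -pi * eps0^2 * E''(f): positive when the viscous modulus is
    negative, i.e. when the fiber does net work on the apparatus.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    work = -np.pi * spectrum.amplitude**2 * spectrum.viscous_modulus * KPA_TO_J_PER_M3
    power = work * spectrum.frequencies
    return work, power


def summarize_spectrum(spectrum: ComplexModulusSpectrum,
                       stiffness_frequency: float = 500.0) -> SpectrumSummary:
    """Locate maximum power/work and read off high-frequency stiffness.

    Optima are reported at measured grid frequencies (no interpolation,
    matching the discrete measurement protocol).  Stiffness is E' at the
    grid point nearest ``stiffness_frequency``, which must lie within 10%
    of it.  An optimum on the grid boundary sets ``boundary_flag``.
    """
    if len(spectrum) < 3:
        raise ValueError("need at least 3 frequencies to summarize")
    work, power = work_and_power(spectrum)
    ip = int(np.argmax(power))
    iw = int(np.argmax(work))
    boundary = ip in (0, len(spectrum) - 1) or iw in (0, len(spectrum) - 1)
    if boundary:
        warnings.warn("power/work optimum on the boundary of the frequency grid",
                      stacklevel=2)
    inear = int(np.argmin(np.abs(spectrum.frequencies - stiffness_frequency)))
    fnear = spectrum.frequencies[inear]
    if abs(fnear - stiffness_frequency) > 0.10 * stiffness_frequency:
        raise ValueError(
            f"no measured frequency within 10% of {stiffness_frequency} Hz "
            f"(nearest: {fnear} Hz)"
        )
    return SpectrumSummary(
        f_max=float(spectrum.frequencies[ip]),
        power_max=float(power[ip]),
        f_wmax=float(spectrum.frequencies[iw]),
        work_max=float(work[iw]),
        stiffness_500hz=float(spectrum.elastic_modulus[inear]),
        boundary_flag=boundary,
    )


def _find_plateau(time: np.ndarray, stress: np.ndarray,
                  max_slope_frac: float = 0.01,
                  min_fraction: float = 0.2) -> slice:
    """Latest window of at least ``min_fraction`` of the trace whose fitted
    slope is below ``max_slope_frac`` of the window mean per second."""
    n = time.size
    wlen = max(int(min_fraction * n), 3)
    for start in range(n - wlen, -1, -max(wlen // 4, 1)):
        sl = slice(start, start + wlen)
        t, s = time[sl], stress[sl]
        mean = np.mean(s)
        slope = np.polyfit(t, s, 1)[0]
        if abs(slope) <= max_slope_frac * abs(mean) or mean == 0 and abs(slope) < 1e-12:
            return sl
    raise ValueError("no plateau found (slope criterion never satisfied)")


def measure_tension(passive_trace: LengthForceTrace,
                    active_trace: LengthForceTrace) -> TensionMeasurement:
    """Isometric tension from relaxed (pCa 8) and activated (pCa 5) traces.

    P0 and A0 are the mean stress over the latest plateau (fitted slope
    below 1%/s of the plateau mean); the net tension F0 = A0 - P0.
    """
    p_sl = _find_plateau(passive_trace.time, passive_trace.stress)
    a_sl = _find_plateau(active_trace.time, active_trace.stress)
    p0 = float(np.mean(passive_trace.stress[p_sl]))
    a0 = float(np.mean(active_trace.stress[a_sl]))
    return TensionMeasurement(passive_P0=p0, active_A0=a0)
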