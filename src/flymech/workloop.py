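"""Work-loop analysis: net work, work generated/absorbed and power from
large-amplitude force-length cycles.

A fiber driven through cyclic length changes traces a loop in the
(length, force) plane.  Integrating force over the length change splits
the cycle into work generated during shortening and work absorbed during
lengthening; their difference is the net work per cycle (the signed loop
area), positive for counter-clockwise traversal, i.e. when the muscle
does net work on the apparatus.  Power is net work times the cycling
frequency.  Work is expressed per unit fiber volume (J/m^3), so the
integral reduces to the stress-strain loop area times 1000 (kN/m^2 ->
J/m^3).

The module also implements the two experimental search protocols: the
amplitude x frequency grid search for maximum power, and the iterative
2%-muscle-length stretch that stops once the power gain drops to 3%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sinusoidal import KPA_TO_J_PER_M3, FiberGeometry, LengthForceTrace

#: measurement cycle used by default ("cycles 7 or 8" become consistent
#: after the initial transient; 8 is fixed here and exposed as an option)
DEFAULT_MEASUREMENT_CYCLE = 8

#: loop endpoints may differ by at most this fraction of the excursion
CLOSURE_RTOL = 0.01


@dataclass
class WorkLoopResult:
    """Energetics of one force-length cycle, per unit fiber volume."""

    work_generated: float   # J/m^3, >= 0
    work_absorbed: float    # J/m^3, >= 0
    frequency: float        # Hz
    amplitude_pct_ml: float
    cycle_index: int

    def __post_init__(self) -> None:
        if self.work_generated < 0 or self.work_absorbed < 0:
            raise ValueError("work components must be non-negative")

    @property
    def net_work(self) -> float:
        return self.work_generated - self.work_absorbed

    @property
    def power(self) -> float:
        return self.net_work * self.frequency

    @property
    def direction(self) -> str:
        return "counter_clockwise" if self.net_work > 0 else "clockwise"


def loop_power(result: WorkLoopResult) -> float:
    """Power = net work x oscillation frequency (W/m^3)."""
    return result.net_work * result.frequency


def cycle_bounds(trace: LengthForceTrace) -> list[tuple[int, int]]:
    """Cycle delimiters: strain upward zero-crossings about the strain mean.

    Crossing times are located by linear interpolation and snapped to the
    nearest sample, so float noise at the sine zeros cannot shift a
    boundary by a sample.  Returns (start, end) index pairs; the end index
    is the start of the next cycle, so slices include the closing sample.
    """
    s = trace.strain - np.mean(trace.strain)
    ptp = np.ptp(s)
    raw = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    bounds: list[int] = []
    for i in raw:
        frac = s[i] / (s[i] - s[i + 1])  # in [0, 1)
        bounds.append(int(i) if frac < 0.5 else int(i) + 1)
    if ptp > 0 and abs(s[0]) < 0.01 * ptp and s[1] > s[0]:
        if not bounds or bounds[0] > 1:
            bounds.insert(0, 0)
    bounds = sorted(set(bounds))
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def integrate_loop(trace: LengthForceTrace, cycle_index: int,
                   geometry: FiberGeometry | None = None) -> WorkLoopResult:
    """Trapezoidal work integrals over one cycle (1-based ``cycle_index``).

    Work generated sums force times (-dL) over shortening steps
    (dL < 0), work absorbed sums force times dL over lengthening steps;
    steps with dL = 0 contribute to neither.  Since stress and strain are
    already normalized, the per-volume result does not depend on
    ``geometry`` (accepted for interface symmetry with raw force/length
    data).  A cycle whose strain endpoints differ by more than 1% of the
    excursion is rejected as open.
    """
    bounds = cycle_bounds(trace)
    if not 1 <= cycle_index <= len(bounds):
        raise ValueError(
            f"cycle {cycle_index} not contained in trace ({len(bounds)} cycles)"
        )
    a, b = bounds[cycle_index - 1]
    eps = trace.strain[a:b + 1]
    sig = trace.stress[a:b + 1]
    excursion = float(np.ptp(eps))
    if excursion == 0:
        raise ValueError("degenerate cycle: no strain excursion")
    if abs(eps[-1] - eps[0]) > CLOSURE_RTOL * excursion:
        raise ValueError("open cycle: strain endpoints differ by more than 1% "
                         "of the excursion")
    # a drifting drive also shows up as a cycle length away from the drive
    # period (tolerance widened to 1.5 samples for coarse sampling)
    period = 1.0 / trace.drive_frequency
    duration = float(trace.time[b] - trace.time[a])
    samples_per_cycle = period * trace.sample_rate
    tol = max(CLOSURE_RTOL, 1.5 / samples_per_cycle)
    if abs(duration / period - 1.0) > tol:
        raise ValueError("open cycle: cycle length deviates from the drive "
                         "period by more than the closure tolerance")
    d_eps = np.diff(eps)
    sig_mid = 0.5 * (sig[:-1] + sig[1:])
    shortening = d_eps < 0
    lengthening = d_eps > 0
    gen = float(np.sum(sig_mid[shortening] * (-d_eps[shortening]))) * KPA_TO_J_PER_M3
    absd = float(np.sum(sig_mid[lengthening] * d_eps[lengthening])) * KPA_TO_J_PER_M3
    return WorkLoopResult(
        work_generated=gen,
        work_absorbed=absd,
        frequency=trace.drive_frequency,
        amplitude_pct_ml=100.0 * trace.amplitude,
        cycle_index=cycle_index,
    )


@dataclass
class WorkLoopOptimum:
    amplitude_pct_ml: float
    frequency: float
    result: WorkLoopResult
    grid: pd.DataFrame = field(repr=False)
    all_negative: bool = False


def optimize_workloop(fiber: Callable[[float, float], LengthForceTrace],
                      amplitudes_pct_ml: Sequence[float],
                      frequencies: Sequence[float],
                      cycle: int = DEFAULT_MEASUREMENT_CYCLE) -> WorkLoopOptimum:
    """Exhaustive amplitude x frequency grid search for maximum power.

    ``fiber(amplitude_pct_ml, frequency)`` must return a trace containing
    at least ``cycle`` full cycles; the configured measurement cycle of
    each trace is integrated.  The argmax of power is returned together
    with the full grid table.  The scan order is sorted, and only a
    strictly larger power displaces the incumbent, so the result does not
    depend on the order of the input grids.  If every grid cell absorbs
    net work, the least-negative cell is returned with ``all_negative``
    set.
    """
    if not len(amplitudes_pct_ml) or not len(frequencies):
        raise ValueError("amplitude and frequency grids must be non-empty")
    rows = []
    best: tuple[float, float, float, WorkLoopResult] | None = None
    for amp in sorted(amplitudes_pct_ml):
        for freq in sorted(frequencies):
            res = integrate_loop(fiber(amp, freq), cycle)
            rows.append({"amplitude_pct_ml": amp, "frequency_hz": freq,
                         "net_work_j_m3": res.net_work,
                         "work_generated_j_m3": res.work_generated,
                         "work_absorbed_j_m3": res.work_absorbed,
                         "power_w_m3": res.power})
            if best is None or res.power > best[0]:
                best = (res.power, amp, freq, res)
    assert best is not None
    power, amp, freq, res = best
    all_negative = power < 0
    if all_negative:
        warnings.warn("all grid cells absorb net work; returning the "
                      "least-negative cell", stacklevel=2)
    return WorkLoopOptimum(amplitude_pct_ml=amp, frequency=freq, result=res,
                           grid=pd.DataFrame(rows), all_negative=all_negative)


def optimize_muscle_length(fiber: Callable[[float], float],
                           step_pct: float = 2.0,
                           stop_gain_pct: float = 3.0,
                           max_steps: int = 25) -> tuple[float, pd.DataFrame]:
    """Stretch in ``step_pct`` increments until power gain <= ``stop_gain_pct``.

    ``fiber(offset_pct)`` returns the power at a cumulative stretch of
    ``offset_pct`` percent muscle length.  After each step, the relative
    power gain over the previous length is compared to the stop
    threshold; a gain exactly equal to the threshold stops (boundary
    inclusive).  Returns the final offset and the (offset, power) trace.
    """
    offset = 0.0
    power_prev = fiber(offset)
    rows = [{"offset_pct": offset, "power": power_prev}]
    for _ in range(max_steps):
        offset += step_pct
        power = fiber(offset)
        rows.append({"offset_pct": offset, "power": power})
        if power_prev > 0:
            gain_pct = 100.0 * (power - power_prev) / power_prev
        else:
            # from non-positive power, any non-positive change stops
            gain_pct = np.inf if power > power_prev else -np.inf
        if gain_pct <= stop_gain_pct:
            return offset, pd.DataFrame(rows)
        power_prev = power
    raise RuntimeError(f"no power plateau within {max_steps} stretch steps")
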