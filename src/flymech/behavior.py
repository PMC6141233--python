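"""Flight index and wingbeat frequency.

Flight ability is scored by releasing flies and recording whether each
flies up (U), horizontal (H), down (D) or not at all (N).  The flight
index is the weighted fraction

    FI = (6 U + 4 H + 2 D + 0 N) / T,    T = U + H + D + N,

ranging from 0 (none fly) to 6 (all fly upward).  Wingbeat frequency is
estimated from an optical-tachometer trace of a tethered fly as the
dominant periodogram peak within a physiological band, refined by
parabolic interpolation of the peak and its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

#: physiological wingbeat band, Hz (covers 15-22 degC Drosophila values)
DEFAULT_WBF_BAND = (80.0, 300.0)
#: required peak power relative to the median band power
PEAK_TO_MEDIAN_MIN = 5.0


@dataclass(frozen=True)
class FlightCounts:
    """Outcome counts of one flight-assay cohort."""

    up: int
    horizontal: int
    down: int
    none: int

    def __post_init__(self) -> None:
        if min(self.up, self.horizontal, self.down, self.none) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one fly must be tested")

    @property
    def total(self) -> int:
        return self.up + self.horizontal + self.down + self.none


def flight_index(counts: FlightCounts) -> float:
    """Weighted flight score (6 U + 4 H + 2 D) / T in [0, 6]."""
    return (6.0 * counts.up + 4.0 * counts.horizontal + 2.0 * counts.down) / counts.total


def wingbeat_frequency(signal: np.ndarray, sample_rate: float,
                       band: tuple[float, float] = DEFAULT_WBF_BAND) -> float:
    """Dominant frequency of a tachometer trace within ``band`` (Hz).

    The mean-removed spectrum (Welch average of quarter-second segments,
    so single-bin noise excursions are averaged down) is searched inside the
    band; the peak must exceed 5x the median band power, otherwise no
    wingbeat is deemed present.  Parabolic interpolation over the peak
    bin and its two neighbours gives sub-bin resolution.  The estimate is
    invariant to amplitude scaling and DC offset of the input.
    """
    signal = np.asarray(signal, dtype=float)
    duration = signal.size / sample_rate
    if duration < 0.5:
        raise ValueError("need at least 0.5 s of signal")
    if sample_rate < 4.0 * band[1]:
        raise ValueError("sample rate below 4x the upper band edge")
    nperseg = int(min(signal.size, sample_rate / 4.0))
    freqs, power = welch(signal - np.mean(signal), fs=sample_rate,
                         nperseg=nperseg)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("no periodogram bins inside the band")
    band_idx = np.flatnonzero(in_band)
    k = band_idx[int(np.argmax(power[band_idx]))]
    med = np.median(power[band_idx])
    if med <= 0 or power[k] < PEAK_TO_MEDIAN_MIN * med:
        raise ValueError("no wingbeat detected: no dominant peak in band")
    # parabolic refinement on the raw power spectrum
    if 0 < k < power.size - 1:
        y0, y1, y2 = power[k - 1], power[k], power[k + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[k] + shift * df)
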