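"""Synthetic inputs for every stage of the pipeline.

Five generators emulate the data the analysis consumes, each storing its
ground truth in the output's metadata so that round-trip recovery can be
tested without any laboratory recording:

* ``gen_linear_trace`` — strain/stress traces of a linear viscoelastic
  fiber whose complex modulus follows the three-process model.
* ``simulate_crossbridge_ensemble`` — Monte-Carlo traces from an ensemble
  of independent two-state (detached/attached) cross-bridges, the
  mechanistic picture in which the work-producing apparent rate constant
  2*pi*b tracks attachment and the work-absorbing 2*pi*c tracks
  detachment.
* ``gen_dose_response`` — Michaelis-Menten rate-vs-concentration tables.
* ``gen_cardiac_trace`` — heart-tube diameter traces with set DD, SD, HP
  and SI.
* ``gen_flight_counts`` — multinomial flight-assay outcomes.

All randomness flows through ``numpy.random.default_rng`` seeded from the
protocol or argument, so every output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import FlightCounts
from .cardiac import SI_THRESHOLD_FRAC, CardiacTrace
from .nyquist import NyquistFit, eval_model
from .sinusoidal import FiberGeometry, LengthForceTrace

#: pN/nm^2 -> kN/m^2 (1 pN/nm^2 = 1 MPa = 1000 kPa)
PN_PER_NM2_TO_KPA = 1000.0

#: tau-leap step as a fraction of the fastest rate's time constant
TAU_LEAP_FRACTION = 0.02
#: hard limit: steps longer than this fraction are rejected outright
TAU_LEAP_LIMIT = 0.1

#: raised-cosine edge width of the cardiac pulse, as a fraction of SI
CARDIAC_EDGE_FRAC = 0.10

#: strain-dependent detachment saturates at this multiple of the baseline
#: rate: a bridge this far past its working range detaches within a step
#: anyway (mistiming those near-instant departures is well under the
#: drive period), and the cap keeps the tau-leap step size bounded
G_DET_CAP_FACTOR = 10.0

PROTOCOL_KINDS = ("sinusoid", "workloop", "isometric")


@dataclass(frozen=True)
class SyntheticProtocol:
    """Drive protocol shared by the fiber generators.

    ``amplitude`` is the strain amplitude eps0 as a fraction of muscle
    length (0.00125 for the standard small-amplitude sweep).  For the
    isometric kind the amplitude is ignored and ``n_cycles/frequency``
    simply sets the duration.  ``noise_sd`` is additive Gaussian noise as
    a fraction of the stress signal amplitude.
    """

    kind: str
    frequency: float
    amplitude: float = 0.00125
    n_cycles: int = 10
    sample_rate: float | None = None
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_rate is None:
            object.__setattr__(self, "sample_rate", 40.0 * self.frequency)
        if self.kind != "isometric" and self.sample_rate < 20.0 * self.frequency:
            # isometric protocols only use the frequency to set duration
            raise ValueError("sample_rate must be at least 20x the drive frequency")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency


@dataclass(frozen=True)
class CrossBridgeParams:
    """Two-state cross-bridge ensemble parameters.

    Defaults describe a fast indirect-flight-muscle myosin: a low duty
    ratio (~0.09) from slow attachment (``f_att``) against fast
    detachment (``g_det0``), a ~5 nm power stroke and ~2 pN/nm bridge
    stiffness.  ``g_strain_scale`` is the e-fold strain distance of the
    detachment rate, which slows under stretch (positive bridge strain)
    and accelerates under shortening; ``inf`` switches strain dependence
    off.  ``atp_km`` optionally scales detachment by 1/(1 + atp_km/[ATP]).
    ``sarcomere_area`` (nm^2) normalizes total bridge force to stress;
    ``half_sarcomere_nm`` converts imposed muscle strain to bridge
    displacement.
    """

    n_bridges: int = 2000
    f_att: float = 200.0          # s^-1
    g_det0: float = 2000.0        # s^-1
    g_strain_scale: float = math.inf  # nm
    kappa: float = 2.0            # pN/nm
    d_stroke: float = 5.0         # nm
    atp_km: float | None = None   # mM
    sarcomere_area: float = 5.0e5  # nm^2 per half-sarcomere cross-section
    half_sarcomere_nm: float = 1700.0

    def __post_init__(self) -> None:
        if self.n_bridges < 1:
            raise ValueError("need at least one bridge")
        if min(self.f_att, self.g_det0, self.kappa) <= 0:
            raise ValueError("rates and stiffness must be strictly positive")
        if self.g_strain_scale <= 0:
            raise ValueError("g_strain_scale must be positive (may be inf)")
        if self.sarcomere_area <= 0 or self.half_sarcomere_nm <= 0:
            raise ValueError("geometric scales must be positive")
        if self.atp_km is not None and self.atp_km <= 0:
            raise ValueError("atp_km must be positive when given")
        if not 0.0 < self.duty_ratio < 1.0:
            raise ValueError("duty ratio outside (0, 1)")

    @property
    def duty_ratio(self) -> float:
        return self.f_att / (self.f_att + self.g_det0)


def control_crossbridge_params(**overrides) -> CrossBridgeParams:
    """Ensemble parameters standing in for control flight-muscle myosin."""
    return CrossBridgeParams(**overrides)


def gen_linear_trace(model: NyquistFit, protocol: SyntheticProtocol,
                     geometry: FiberGeometry | None = None,
                     offset: float = 0.0,
                     condition: dict | None = None) -> LengthForceTrace:
    """Stress response of a linear fiber with complex modulus ``model``.

    strain(t) = eps0 sin(2 pi f t); stress(t) = offset +
    eps0 (E' sin + E'' cos) + Gaussian noise of sd ``noise_sd * eps0 |Y|``.
    The true E', E'' are recorded in the trace metadata.
    """
    if protocol.kind != "sinusoid":
        raise ValueError("gen_linear_trace requires a sinusoid protocol")
    f = protocol.frequency
    y = eval_model(model, f)
    eps0 = protocol.amplitude
    n = int(math.ceil(protocol.duration * protocol.sample_rate)) + 1
    time = np.arange(n) / protocol.sample_rate
    w = 2.0 * np.pi * f
    strain = eps0 * np.sin(w * time)
    stress = offset + eps0 * (y.real * np.sin(w * time) + y.imag * np.cos(w * time))
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(protocol.seed)
        stress = stress + rng.normal(0.0, protocol.noise_sd * eps0 * abs(y), size=n)
    meta = {"true_elastic": float(y.real), "true_viscous": float(y.imag),
            "offset": offset}
    if geometry is not None:
        meta["geometry"] = geometry
    return LengthForceTrace(time=time, strain=strain, stress=stress,
                            drive_frequency=f, amplitude=eps0,
                            condition=dict(condition or {}), metadata=meta)


def _strain_waveform(protocol: SyntheticProtocol, time: np.ndarray) -> np.ndarray:
    if protocol.kind == "isometric":
        return np.zeros_like(time)
    return protocol.amplitude * np.sin(2.0 * np.pi * protocol.frequency * time)


def simulate_crossbridge_ensemble(params: CrossBridgeParams,
                                  protocol: SyntheticProtocol,
                                  atp_mM: float | None = None,
                                  dt: float | None = None,
                                  burn_in: float | None = None,
                                  condition: dict | None = None) -> LengthForceTrace:
    """Monte-Carlo stress trace of an ensemble of two-state cross-bridges.

    Each of ``n_bridges`` independent bridges attaches at rate ``f_att``
    (strain on attachment uniform on [-d_stroke/2, d_stroke/2]) and
    detaches at rate ``g_det0 * exp(-x / g_strain_scale)``, optionally
    scaled by 1/(1 + atp_km/[ATP]).  An attached bridge exerts force
    kappa * (x + d_stroke), with its strain x advected by the imposed
    length change (muscle strain times the half-sarcomere length).  Total
    stress is the summed force over ``sarcomere_area``, in kN/m^2.

    The signed strain dependence (detachment slowing under stretch) is
    what gives the ensemble a delayed-tension, work-producing response:
    stretch transiently raises the attached number with a lag set by the
    attachment-side kinetics, so the fitted work-producing rate 2*pi*b
    tracks attachment while the work-absorbing 2*pi*c tracks detachment.
    With ``g_strain_scale = inf`` the ensemble is a pure work absorber
    whose single relaxation rate is the detachment rate.

    Updates are fixed-step tau-leap Bernoulli draws with
    dt = 0.02 / max(rates) (rounded down to divide the sample period); a
    caller-supplied ``dt`` above 0.1 / max(rates) is rejected.  The
    ensemble is initialized at its isometric steady state and settled for
    ``burn_in`` seconds (default 5 relaxation times) before recording.
    """
    atp_factor = 1.0
    if params.atp_km is not None and atp_mM is not None:
        atp_factor = 1.0 / (1.0 + params.atp_km / atp_mM)

    hs_amp = protocol.amplitude * params.half_sarcomere_nm
    if math.isinf(params.g_strain_scale):
        g_max = params.g_det0 * atp_factor
    else:
        x_cap = params.d_stroke / 2.0 + 2.0 * hs_amp
        g_max = params.g_det0 * atp_factor * min(
            math.exp(x_cap / params.g_strain_scale), G_DET_CAP_FACTOR)
    max_rate = params.f_att + g_max

    sample_period = 1.0 / protocol.sample_rate
    if dt is None:
        n_sub = max(1, int(math.ceil(sample_period * max_rate / TAU_LEAP_FRACTION)))
        dt = sample_period / n_sub
    else:
        if dt > TAU_LEAP_LIMIT / max_rate:
            raise ValueError(
                f"rate overflow: dt={dt:.3g} s exceeds 0.1/max_rate="
                f"{TAU_LEAP_LIMIT / max_rate:.3g} s"
            )
        n_sub = max(1, int(round(sample_period / dt)))
        dt = sample_period / n_sub

    if burn_in is None:
        burn_in = 5.0 / (params.f_att + params.g_det0)
    n_burn = int(math.ceil(burn_in / dt))

    n_out = int(math.ceil(protocol.duration * protocol.sample_rate)) + 1
    out_time = np.arange(n_out) * sample_period
    n_fine = (n_out - 1) * n_sub + 1
    fine_time = np.arange(n_fine) * dt
    fine_strain = _strain_waveform(protocol, fine_time)
    # half-sarcomere displacement increments, nm
    d_hs = np.diff(fine_strain, prepend=fine_strain[0]) * params.half_sarcomere_nm

    rng = np.random.default_rng(protocol.seed)
    n = params.n_bridges
    duty = params.duty_ratio
    attached = rng.random(n) < duty
    x = rng.uniform(-params.d_stroke / 2.0, params.d_stroke / 2.0, size=n)

    p_att = 1.0 - math.exp(-params.f_att * dt)
    g0 = params.g_det0 * atp_factor
    g_cap = g0 * G_DET_CAP_FACTOR
    inv_scale = 0.0 if math.isinf(params.g_strain_scale) else 1.0 / params.g_strain_scale

    half_d = params.d_stroke / 2.0
    stress_scale = params.kappa / params.sarcomere_area * PN_PER_NM2_TO_KPA
    stress = np.empty(n_out)

    def step(advect: float) -> None:
        nonlocal attached, x
        if advect != 0.0:
            x = np.where(attached, x + advect, x)
        if inv_scale:
            g = np.minimum(g0 * np.exp(-x * inv_scale), g_cap)
            p_det = 1.0 - np.exp(-g * dt)
        else:
            p_det = 1.0 - math.exp(-g0 * dt)
        u = rng.random(n)
        detach = attached & (u < p_det)
        attach = ~attached & (u < p_att)
        attached = (attached & ~detach) | attach
        if np.any(attach):
            x[attach] = rng.uniform(-half_d, half_d, size=int(attach.sum()))

    for _ in range(n_burn):
        step(0.0)

    stress[0] = np.sum(x[attached] + params.d_stroke) * stress_scale
    for i_out in range(1, n_out):
        base = (i_out - 1) * n_sub
        for j in range(1, n_sub + 1):
            step(float(d_hs[base + j]))
        stress[i_out] = np.sum(x[attached] + params.d_stroke) * stress_scale

    if protocol.noise_sd > 0:
        amp = 0.5 * (np.percentile(stress, 95) - np.percentile(stress, 5))
        stress = stress + rng.normal(0.0, protocol.noise_sd * max(amp, 1e-12),
                                     size=n_out)

    meta = {"params": params, "duty_ratio": duty, "dt": dt,
            "atp_factor": atp_factor}
    return LengthForceTrace(
        time=out_time,
        strain=_strain_waveform(protocol, out_time),
        stress=stress,
        drive_frequency=protocol.frequency,
        amplitude=0.0 if protocol.kind == "isometric" else protocol.amplitude,
        condition=dict(condition or {}),
        metadata=meta,
    )


def ensemble_spectrum(params: CrossBridgeParams, frequencies, seeds,
                      amplitude: float = 0.00125, n_cycles: int = 6,
                      atp_mM: float | None = None):
    """Seed-averaged complex-modulus spectrum of a cross-bridge ensemble.

    Runs a small-amplitude sinusoidal sweep at each frequency for every
    seed, extracts the moduli, and averages across seeds to beat down the
    Monte-Carlo noise (which scales as 1/sqrt(n_bridges * cycles * seeds)).
    """
    from .sinusoidal import ComplexModulusSpectrum, extract_complex_modulus

    frequencies = np.asarray(frequencies, dtype=float)
    seeds = list(seeds)
    e1 = np.zeros((len(seeds), frequencies.size))
    e2 = np.zeros_like(e1)
    for si, seed in enumerate(seeds):
        for fi, f in enumerate(frequencies):
            proto = SyntheticProtocol(kind="sinusoid", frequency=float(f),
                                      amplitude=amplitude, n_cycles=n_cycles,
                                      sample_rate=40.0 * float(f), seed=int(seed))
            trace = simulate_crossbridge_ensemble(params, proto, atp_mM=atp_mM)
            est = extract_complex_modulus(trace)
            e1[si, fi], e2[si, fi] = est.elastic, est.viscous
    return ComplexModulusSpectrum(frequencies, e1.mean(axis=0), e2.mean(axis=0),
                                  amplitude=amplitude)


def gen_dose_response(vmax: float, km: float, basal: float,
                      x_values, noise_sd: float = 0.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Michaelis-Menten rate table: rate = basal + vmax x / (km + x) + noise."""
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    x = np.asarray(x_values, dtype=float)
    if x.size == 0:
        raise ValueError("x_values is empty")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    rate = basal + vmax * x / (km + x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rate = rate + rng.normal(0.0, noise_sd, size=x.size)
    df = pd.DataFrame({"x": x, "rate": rate})
    df.attrs["truth"] = {"vmax": vmax, "km": km, "basal": basal}
    return df


def _raised_cosine_pulse(tau: np.ndarray, total: float, edge: float) -> np.ndarray:
    """Unit-depth pulse over [0, total] with raised-cosine edges of width
    ``edge``; zero outside."""
    p = np.zeros_like(tau)
    rise = (tau >= 0) & (tau < edge)
    p[rise] = 0.5 * (1.0 - np.cos(np.pi * tau[rise] / edge))
    flat = (tau >= edge) & (tau <= total - edge)
    p[flat] = 1.0
    fall = (tau > total - edge) & (tau <= total)
    p[fall] = 0.5 * (1.0 - np.cos(np.pi * (total - tau[fall]) / edge))
    return p


def gen_cardiac_trace(dd: float, sd: float, hp: float, si: float,
                      n_beats: int, sample_rate: float = 120.0,
                      noise_sd: float = 0.0,
                      seed: int | None = None) -> CardiacTrace:
    """Diameter trace with ``n_beats`` constrictions of set DD/SD/HP/SI.

    Each beat is a smoothed rectangular dip from DD to SD with
    raised-cosine edges (width 10% of SI).  The pulse is sized so that SI
    measured at the standard analysis threshold (SD + 15% of excursion)
    equals the requested value.  Ground truth is stored in metadata.
    """
    if sd >= dd:
        raise ValueError("systolic diameter must be below diastolic diameter")
    if si >= hp:
        raise ValueError("systolic interval must be below the heart period")
    if n_beats < 1:
        raise ValueError("need at least one beat")
    if sample_rate * si < 5:
        raise ValueError("sample_rate * si must be at least 5")

    edge = CARDIAC_EDGE_FRAC * si
    # the SI threshold sits at 85% of the pulse depth; each raised-cosine
    # edge crosses it acos(2*thr - 1)/pi of the way along the edge
    tau_thr = edge * math.acos(2.0 * SI_THRESHOLD_FRAC - 1.0) / math.pi
    total = si + 2.0 * tau_thr   # full width so threshold crossings sit si apart
    if total >= hp:
        raise ValueError("pulse (including edges) does not fit in the heart period")

    lead = 0.5 * hp
    duration = lead + (n_beats - 1) * hp + total + 0.5 * hp
    n = int(math.ceil(duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    diameter = np.full(n, float(dd))
    depth = dd - sd
    for k in range(n_beats):
        t0 = lead + k * hp
        diameter -= depth * _raised_cosine_pulse(time - t0, total, edge)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        diameter = diameter + rng.normal(0.0, noise_sd, size=n)
    meta = {"dd": dd, "sd": sd, "hp": hp, "si": si, "n_beats": n_beats}
    return CardiacTrace(time=time, diameter=diameter, metadata=meta)


def gen_flight_counts(p_up: float, p_horizontal: float, p_down: float,
                      p_none: float, total: int,
                      seed: int | None = None) -> FlightCounts:
    """Multinomial flight-assay outcome counts."""
    probs = np.array([p_up, p_horizontal, p_down, p_none], dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("probabilities must sum to 1")
    if total < 1:
        raise ValueError("total must be at least 1")
    rng = np.random.default_rng(seed)
    u, h, d, nn = rng.multinomial(total, probs)
    return FlightCounts(up=int(u), horizontal=int(h), down=int(d), none=int(nn))
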