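"""Beat-level analysis of Drosophila heart-tube diameter traces.

The input is an edge trace of heart-wall diameter over time (µm, ~120
samples/s), the one-dimensional summary of an M-mode kymogram.  Each beat
is a transient constriction from the diastolic diameter (DD) down to the
systolic diameter (SD).  Derived quantities per heart:

    FS  = 100 * (DD - SD) / DD     fractional shortening, %
    HP  = trough-to-trough time    heart period, s
    SI  = time spent constricted   systolic interval, s
    DI  = HP - SI                  diastolic interval, s
    SI/HP                          fraction of the cycle under tension

The systolic interval is measured as the contiguous time the diameter
stays below SD + 15% of the beat excursion; the threshold is a module
constant, not a physiological claim.  The relaxation assay quantifies the
diameter gain after calcium chelation (EGTA/EGTA-AM) and after
blebbistatin, per heart, with paired and unpaired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import ttest_ind, ttest_rel

#: fraction of beat excursion above the systolic minimum defining SI
SI_THRESHOLD_FRAC = 0.15
#: fraction of beat excursion below DD defining the diastolic plateau
PLATEAU_LEVEL_FRAC = 0.85
#: trough prominence required, as a fraction of the 5th-95th pct range
BEAT_PROMINENCE_FRAC = 0.25

MIN_DURATION_S = 2.0
MIN_SAMPLE_RATE_HZ = 50.0


@dataclass
class CardiacTrace:
    """Heart-wall diameter (µm) on a uniform time grid (s)."""

    time: np.ndarray
    diameter: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.shape != self.diameter.shape:
            raise ValueError("time and diameter must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class Beat:
    """One detected beat: trough index plus flanking plateau index arrays."""

    trough_index: int
    pre_plateau: np.ndarray
    post_plateau: np.ndarray


@dataclass
class BeatMetrics:
    dd: float       # µm, median of the pre-trough diastolic plateau
    sd_diam: float  # µm, trough minimum
    hp: float       # s, to next trough (nan for the last beat)
    si: float       # s, contiguous time below the SI threshold


@dataclass
class CardiacSummary:
    dd: float
    sd_diam: float
    hp: float
    si: float
    n_beats: int

    def __post_init__(self) -> None:
        if self.sd_diam > self.dd:
            raise ValueError("systolic diameter exceeds diastolic diameter")
        if self.si > self.hp:
            raise ValueError("systolic interval exceeds heart period")

    @property
    def fs_pct(self) -> float:
        return 100.0 * (self.dd - self.sd_diam) / self.dd

    @property
    def di(self) -> float:
        return self.hp - self.si

    @property
    def si_over_hp(self) -> float:
        return self.si / self.hp


@dataclass(frozen=True)
class RelaxationAssayRecord:
    """Diastolic diameters of one heart along the relaxation protocol."""

    heart_id: str
    diameter_baseline: float
    diameter_post_chelation: float
    diameter_post_blebbistatin: float

    def __post_init__(self) -> None:
        if min(self.diameter_baseline, self.diameter_post_chelation,
               self.diameter_post_blebbistatin) <= 0:
            raise ValueError("diameters must be positive")

    @property
    def delta_chelation(self) -> float:
        return self.diameter_post_chelation - self.diameter_baseline

    @property
    def delta_blebbistatin(self) -> float:
        return self.diameter_post_blebbistatin - self.diameter_post_chelation


def detect_beats(trace: CardiacTrace) -> list[Beat]:
    """Locate beats as prominence-filtered diameter minima.

    Troughs must be at least 25% of the trace's 5th-to-95th percentile
    range deep; a beat is kept only if a diastolic plateau (samples above
    85% of the global excursion) of >= 3 samples flanks it on both sides,
    which discards beats truncated at the trace edges.
    """
    x = trace.diameter
    if trace.time[-1] - trace.time[0] < MIN_DURATION_S:
        raise ValueError("need at least 2 s of signal")
    if trace.sample_rate < MIN_SAMPLE_RATE_HZ:
        raise ValueError("sampling rate below 50 Hz")
    lo, hi = np.percentile(x, [5, 95])
    excursion = hi - lo
    if excursion <= 0:
        raise ValueError("no beats: flat trace")
    troughs, _ = find_peaks(-x, prominence=BEAT_PROMINENCE_FRAC * excursion)
    if troughs.size == 0:
        raise ValueError("no beats: no troughs above prominence threshold")

    plateau_level = lo + PLATEAU_LEVEL_FRAC * excursion
    bounds = np.concatenate([[0], troughs, [x.size - 1]])
    beats: list[Beat] = []
    for i, k in enumerate(troughs):
        pre = np.arange(bounds[i], k)
        post = np.arange(k + 1, bounds[i + 2] + 1)
        pre = pre[x[pre] >= plateau_level]
        post = post[x[post] >= plateau_level]
        if pre.size >= 3 and post.size >= 3:
            beats.append(Beat(trough_index=int(k), pre_plateau=pre,
                              post_plateau=post))
    if not beats:
        raise ValueError("no beats: every trough truncated at a trace edge")
    return beats


def _threshold_crossing_times(trace: CardiacTrace, k: int, thr: float) -> tuple[float, float]:
    """Sub-sample times where the diameter crosses ``thr`` on either side of
    the trough at index ``k`` (linear interpolation)."""
    t, x = trace.time, trace.diameter
    i = k
    while i > 0 and x[i] < thr:
        i -= 1
    if x[i] < thr:
        t_left = t[0]
    else:
        t_left = t[i] + (t[i + 1] - t[i]) * (x[i] - thr) / (x[i] - x[i + 1])
    j = k
    while j < x.size - 1 and x[j] < thr:
        j += 1
    if x[j] < thr:
        t_right = t[-1]
    else:
        t_right = t[j] - (t[j] - t[j - 1]) * (x[j] - thr) / (x[j] - x[j - 1])
    return t_left, t_right


def beat_metrics(trace: CardiacTrace, beats: list[Beat], index: int) -> BeatMetrics:
    """Diameters and intervals for one detected beat.

    DD is the median of the pre-trough diastolic plateau (median resists
    residual noise spikes), SD the trough minimum.  HP runs trough to next
    trough (NaN for the final beat).  SI is the contiguous time below
    SD + 0.15 * (DD - SD), with sub-sample crossing interpolation.
    """
    beat = beats[index]
    if beat.pre_plateau.size < 3:
        raise ValueError("diastolic plateau shorter than 3 samples")
    x = trace.diameter
    raw_sd = float(x[beat.trough_index])
    dd = float(np.median(x[beat.pre_plateau]))
    if dd <= raw_sd:
        raise ValueError("degenerate beat: no excursion between DD and SD")
    # noise-robust SD: median of the contiguous deep-systole region (within
    # 25% of the excursion above the raw trough) rather than the raw
    # minimum, whose noise bias grows with the bottom-plateau length
    deep = raw_sd + 0.25 * (dd - raw_sd)
    i = beat.trough_index
    while i > 0 and x[i - 1] < deep:
        i -= 1
    j = beat.trough_index
    while j < x.size - 1 and x[j + 1] < deep:
        j += 1
    sd = float(np.median(x[i:j + 1]))
    thr = sd + SI_THRESHOLD_FRAC * (dd - sd)
    t_left, t_right = _threshold_crossing_times(trace, beat.trough_index, thr)
    si = t_right - t_left
    if index + 1 < len(beats):
        hp = float(trace.time[beats[index + 1].trough_index]
                   - trace.time[beat.trough_index])
    else:
        hp = float("nan")
    return BeatMetrics(dd=dd, sd_diam=sd, hp=hp, si=float(si))


def summarize_heart(trace: CardiacTrace, fs_from_means: bool = True) -> CardiacSummary:
    """Per-beat metrics averaged over the whole trace (>= 3 beats).

    By default FS and SI/HP are computed from the mean diameters and mean
    intervals; ``fs_from_means=False`` instead averages per-beat FS values.
    The resulting FS is exposed via ``CardiacSummary.fs_pct``; for per-beat
    averaging the summary's DD/SD are rescaled so the invariant formula
    reproduces the per-beat mean FS.
    """
    beats = detect_beats(trace)
    if len(beats) < 3:
        raise ValueError(f"need >= 3 beats, found {len(beats)}")
    metrics = [beat_metrics(trace, beats, i) for i in range(len(beats))]
    dd = float(np.mean([m.dd for m in metrics]))
    sd = float(np.mean([m.sd_diam for m in metrics]))
    hp = float(np.nanmean([m.hp for m in metrics]))
    si = float(np.mean([m.si for m in metrics]))
    if not fs_from_means:
        fs_per_beat = np.mean([100.0 * (m.dd - m.sd_diam) / m.dd for m in metrics])
        sd = dd * (1.0 - fs_per_beat / 100.0)
    return CardiacSummary(dd=dd, sd_diam=sd, hp=hp, si=si, n_beats=len(beats))


def relaxation_assay(records_by_genotype: dict[str, list[RelaxationAssayRecord]]) -> dict:
    """Relaxation-step deltas per genotype with paired and unpaired tests.

    For each genotype: per-heart Delta1 (post-chelation - baseline) and
    Delta2 (post-blebbistatin - post-chelation), their mean +/- SEM, and a
    within-genotype paired t-test for each step.  For every genotype pair,
    unpaired two-tailed t-tests compare Delta1 and Delta2.  All-equal
    deltas make the paired t undefined (zero variance); the test entry is
    then flagged instead of reporting a statistic.
    """
    out: dict = {"genotypes": {}, "between": {}}
    deltas: dict[str, dict[str, np.ndarray]] = {}
    for geno, records in records_by_genotype.items():
        if len(records) < 2:
            raise ValueError(f"genotype {geno!r}: need >= 2 hearts")
        d1 = np.array([r.delta_chelation for r in records])
        d2 = np.array([r.delta_blebbistatin for r in records])
        deltas[geno] = {"chelation": d1, "blebbistatin": d2}
        entry: dict = {"n": len(records)}
        for step, d, pre, post in (
            ("chelation", d1,
             [r.diameter_baseline for r in records],
             [r.diameter_post_chelation for r in records]),
            ("blebbistatin", d2,
             [r.diameter_post_chelation for r in records],
             [r.diameter_post_blebbistatin for r in records]),
        ):
            sem = float(np.std(d, ddof=1) / np.sqrt(d.size))
            if np.allclose(d, d[0]):
                test = {"flag": "zero_variance", "statistic": None, "p_value": None}
            else:
                t = ttest_rel(post, pre)
                test = {"flag": None, "statistic": float(t.statistic),
                        "p_value": float(t.pvalue)}
            entry[step] = {"mean_delta": float(np.mean(d)), "sem_delta": sem,
                           "paired_t": test}
        out["genotypes"][geno] = entry

    names = list(records_by_genotype)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            pair: dict = {}
            for step in ("chelation", "blebbistatin"):
                t = ttest_ind(deltas[ga][step], deltas[gb][step], equal_var=True)
                pair[step] = {"statistic": float(t.statistic),
                              "p_value": float(t.pvalue)}
            out["between"][f"{ga} vs {gb}"] = pair
    return out
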