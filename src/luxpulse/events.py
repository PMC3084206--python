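"""Growth-rate pauses, transcription bursts, and their phase relationship.

A *pause* is a local minimum of the numerically derived growth rate with a
depth of at least ``min_depth`` relative to the lower of its two flanking
maxima (making detection scale-free) and a minimum width.  A *burst* is a
local maximum of a promoter-activity series with prominence of at least a
fraction of the series' global range (making detection invariant to affine
rescaling of the arbitrary RLU units).  Pauses and bursts are paired
greedily by nearest time; the antiphase claim -- activity bursts sit half a
period away from growth-rate maxima -- is quantified by the lag of the
cross-correlation extremum expressed in degrees of the dominant
oscillation period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths
from scipy.stats import pearsonr

from .errors import AnalysisError, DomainError

__all__ = [
    "PauseEvent",
    "BurstEvent",
    "PhaseReport",
    "MatchResult",
    "define_T0",
    "detect_pauses",
    "detect_bursts",
    "match_events",
    "phase_offset",
    "correlation_signs",
]


@dataclass(frozen=True)
class PauseEvent:
    """A local growth-rate minimum."""

    time: float
    mu_min: float
    depth: float          # 1 - mu_min / (lower flanking maximum), clipped to 1
    width: float          # hours at half depth


@dataclass(frozen=True)
class BurstEvent:
    """A local promoter-activity maximum."""

    time: float
    peak: float
    prominence: float     # as a fraction of the series' global range
    rise_start: float


@dataclass(frozen=True)
class PhaseReport:
    """Phase relationship between growth rate and a promoter activity."""

    period: float         # dominant oscillation period, h
    lag: float            # lag at the cross-correlation extremum, h
    phase_deg: float      # 360 * |lag| / period, mapped to [0, 360)
    pearson_r: float
    window: tuple[float, float]
    T0: float | None = None

    @property
    def T1(self) -> float | None:
        return None if self.T0 is None else self.T0 + 1.0

    @property
    def T2(self) -> float | None:
        return None if self.T0 is None else self.T0 + 2.0


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[PauseEvent, BurstEvent, float], ...]
    unmatched_pauses: tuple[PauseEvent, ...]
    unmatched_bursts: tuple[BurstEvent, ...]


def define_T0(time, mu, threshold_frac: float = 0.1,
              hold_samples: int = 20) -> float:
    """Transition to stationary phase: the first time the growth rate drops
    below ``threshold_frac`` of its 90th percentile and stays there for at
    least ``hold_samples`` consecutive samples.

    Raises :class:`AnalysisError` if the culture is still growing at the
    end of the run.
    """
    time = np.asarray(time, dtype=float)
    mu = np.asarray(mu, dtype=float)
    thr = threshold_frac * np.percentile(mu, 90)
    below = mu < thr
    run = 0
    for i in range(below.size):
        run = run + 1 if below[i] else 0
        if run >= hold_samples:
            start = i - hold_samples + 1
            # extend backwards through the contiguous below-threshold run
            while start > 0 and below[start - 1]:
                start -= 1
            return float(time[start])
    raise AnalysisError("T0 undefined: growth rate never settles below "
                        f"{thr:.3g} /h for {hold_samples} samples")


def detect_pauses(time, mu, min_depth: float = 0.2, min_width: float = 0.1,
                  t_max: float | None = None,
                  min_flank: float | None = None) -> list[PauseEvent]:
    """Local growth-rate minima deep and wide enough to count as pauses.

    Depth is relative to the lower of the two flanking maxima (the
    prominence base of the inverted series), making detection scale-free;
    width is measured at half depth.  A pause must additionally interrupt
    genuine growth: its lower flanking maximum must reach ``min_flank``
    (default 25% of the window's 90th-percentile rate), which keeps noise
    wiggles on the near-zero stationary-phase rate from counting.  When
    ``t_max`` is given (normally T0) only the window up to it is searched.
    """
    time = np.asarray(time, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if t_max is not None:
        keep = time <= t_max
        time, mu = time[keep], mu[keep]
    if mu.size < 3:
        return []
    dt = float(np.median(np.diff(time)))
    if min_flank is None:
        min_flank = 0.25 * np.percentile(mu, 90)
    # a prominence floor merges noise sub-minima inside one dip: only the
    # deepest point of a depression survives as its representative minimum
    prom_floor = min_depth * max(min_flank, 0.0)
    minima, props = find_peaks(-mu, prominence=max(prom_floor, 1e-12))
    if minima.size == 0:
        return []
    widths_samples = peak_widths(-mu, minima, rel_height=0.5)[0]
    events = []
    for j, idx in enumerate(minima):
        flank = mu[idx] + props["prominences"][j]  # lower flanking maximum
        if flank < min_flank or flank <= 0:
            continue
        depth = min(1.0, 1.0 - mu[idx] / flank)
        width = float(widths_samples[j] * dt)
        if depth >= min_depth and width >= min_width:
            events.append(PauseEvent(time=float(time[idx]), mu_min=float(mu[idx]),
                                     depth=float(depth), width=width))
    return sorted(events, key=lambda e: e.time)


def detect_bursts(time, activity, min_prominence: float = 0.15,
                  merge_radius: float = 0.15) -> list[BurstEvent]:
    """Local activity maxima with prominence >= ``min_prominence`` of the
    series' global range; peaks closer than ``merge_radius`` hours are
    merged (highest kept), which prevents double-counting shouldered
    stationary-phase waves.
    """
    time = np.asarray(time, dtype=float)
    activity = np.asarray(activity, dtype=float)
    rng = float(activity.max() - activity.min())
    if rng <= 0:
        return []
    peaks, props = find_peaks(activity, prominence=min_prominence * rng)
    if peaks.size == 0:
        return []
    prom = dict(zip(peaks, props["prominences"]))
    lbase = dict(zip(peaks, props["left_bases"]))
    # merge close peaks, keeping the higher one
    kept: list[int] = []
    for idx in peaks:
        if kept and time[idx] - time[kept[-1]] < merge_radius:
            if activity[idx] > activity[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return [
        BurstEvent(time=float(time[i]), peak=float(activity[i]),
                   prominence=float(prom[i] / rng),
                   rise_start=float(time[lbase[i]]))
        for i in kept
    ]


def match_events(pauses: Sequence[PauseEvent], bursts: Sequence[BurstEvent],
                 max_lag: float = 0.3) -> MatchResult:
    """Greedy nearest-time pairing of pauses and bursts within ``max_lag`` h.

    The lag of a pair is ``burst.time - pause.time`` (positive when the
    burst peaks after the growth-rate minimum).
    """
    candidates = sorted(
        ((abs(b.time - p.time), pi, bi)
         for pi, p in enumerate(pauses)
         for bi, b in enumerate(bursts)
         if abs(b.time - p.time) <= max_lag),
        key=lambda c: c[0])
    used_p: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, pi, bi in candidates:
        if pi in used_p or bi in used_b:
            continue
        used_p.add(pi)
        used_b.add(bi)
        pairs.append((pauses[pi], bursts[bi], bursts[bi].time - pauses[pi].time))
    pairs.sort(key=lambda pr: pr[0].time)
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_pauses=tuple(p for i, p in enumerate(pauses) if i not in used_p),
        unmatched_bursts=tuple(b for i, b in enumerate(bursts) if i not in used_b),
    )


def _detrend(x: np.ndarray, t: np.ndarray, degree: int) -> np.ndarray:
    coeff = np.polynomial.polynomial.polyfit(t, x, degree)
    return x - np.polynomial.polynomial.polyval(t, coeff)


def phase_offset(time, mu, activity, window: tuple[float, float] | None = None,
                 detrend_degree: int = 2, min_autocorr: float = 0.2,
                 t0: float | None = None) -> PhaseReport:
    """Phase displacement between growth rate and promoter activity.

    Both series are detrended with a low-order polynomial over the window;
    the dominant period comes from the first positive-lag peak of the
    growth-rate autocorrelation, and the lag from the maximum of the
    normalized cross-correlation within +-0.75 period.  The phase is
    ``360 |lag| / period`` mapped to [0, 360): identical series give 0,
    sign-flipped series give 180.
    """
    time = np.asarray(time, dtype=float)
    mu = np.asarray(mu, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if not (time.shape == mu.shape == activity.shape):
        raise DomainError("phase_offset: series must share the time grid")
    if window is not None:
        keep = (time >= window[0]) & (time <= window[1])
        time, mu, activity = time[keep], mu[keep], activity[keep]
    else:
        window = (float(time[0]), float(time[-1]))
    n = time.size
    if n < 8:
        raise AnalysisError("phase_offset: window too short")
    dt = float(np.median(np.diff(time)))

    x = _detrend(mu, time, detrend_degree)
    y = _detrend(activity, time, detrend_degree)
    sx, sy = x.std(), y.std()
    # a series that is flat (or a pure trend) carries no oscillation
    if sx <= 1e-9 * (np.abs(mu).max() + 1e-300) or \
            sy <= 1e-9 * (np.abs(activity).max() + 1e-300):
        raise AnalysisError("phase_offset: no detectable oscillation "
                            "(series is flat after detrending)")

    # dominant period from the first positive-lag autocorrelation peak
    ac = np.array([np.mean(x[:n - k] * x[k:]) for k in range(n // 2)]) / (sx * sx)
    ac_peaks, _ = find_peaks(ac)
    if ac_peaks.size == 0 or ac[ac_peaks[0]] < min_autocorr:
        raise AnalysisError(
            "phase_offset: no detectable oscillation (autocorrelation peak "
            f"{ac[ac_peaks[0]]:.2f} < {min_autocorr})" if ac_peaks.size
            else "phase_offset: no detectable oscillation")
    period = float(ac_peaks[0] * dt)

    max_shift = int(round(0.75 * period / dt))
    max_shift = min(max_shift, n - 2)
    lags = np.arange(-max_shift, max_shift + 1)

    def ccf(k: int) -> float:
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        return float(np.mean(a * b) / (sx * sy))

    vals = np.array([ccf(int(k)) for k in lags])
    i_max, i_min = int(np.argmax(vals)), int(np.argmin(vals))
    # use whichever extremum aligns the curves more strongly: a minimum at
    # lag L means the series are antiphase at L, i.e. in phase at L + T/2
    if abs(vals[i_min]) > abs(vals[i_max]):
        lag = float(lags[i_min] * dt)
        phase = (180.0 + 360.0 * abs(lag) / period) % 360.0
    else:
        lag = float(lags[i_max] * dt)
        phase = (360.0 * abs(lag) / period) % 360.0
    r = float(pearsonr(mu, activity)[0])
    return PhaseReport(period=period, lag=lag, phase_deg=phase, pearson_r=r,
                       window=(float(window[0]), float(window[1])), T0=t0)


def correlation_signs(time, mu, activities: Mapping[str, np.ndarray],
                      window: tuple[float, float] | None = None
                      ) -> dict[str, float | None]:
    """Pearson correlation of each activity channel with the growth rate.

    Computed over ``window`` (typically the growth phase); constant series
    yield ``None`` since the correlation is undefined.
    """
    time = np.asarray(time, dtype=float)
    mu = np.asarray(mu, dtype=float)
    keep = np.ones_like(time, dtype=bool)
    if window is not None:
        keep = (time >= window[0]) & (time <= window[1])
    out: dict[str, float | None] = {}
    for name, act in activities.items():
        a = np.asarray(act, dtype=float)[keep]
        m = mu[keep]
        if a.std() == 0 or m.std() == 0:
            out[name] = None
        else:
            out[name] = float(pearsonr(m, a)[0])
    return out
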