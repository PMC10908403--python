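"""Landmark detection on single pressure and PPG beats.

The pulse foot is located by the intersecting-tangent construction: the
tangent at the point of maximum systolic upslope is intersected with the
horizontal line through the pre-systolic minimum.  Pressure shoulders
(P1/P2) and the PPG systolic shoulders (PT1/PT2) are found as local minima
of the smoothed second derivative in systole; the five classical
second-derivative PPG landmarks (a-e) are alternating extrema of the
smoothed second derivative.

All derivatives are taken with a local-polynomial (Savitzky-Golay)
smoothing differentiator on the circularly extended beat, so every detector
is invariant to amplitude scaling and equivariant to circular time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .core import PulseWave

#: Smoothing-differentiator window [s] and polynomial order.
SMOOTH_WINDOW = 0.05
SMOOTH_ORDER = 3

#: Fraction of the beat period searched backwards from the maximum-upslope
#: point for the pre-systolic minimum (guards against the dicrotic rise).
FOOT_MIN_WINDOW = 0.4

#: Systolic shoulder search extent as a fraction of the period past the foot.
SHOULDER_WINDOW = 0.45

#: Minimum depth of a second-derivative valley, relative to the deepest one,
#: for it to count as a shoulder.
SHOULDER_DEPTH = 0.15


def _savgol(x: np.ndarray, fs: float, deriv: int,
            polyorder: int = SMOOTH_ORDER) -> np.ndarray:
    win = int(round(SMOOTH_WINDOW * fs))
    win = max(win | 1, polyorder + 2 | 1)  # odd, > polyorder
    return signal.savgol_filter(x, win, polyorder, deriv=deriv,
                                delta=1.0 / fs, mode="wrap")


def _wrap_time(t: float, period: float) -> float:
    return float(np.mod(t, period))


def _parabolic_offset(y_prev: float, y0: float, y_next: float) -> float:
    denom = y_prev - 2.0 * y0 + y_next
    if abs(denom) < 1e-12 * max(abs(y0), 1e-300):
        return 0.0
    return float(np.clip(0.5 * (y_prev - y_next) / denom, -0.5, 0.5))


def _interp_circular(x: np.ndarray, idx: float) -> float:
    """Linear interpolation of ``x`` at a fractional circular index."""
    n = x.size
    i0 = int(np.floor(idx)) % n
    frac = idx - np.floor(idx)
    return float((1.0 - frac) * x[i0] + frac * x[(i0 + 1) % n])


def pulse_foot(wave: PulseWave) -> float:
    """Pulse-onset time [s] by the intersecting-tangent method.

    Sub-sample resolution comes from the analytic intersection of the
    maximum-upslope tangent with the horizontal through the pre-systolic
    minimum; the upslope peak itself is refined parabolically.  Raises if
    the maximum slope is not positive.
    """
    x = wave.samples
    fs = wave.fs
    n = x.size
    period = n / fs

    d1 = _savgol(x, fs, 1)
    # A beat whose last sample sits above its first has a falling step at
    # the circular wrap; the local-polynomial fit rings there and can fake
    # a steep ascent.  Excluding a window around the steepest raw descent
    # is harmless on smooth beats (the max ascent is never there) and keeps
    # the detector circular-shift equivariant.
    raw = np.diff(x, append=x[:1])
    win = max(int(round(SMOOTH_WINDOW * fs)) | 1, SMOOTH_ORDER + 2 | 1)
    guard = (int(np.argmin(raw)) + np.arange(-(win // 2 + 1),
                                             win // 2 + 2)) % n
    candidates = d1.copy()
    candidates[guard] = -np.inf
    i_max = int(np.argmax(candidates))
    slope = float(d1[i_max])
    if slope <= 0:
        raise ValueError("no rising systolic limb (max slope <= 0)")
    delta = _parabolic_offset(d1[(i_max - 1) % n], d1[i_max],
                              d1[(i_max + 1) % n])
    t_m = (i_max + delta) / fs
    p_m = _interp_circular(x, i_max + delta)

    k = max(2, int(FOOT_MIN_WINDOW * n))
    back = x[(i_max - np.arange(1, k + 1)) % n]
    p_min = float(back.min())

    return _wrap_time(t_m - (p_m - p_min) / slope, period)


@dataclass
class FiducialSetPressure:
    """Pressure-beat landmarks: foot, systolic peak, P1/P2 shoulders."""

    foot_time: float
    systolic_peak_time: float
    systolic_peak_value: float
    p1: float
    p2: float
    p1_time: float
    p2_time: float
    wave_type: str            # "A" | "B" | "C"
    degenerate: bool = False  # no distinct shoulder found


def _shoulder_candidates(x: np.ndarray, fs: float, i_start: int,
                         span: int) -> list:
    """Fractional indices of second-derivative valleys after ``i_start``.

    The beat is scanned circularly over ``span`` samples; valleys shallower
    than ``SHOULDER_DEPTH`` of the deepest valley are discarded.  Works on
    the min-max-normalised beat so detection is scale invariant.
    """
    n = x.size
    xn = (x - x.min()) / (np.ptp(x) if np.ptp(x) > 0 else 1.0)
    d2 = _savgol(xn, fs, 2)
    seg = d2[(i_start + np.arange(span)) % n]
    minima, _ = signal.find_peaks(-seg)
    if minima.size == 0:
        return []
    depths = -seg[minima]
    keep = depths >= SHOULDER_DEPTH * depths.max()
    out = []
    for j in minima[keep]:
        delta = _parabolic_offset(seg[max(j - 1, 0)], seg[j],
                                  seg[min(j + 1, span - 1)])
        out.append((i_start + j + delta) % n)
    return out


def pressure_inflections(wave: PulseWave) -> FiducialSetPressure:
    """Locate P1 and P2 on a pressure beat and classify the wave type.

    P1 is the earlier of (shoulder, systolic peak) and P2 the later.  Type
    "A" when the reflected wave forms the peak after an earlier shoulder,
    "C" when the reflected shoulder follows the peak (negative augmentation
    allowed), "B" when the two nearly coincide.  With no detectable
    shoulder, P1 = P2 = systolic peak and the result is flagged degenerate.
    """
    x = wave.samples
    fs = wave.fs
    n = x.size
    period = n / fs

    foot = pulse_foot(wave)
    i_foot = int(round(foot * fs)) % n
    i_peak = int(np.argmax(x))
    t_peak = i_peak / fs
    sbp = float(x[i_peak])

    span = int(SHOULDER_WINDOW * n)
    cands = _shoulder_candidates(x, fs, i_foot, span)
    # Order by elapsed time since the foot.
    cands.sort(key=lambda idx: (idx - i_foot) % n)

    if len(cands) < 2:
        return FiducialSetPressure(foot, t_peak, sbp, sbp, sbp,
                                   t_peak, t_peak, "B", degenerate=True)

    # A shoulder that carries the systolic peak is better measured at the
    # peak sample itself than at the curvature valley, which the smoothing
    # differentiator shifts slightly.
    snap = int(0.02 * fs)
    cands = [float(i_peak) if min((c - i_peak) % n, (i_peak - c) % n) <= snap
             else c for c in cands[:2]]
    i1, i2 = cands[0], cands[1]
    p1 = _interp_circular(x, i1)
    p2 = _interp_circular(x, i2)
    t1 = _wrap_time(i1 / fs, period)
    t2 = _wrap_time(i2 / fs, period)

    # Which candidate carries the systolic peak?
    d_peak_1 = abs((i_peak - i1)) % n
    d_peak_2 = abs((i_peak - i2)) % n
    pp = np.ptp(x)
    if abs(p2 - p1) < 0.02 * pp:
        wave_type = "B"
    elif min(d_peak_2, n - d_peak_2) <= min(d_peak_1, n - d_peak_1):
        wave_type = "A"   # peak is the later (reflected) wave
    else:
        wave_type = "C"   # reflected shoulder follows the peak
    return FiducialSetPressure(foot, t_peak, sbp, p1, p2, t1, t2, wave_type)


@dataclass
class FiducialSetPPG:
    """PPG-beat landmarks on the min-max-normalised beat."""

    foot_time: float
    s: float                    # systolic amplitude (1.0 after normalisation)
    s_time: float
    dia: Optional[float]        # diastolic peak (or inflection fallback)
    dia_time: Optional[float]
    delta_t: Optional[float]    # t(dia) - t(s), seconds
    pt1: Optional[float]        # early systolic shoulder amplitude
    pt2: Optional[float]        # late systolic shoulder amplitude
    dia_found: bool = False     # True when a genuine diastolic peak exists
    shoulders_found: bool = False


def ppg_landmarks(wave: PulseWave) -> FiducialSetPPG:
    """Systolic/diastolic PPG landmarks of a normalised beat.

    ``s`` is the global maximum; ``dia`` the first diastolic local maximum
    after the dicrotic region.  When the diastolic peak has vanished the
    detector falls back to the diastolic inflection (local maximum of the
    first derivative during the decay) with ``dia_found=False``.  PT1/PT2
    reuse the pressure-shoulder logic.
    """
    x = wave.samples
    if np.ptp(x) == 0:
        raise ValueError("PPG beat has zero amplitude range")
    xn = (x - x.min()) / np.ptp(x)
    fs = wave.fs
    n = x.size
    period = n / fs

    foot = pulse_foot(wave)
    i_sys = int(np.argmax(xn))
    t_sys = i_sys / fs
    s_amp = 1.0

    # Diastolic search window: 10-75% of the period past the systolic peak.
    # The *most prominent* local maximum is taken as the diastolic peak:
    # the first one can be a small reflection bump inside the dicrotic
    # region, which the prominence criterion skips.
    lo = int(0.10 * n)
    hi = int(0.75 * n)
    seg_idx = (i_sys + np.arange(lo, hi)) % n
    seg = xn[seg_idx]

    dia = dia_time = delta_t = None
    dia_found = False
    peaks, props = signal.find_peaks(seg, prominence=0.005)
    if peaks.size:
        j = peaks[int(np.argmax(props["prominences"]))]
        dia = float(seg[j])
        dia_time = _wrap_time((i_sys + lo + j) / fs, period)
        dia_found = True
    else:
        d1 = _savgol(xn, fs, 1)
        d1_seg = d1[seg_idx]
        infl, props = signal.find_peaks(d1_seg, prominence=0.0)
        if infl.size:
            j = infl[int(np.argmax(props["prominences"]))]
            dia = float(seg[j])
            dia_time = _wrap_time((i_sys + lo + j) / fs, period)
    if dia_time is not None:
        delta_t = _wrap_time(dia_time - t_sys, period)

    i_foot = int(round(foot * fs)) % n
    cands = _shoulder_candidates(xn, fs, i_foot, int(SHOULDER_WINDOW * n))
    cands.sort(key=lambda idx: (idx - i_foot) % n)
    if len(cands) >= 2:
        pt1 = _interp_circular(xn, cands[0])
        pt2 = _interp_circular(xn, cands[1])
        shoulders = True
    else:
        pt1 = pt2 = s_amp
        shoulders = False

    return FiducialSetPPG(foot, s_amp, t_sys, dia, dia_time, delta_t,
                          pt1, pt2, dia_found, shoulders)


@dataclass
class SdppgLandmarks:
    """The a-e waves of the second-derivative PPG (times [s] and values)."""

    times: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def has(self, name: str) -> bool:
        return name in self.values

    def complete(self) -> bool:
        return all(self.has(k) for k in "abcde")


#: Smoothing window [s] for the second-derivative PPG; wider than the foot
#: window because the curvature waves of interest (reflected and diastolic
#: complexes) span ~100 ms and a wide window suppresses in-band noise.
SDPPG_WINDOW = 0.07

#: Two-tier peak-prominence gates for the a-e landmarks, as fractions of
#: the second-derivative range.  The strict gate keeps the alternation
#: chain on genuine curvature waves (noise wiggles and decay ripples fall
#: below it); landmarks that remain unmatched are filled from the relaxed
#: tier so that faint-but-real features (e.g. the fading diastolic wave of
#: older subjects) are still reported.
SDPPG_PROMINENCE = 0.05
SDPPG_PROMINENCE_RELAXED = 0.005


def sdppg_landmarks(wave: PulseWave) -> SdppgLandmarks:
    """Locate the a, b, c, d, e waves on the smoothed second derivative.

    ``a`` is the first prominent maximum after the foot, then alternating
    minima/maxima give b-e, all before the late-diastolic region.  The
    chain prefers extrema passing the strict prominence gate and falls
    back to the relaxed gate for landmarks with no strict match.  Absent
    landmarks are simply missing from the result (flagged by ``has``).
    Values are in second-derivative units of the normalised beat.
    """
    if wave.fs < 100:
        raise ValueError("sdppg landmarks require fs >= 100 Hz")
    x = wave.samples
    if np.ptp(x) == 0:
        raise ValueError("beat has zero amplitude range")
    xn = (x - x.min()) / np.ptp(x)
    fs = wave.fs
    n = x.size
    period = n / fs

    win = max(int(round(SDPPG_WINDOW * fs)) | 1, SMOOTH_ORDER + 2 | 1)
    d2 = signal.savgol_filter(xn, win, SMOOTH_ORDER, deriv=2,
                              delta=1.0 / fs, mode="wrap")
    i_foot = int(round(pulse_foot(wave) * fs)) % n
    span = int(0.75 * n)
    idx = (i_foot + np.arange(span)) % n
    seg = d2[idx]
    rng = float(np.ptp(seg))

    def extrema(prom_frac):
        maxima, _ = signal.find_peaks(seg, prominence=prom_frac * rng)
        minima, _ = signal.find_peaks(-seg, prominence=prom_frac * rng)
        return sorted([(int(j), +1) for j in maxima]
                      + [(int(j), -1) for j in minima])

    strict = extrema(SDPPG_PROMINENCE)
    relaxed = extrema(SDPPG_PROMINENCE_RELAXED)

    # a: first strict maximum at least 30% as tall as the largest one.
    tallest = max((seg[j] for j, kind in strict if kind == +1), default=0.0)
    a_pos = next((j for j, kind in strict
                  if kind == +1 and seg[j] >= 0.3 * tallest), None)
    if a_pos is None:
        return SdppgLandmarks()

    out = SdppgLandmarks()

    def record(name: str, j: int) -> None:
        out.times[name] = _wrap_time((i_foot + j) / fs, period)
        out.values[name] = float(seg[j])

    record("a", a_pos)
    pos, want = a_pos, -1  # landmarks alternate min/max after a
    for name in "bcde":
        nxt = next((j for j, kind in strict if j > pos and kind == want),
                   None)
        if nxt is None:
            nxt = next((j for j, kind in relaxed
                        if j > pos and kind == want), None)
        if nxt is None:
            break
        record(name, nxt)
        pos, want = nxt, -want
    return out
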