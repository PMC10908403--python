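"""Virtual-subject generator with known ground-truth aortic stiffness.

Each synthetic subject carries single-beat pressure, flow-velocity, luminal
area and PPG waveforms at the standard measurement sites, built from a
closed-form forward ejection wave plus a delayed, scaled reflection:

* the aortic-root pressure is ``DBP + Pf(t) + Pb(t)`` where the forward wave
  ``Pf`` has a raised-cosine systolic upstroke followed by an exponential
  diastolic decay, and the backward wave ``Pb`` is the forward wave scaled
  by a reflection gain and delayed by a reflection time that shortens as the
  wall stiffens;
* flow velocity obeys the water-hammer relation
  ``U = (Pf - Pb) / (rho * c)`` with ``c`` the theoretical aortic-root wave
  speed, so wave-separation analysis can recover the construction exactly;
* distal waveforms are the root beat delayed by the cumulative segment
  transit time ``sum L_j / c_j`` (local thin-wall elastic speeds), with mild
  pulse-pressure amplification toward the periphery;
* the carotid area waveform is linearly coupled to local pressure so that
  the true distensibility is ``1 / (rho * c_carotid^2)``;
* digital and ankle PPG waveforms are min-max-normalised local pressure
  plus a diastolic Gaussian wave whose amplitude fades with age, emulating
  the disappearance of the PPG diastolic peak in older subjects.

Waveform values are evaluated analytically at shifted phases, so stored
transit delays are exact (not quantised to the sample grid).  Wall
stiffness follows the Olufsen law with the large-artery constant ``k3``
scaled linearly in age so that the length-weighted aortic Young's modulus
spans roughly 0.4-1.3 MPa between ages 25 and 75.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ArterialSegment, PulseWave, VirtualSubject
from .stiffness import (WallLaw, aortic_young_modulus, local_wave_speed,
                        theoretical_ao_pwv)

# Olufsen wall-law constants in SI (1 g s^-2 cm^-1 = 0.1 Pa).
K1_DEFAULT = 2.0e6     # Pa
K2_DEFAULT = -2253.0   # 1/m
K3_DEFAULT = 8.65e4    # Pa

RHO_DEFAULT = 1060.0   # kg/m^3

#: Effective distance to the dominant reflection site [m]; the reflection
#: delay of the root beat is 2 * D_REFLECT / c.
D_REFLECT = 0.45

#: Diastolic pressure at unit peripheral-resistance scale [Pa] (~70 mmHg).
DBP_BASE = 9330.0

#: Peak forward flow velocity at unit stroke-volume scale [m/s].
U_PEAK_BASE = 0.75

#: Pulse-pressure amplification per metre of path toward the periphery.
AMPLIFICATION_PER_M = 0.08

_ONSET = 0.02  # s, start of the systolic upstroke within the beat window

#: Time from upstroke start to the forward-wave peak, as a fraction of the
#: systolic duration; kept short so the upslope is impulse-like and the
#: forward/backward derivative overlap (which biases wave separation) stays
#: small.
T_UP_FRACTION = 0.15

#: Diastolic decay time constant as a fraction of the period.
TAU_D_FRACTION = 0.45


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator controls (the study conditions, not per-subject state).

    ``stiffness_scale``, ``reflection_gain`` and ``diastolic_ppg_gain`` are
    the values at the *reference* operating point; :func:`make_subject`
    modulates them with age.  ``diameter_scale`` and ``pvr_scale`` scale the
    large-artery radii and the peripheral vascular resistance (which sets
    diastolic pressure and the diastolic decay time).
    """

    n_subjects: int = 1
    age_range: tuple = (25.0, 75.0)
    hr: float = 65.0                    # bpm
    stroke_volume_scale: float = 1.0
    systole_fraction: float = 0.35      # fraction of the cycle
    stiffness_scale: float = 1.0        # multiplies k3
    reflection_gain: float = 0.3        # backward/forward amplitude, [0, 1)
    diastolic_ppg_gain: float = 0.4     # PPG diastolic-wave amplitude, [0, 1]
    diameter_scale: float = 1.0
    pvr_scale: float = 1.0
    fs: float = 500.0                   # Hz
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not 0 <= self.reflection_gain < 1:
            raise ValueError("reflection_gain must lie in [0, 1)")
        if not 0 <= self.diastolic_ppg_gain <= 1:
            raise ValueError("diastolic_ppg_gain must lie in [0, 1]")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Exact per-subject reference values stored by the generator."""

    ao_pwv_t: float                      # m/s, theoretical root wave speed
    onset_time: float                    # s, tangent-method foot of the root
                                         # beat (closed form for this shape)
    reflection_gain: float
    reflection_delay: float              # s
    upstroke_start: float = _ONSET       # s, where the upstroke leaves DBP
    forward_wave: Optional[PulseWave] = None
    backward_wave: Optional[PulseWave] = None
    e_ao: Optional[float] = None         # Pa, length-weighted aortic modulus
    dc_true: Optional[float] = None      # 1/Pa, carotid distensibility
    transit_delays: dict = field(default_factory=dict)   # site-pair -> s
    site_delays: dict = field(default_factory=dict)      # site -> s from root


def _aging_stiffness(age: float) -> float:
    """k3 multiplier vs age: 0.7 at 25 yr rising linearly to 2.25 at 75 yr."""
    return 0.7 + 1.55 * (age - 25.0) / 50.0


def _aging_reflection(age: float, base: float) -> float:
    g = base * (0.7 + 0.8 * (age - 25.0) / 50.0)
    return min(g, 0.95)


def _aging_ppg_gain(age: float, base: float) -> float:
    """Diastolic-wave amplitude fades with age but keeps a small floor, so
    elderly beats lose the distinct peak yet retain a diastolic inflection."""
    frac = np.clip((75.0 - age) / 50.0, 0.0, 1.0)
    return base * (0.15 + 0.85 * frac)


def _forward_shape(phase: np.ndarray, t_up: float, period: float,
                   tau_d: float) -> np.ndarray:
    """Unit-amplitude forward wave on the periodic phase grid [0, period).

    Raised-cosine upstroke over [0, t_up], then an exponential decay pinned
    to zero at the period end so the periodic extension has no jump.
    """
    phase = np.mod(phase, period)
    out = np.zeros_like(phase)
    up = phase < t_up
    out[up] = 0.5 * (1.0 - np.cos(np.pi * phase[up] / t_up))
    x = phase[~up] - t_up
    x_end = period - t_up
    tail = np.exp(-x / tau_d)
    floor = np.exp(-x_end / tau_d)
    out[~up] = (tail - floor) / (1.0 - floor)
    return out


def _root_law(spec: SyntheticSpec) -> WallLaw:
    return WallLaw(K1_DEFAULT, K2_DEFAULT, K3_DEFAULT * spec.stiffness_scale)


def _root_radius(spec: SyntheticSpec) -> float:
    return 0.01363 * spec.diameter_scale  # mean radius of the first segment


def make_root_beat(spec: SyntheticSpec):
    """Build the aortic-root pressure and flow-velocity beat.

    Returns ``(pressure, flow_velocity, truth)`` where ``truth`` is a
    partially filled :class:`GroundTruth` carrying the theoretical root wave
    speed, the beat onset and the forward/backward pressure components.
    """
    period = 60.0 / spec.hr
    n = int(round(period * spec.fs))
    t = np.arange(n) / spec.fs

    law = _root_law(spec)
    r0 = _root_radius(spec)
    seg0 = ArterialSegment(0.04, r0, r0, law.k1, law.k2, law.k3)
    c0 = theoretical_ao_pwv(seg0, RHO_DEFAULT)

    t_sys = spec.systole_fraction * period
    t_up = T_UP_FRACTION * t_sys
    tau_d = TAU_D_FRACTION * period * spec.pvr_scale
    tau_r = 2.0 * D_REFLECT / c0
    if tau_r < 2.0 / spec.fs:
        raise ValueError("reflection delay shorter than 2 sample intervals")

    u_peak = U_PEAK_BASE * spec.stroke_volume_scale / spec.diameter_scale ** 2
    amp_f = RHO_DEFAULT * c0 * u_peak
    dbp = DBP_BASE * np.sqrt(spec.pvr_scale)

    phase = t - _ONSET
    fwd = amp_f * _forward_shape(phase, t_up, period, tau_d)
    bwd = spec.reflection_gain * amp_f * _forward_shape(
        phase - tau_r, t_up, period, tau_d)

    p = PulseWave(dbp + fwd + bwd, spec.fs, "aortic_root", "pressure")
    u = PulseWave((fwd - bwd) / (RHO_DEFAULT * c0), spec.fs,
                  "aortic_root", "flow_velocity")

    # For a raised-cosine upstroke the intersecting-tangent foot sits at
    # t0 + t_up * (1/2 - 1/pi): maximum slope pi/(2 t_up) at mid-upstroke
    # (value 1/2), intersected with the pre-systolic baseline.
    foot_time = _ONSET + t_up * (0.5 - 1.0 / np.pi)

    truth = GroundTruth(
        ao_pwv_t=c0,
        onset_time=foot_time,
        upstroke_start=_ONSET,
        reflection_gain=spec.reflection_gain,
        reflection_delay=tau_r,
        forward_wave=PulseWave(fwd, spec.fs, "aortic_root", "pressure"),
        backward_wave=p.with_samples(bwd) if spec.reflection_gain > 0
        else PulseWave(np.zeros(n), spec.fs, "aortic_root", "pressure"),
    )
    return p, u, truth


# ---------------------------------------------------------------------------
# Arterial-tree geometry

_AORTIC_LENGTHS = np.array(
    [0.04, 0.02, 0.02, 0.05, 0.05, 0.06, 0.06, 0.06, 0.07, 0.07])  # m
_AORTIC_R_PROX, _AORTIC_R_DIST = 0.0140, 0.0065  # m

# Peripheral branches: (length, r_in, r_out) continuing from a trunk point.
_BRANCHES = {
    "carotid": [(0.11, 0.0040, 0.0030)],
    "brachial": [(0.39, 0.0060, 0.0035)],
    "forearm": [(0.25, 0.0025, 0.0015)],
    "hand": [(0.10, 0.0012, 0.0008)],
    "iliofemoral": [(0.15, 0.0050, 0.0040)],
    "leg": [(0.65, 0.0035, 0.0020)],
}

#: Number of aortic segments traversed before each branch leaves the trunk.
_TAKEOFF = {"carotid": 1, "brachial": 2, "desc_aorta": 4, "iliofemoral": 10}


def _build_aorta(spec: SyntheticSpec) -> list:
    law = _root_law(spec)
    bounds = np.linspace(_AORTIC_R_PROX, _AORTIC_R_DIST, 11)
    bounds = bounds * spec.diameter_scale
    return [
        ArterialSegment(float(L), float(bounds[i]), float(bounds[i + 1]),
                        law.k1, law.k2, law.k3)
        for i, L in enumerate(_AORTIC_LENGTHS)
    ]


def _branch_segments(spec: SyntheticSpec, names) -> list:
    law = _root_law(spec)
    segs = []
    for name in names:
        for L, r_in, r_out in _BRANCHES[name]:
            segs.append(ArterialSegment(
                L, r_in * spec.diameter_scale, r_out * spec.diameter_scale,
                law.k1, law.k2, law.k3))
    return segs


def _site_paths(spec: SyntheticSpec) -> dict:
    """Map each distal site to its ordered root-to-site segment list."""
    aorta = _build_aorta(spec)
    return {
        "carotid": aorta[:_TAKEOFF["carotid"]]
        + _branch_segments(spec, ["carotid"]),
        "brachial": aorta[:_TAKEOFF["brachial"]]
        + _branch_segments(spec, ["brachial"]),
        "radial": aorta[:_TAKEOFF["brachial"]]
        + _branch_segments(spec, ["brachial", "forearm"]),
        "digital": aorta[:_TAKEOFF["brachial"]]
        + _branch_segments(spec, ["brachial", "forearm", "hand"]),
        "desc_aorta": aorta[:_TAKEOFF["desc_aorta"]],
        "femoral": aorta + _branch_segments(spec, ["iliofemoral"]),
        "ankle": aorta + _branch_segments(spec, ["iliofemoral", "leg"]),
    }


def _path_length(segs) -> float:
    return float(sum(s.length for s in segs))


def _path_delay(segs, rho: float) -> float:
    """Transit delay along a segment chain: sum of L_j / c_j."""
    total = 0.0
    for s in segs:
        law = WallLaw(s.k1, s.k2, s.k3, s.h_over_r)
        total += s.length / local_wave_speed(s.mean_radius, law, rho)
    return total


def make_subject(spec: SyntheticSpec, age: float,
                 subject_id: str = "s0", height: float = 1.75):
    """Generate one virtual subject of the given age.

    Returns ``(subject, truth)``.  The spec's stiffness scale, reflection
    gain and PPG diastolic gain are modulated by the built-in aging laws
    before the beat is synthesised.
    """
    eff = dataclasses.replace(
        spec,
        stiffness_scale=spec.stiffness_scale * _aging_stiffness(age),
        reflection_gain=_aging_reflection(age, spec.reflection_gain),
        diastolic_ppg_gain=_aging_ppg_gain(age, spec.diastolic_ppg_gain),
    )
    p_root, u_root, truth = make_root_beat(eff)
    n = p_root.n
    period = n / eff.fs
    t = p_root.t
    rho = RHO_DEFAULT

    paths = _site_paths(eff)
    site_delays = {site: _path_delay(segs, rho) for site, segs in paths.items()}
    site_lengths = {site: _path_length(segs) for site, segs in paths.items()}

    path_lengths = {
        "ao": site_lengths["desc_aorta"],
        "cf": site_lengths["femoral"] - site_lengths["carotid"],
        "ba": site_lengths["ankle"] - site_lengths["brachial"],
        "cb": site_lengths["brachial"] - site_lengths["carotid"],
        "cr": site_lengths["radial"] - site_lengths["carotid"],
        "ft": site_lengths["ankle"] - site_lengths["digital"],
        "ha": site_lengths["ankle"],
    }
    truth.site_delays = dict(site_delays, aortic_root=0.0)
    truth.transit_delays = {
        "ao": site_delays["desc_aorta"],
        "cf": site_delays["femoral"] - site_delays["carotid"],
        "ba": site_delays["ankle"] - site_delays["brachial"],
        "cb": site_delays["brachial"] - site_delays["carotid"],
        "cr": site_delays["radial"] - site_delays["carotid"],
        "ft": site_delays["ankle"] - site_delays["digital"],
        "ha": site_delays["ankle"],
    }

    # Re-evaluate the analytic beat at shifted phases per site, so transit
    # delays are exact rather than rounded to the sample grid.
    law = _root_law(eff)
    r0 = _root_radius(eff)
    seg0 = ArterialSegment(0.04, r0, r0, law.k1, law.k2, law.k3)
    c0 = truth.ao_pwv_t
    t_sys = eff.systole_fraction * period
    t_up = T_UP_FRACTION * t_sys
    tau_d = TAU_D_FRACTION * period * eff.pvr_scale
    tau_r = truth.reflection_delay
    u_peak = U_PEAK_BASE * eff.stroke_volume_scale / eff.diameter_scale ** 2
    amp_f = rho * c0 * u_peak
    dbp = DBP_BASE * np.sqrt(eff.pvr_scale)

    def pulsatile(delay: float) -> np.ndarray:
        phase = t - _ONSET - delay
        fwd = _forward_shape(phase, t_up, period, tau_d)
        bwd = eff.reflection_gain * _forward_shape(
            phase - tau_r, t_up, period, tau_d)
        return amp_f * (fwd + bwd)

    def flow(delay: float) -> np.ndarray:
        phase = t - _ONSET - delay
        fwd = _forward_shape(phase, t_up, period, tau_d)
        bwd = eff.reflection_gain * _forward_shape(
            phase - tau_r, t_up, period, tau_d)
        return u_peak * (fwd - bwd)

    waves = {
        ("aortic_root", "pressure"): p_root,
        ("aortic_root", "flow_velocity"): u_root,
        ("desc_aorta", "flow_velocity"): PulseWave(
            flow(site_delays["desc_aorta"]), eff.fs, "desc_aorta",
            "flow_velocity"),
    }
    for site in ("carotid", "brachial", "radial", "femoral", "ankle"):
        amp = 1.0 + AMPLIFICATION_PER_M * site_lengths[site]
        waves[(site, "pressure")] = PulseWave(
            dbp + amp * pulsatile(site_delays[site]), eff.fs, site, "pressure")

    # Carotid area: linear pressure-area coupling at the local wave speed.
    r_car = 0.5 * (_BRANCHES["carotid"][0][1] + _BRANCHES["carotid"][0][2])
    r_car *= eff.diameter_scale
    c_car = local_wave_speed(r_car, law, rho)
    a_dia = np.pi * r_car ** 2
    p_car = waves[("carotid", "pressure")].samples
    waves[("carotid", "area")] = PulseWave(
        a_dia * (1.0 + (p_car - dbp) / (rho * c_car ** 2)),
        eff.fs, "carotid", "area")
    truth.dc_true = 1.0 / (rho * c_car ** 2)

    # Digital and ankle PPG: normalised local pressure + diastolic wave.
    # The diastolic wave trails end-systole by the reflection delay, so the
    # systolic-to-diastolic interval shortens as the wall stiffens (the
    # in vivo basis of the PPG stiffness index) while staying clear of the
    # systolic complex.
    sigma_dia = 0.04
    mu_dia = t_sys + tau_r
    for site in ("digital", "ankle"):
        raw = pulsatile(site_delays[site])
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        phase = np.mod(t - _ONSET - site_delays[site], period)
        gauss = eff.diastolic_ppg_gain * np.exp(
            -0.5 * ((phase - mu_dia) / sigma_dia) ** 2)
        ppg = norm + gauss
        ppg = (ppg - ppg.min()) / (ppg.max() - ppg.min())
        waves[(site, "ppg")] = PulseWave(ppg, eff.fs, site, "ppg")

    aorta = _build_aorta(eff)
    truth.e_ao = aortic_young_modulus(aorta)

    subject = VirtualSubject(
        id=subject_id, age=age, height=height,
        aortic_path=aorta, path_lengths=path_lengths,
        waves=waves, rho=rho)
    return subject, truth


def make_population(spec: SyntheticSpec):
    """Generate ``spec.n_subjects`` subjects with seeded per-subject jitter.

    Ages are drawn uniformly over ``spec.age_range``; heart rate, stroke
    volume and stiffness receive mild multiplicative jitter; height is
    normally distributed.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_subjects):
        age = float(rng.uniform(*spec.age_range))
        subj_spec = dataclasses.replace(
            spec,
            hr=spec.hr * float(rng.normal(1.0, 0.06)),
            stroke_volume_scale=spec.stroke_volume_scale
            * float(rng.normal(1.0, 0.08)),
            stiffness_scale=spec.stiffness_scale
            * float(np.exp(rng.normal(0.0, 0.06))),
        )
        height = float(rng.normal(1.75, 0.07))
        subject, truth = make_subject(subj_spec, age,
                                      subject_id=f"s{i:04d}", height=height)
        out.append((subject, truth))
    return out
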