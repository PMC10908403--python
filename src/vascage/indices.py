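"""The 19 pulse-wave indices of vascular aging.

Six transit-time pulse wave velocities (aoPWV, cfPWV, baPWV, cbPWV, crPWV,
ftPWV) use the foot-to-foot delay between two sites divided into the
arterial path distance.  Pressure-morphology indices (cPP, bPP, AP, AIx)
come from the aortic-root and brachial beats; Pb amplitude and reflection
magnitude from wave-separation analysis of simultaneous aortic pressure and
flow velocity; CAVI from brachial pressures and the heart-ankle PWV; the
carotid distensibility coefficient from the carotid area beat and brachial
pulse pressure; and five PPG indices (RI, SI, AGI, AIx_ppg, d/a) from the
digital PPG and its second derivative.

All inputs and outputs are SI; AIx, RM and AIx_ppg are returned as ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IndexPanel, PulseWave, VirtualSubject
from .fiducials import (FiducialSetPPG, FiducialSetPressure, SdppgLandmarks,
                        ppg_landmarks, pressure_inflections, pulse_foot,
                        sdppg_landmarks)


@dataclass(frozen=True)
class WaveSeparationResult:
    """Forward/backward pressure decomposition of one beat."""

    pf: PulseWave
    pb: PulseWave
    c: float        # m/s, water-hammer wave speed estimate
    pf_amp: float   # Pa
    pb_amp: float   # Pa
    rm: float       # reflection magnitude, pb_amp / pf_amp


@dataclass(frozen=True)
class CaviCoefficients:
    """Empirical scale/offset of the cardio-ankle vascular index."""

    c1: float = 1.0
    c2: float = 0.0


@dataclass(frozen=True)
class IndexConfig:
    """Tunable conventions for the panel computation.

    ``ri_systolic_over_diastolic`` selects RI = s/dia (the orientation that
    rises with stiffness); set False for the in vivo dia/s convention.
    """

    cavi: CaviCoefficients = CaviCoefficients()
    ri_systolic_over_diastolic: bool = True


def transit_time_pwv(wave_a: PulseWave, wave_b: PulseWave,
                     delta_x: float):
    """Foot-to-foot pulse wave velocity [m/s] between two sites.

    The delay is the difference of intersecting-tangent foot times wrapped
    into (0, period).  Returns ``(pwv, reliable)``; delays below two sample
    intervals are flagged unreliable.
    """
    if wave_a.fs != wave_b.fs:
        raise ValueError("waveforms must share the sampling frequency")
    if not delta_x > 0:
        raise ValueError("path length must be positive")
    period = wave_a.duration
    dt = float(np.mod(pulse_foot(wave_b) - pulse_foot(wave_a), period))
    reliable = dt >= 2.0 / wave_a.fs
    if dt == 0.0:
        return np.nan, False
    return delta_x / dt, reliable


def pulse_pressure(wave: PulseWave) -> float:
    """Pulse pressure [Pa]: beat maximum minus minimum."""
    if wave.modality != "pressure":
        raise ValueError("pulse_pressure expects a pressure beat")
    return float(np.ptp(wave.samples))


def augmentation(fids: FiducialSetPressure, pp: float):
    """Augmentation pressure AP = P2 - P1 [Pa] and index AIx = AP/PP.

    AP may be negative for late-reflection (type C) beats.  Returns
    ``(ap, aix, ok)``; degenerate fiducials yield (0, 0, False).
    """
    if not pp > 0:
        raise ValueError("pulse pressure must be positive")
    ap = fids.p2 - fids.p1
    return ap, ap / pp, not fids.degenerate


def wave_separation(p: PulseWave, u: PulseWave,
                    rho: float) -> WaveSeparationResult:
    """Separate pressure into forward and backward traveling components.

    The wave speed is the sum-of-squares water-hammer estimate
    ``c = sqrt(sum dP^2 / sum dU^2) / rho``; forward and backward waves are
    cumulative sums of ``(dP ± rho c dU)/2`` started at zero.  The backward
    amplitude is max(Pb) - min(Pb) and RM = Pb_amp / Pf_amp.
    """
    if p.n != u.n or p.fs != u.fs:
        raise ValueError("pressure and velocity beats must be aligned")
    dp = np.diff(p.samples)
    du = np.diff(u.samples)
    sum_du2 = float(np.sum(du ** 2))
    if sum_du2 == 0.0:
        raise ValueError("flow-velocity beat has no variation")
    c = float(np.sqrt(np.sum(dp ** 2) / sum_du2)) / rho

    pf = np.concatenate(([0.0], np.cumsum(0.5 * (dp + rho * c * du))))
    pb = np.concatenate(([0.0], np.cumsum(0.5 * (dp - rho * c * du))))
    pf_amp = float(np.ptp(pf))
    pb_amp = float(np.ptp(pb))
    # Pure forward waves leave a backward residual at rounding level; snap
    # it to zero so the algebraic identity U = P/(rho c) => Pb = 0 holds.
    if pb_amp <= 1e-12 * pf_amp:
        pb = np.zeros_like(pb)
        pb_amp = 0.0
    return WaveSeparationResult(
        pf=p.with_samples(pf), pb=p.with_samples(pb), c=c,
        pf_amp=pf_amp, pb_amp=pb_amp,
        rm=pb_amp / pf_amp if pf_amp > 0 else np.nan)


def cavi(sbp: float, dbp: float, pp: float, ha_pwv: float, rho: float,
         coef: CaviCoefficients = CaviCoefficients()) -> float:
    """Cardio-ankle vascular index (dimensionless).

    ``c1 * ln(SBP/DBP) * (2 rho / PP) * haPWV^2 + c2`` with brachial
    pressures in Pa and the heart-ankle PWV in m/s.
    """
    if not (sbp > dbp > 0 and pp > 0):
        raise ValueError("require SBP > DBP > 0 and PP > 0")
    return coef.c1 * np.log(sbp / dbp) * (2.0 * rho / pp) * ha_pwv ** 2 \
        + coef.c2


def distensibility(delta_a: float, a_dia: float, bpp: float) -> float:
    """Carotid distensibility coefficient [1/Pa]: (dA/A_dia) / bPP."""
    if not (a_dia > 0 and bpp > 0):
        raise ValueError("require positive diastolic area and brachial PP")
    return (delta_a / a_dia) / bpp


def ppg_panel(fids: FiducialSetPPG, sd: SdppgLandmarks, height: float,
              config: IndexConfig = IndexConfig()) -> dict:
    """The five PPG indices; absent landmarks yield None entries.

    RI = s/dia (configurable orientation), SI = H/deltaT [m/s],
    AGI = (b - c - d - e)/a, AIx_ppg = PT2/PT1, and d/a, the last three on
    signed second-derivative values.
    """
    out = {"RI_ppg": None, "SI_ppg": None, "AGI": None,
           "AIx_ppg": None, "d_over_a": None}
    if fids.dia is not None and fids.dia > 0:
        out["RI_ppg"] = (fids.s / fids.dia if config.ri_systolic_over_diastolic
                         else fids.dia / fids.s)
    if fids.delta_t is not None and fids.delta_t > 0:
        out["SI_ppg"] = height / fids.delta_t
    if fids.shoulders_found and fids.pt1 and fids.pt1 > 0:
        out["AIx_ppg"] = fids.pt2 / fids.pt1
    if sd.complete() and sd.values["a"] != 0:
        v = sd.values
        out["AGI"] = (v["b"] - v["c"] - v["d"] - v["e"]) / v["a"]
    if sd.has("a") and sd.has("d") and sd.values["a"] != 0:
        out["d_over_a"] = sd.values["d"] / sd.values["a"]
    return out


_PWV_INPUTS = {
    # index -> (site_a, modality_a, site_b, modality_b, path key)
    "aoPWV": ("aortic_root", "flow_velocity", "desc_aorta", "flow_velocity",
              "ao"),
    "cfPWV": ("carotid", "pressure", "femoral", "pressure", "cf"),
    "baPWV": ("brachial", "pressure", "ankle", "pressure", "ba"),
    "cbPWV": ("carotid", "pressure", "brachial", "pressure", "cb"),
    "crPWV": ("carotid", "pressure", "radial", "pressure", "cr"),
    "ftPWV": ("digital", "ppg", "ankle", "ppg", "ft"),
}


def compute_panel(subject: VirtualSubject,
                  config: IndexConfig = IndexConfig()) -> IndexPanel:
    """Compute every index available from a subject's waveforms.

    Missing input signals degrade only the indices that need them; each
    absent index is flagged with the reason rather than failing the panel.
    """
    panel = IndexPanel()

    def flag(name, reason):
        panel.flag_missing(name, reason)

    for name, (sa, ma, sb, mb, key) in _PWV_INPUTS.items():
        wa, wb = subject.wave(sa, ma), subject.wave(sb, mb)
        dx = subject.path_lengths.get(key)
        if wa is None or wb is None or dx is None:
            flag(name, f"missing input for {name}")
            continue
        try:
            pwv, reliable = transit_time_pwv(wa, wb, dx)
        except ValueError as exc:
            flag(name, str(exc))
            continue
        if np.isfinite(pwv) and reliable:
            panel.set(name, pwv)
        else:
            flag(name, "transit delay below resolution")

    p_root = subject.wave("aortic_root", "pressure")
    p_brach = subject.wave("brachial", "pressure")

    cpp = bpp = None
    if p_root is not None:
        cpp = pulse_pressure(p_root)
        panel.set("cPP", cpp)
    else:
        flag("cPP", "missing aortic root pressure")
    if p_brach is not None:
        bpp = pulse_pressure(p_brach)
        panel.set("bPP", bpp)
    else:
        flag("bPP", "missing brachial pressure")

    if p_root is not None and cpp and cpp > 0:
        fids = pressure_inflections(p_root)
        ap, aix, ok = augmentation(fids, cpp)
        if ok:
            panel.set("AP", ap)
            panel.set("AIx", aix)
        else:
            flag("AP", "no distinct P1/P2 shoulders")
            flag("AIx", "no distinct P1/P2 shoulders")
    else:
        flag("AP", "missing aortic root pressure")
        flag("AIx", "missing aortic root pressure")

    u_root = subject.wave("aortic_root", "flow_velocity")
    if p_root is not None and u_root is not None:
        try:
            sep = wave_separation(p_root, u_root, subject.rho)
            panel.set("Pb_amp", sep.pb_amp)
            panel.set("RM", sep.rm)
        except ValueError as exc:
            flag("Pb_amp", str(exc))
            flag("RM", str(exc))
    else:
        flag("Pb_amp", "missing aortic root pressure or flow")
        flag("RM", "missing aortic root pressure or flow")

    p_ankle = subject.wave("ankle", "pressure")
    ha_dx = subject.path_lengths.get("ha")
    if (p_brach is not None and p_root is not None and p_ankle is not None
            and ha_dx is not None and bpp and bpp > 0):
        sbp = float(np.max(p_brach.samples))
        dbp = float(np.min(p_brach.samples))
        ha_pwv, reliable = transit_time_pwv(p_root, p_ankle, ha_dx)
        if np.isfinite(ha_pwv) and reliable and sbp > dbp > 0:
            panel.set("CAVI", cavi(sbp, dbp, bpp, ha_pwv, subject.rho,
                                   config.cavi))
        else:
            flag("CAVI", "heart-ankle transit unreliable")
    else:
        flag("CAVI", "missing brachial/ankle pressure")

    a_car = subject.wave("carotid", "area")
    if a_car is not None and bpp and bpp > 0:
        a = a_car.samples
        panel.set("DC", distensibility(float(np.ptp(a)), float(np.min(a)),
                                       bpp))
    else:
        flag("DC", "missing carotid area or brachial PP")

    ppg = subject.wave("digital", "ppg")
    if ppg is not None:
        try:
            pf = ppg_landmarks(ppg)
            sd = sdppg_landmarks(ppg)
            for name, value in ppg_panel(pf, sd, subject.height,
                                         config).items():
                if value is None:
                    flag(name, "PPG landmark absent")
                else:
                    panel.set(name, value)
        except ValueError as exc:
            for name in ("RI_ppg", "SI_ppg", "AGI", "AIx_ppg", "d_over_a"):
                flag(name, str(exc))
    else:
        for name in ("RI_ppg", "SI_ppg", "AGI", "AIx_ppg", "d_over_a"):
            flag(name, "missing digital PPG")

    panel.validate()
    return panel
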