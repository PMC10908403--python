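"""Shared domain types and unit conventions.

All quantities are stored in coherent SI units internally: pressure in Pa,
velocity in m/s, luminal area in m^2, lengths and radii in m, blood density
in kg/m^3.  Millimetres of mercury appear only at I/O boundaries.  PPG
signals are dimensionless.

Every waveform is a single pre-segmented cardiac cycle: the first sample is
at or before the pulse foot and the last sample is at end of diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

MMHG_PA = 133.322
"""Pascals per millimetre of mercury."""

SITES = (
    "aortic_root",
    "carotid",
    "brachial",
    "radial",
    "digital",
    "femoral",
    "ankle",
    "desc_aorta",
)

MODALITIES = ("pressure", "flow_velocity", "area", "ppg")

#: The 19 pulse-wave indices of vascular aging handled by this package.
INDEX_NAMES = (
    "aoPWV", "cfPWV", "baPWV", "cbPWV", "crPWV", "ftPWV",
    "cPP", "bPP", "AP", "AIx", "Pb_amp", "RM",
    "CAVI", "DC",
    "RI_ppg", "SI_ppg", "AGI", "AIx_ppg", "d_over_a",
)

_UNIT_TO_PA = {"Pa": 1.0, "kPa": 1000.0, "mmHg": MMHG_PA}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure value between Pa, kPa and mmHg.

    Uses the exact factor 1 mmHg = 133.322 Pa.  Raises ``ValueError`` for
    an unknown unit label.
    """
    try:
        in_pa = value * _UNIT_TO_PA[from_unit]
        return in_pa / _UNIT_TO_PA[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown pressure unit {exc.args[0]!r}; "
                         f"expected one of {sorted(_UNIT_TO_PA)}") from None


@dataclass(frozen=True)
class PulseWave:
    """One cardiac cycle of a pressure, flow-velocity, area or PPG signal.

    Parameters
    ----------
    samples
        Uniformly sampled signal values (SI units per modality).
    fs
        Sampling frequency in Hz.
    site
        Arterial measurement site, one of :data:`SITES`.
    modality
        Signal kind, one of :data:`MODALITIES`.
    """

    samples: np.ndarray
    fs: float
    site: str
    modality: str

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if samples.ndim != 1 or samples.size < 3:
            raise ValueError("samples must be a 1-D array of length >= 3")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Beat period in seconds (n samples at fs, periodic convention)."""
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "PulseWave":
        """Return a copy carrying new sample values (same fs/site/modality)."""
        return PulseWave(np.asarray(samples, dtype=float), self.fs,
                         self.site, self.modality)


@dataclass(frozen=True)
class ArterialSegment:
    """A straight arterial segment with an Olufsen-type elastic wall.

    ``k1`` [Pa], ``k2`` [1/m] and ``k3`` [Pa] are the empirical wall-law
    constants (small-artery stiffness, stiffness transition rate, and
    large-artery stiffness).  ``h_over_r`` is the wall thickness-to-radius
    ratio, 0.15 by default.
    """

    length: float
    r_in: float
    r_out: float
    k1: float
    k2: float
    k3: float
    h_over_r: float = 0.15

    def __post_init__(self):
        if not self.length > 0:
            raise ValueError("segment length must be positive")
        if not (self.r_in > 0 and self.r_out > 0):
            raise ValueError("radii must be positive")
        if not 0 < self.h_over_r < 1:
            raise ValueError("h_over_r must lie in (0, 1)")

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.r_in + self.r_out)


@dataclass
class VirtualSubject:
    """One virtual subject: geometry, demographics and single-beat waveforms.

    ``waves`` maps ``(site, modality)`` pairs to :class:`PulseWave` objects;
    ``path_lengths`` maps the site-pair labels used by the transit-time
    indices (``ao``, ``cf``, ``ba``, ``cb``, ``cr``, ``ft``, ``ha``) to
    propagation distances in metres.
    """

    id: str
    age: float
    height: float
    aortic_path: list
    path_lengths: Mapping[str, float]
    waves: dict
    rho: float = 1060.0

    def __post_init__(self):
        if not self.aortic_path:
            raise ValueError("aortic_path must be non-empty")
        if any(dx <= 0 for dx in self.path_lengths.values()):
            raise ValueError("all path lengths must be positive")
        fss = {w.fs for w in self.waves.values()}
        if len(fss) > 1:
            raise ValueError("all waveforms of a subject must share fs")

    def wave(self, site: str, modality: str) -> Optional[PulseWave]:
        """The beat recorded at ``site`` in ``modality``, or None if absent."""
        return self.waves.get((site, modality))


@dataclass
class IndexPanel:
    """The 19 named vascular-aging index values for one subject.

    Missing indices are explicitly ``None`` (with the reason recorded in
    ``missing``), never silently zero.  PWV values are m/s; cPP, bPP, AP and
    Pb_amp are Pa; DC is 1/Pa; SI_ppg is m/s; the remaining indices are
    dimensionless ratios (AIx, RM, AIx_ppg as ratios, not percent).
    """

    values: dict = field(default_factory=dict)
    missing: dict = field(default_factory=dict)

    def set(self, name: str, value: float) -> None:
        if name not in INDEX_NAMES:
            raise KeyError(f"unknown index {name!r}")
        self.values[name] = float(value)

    def flag_missing(self, name: str, reason: str) -> None:
        if name not in INDEX_NAMES:
            raise KeyError(f"unknown index {name!r}")
        self.missing[name] = reason

    def get(self, name: str) -> Optional[float]:
        return self.values.get(name)

    def is_complete(self) -> bool:
        return all(name in self.values for name in INDEX_NAMES)

    def as_dict(self) -> dict:
        """All 19 indices; absent values appear as None."""
        out = {}
        for name in INDEX_NAMES:
            out[name] = self.values.get(name)
        return out

    def validate(self) -> None:
        """Check that every index is either populated or explicitly flagged."""
        for name in INDEX_NAMES:
            if name not in self.values and name not in self.missing:
                raise ValueError(f"index {name!r} neither computed nor flagged")
        for name in ("aoPWV", "cfPWV", "baPWV", "cbPWV", "crPWV", "ftPWV"):
            v = self.values.get(name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when defined")
        dc = self.values.get("DC")
        if dc is not None and not dc > 0:
            raise ValueError("DC must be positive when defined")
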