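"""Exact reference measures of aortic stiffness.

The arterial wall follows an empirical exponential law (Olufsen) linking the
stiffness-thickness product to the vessel radius,

    Eh / r = k1 * exp(k2 * r) + k3,

with k1 the stiffness of smaller arteries, k2 the rate of transition between
small- and large-artery stiffness (k2 <= 0 in practice) and k3 the stiffness
of larger arteries.  With a fixed wall thickness-to-radius ratio h/r the
effective Young's modulus follows as E = (Eh/r) / (h/r).

The reference aortic stiffness of a subject is the mean of the per-segment
moduli weighted by segment length, and the theoretical aortic-root pulse
wave velocity is the thin-wall elastic (Bramwell-Hill) speed

    aoPWV_t = sqrt(2 Eh / (3 rho r)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ArterialSegment


@dataclass(frozen=True)
class WallLaw:
    """Olufsen wall-law constants plus the wall thickness ratio."""

    k1: float  # Pa
    k2: float  # 1/m
    k3: float  # Pa
    h_over_r: float = 0.15

    def __post_init__(self):
        if not 0 < self.h_over_r < 1:
            raise ValueError("h_over_r must lie in (0, 1)")


def eh_product(r: float, law: WallLaw) -> float:
    """Stiffness-thickness product Eh [Pa*m] at diastolic radius ``r`` [m].

    Eh = r * (k1 * exp(k2 * r) + k3).  Raises for non-positive radius.
    """
    if not r > 0:
        raise ValueError("radius must be positive")
    return r * (law.k1 * np.exp(law.k2 * r) + law.k3)


def young_modulus(r: float, law: WallLaw) -> float:
    """Effective Young's modulus E [Pa] at radius ``r``: Eh / (h/r * r)."""
    return eh_product(r, law) / (law.h_over_r * r)


def segment_young_modulus(seg: ArterialSegment) -> float:
    """E [Pa] of one segment, evaluated at the mean of inlet/outlet radii."""
    law = WallLaw(seg.k1, seg.k2, seg.k3, seg.h_over_r)
    return young_modulus(seg.mean_radius, law)


def aortic_young_modulus(path: Sequence[ArterialSegment]) -> float:
    """Length-weighted aortic Young's modulus E_Ao [Pa].

    E_Ao = sum_j (L_j / L_total) * E_j over the aortic segments.
    """
    path = list(path)
    if not path:
        raise ValueError("aortic path must be non-empty")
    lengths = np.array([s.length for s in path])
    moduli = np.array([segment_young_modulus(s) for s in path])
    return float(np.sum(lengths * moduli) / np.sum(lengths))


def theoretical_ao_pwv(seg: ArterialSegment, rho: float) -> float:
    """Theoretical aortic-root pulse wave velocity [m/s].

    aoPWV_t = sqrt(2 Eh / (3 rho r)) with Eh evaluated from the wall law at
    the root radius.  Because Eh/r = (h/r) * E, this equals
    sqrt(2 (h/r) E / (3 rho)) — sqrt(0.1 E / rho) at the default h/r = 0.15.
    """
    if not rho > 0:
        raise ValueError("blood density must be positive")
    law = WallLaw(seg.k1, seg.k2, seg.k3, seg.h_over_r)
    r = seg.mean_radius
    return float(np.sqrt(2.0 * eh_product(r, law) / (3.0 * rho * r)))


def local_wave_speed(r: float, law: WallLaw, rho: float) -> float:
    """Local thin-wall elastic wave speed c [m/s] at radius ``r``.

    c = sqrt(2 Eh / (3 rho r)) = sqrt(2 (k1 e^{k2 r} + k3) / (3 rho)); this
    is the per-segment speed used for transit-delay bookkeeping.
    """
    if not rho > 0:
        raise ValueError("blood density must be positive")
    return float(np.sqrt(2.0 * eh_product(r, law) / (3.0 * rho * r)))
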