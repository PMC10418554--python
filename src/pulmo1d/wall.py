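"""Vessel wall law, hemodynamic summaries, and nominal Windkessel construction.

The wall is a linearly elastic thin cylinder whose pressure-area relation is

    P(A) = (4/3) * (Eh/r0) * (sqrt(A/Adia) - 1) + Pdia

parameterized by the single composite stiffness ``Eh/r0``.  The relation is
algebraically invertible, which also yields the stiffness analytically from
a measured systolic/diastolic pressure-area pair.

Nominal three-element Windkessel outlets distribute the measured total
pulmonary vascular resistance over the terminal vessels by root-to-terminal
Poiseuille path resistance (rescaled so the parallel combination matches the
measurement) and distribute total compliance proportionally to terminal
conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import VesselNetwork, poiseuille_resistance, terminal_segments
from .units import MMHG

__all__ = [
    "WallModel",
    "Windkessel3",
    "HemodynamicSummary",
    "mean_pa_pressure",
    "total_pvr",
    "tube_law_pressure",
    "tube_law_area",
    "wave_speed",
    "stiffness_from_systole",
    "total_compliance_from_decay",
    "nominal_windkessels",
    "nominal_windkessels_lung_split",
    "parallel_resistance",
    "total_compliance",
]


@dataclass(frozen=True)
class WallModel:
    """Elastic tube law parameters, CGS units.

    stiffness : Eh/r0, dyn/cm^2 (> 0)
    area_dia  : diastolic reference area Adia, cm^2 (> 0)
    p_dia     : diastolic reference pressure, dyn/cm^2
    """

    stiffness: float
    area_dia: float
    p_dia: float

    def __post_init__(self) -> None:
        if not self.stiffness > 0:
            raise ValueError(f"stiffness must be positive, got {self.stiffness}")
        if not self.area_dia > 0:
            raise ValueError(f"Adia must be positive, got {self.area_dia}")


@dataclass(frozen=True)
class Windkessel3:
    """Three-element (RCR) Windkessel, CGS units.

    Rp, Rd : proximal/distal resistances, dyn*s/cm^5 (> 0)
    C      : compliance, cm^5/dyn (> 0)
    Pout   : distal reference pressure (mean wedge pressure), dyn/cm^2
    """

    Rp: float
    Rd: float
    C: float
    Pout: float

    def __post_init__(self) -> None:
        for attr in ("Rp", "Rd", "C"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")

    def scaled(self, rp: float = 1.0, rd: float = 1.0, c: float = 1.0) -> "Windkessel3":
        return Windkessel3(self.Rp * rp, self.Rd * rd, self.C * c, self.Pout)


@dataclass(frozen=True)
class HemodynamicSummary:
    """Scalar clinical measurements in clinical units (mmHg, cm^2, mL/s, s)."""

    p_sys: float
    p_dia: float
    a_sys: float
    a_dia: float
    p_wedge: float
    q_mean: float
    period: float
    t_dia: float  # diastolic duration, s

    def __post_init__(self) -> None:
        if not self.p_sys > self.p_dia:
            raise ValueError("Psys must exceed Pdia")
        if self.a_sys < self.a_dia:
            raise ValueError("Asys must be >= Adia")
        if not (self.period > self.t_dia > 0):
            raise ValueError("need period > diastolic duration > 0")
        if not self.q_mean > 0:
            raise ValueError("mean flow must be positive")

    @property
    def p_mean(self) -> float:
        return mean_pa_pressure(self.p_sys, self.p_dia)


def mean_pa_pressure(p_sys: float, p_dia: float) -> float:
    """Mean PA pressure (Psys + 2*Pdia)/3, mmHg in -> mmHg out."""
    if p_sys < p_dia:
        raise ValueError(f"Psys ({p_sys}) < Pdia ({p_dia})")
    return (p_sys + 2.0 * p_dia) / 3.0


def total_pvr(p_mean: float, p_wedge: float, q_mean: float) -> float:
    """Total pulmonary vascular resistance (Pmean - Pwedge)/Qmean, mmHg*s/mL."""
    if p_mean <= p_wedge:
        raise ValueError(f"mean PA pressure ({p_mean}) must exceed wedge ({p_wedge})")
    if not q_mean > 0:
        raise ValueError(f"mean flow must be positive, got {q_mean}")
    return (p_mean - p_wedge) / q_mean


def tube_law_pressure(area, wall: WallModel):
    """Transmural pressure (dyn/cm^2) at lumen area ``area`` (cm^2)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    p = (4.0 / 3.0) * wall.stiffness * (np.sqrt(area / wall.area_dia) - 1.0) + wall.p_dia
    return float(p) if p.ndim == 0 else p


def tube_law_area(pressure, wall: WallModel):
    """Lumen area (cm^2) at transmural pressure ``pressure`` (dyn/cm^2).

    Exact algebraic inverse of :func:`tube_law_pressure`.  Raises in the
    collapse regime where the bracketed root would be nonpositive.
    """
    pressure = np.asarray(pressure, dtype=float)
    root = 1.0 + 3.0 * (pressure - wall.p_dia) / (4.0 * wall.stiffness)
    if np.any(root <= 0):
        raise ValueError("pressure in collapse regime (tube law root <= 0)")
    a = wall.area_dia * root**2
    return float(a) if a.ndim == 0 else a


def wave_speed(area: float, wall: WallModel, rho: float) -> float:
    """Local pulse wave speed c = sqrt((A/rho) dP/dA), cm/s.

    At A = Adia this reduces to sqrt((2/3) * (Eh/r0) / rho).
    """
    return math.sqrt(2.0 * wall.stiffness / (3.0 * rho) * math.sqrt(area / wall.area_dia))


def stiffness_from_systole(p_sys: float, p_dia: float, a_sys: float, a_dia: float) -> float:
    """Analytic Eh/r0 (same pressure units as the inputs) from a systolic/diastolic pair.

    Inverts the tube law at the systolic point:
    Eh/r0 = 3 (Psys - Pdia) / (4 (sqrt(Asys/Adia) - 1)).
    """
    if p_sys <= p_dia:
        raise ValueError("Psys must exceed Pdia")
    if a_sys <= a_dia:
        raise ValueError("no distension measured (Asys <= Adia)")
    return 3.0 * (p_sys - p_dia) / (4.0 * (math.sqrt(a_sys / a_dia) - 1.0))


def total_compliance_from_decay(
    summary: HemodynamicSummary,
    r_total: float,
    pressure_trace: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Total compliance (mL/mmHg) from the diastolic pressure decay.

    With only scalar systolic/diastolic pressures, the mono-exponential decay
    P(t) = Pwedge + (Psys - Pwedge) exp(-t/(R C)) from Psys to Pdia over the
    diastolic interval Td gives the closed form

        C = Td / (R * ln((Psys - Pwedge)/(Pdia - Pwedge))).

    When a diastolic pressure trace ``(t, P)`` (s, mmHg) is supplied, the
    decay constant is instead fit by least squares on log(P - Pwedge).
    """
    if summary.p_dia <= summary.p_wedge:
        raise ValueError("Pdia must exceed wedge pressure for a decay fit")
    if not r_total > 0:
        raise ValueError("resistance must be positive")
    if pressure_trace is not None:
        t, p = (np.asarray(v, dtype=float) for v in pressure_trace)
        if t.shape != p.shape or t.size < 3:
            raise ValueError("pressure trace needs matching t/P arrays of length >= 3")
        if np.any(p <= summary.p_wedge):
            raise ValueError("trace dips below wedge pressure; cannot fit decay")
        slope = np.polyfit(t, np.log(p - summary.p_wedge), 1)[0]
        if slope >= 0:
            raise ValueError("trace does not decay")
        return -1.0 / (slope * r_total)
    ratio = (summary.p_sys - summary.p_wedge) / (summary.p_dia - summary.p_wedge)
    return summary.t_dia / (r_total * math.log(ratio))


def parallel_resistance(values: Sequence[float]) -> float:
    """Combine resistances in parallel: 1 / sum(1/R_i)."""
    if len(values) == 0:
        raise ValueError("empty resistance list")
    if any(v <= 0 for v in values):
        raise ValueError("resistances must be positive")
    return 1.0 / sum(1.0 / v for v in values)


def total_compliance(values: Sequence[float]) -> float:
    """Combine compliances of parallel outlets: sum(C_i)."""
    if len(values) == 0:
        raise ValueError("empty compliance list")
    if any(v <= 0 for v in values):
        raise ValueError("compliances must be positive")
    return float(sum(values))


def nominal_windkessels(
    net: VesselNetwork,
    r_total: float,
    c_total: float,
    mu: float,
    p_out: float,
) -> dict[str, Windkessel3]:
    """Construct nominal Windkessel outlets for every terminal vessel (CGS in/out).

    Each terminal receives a total resistance proportional to the cumulative
    root-to-terminal Poiseuille path resistance, uniformly rescaled so that
    the parallel combination of all terminals equals ``r_total``; the split
    is Rp = Rd = RT/2.  Compliance is distributed proportionally to terminal
    conductance 1/RT so the outlet compliances sum to ``c_total``.
    """
    if not (r_total > 0 and c_total > 0):
        raise ValueError("r_total and c_total must be positive")
    terms = terminal_segments(net)
    if not terms:
        raise ValueError("network has no terminal segments")
    path_r = np.array(
        [sum(poiseuille_resistance(s, mu) for s in net.path_to_root(t.id)) for t in terms]
    )
    conductance = 1.0 / path_r
    kappa = r_total * conductance.sum()  # parallel total of kappa*path_r equals r_total
    rt = kappa * path_r
    weights = (1.0 / rt) / (1.0 / rt).sum()
    out: dict[str, Windkessel3] = {}
    for seg, rti, w in zip(terms, rt, weights):
        out[seg.id] = Windkessel3(Rp=rti / 2.0, Rd=rti / 2.0, C=c_total * w, Pout=p_out)
    return out


def nominal_windkessels_lung_split(
    net: VesselNetwork,
    r_total: float,
    c_total: float,
    mu: float,
    p_out: float,
    q_left_mean: float,
    q_right_mean: float,
) -> dict[str, Windkessel3]:
    """Nominal Windkessels with the left/right lung resistance split set by
    the measured mean branch flows (CGS in/out).

    Each lung receives a total resistance (P-drop shared): R_lung =
    r_total * (q_left + q_right) / q_lung, so the parallel combination of
    the two lungs reproduces ``r_total``.  Within each lung the total is
    distributed over terminals by root-to-terminal Poiseuille path
    resistance; compliance is distributed across all terminals
    proportionally to conductance.
    """
    if not (q_left_mean > 0 and q_right_mean > 0):
        raise ValueError("mean branch flows must be positive")
    lpa_id, rpa_id = net.root.children
    left_ids = net.subtree_ids(lpa_id)
    q_sum = q_left_mean + q_right_mean
    r_lung = {
        lpa_id: r_total * q_sum / q_left_mean,
        rpa_id: r_total * q_sum / q_right_mean,
    }
    terms = terminal_segments(net)
    path_r = np.array(
        [sum(poiseuille_resistance(s, mu) for s in net.path_to_root(t.id)) for t in terms]
    )
    is_left = np.array([t.id in left_ids for t in terms])
    rt = np.empty(len(terms))
    for side, r_side in ((True, r_lung[lpa_id]), (False, r_lung[rpa_id])):
        mask = is_left == side
        kappa = r_side * (1.0 / path_r[mask]).sum()
        rt[mask] = kappa * path_r[mask]
    weights = (1.0 / rt) / (1.0 / rt).sum()
    out: dict[str, Windkessel3] = {}
    for seg, rti, w in zip(terms, rt, weights):
        out[seg.id] = Windkessel3(Rp=rti / 2.0, Rd=rti / 2.0, C=c_total * w, Pout=p_out)
    return out


def stiffness_map(net: VesselNetwork, default: float | None = None) -> dict[str, float]:
    """Per-segment Eh/r0 (dyn/cm^2), using ``default`` where unset."""
    out = {}
    for seg in net.ordered_segments():
        s = seg.stiffness if seg.stiffness is not None else default
        if s is None:
            raise ValueError(f"segment {seg.id} has no stiffness and no default given")
        out[seg.id] = float(s)
    return out


def summary_from_cgs(
    p_sys: float, p_dia: float, a_sys: float, a_dia: float,
    p_wedge: float, q_mean: float, period: float, t_dia: float,
) -> HemodynamicSummary:
    """Build a clinical-unit summary from CGS pressures (convenience)."""
    return HemodynamicSummary(
        p_sys=p_sys / MMHG, p_dia=p_dia / MMHG, a_sys=a_sys, a_dia=a_dia,
        p_wedge=p_wedge / MMHG, q_mean=q_mean, period=period, t_dia=t_dia,
    )
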