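"""Wall shear stress metrics: signed WSS, TAWSS, OSI, and the combined
low-TAWSS/high-OSI network fraction phi.

For the power-law velocity profile the wall shear is mu*du/dr at r = R,
whose magnitude is mu*(gamma+2)*|Ubar|/R.  The stress is reported signed by
the local flow direction so the oscillatory shear index can detect flow
reversal; TAWSS always uses the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import VesselNetwork
from .solver import FluidProperties, SolutionField

__all__ = [
    "ShearField",
    "ShearSummary",
    "wall_shear_stress",
    "shear_field",
    "tawss",
    "osi",
    "summarize_network",
]

TAU_LOW_DEFAULT = 5.0  # dyn/cm^2
OSI_HIGH_DEFAULT = 0.05


def wall_shear_stress(q, a, props: FluidProperties = FluidProperties()):
    """Signed wall shear stress, dyn/cm^2.

    tau = sign(Q) * mu*(gamma+2)*|Q/A| / sqrt(A/pi); accepts scalars or
    aligned arrays of flow (mL/s) and area (cm^2).
    """
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be positive")
    tau = props.mu * (props.gamma + 2.0) * q / a / np.sqrt(a / np.pi)
    return float(tau) if tau.ndim == 0 else tau


@dataclass
class ShearField:
    """Signed tau(x, t) per segment on grids aligned with the solution."""

    t: np.ndarray
    segments: dict[str, np.ndarray]  # seg id -> (n_x, n_t)


def shear_field(sol: SolutionField, props: FluidProperties = FluidProperties()) -> ShearField:
    """Evaluate the signed WSS everywhere on a solution field."""
    return ShearField(
        t=sol.t,
        segments={
            sid: wall_shear_stress(seg.Q, seg.A, props) for sid, seg in sol.segments.items()
        },
    )


def _time_grid(series: np.ndarray, t) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty shear series")
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return np.linspace(0.0, float(t), series.shape[-1])
    t = np.asarray(t, dtype=float)
    if t.size != series.shape[-1]:
        raise ValueError("time grid does not match series length")
    return t


def tawss(tau, t):
    """Time-averaged |tau| over one cycle by trapezoidal quadrature.

    ``t`` is either the cycle length T (uniform sampling assumed) or the
    time grid of the series.  ``tau`` may be 1D (a single trace) or 2D
    with time as the last axis.
    """
    tau = np.asarray(tau, dtype=float)
    tg = _time_grid(tau, t)
    span = tg[-1] - tg[0]
    return np.trapezoid(np.abs(tau), tg, axis=-1) / span


def osi(tau, t):
    """Oscillatory shear index 0.5*(1 - |mean tau| / mean |tau|), in [0, 0.5].

    An identically zero series is undefined; it is reported as 0.0 (use
    :func:`osi_defined` for the flag).
    """
    tau = np.asarray(tau, dtype=float)
    tg = _time_grid(tau, t)
    num = np.abs(np.trapezoid(tau, tg, axis=-1))
    den = np.trapezoid(np.abs(tau), tg, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0))
    return val if val.ndim else float(val)


def osi_defined(tau, t) -> np.ndarray | bool:
    """False where the OSI is undefined (identically zero shear)."""
    tau = np.asarray(tau, dtype=float)
    tg = _time_grid(tau, t)
    den = np.trapezoid(np.abs(tau), tg, axis=-1)
    out = den > 0
    return out if out.ndim else bool(out)


@dataclass
class ShearSummary:
    """Per-segment and network-level shear metrics.

    ``per_segment`` columns: segment, name, extralobar, length_cm,
    tawss_dyn_cm2, osi, osi_defined, low_tawss_high_osi_fraction.
    ``phi`` is the percentage of network centerline length with both
    TAWSS < tau_low and OSI > osi_high.
    """

    per_segment: pd.DataFrame
    extralobar: dict[str, dict[str, float]]  # name -> {tawss, osi}
    intralobar_tawss: float
    intralobar_osi: float
    phi: float
    tau_low: float
    osi_high: float


def summarize_network(
    shear: ShearField,
    net: VesselNetwork,
    tau_low: float = TAU_LOW_DEFAULT,
    osi_high: float = OSI_HIGH_DEFAULT,
    length_weighted_intralobar: bool = False,
) -> ShearSummary:
    """Reduce a shear field to per-segment TAWSS/OSI and the phi fraction.

    Per-segment TAWSS/OSI are nodewise metrics averaged along x.  phi
    weights each grid node by its local share of segment length (half
    weights at segment ends) so it approximates the fraction of network
    centerline length meeting both thresholds.
    """
    if not (tau_low > 0 and osi_high > 0):
        raise ValueError("thresholds must be positive")
    rows = []
    flagged_len = 0.0
    total_len = 0.0
    for seg in net.ordered_segments():
        tau = shear.segments[seg.id]
        nx = tau.shape[0]
        tw = tawss(tau, shear.t)  # per node
        oi = np.asarray(osi(tau, shear.t))
        node_w = np.full(nx, seg.length / (nx - 1))
        node_w[0] *= 0.5
        node_w[-1] *= 0.5
        flagged = (tw < tau_low) & (oi > osi_high)
        flagged_len += float(node_w[flagged].sum())
        total_len += seg.length
        rows.append(
            {
                "segment": seg.id,
                "name": seg.name,
                "extralobar": seg.is_extralobar,
                "length_cm": seg.length,
                "tawss_dyn_cm2": float(tw.mean()),
                "osi": float(oi.mean()),
                "osi_defined": bool(np.all(osi_defined(tau, shear.t))),
                "low_tawss_high_osi_fraction": float(node_w[flagged].sum() / seg.length),
            }
        )
    df = pd.DataFrame(rows)
    extral = {}
    for _, row in df[df["extralobar"] & (df["name"] != "")].iterrows():
        extral[row["name"]] = {"tawss": row["tawss_dyn_cm2"], "osi": row["osi"]}
    intra = df[~df["extralobar"]]
    if len(intra):
        if length_weighted_intralobar:
            w = intra["length_cm"].to_numpy()
            intral_tawss = float(np.average(intra["tawss_dyn_cm2"], weights=w))
            intral_osi = float(np.average(intra["osi"], weights=w))
        else:
            intral_tawss = float(intra["tawss_dyn_cm2"].mean())
            intral_osi = float(intra["osi"].mean())
    else:
        intral_tawss = float("nan")
        intral_osi = float("nan")
    return ShearSummary(
        per_segment=df,
        extralobar=extral,
        intralobar_tawss=intral_tawss,
        intralobar_osi=intral_osi,
        phi=100.0 * flagged_len / total_len,
        tau_low=tau_low,
        osi_high=osi_high,
    )
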