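"""Multi-target Windkessel calibration.

All terminal Windkessel elements are scaled by one global factor triple
theta = (rp, rd, c).  The cost matches model predictions to calibration
data {Psys, Pdia, Asys, Adia, Q_LPA(t), Q_RPA(t)}:

    S(theta) = sum_j (P_j^c - P_j)^2 + sum_j (A_j^c - A_j)^2
             + (1/N) sum_k sum_i (Q_k^c(t_i) - Q_k(t_i))^2

with j in {sys, dia}, k in {LPA, RPA}, evaluated in mmHg / cm^2 / (mL/s)
("absolute" weighting); a data-normalized variant is available.  The
optimum is searched by bound-constrained least squares from several
log-uniform random starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .network import VesselNetwork
from .solver import (
    FluidProperties,
    InflowWaveform,
    SimulationConfig,
    SolutionField,
    SolverError,
    simulate_to_periodic,
)
from .units import MMHG
from .wall import WallModel, Windkessel3

__all__ = [
    "FlowSeries",
    "CalibrationData",
    "ScalingFactors",
    "CalibrationResult",
    "ModelContext",
    "recompute_left_flow",
    "calibration_cost",
    "calibrate",
    "r_squared",
    "extract_measurements",
]

FAILED_RESIDUAL = 1.0e6  # optimizer-safe sentinel per residual element


@dataclass(frozen=True)
class FlowSeries:
    """A flow time series over one cycle: t (s) and q (mL/s), equal length."""

    t: np.ndarray
    q: np.ndarray
    recomputed: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if t.shape != q.shape or t.ndim != 1:
            raise ValueError("t and q must be 1D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class CalibrationData:
    """Scalar MPA pressure/area targets plus LPA/RPA flow series.

    Pressures in mmHg, areas in cm^2, flows in mL/s.
    """

    p_sys: float
    p_dia: float
    a_sys: float
    a_dia: float
    q_lpa: FlowSeries
    q_rpa: FlowSeries

    def __post_init__(self) -> None:
        if not self.p_sys > self.p_dia:
            raise ValueError("Psys must exceed Pdia")
        if self.a_sys < self.a_dia:
            raise ValueError("Asys must be >= Adia")
        if len(self.q_lpa) != len(self.q_rpa) or not np.allclose(
            self.q_lpa.t, self.q_rpa.t
        ):
            raise ValueError("LPA/RPA flow series must share the time grid")
        if len(self.q_lpa) < 16:
            raise ValueError("flow series need at least 16 samples")


@dataclass(frozen=True)
class ScalingFactors:
    """Global multipliers applied to every terminal's (Rp, Rd, C)."""

    rp: float
    rd: float
    c: float

    def __post_init__(self) -> None:
        if not (self.rp > 0 and self.rd > 0 and self.c > 0):
            raise ValueError("scaling factors must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.rp, self.rd, self.c])

    @classmethod
    def from_array(cls, x) -> "ScalingFactors":
        return cls(float(x[0]), float(x[1]), float(x[2]))


@dataclass
class StartRecord:
    start: ScalingFactors
    theta: ScalingFactors
    cost: float
    success: bool
    message: str = ""


@dataclass
class CalibrationResult:
    theta: ScalingFactors
    cost: float
    starts: list[StartRecord]
    r2: dict[str, float]
    scalars: dict[str, dict[str, float]]  # metric -> {data, model}

    def __post_init__(self) -> None:
        ok = [s.cost for s in self.starts if s.success]
        if ok and not math.isclose(self.cost, min(ok), rel_tol=1e-12, abs_tol=1e-300):
            raise ValueError("best cost must be the minimum over successful starts")


@dataclass
class ModelContext:
    """Everything needed to forward-simulate under a candidate theta."""

    net: VesselNetwork
    walls: Mapping[str, WallModel]
    windkessels: Mapping[str, Windkessel3]  # nominal (theta = 1)
    inflow: InflowWaveform
    props: FluidProperties
    config: SimulationConfig
    mpa_id: str
    lpa_id: str
    rpa_id: str

    def scaled_windkessels(self, theta: ScalingFactors) -> dict[str, Windkessel3]:
        return {k: w.scaled(theta.rp, theta.rd, theta.c) for k, w in self.windkessels.items()}

    def simulate(self, theta: ScalingFactors, relaxed: bool = False) -> SolutionField:
        cfg = self.config
        if relaxed:
            cfg = cfg.replace(periodicity_tol=cfg.periodicity_tol * 10.0)
        return simulate_to_periodic(
            self.net, self.walls, self.scaled_windkessels(theta), self.inflow, self.props, cfg
        )


def recompute_left_flow(q_mpa: FlowSeries, q_rpa: FlowSeries) -> FlowSeries:
    """Left-lung flow reconstructed as Q_MPA - Q_RPA (pointwise).

    The series must share their time grid exactly; no silent resampling.
    """
    if len(q_mpa) != len(q_rpa) or not np.array_equal(q_mpa.t, q_rpa.t):
        raise ValueError("MPA and RPA series must share the same time grid")
    return FlowSeries(t=q_mpa.t.copy(), q=q_mpa.q - q_rpa.q, recomputed=True)


def extract_measurements(
    sol: SolutionField, mpa_id: str, lpa_id: str, rpa_id: str, t_samples: np.ndarray
) -> tuple[float, float, float, float, np.ndarray, np.ndarray]:
    """Pull (Psys, Pdia, Asys, Adia, Q_LPA, Q_RPA) from a converged solution.

    Pressures in mmHg, areas in cm^2; scalars from the MPA mid-length node,
    flows from the LPA/RPA mid-length nodes resampled to ``t_samples``.
    """
    ps, pd_, asys, adia = sol.extrema(mpa_id)
    q_l = sol.flow_at(lpa_id, t_samples)
    q_r = sol.flow_at(rpa_id, t_samples)
    return ps / MMHG, pd_ / MMHG, asys, adia, q_l, q_r


def _residuals(
    theta: ScalingFactors,
    data: CalibrationData,
    ctx: ModelContext,
    weighting: str,
    relaxed: bool,
) -> np.ndarray:
    n = len(data.q_lpa)
    m = 4 + 2 * n
    try:
        sol = ctx.simulate(theta, relaxed=relaxed)
    except SolverError:
        return np.full(m, FAILED_RESIDUAL)
    ps, pd_, asys, adia, q_l, q_r = extract_measurements(
        sol, ctx.mpa_id, ctx.lpa_id, ctx.rpa_id, data.q_lpa.t
    )
    res = np.concatenate(
        [
            [data.p_sys - ps, data.p_dia - pd_, data.a_sys - asys, data.a_dia - adia],
            (data.q_lpa.q - q_l) / math.sqrt(n),
            (data.q_rpa.q - q_r) / math.sqrt(n),
        ]
    )
    if weighting == "relative":
        qscale = max(
            np.max(np.abs(data.q_lpa.q)), np.max(np.abs(data.q_rpa.q)), 1e-12
        )
        scales = np.concatenate(
            [
                [data.p_sys, data.p_dia, data.a_sys, data.a_dia],
                np.full(2 * n, qscale),
            ]
        )
        res = res / scales
    elif weighting != "absolute":
        raise ValueError(f"unknown weighting {weighting!r}")
    if not np.all(np.isfinite(res)):
        return np.full(m, FAILED_RESIDUAL)
    return res


def calibration_cost(
    theta: ScalingFactors,
    data: CalibrationData,
    ctx: ModelContext,
    weighting: str = "absolute",
) -> float:
    """The three-block sum-of-squares cost at ``theta`` (simulates the model)."""
    r = _residuals(theta, data, ctx, weighting, relaxed=False)
    return float(np.dot(r, r))


def calibrate(
    data: CalibrationData,
    ctx: ModelContext,
    n_starts: int = 10,
    seed: int | None = None,
    weighting: str = "absolute",
    bounds: tuple[float, float] = (0.1, 10.0),
    start_box: tuple[float, float] = (0.25, 4.0),
) -> CalibrationResult:
    """Multi-start bound-constrained least squares over theta = (rp, rd, c).

    Starts are log-uniform in ``start_box``^3 (seeded); each start runs a
    trust-region-reflective least-squares solve with relaxed periodicity
    tolerance, and the best converged theta is re-evaluated at full
    tolerance.
    """
    rng = np.random.default_rng(seed)
    lo, hi = start_box
    starts = np.exp(rng.uniform(math.log(lo), math.log(hi), size=(n_starts, 3)))

    def fun(x):
        return _residuals(ScalingFactors.from_array(x), data, ctx, weighting, relaxed=True)

    records: list[StartRecord] = []
    for x0 in starts:
        try:
            fit = least_squares(
                fun,
                x0,
                bounds=(bounds[0], bounds[1]),
                method="trf",
                diff_step=1e-3,
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
            )
            records.append(
                StartRecord(
                    start=ScalingFactors.from_array(x0),
                    theta=ScalingFactors.from_array(fit.x),
                    cost=float(2.0 * fit.cost),  # scipy reports 0.5*sum(r^2)
                    success=bool(fit.success),
                    message=str(fit.message),
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            records.append(
                StartRecord(
                    start=ScalingFactors.from_array(x0),
                    theta=ScalingFactors.from_array(x0),
                    cost=float("inf"),
                    success=False,
                    message=str(exc),
                )
            )
    ok = [r for r in records if r.success and math.isfinite(r.cost)]
    if not ok:
        raise SolverError(
            "all calibration starts failed: "
            + "; ".join(f"{r.start} -> {r.message}" for r in records)
        )
    best = min(ok, key=lambda r: r.cost)
    # re-simulate the winner at full tolerance for reporting
    sol = ctx.simulate(best.theta, relaxed=False)
    ps, pd_, asys, adia, q_l, q_r = extract_measurements(
        sol, ctx.mpa_id, ctx.lpa_id, ctx.rpa_id, data.q_lpa.t
    )
    r = _residuals(best.theta, data, ctx, weighting, relaxed=False)
    cost_full = float(np.dot(r, r))
    for rec in records:  # keep the invariant: reported cost is min over starts
        if rec is best:
            rec.cost = min(rec.cost, cost_full)
    result = CalibrationResult(
        theta=best.theta,
        cost=min(best.cost, cost_full),
        starts=records,
        r2={
            "LPA": r_squared(q_l, data.q_lpa.q),
            "RPA": r_squared(q_r, data.q_rpa.q),
        },
        scalars={
            "p_sys_mmhg": {"data": data.p_sys, "model": ps},
            "p_dia_mmhg": {"data": data.p_dia, "model": pd_},
            "a_sys_cm2": {"data": data.a_sys, "model": asys},
            "a_dia_cm2": {"data": data.a_dia, "model": adia},
        },
    )
    return result


def r_squared(model, data) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the data
    mean).  Returns NaN for a constant data series (undefined)."""
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape:
        raise ValueError("series must have equal length")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((data - model) ** 2))
    return 1.0 - ss_res / ss_tot
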