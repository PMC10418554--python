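"""1D pulse-wave solver on a bifurcating arterial network.

Solves the nonlinear mass/momentum system

    dA/dt + dQ/dx = 0
    dQ/dt + ((g+2)/(g+1)) d/dx(Q^2/A) + (A/rho) dP/dx = -2*pi*mu*(g+2)/rho * Q/A

closed by the elastic tube law, with a prescribed inlet flow, flow/pressure
continuity at bifurcations, and three-element Windkessel outlets.  Interior
points advance with the two-step (Richtmyer) Lax-Wendroff scheme on the
conservative variables (A, Q); boundary unknowns are closed with the
outgoing Riemann invariant of the linearized system plus the physical
condition, each solved by Newton iteration.

Simulations start from the diastolic rest state (A = Adia, Q = 0) and run
cycle by cycle until the pressure field is periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _kernels
from .network import VesselNetwork, terminal_segments
from .wall import WallModel, Windkessel3

__all__ = [
    "FluidProperties",
    "SimulationConfig",
    "InflowWaveform",
    "SolutionField",
    "SegmentSolution",
    "ConvergenceReport",
    "SolverError",
    "velocity_profile",
    "windkessel_outlet_step",
    "junction_coupling",
    "lax_wendroff_cycle",
    "simulate_to_periodic",
    "uniform_walls",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Blood properties: density (g/mL), viscosity (Poise), profile exponent."""

    rho: float = 1.03
    mu: float = 0.03
    gamma: float = 9.0

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.mu > 0):
            raise ValueError("rho and mu must be positive")
        if self.gamma < 2:
            raise ValueError("power-law exponent gamma must be >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical controls.

    cycle_length    : cardiac period T, s
    dx_target       : upper bound on grid spacing, cm
    cfl_number      : Courant number used for the a-priori dt estimate
    max_cycles      : cap on cycles run toward periodicity
    periodicity_tol : relative tolerance on cycle-to-cycle pressure change
    speed_margin    : safety factor on the estimated peak signal speed
    min_nodes       : minimum nodes per segment
    """

    cycle_length: float
    dx_target: float = 0.1
    cfl_number: float = 0.5
    max_cycles: int = 30
    periodicity_tol: float = 1e-3
    speed_margin: float = 1.6
    min_nodes: int = 5

    def __post_init__(self) -> None:
        if not (self.cycle_length > 0 and self.dx_target > 0):
            raise ValueError("cycle_length and dx_target must be positive")
        if not (0 < self.cfl_number < 1):
            raise ValueError("cfl_number must lie in (0, 1)")
        if self.max_cycles < 1 or self.min_nodes < 3:
            raise ValueError("max_cycles >= 1 and min_nodes >= 3 required")
        if not (self.periodicity_tol > 0 and self.speed_margin >= 1):
            raise ValueError("periodicity_tol > 0 and speed_margin >= 1 required")

    def replace(self, **kw) -> "SimulationConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


class InflowWaveform:
    """Periodic volumetric inflow Q(t), mL/s, sampled over one period.

    Samples cover [0, T] inclusive, so the first and last samples must
    coincide.  Evaluation at arbitrary times uses trigonometric (Fourier)
    interpolation, which resamples the waveform smoothly onto any solver
    clock.
    """

    def __init__(self, q: np.ndarray, period: float):
        q = np.asarray(q, dtype=float)
        if q.ndim != 1 or q.size < 8:
            raise ValueError("waveform needs a 1D array of >= 8 samples")
        if not period > 0:
            raise ValueError("period must be positive")
        if not np.all(np.isfinite(q)):
            raise ValueError("waveform samples must be finite")
        scale = max(1.0, float(np.max(np.abs(q))))
        if abs(q[0] - q[-1]) > 1e-9 * scale:
            raise ValueError("waveform is not periodic (first sample != last sample)")
        self.q = q
        self.period = float(period)
        base = q[:-1]
        self._n = base.size
        self._coef = np.fft.rfft(base) / self._n

    @classmethod
    def from_function(cls, fn, period: float, n: int = 256) -> "InflowWaveform":
        t = np.linspace(0.0, period, n + 1)
        q = np.asarray([fn(tk % period) for tk in t], dtype=float)
        q[-1] = q[0]
        return cls(q, period)

    def at(self, t) -> np.ndarray | float:
        """Evaluate by Fourier series at time(s) t (s)."""
        t = np.asarray(t, dtype=float)
        m = np.arange(self._coef.size)
        phase = np.exp(2j * np.pi * np.outer(t.ravel(), m) / self.period)
        w = np.full(self._coef.size, 2.0)
        w[0] = 1.0
        if self._n % 2 == 0:
            w[-1] = 1.0
        vals = (phase * (w * self._coef)).real.sum(axis=1)
        vals = vals.reshape(t.shape)
        return float(vals) if vals.ndim == 0 else vals

    @property
    def mean(self) -> float:
        return float(np.mean(self.q[:-1]))

    @property
    def stroke_volume(self) -> float:
        return self.mean * self.period


def velocity_profile(u_bar, r, radius: float, gamma: float = 9.0):
    """Power-law axial velocity u(r) = Ubar*(g+2)/g*(1-(r/R)^g), cm/s.

    Satisfies no slip at the wall and averages to ``u_bar`` over the cross
    section.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > radius):
        raise ValueError("radial coordinate must lie in [0, R]")
    u = u_bar * (gamma + 2.0) / gamma * (1.0 - (r / radius) ** gamma)
    return float(u) if u.ndim == 0 else u


def windkessel_outlet_step(
    q_boundary: float, pc_prev: float, wk: Windkessel3, dt: float
) -> tuple[float, float]:
    """One implicit-Euler step of the RCR outlet (CGS units).

    Integrates dPc/dt = (Q - (Pc - Pout)/Rd)/C and returns
    (P_boundary, Pc_next) with P_boundary = Pc_next + Q*Rp.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    den = 1.0 + dt / (wk.Rd * wk.C)
    pc_next = (pc_prev + dt / wk.C * (q_boundary + wk.Pout / wk.Rd)) / den
    return pc_next + q_boundary * wk.Rp, pc_next


@dataclass(frozen=True)
class JunctionSolution:
    """Boundary values at a bifurcation after enforcing continuity."""

    parent: tuple[float, float, float]  # (A, Q, P)
    child1: tuple[float, float, float]
    child2: tuple[float, float, float]
    flow_residual: float
    pressure_residual: float


def junction_coupling(
    parent_state: tuple[float, float],
    child1_state: tuple[float, float],
    child2_state: tuple[float, float],
    walls: tuple[WallModel, WallModel, WallModel],
    rho: float = 1.03,
) -> JunctionSolution:
    """Solve the bifurcation interface given (A, Q) end states of the three
    vessels.

    The characteristic invariants (u + 4c for the parent outlet, u - 4c for
    each daughter inlet) are computed from the supplied states; the returned
    boundary values satisfy flow conservation Qp = Qd1 + Qd2 and pressure
    continuity Pp = Pd1 = Pd2 together with those invariants.
    """
    wall_p, wall_1, wall_2 = walls

    def inv(state, wall, sgn):
        a, q = state
        c = math.sqrt(2.0 * wall.stiffness / (3.0 * rho) * math.sqrt(a / wall.area_dia))
        return q / a + sgn * 4.0 * c

    wp = inv(parent_state, wall_p, +1)
    w1 = inv(child1_state, wall_1, -1)
    w2 = inv(child2_state, wall_2, -1)
    X = np.array(
        [
            parent_state[1],
            parent_state[0],
            child1_state[1],
            child1_state[0],
            child2_state[1],
            child2_state[0],
        ]
    )
    J = np.empty((6, 6))
    R = np.empty(6)

    def c2(wall):
        return 2.0 * wall.stiffness / (3.0 * rho)

    st, fres, pres = _kernels._solve_junction(
        X, J, R, wp, w1, w2,
        wall_p.stiffness, c2(wall_p), wall_p.area_dia, wall_p.p_dia,
        wall_1.stiffness, c2(wall_1), wall_1.area_dia, wall_1.p_dia,
        wall_2.stiffness, c2(wall_2), wall_2.area_dia, wall_2.p_dia,
    )
    if st != 0:
        raise SolverError(
            f"junction Newton failed to converge (flow res {fres:.2e}, pressure res {pres:.2e})"
        )
    from .wall import tube_law_pressure

    return JunctionSolution(
        parent=(X[1], X[0], tube_law_pressure(X[1], wall_p)),
        child1=(X[3], X[2], tube_law_pressure(X[3], wall_1)),
        child2=(X[5], X[4], tube_law_pressure(X[5], wall_2)),
        flow_residual=fres,
        pressure_residual=pres,
    )


# ---------------------------------------------------------------------------
# flattened model


@dataclass
class _FlatModel:
    seg_ids: list[str]
    off: np.ndarray
    dx: np.ndarray
    fwall: np.ndarray
    adia: np.ndarray
    pdia: np.ndarray
    junc: np.ndarray
    term: np.ndarray
    term_ids: list[str]
    wk: np.ndarray
    root: int

    @property
    def ntot(self) -> int:
        return int(self.off[-1])

    def node_array(self, per_seg: np.ndarray) -> np.ndarray:
        out = np.empty(self.ntot)
        for s in range(len(self.seg_ids)):
            out[self.off[s] : self.off[s + 1]] = per_seg[s]
        return out


def _flatten(
    net: VesselNetwork,
    walls: Mapping[str, WallModel],
    windkessels: Mapping[str, Windkessel3],
    config: SimulationConfig,
) -> _FlatModel:
    seg_ids = sorted(net.segments)
    idx = {sid: i for i, sid in enumerate(seg_ids)}
    nseg = len(seg_ids)
    counts = np.empty(nseg, dtype=np.int64)
    dx = np.empty(nseg)
    fwall = np.empty(nseg)
    adia = np.empty(nseg)
    pdia = np.empty(nseg)
    for i, sid in enumerate(seg_ids):
        seg = net.segments[sid]
        if sid not in walls:
            raise ValueError(f"no wall model for segment {sid}")
        wall = walls[sid]
        n = max(config.min_nodes, int(math.ceil(seg.length / config.dx_target)) + 1)
        counts[i] = n
        dx[i] = seg.length / (n - 1)
        fwall[i] = wall.stiffness
        adia[i] = wall.area_dia
        pdia[i] = wall.p_dia
    off = np.zeros(nseg + 1, dtype=np.int64)
    off[1:] = np.cumsum(counts)
    junc_rows = []
    for sid in seg_ids:
        seg = net.segments[sid]
        if not seg.is_terminal:
            c1, c2 = seg.children
            junc_rows.append((idx[sid], idx[c1], idx[c2]))
    junc = np.array(junc_rows, dtype=np.int64).reshape(-1, 3)
    term_ids = [t.id for t in terminal_segments(net)]
    term = np.array([idx[t] for t in term_ids], dtype=np.int64)
    wk = np.empty((len(term_ids), 4))
    for m, tid in enumerate(term_ids):
        if tid not in windkessels:
            raise ValueError(f"no Windkessel for terminal segment {tid}")
        w = windkessels[tid]
        wk[m] = (w.Rp, w.Rd, w.C, w.Pout)
    return _FlatModel(
        seg_ids=seg_ids,
        off=off,
        dx=dx,
        fwall=fwall,
        adia=adia,
        pdia=pdia,
        junc=junc,
        term=term,
        term_ids=term_ids,
        wk=wk,
        root=idx[net.root_id],
    )


def uniform_walls(
    net: VesselNetwork, stiffness: float | None, p_dia: float
) -> dict[str, WallModel]:
    """Wall models with Adia from segment radii; per-segment stiffness where
    set on the network, otherwise the uniform ``stiffness`` (dyn/cm^2)."""
    out = {}
    for seg in net.ordered_segments():
        s = seg.stiffness if seg.stiffness is not None else stiffness
        if s is None:
            raise ValueError(f"segment {seg.id} has no stiffness")
        out[seg.id] = WallModel(stiffness=float(s), area_dia=seg.area, p_dia=p_dia)
    return out


# ---------------------------------------------------------------------------
# solution containers


@dataclass
class SegmentSolution:
    """Space-time solution on one segment; arrays are (n_x, n_t)."""

    x: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray


@dataclass
class ConvergenceReport:
    converged: bool
    n_cycles: int
    periodicity: list[float]
    dt: float
    n_steps: int
    restarts: int
    max_flow_residual: float
    max_pressure_residual: float
    max_cfl: float
    volume_in: float = math.nan
    volume_out: float = math.nan
    volume_stored: float = math.nan

    @property
    def volume_error(self) -> float:
        """|inflow - outflow - storage change| as a fraction of inflow volume."""
        return abs(self.volume_in - self.volume_out - self.volume_stored) / abs(
            self.volume_in
        )


@dataclass
class SolutionField:
    """Converged-cycle solution: per-segment (P, Q, A) on (x, t) grids (CGS)."""

    t: np.ndarray
    segments: dict[str, SegmentSolution]
    report: ConvergenceReport = field(repr=False, default=None)  # type: ignore[assignment]

    def midpoint_series(self, seg_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(P(t), Q(t), A(t)) at the mid-length node of a segment."""
        seg = self.segments[seg_id]
        j = seg.x.size // 2
        return seg.P[j], seg.Q[j], seg.A[j]

    def flow_at(self, seg_id: str, t_new: np.ndarray) -> np.ndarray:
        """Mid-segment flow resampled onto ``t_new`` (within the cycle)."""
        _, q, _ = self.midpoint_series(seg_id)
        return np.interp(np.mod(t_new, self.t[-1]), self.t, q)

    def extrema(self, seg_id: str) -> tuple[float, float, float, float]:
        """(Psys, Pdia, Asys, Adia) at the segment's mid-length node (CGS)."""
        p, _, a = self.midpoint_series(seg_id)
        return float(p.max()), float(p.min()), float(a.max()), float(a.min())


# ---------------------------------------------------------------------------
# drivers


def _estimate_dt(
    flat: _FlatModel, inflow: InflowWaveform, props: FluidProperties, config: SimulationConfig
) -> float:
    c_dia = np.sqrt(2.0 * flat.fwall / (3.0 * props.rho))
    u_est = float(np.max(np.abs(inflow.q))) / float(np.min(flat.adia))
    speed = config.speed_margin * c_dia + u_est
    return config.cfl_number * float(np.min(flat.dx / speed))


def _pressure_hist(flat: _FlatModel, a_hist: np.ndarray) -> np.ndarray:
    f_n = flat.node_array(flat.fwall)
    ad_n = flat.node_array(flat.adia)
    pd_n = flat.node_array(flat.pdia)
    return (4.0 / 3.0) * f_n * (np.sqrt(a_hist / ad_n) - 1.0) + pd_n


_STATUS_MSG = {
    1: "CFL violation",
    2: "negative area (collapse -- check stiffness/inflow)",
    3: "junction Newton failure",
    4: "inlet/outlet Newton failure",
}


def simulate_to_periodic(
    net: VesselNetwork,
    walls: Mapping[str, WallModel],
    windkessels: Mapping[str, Windkessel3],
    inflow: InflowWaveform,
    props: FluidProperties,
    config: SimulationConfig,
) -> SolutionField:
    """Run cycles from the diastolic rest state until the pressure field is
    periodic; return the final cycle.

    Periodicity is max |P_k - P_{k-1}| / max |P_k| over all nodes and times
    of consecutive cycles.  On CFL violation or collapse the whole run is
    restarted from cold with a halved time step (up to 6 times).
    """
    if abs(inflow.period - config.cycle_length) > 1e-9 * config.cycle_length:
        raise ValueError("inflow period must equal config.cycle_length")
    flat = _flatten(net, walls, windkessels, config)
    dt0 = _estimate_dt(flat, inflow, props, config)
    n_steps = int(math.ceil(config.cycle_length / dt0))
    restarts = 0
    while True:
        dt = config.cycle_length / n_steps
        result = _run_cycles(flat, inflow, props, config, dt, n_steps, restarts)
        if result is not None:
            return result
        n_steps *= 2
        restarts += 1
        if restarts > 6:
            raise SolverError("time step repeatedly unstable; check parameters")


def _run_cycles(flat, inflow, props, config, dt, n_steps, restarts):
    ntot = flat.ntot
    A = flat.node_array(flat.adia).copy()
    Q = np.zeros(ntot)
    Pc = np.full(len(flat.term_ids), 0.0)
    for m in range(len(flat.term_ids)):
        Pc[m] = flat.wk[m, 3]  # start capacitors at the distal reference
    t_steps = dt * np.arange(n_steps + 1)
    qin = np.asarray(inflow.at(t_steps), dtype=float)
    a_hist = np.empty((n_steps + 1, ntot))
    q_hist = np.empty((n_steps + 1, ntot))
    p_prev: np.ndarray | None = None
    periodicity: list[float] = []
    max_fres = 0.0
    max_pres = 0.0
    max_cfl = 0.0
    converged = False
    n_cycles = 0
    for cyc in range(config.max_cycles):
        status, fres, pres, cfl = _kernels.run_cycle(
            A, Q, Pc, a_hist, q_hist,
            flat.off, flat.dx, flat.fwall, flat.adia, flat.pdia,
            flat.junc, flat.term, flat.wk, flat.root,
            qin, dt, props.gamma, props.rho, props.mu,
        )
        if status in (1, 2):
            return None  # caller restarts with smaller dt
        if status in (3, 4):
            raise SolverError(f"solver aborted: {_STATUS_MSG[status]}")
        max_fres = max(max_fres, fres)
        max_pres = max(max_pres, pres)
        max_cfl = max(max_cfl, cfl)
        n_cycles = cyc + 1
        p_hist = _pressure_hist(flat, a_hist)
        if p_prev is not None:
            metric = float(
                np.max(np.abs(p_hist - p_prev)) / np.max(np.abs(p_hist))
            )
            periodicity.append(metric)
            if metric < config.periodicity_tol:
                converged = True
                break
        p_prev = p_hist.copy()
    report = ConvergenceReport(
        converged=converged,
        n_cycles=n_cycles,
        periodicity=periodicity,
        dt=dt,
        n_steps=n_steps,
        restarts=restarts,
        max_flow_residual=max_fres,
        max_pressure_residual=max_pres,
        max_cfl=max_cfl,
    )
    p_hist = _pressure_hist(flat, a_hist)
    # volume audit over the final cycle
    report.volume_in = float(np.trapezoid(qin, dx=dt))
    vout = 0.0
    for m, tid in enumerate(flat.term_ids):
        ie = flat.off[flat.term[m] + 1] - 1
        vout += float(np.trapezoid(q_hist[:, ie], dx=dt))
    report.volume_out = vout
    stored = 0.0
    for s in range(len(flat.seg_ids)):
        sl = slice(flat.off[s], flat.off[s + 1])
        stored += float(
            np.trapezoid(a_hist[-1, sl], dx=flat.dx[s])
            - np.trapezoid(a_hist[0, sl], dx=flat.dx[s])
        )
    report.volume_stored = stored
    segments = {}
    for s, sid in enumerate(flat.seg_ids):
        sl = slice(flat.off[s], flat.off[s + 1])
        x = flat.dx[s] * np.arange(flat.off[s + 1] - flat.off[s])
        segments[sid] = SegmentSolution(
            x=x, P=p_hist[:, sl].T.copy(), Q=q_hist[:, sl].T.copy(), A=a_hist[:, sl].T.copy()
        )
    return SolutionField(t=t_steps, segments=segments, report=report)


def lax_wendroff_cycle(
    net: VesselNetwork,
    walls: Mapping[str, WallModel],
    windkessels: Mapping[str, Windkessel3],
    inflow: InflowWaveform,
    props: FluidProperties,
    config: SimulationConfig,
    initial_state: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SolutionField:
    """Advance exactly one cycle from ``initial_state`` (or the diastolic
    rest state) and return the space-time solution of that cycle.

    ``initial_state`` is (A, Q, Pc) in the flattened node ordering
    (id-sorted segments, proximal to distal nodes).
    """
    flat = _flatten(net, walls, windkessels, config)
    dt0 = _estimate_dt(flat, inflow, props, config)
    n_steps = int(math.ceil(config.cycle_length / dt0))
    dt = config.cycle_length / n_steps
    if initial_state is None:
        A = flat.node_array(flat.adia).copy()
        Q = np.zeros(flat.ntot)
        Pc = flat.wk[:, 3].copy()
    else:
        A, Q, Pc = (np.array(v, dtype=float) for v in initial_state)
    t_steps = dt * np.arange(n_steps + 1)
    qin = np.asarray(inflow.at(t_steps), dtype=float)
    a_hist = np.empty((n_steps + 1, flat.ntot))
    q_hist = np.empty((n_steps + 1, flat.ntot))
    status, fres, pres, cfl = _kernels.run_cycle(
        A, Q, Pc, a_hist, q_hist,
        flat.off, flat.dx, flat.fwall, flat.adia, flat.pdia,
        flat.junc, flat.term, flat.wk, flat.root,
        qin, dt, props.gamma, props.rho, props.mu,
    )
    if status != 0:
        raise SolverError(f"solver aborted: {_STATUS_MSG[status]}")
    p_hist = _pressure_hist(flat, a_hist)
    segments = {}
    for s, sid in enumerate(flat.seg_ids):
        sl = slice(flat.off[s], flat.off[s + 1])
        x = flat.dx[s] * np.arange(flat.off[s + 1] - flat.off[s])
        segments[sid] = SegmentSolution(
            x=x, P=p_hist[:, sl].T.copy(), Q=q_hist[:, sl].T.copy(), A=a_hist[:, sl].T.copy()
        )
    report = ConvergenceReport(
        converged=False,
        n_cycles=1,
        periodicity=[],
        dt=dt,
        n_steps=n_steps,
        restarts=0,
        max_flow_residual=fres,
        max_pressure_residual=pres,
        max_cfl=cfl,
    )
    return SolutionField(t=t_steps, segments=segments, report=report)
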