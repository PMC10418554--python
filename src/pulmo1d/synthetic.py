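"""Synthetic subjects: arterial tree, ground-truth parameters, inflow,
pseudo-measurements, and a CTEPH-like diseased state.

No animal data ship with this package; every pipeline stage is exercised
against subjects generated here.  A subject is fully determined by its
configuration and seed: the tree is a structured bifurcating network with
MPA/LPA/RPA extralobar roots, the inflow is a half-sine ejection waveform,
ground-truth Windkessels are the nominal construction perturbed by a known
scaling triple, and pseudo-measurements are extracted from a forward
simulation with seeded multiplicative noise on the flow series.

The CTEPH state emulates asymmetric (left-dominant) distal obstruction:
left-lung terminal resistances are multiplied by ``severity`` (right lung
by a milder factor), outlet compliances divided by the same factors, and
all wall stiffnesses multiplied by ``stiffening``.  The left-lung flow
measurement is marked for recomputation from Q_MPA - Q_RPA, mirroring the
signal-loss workaround the diseased state forces on imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import numpy as np

from .calibration import (
    CalibrationData,
    FlowSeries,
    ModelContext,
    ScalingFactors,
    extract_measurements,
    recompute_left_flow,
)
from .network import VesselNetwork, VesselSegment, build_network
from .solver import (
    FluidProperties,
    InflowWaveform,
    SimulationConfig,
    SolutionField,
    simulate_to_periodic,
    uniform_walls,
)
from .units import MMHG, compliance_to_cgs, resistance_to_cgs
from .wall import (
    HemodynamicSummary,
    Windkessel3,
    mean_pa_pressure,
    nominal_windkessels,
    total_compliance_from_decay,
    total_pvr,
    tube_law_area,
    WallModel,
)

__all__ = [
    "SubjectConfig",
    "SyntheticSubject",
    "generate_tree",
    "generate_inflow",
    "make_baseline_subject",
    "apply_cteph",
]

MIN_RADIUS = 0.01  # cm


def generate_tree(
    generations: int,
    r_root: float = 0.72,
    radius_ratio: float = 0.79,
    length_radius_ratio: float = 5.0,
    asymmetry: float = 0.0,
    seed: int | None = None,
) -> VesselNetwork:
    """Structured bifurcating tree with MPA root and LPA/RPA extralobar children.

    Daughter radii are r_parent * radius_ratio * (1 +/- asymmetry) (left
    daughter gets the plus sign) and lengths are length_radius_ratio * r.
    ``generations`` counts bifurcation levels below the root, so the tree
    has 2**(generations+1) - 1 segments.  Deterministic; ``seed`` is kept
    in the signature for forward compatibility but unused.
    """
    del seed
    if generations < 1:
        raise ValueError("need at least 1 generation (LPA/RPA)")
    if not (0 < radius_ratio < 1):
        raise ValueError("radius_ratio must lie in (0, 1)")
    if not (0 <= asymmetry < 1):
        raise ValueError("asymmetry must lie in [0, 1)")
    n_nodes = 2 ** (generations + 1) - 1
    radii = np.empty(n_nodes)
    radii[0] = r_root
    for i in range(1, n_nodes):
        parent = (i - 1) // 2
        side = 1.0 + asymmetry if i % 2 == 1 else 1.0 - asymmetry
        radii[i] = radii[parent] * radius_ratio * side
    if np.min(radii) < MIN_RADIUS:
        raise ValueError(
            f"smallest radius {np.min(radii):.4f} cm < {MIN_RADIUS} cm; "
            "use fewer generations or a larger root radius"
        )
    names = {0: "MPA", 1: "LPA", 2: "RPA"}
    segs = []
    for i in range(n_nodes):
        has_children = 2 * i + 2 < n_nodes
        segs.append(
            VesselSegment(
                id=f"s{i:03d}",
                name=names.get(i, ""),
                parent=None if i == 0 else f"s{(i - 1) // 2:03d}",
                children=(f"s{2 * i + 1:03d}", f"s{2 * i + 2:03d}") if has_children else (),
                length=length_radius_ratio * radii[i],
                radius=float(radii[i]),
                is_extralobar=i < 3,
            )
        )
    return build_network(segs, "s000")


def generate_inflow(
    period: float,
    stroke_volume: float,
    systole_fraction: float = 0.4,
    seed: int | None = None,
    n_samples: int = 512,
) -> InflowWaveform:
    """Half-sine ejection over systole_fraction*T, zero in diastole, scaled
    so the cycle integral equals ``stroke_volume`` (mL).  Deterministic;
    ``seed`` is unused and kept for interface stability."""
    del seed
    if not stroke_volume > 0:
        raise ValueError("stroke volume must be positive")
    if not (0 < systole_fraction < 1):
        raise ValueError("systole_fraction must lie in (0, 1)")
    t_sys = systole_fraction * period
    peak = math.pi * stroke_volume / (2.0 * t_sys)

    def q(t):
        return peak * math.sin(math.pi * t / t_sys) if t < t_sys else 0.0

    return InflowWaveform.from_function(q, period, n=n_samples)


@dataclass(frozen=True)
class SubjectConfig:
    """Generator configuration; defaults sit in a canine-scale physiologic
    range but are placeholders, not measured values."""

    generations: int = 2
    r_root: float = 0.72
    radius_ratio: float = 0.79
    length_radius_ratio: float = 5.0
    asymmetry: float = 0.0
    period: float = 0.5
    stroke_volume: float = 15.0
    systole_fraction: float = 0.4
    p_wedge: float = 5.0  # mmHg
    p_sys_target: float = 25.0  # mmHg, used only to build the nominal Windkessels
    p_dia_target: float = 13.0  # mmHg
    stiffness_mmhg: float = 75.0  # uniform Eh/r0
    flow_noise: float = 0.02  # multiplicative sd on flow series
    n_flow_samples: int = 64
    true_theta: ScalingFactors | None = None  # drawn from [0.5, 2]^3 if None
    dx_target: float = 0.3  # coarse but grid-converged for these geometries
    periodicity_tol: float = 1e-3
    max_cycles: int = 30


@dataclass
class SyntheticSubject:
    """A fully specified pseudo-subject with known ground truth."""

    subject_id: str
    scenario: str  # "baseline" | "cteph"
    config: SubjectConfig
    seed: int
    network: VesselNetwork
    walls: Mapping[str, WallModel]
    windkessels_nominal: Mapping[str, Windkessel3]
    windkessels_true: Mapping[str, Windkessel3]
    true_theta: ScalingFactors
    inflow: InflowWaveform
    measurements: CalibrationData
    q_mpa: FlowSeries
    summary: HemodynamicSummary
    solution: SolutionField = field(repr=False, default=None)  # type: ignore[assignment]
    baseline_id: str | None = None
    stiffening: float = 1.0

    @property
    def mpa_id(self) -> str:
        return self.network.root_id

    @property
    def lpa_id(self) -> str:
        return self.network.root.children[0]

    @property
    def rpa_id(self) -> str:
        return self.network.root.children[1]

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            cycle_length=self.config.period,
            dx_target=self.config.dx_target,
            periodicity_tol=self.config.periodicity_tol,
            max_cycles=self.config.max_cycles,
        )

    def model_context(self, props: FluidProperties = FluidProperties()) -> ModelContext:
        """Calibration context against this subject's nominal Windkessels."""
        return ModelContext(
            net=self.network,
            walls=self.walls,
            windkessels=self.windkessels_nominal,
            inflow=self.inflow,
            props=props,
            config=self.simulation_config(),
            mpa_id=self.mpa_id,
            lpa_id=self.lpa_id,
            rpa_id=self.rpa_id,
        )


def _attach_stiffness(net: VesselNetwork, stiffness_cgs: float) -> VesselNetwork:
    return net.with_segments(
        [dc_replace(s, stiffness=stiffness_cgs) for s in net.ordered_segments()]
    )


def _noisy(q: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0.0:
        return q.copy()
    return q * (1.0 + sd * rng.standard_normal(q.size))


def _measure(
    subject_id: str,
    scenario: str,
    cfg: SubjectConfig,
    seed: int,
    net: VesselNetwork,
    walls: Mapping[str, WallModel],
    wk_nominal: Mapping[str, Windkessel3],
    wk_true: Mapping[str, Windkessel3],
    theta: ScalingFactors,
    inflow: InflowWaveform,
    props: FluidProperties,
    rng: np.random.Generator,
    baseline_id: str | None = None,
    stiffening: float = 1.0,
) -> SyntheticSubject:
    sim_cfg = SimulationConfig(
        cycle_length=cfg.period,
        dx_target=cfg.dx_target,
        periodicity_tol=cfg.periodicity_tol,
        max_cycles=cfg.max_cycles,
    )
    sol = simulate_to_periodic(net, walls, wk_true, inflow, props, sim_cfg)
    t_samples = np.linspace(0.0, cfg.period, cfg.n_flow_samples, endpoint=False)
    mpa_id = net.root_id
    lpa_id, rpa_id = net.root.children
    ps, pd_, asys, adia, q_l, q_r = extract_measurements(
        sol, mpa_id, lpa_id, rpa_id, t_samples
    )
    q_mpa = FlowSeries(
        t=t_samples, q=_noisy(np.asarray(inflow.at(t_samples)), rng, cfg.flow_noise)
    )
    q_rpa = FlowSeries(t=t_samples, q=_noisy(q_r, rng, cfg.flow_noise))
    if scenario == "cteph":
        q_lpa = recompute_left_flow(q_mpa, q_rpa)
    else:
        q_lpa = FlowSeries(t=t_samples, q=_noisy(q_l, rng, cfg.flow_noise))
    measurements = CalibrationData(
        p_sys=ps, p_dia=pd_, a_sys=asys, a_dia=adia, q_lpa=q_lpa, q_rpa=q_rpa
    )
    summary = HemodynamicSummary(
        p_sys=ps,
        p_dia=pd_,
        a_sys=asys,
        a_dia=adia,
        p_wedge=cfg.p_wedge,
        q_mean=inflow.mean,
        period=cfg.period,
        t_dia=(1.0 - cfg.systole_fraction) * cfg.period,
    )
    return SyntheticSubject(
        subject_id=subject_id,
        scenario=scenario,
        config=cfg,
        seed=seed,
        network=net,
        walls=walls,
        windkessels_nominal=wk_nominal,
        windkessels_true=wk_true,
        true_theta=theta,
        inflow=inflow,
        measurements=measurements,
        q_mpa=q_mpa,
        summary=summary,
        solution=sol,
        baseline_id=baseline_id,
        stiffening=stiffening,
    )


def make_baseline_subject(
    config: SubjectConfig = SubjectConfig(),
    seed: int = 0,
    props: FluidProperties = FluidProperties(),
) -> SyntheticSubject:
    """Build a baseline subject: tree, walls, nominal Windkessels perturbed
    by a (possibly drawn) true theta, forward simulation, and noisy
    pseudo-measurements."""
    rng = np.random.default_rng(seed)
    f_cgs = config.stiffness_mmhg * MMHG
    p_dia_cgs = config.p_dia_target * MMHG
    net = _attach_stiffness(
        generate_tree(
            config.generations,
            config.r_root,
            config.radius_ratio,
            config.length_radius_ratio,
            config.asymmetry,
        ),
        f_cgs,
    )
    walls = uniform_walls(net, None, p_dia_cgs)
    q_mean = config.stroke_volume / config.period
    p_mean = mean_pa_pressure(config.p_sys_target, config.p_dia_target)
    r_tot = total_pvr(p_mean, config.p_wedge, q_mean)  # mmHg*s/mL
    mpa_wall = walls[net.root_id]
    a_sys_target = tube_law_area(config.p_sys_target * MMHG, mpa_wall)
    target_summary = HemodynamicSummary(
        p_sys=config.p_sys_target,
        p_dia=config.p_dia_target,
        a_sys=a_sys_target,
        a_dia=mpa_wall.area_dia,
        p_wedge=config.p_wedge,
        q_mean=q_mean,
        period=config.period,
        t_dia=(1.0 - config.systole_fraction) * config.period,
    )
    c_tot = total_compliance_from_decay(target_summary, r_tot)  # mL/mmHg
    wk_nominal = nominal_windkessels(
        net,
        resistance_to_cgs(r_tot),
        compliance_to_cgs(c_tot),
        props.mu,
        config.p_wedge * MMHG,
    )
    if config.true_theta is not None:
        theta = config.true_theta
    else:
        draw = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=3))
        theta = ScalingFactors.from_array(draw)
    wk_true = {k: w.scaled(theta.rp, theta.rd, theta.c) for k, w in wk_nominal.items()}
    inflow = generate_inflow(config.period, config.stroke_volume, config.systole_fraction)
    # Anchor the wall reference at the simulated diastole: the reference area
    # is defined at the measured diastolic pressure, so probe once and rebuild
    # the walls with p_dia set to the simulated MPA diastolic minimum.
    probe_cfg = SimulationConfig(
        cycle_length=config.period,
        dx_target=config.dx_target,
        periodicity_tol=config.periodicity_tol * 10.0,
        max_cycles=config.max_cycles,
    )
    probe = simulate_to_periodic(net, walls, wk_true, inflow, props, probe_cfg)
    _, p_dia_sim, _, _ = probe.extrema(net.root_id)
    walls = uniform_walls(net, None, p_dia_sim)
    return _measure(
        subject_id=f"subject-{seed}",
        scenario="baseline",
        cfg=config,
        seed=seed,
        net=net,
        walls=walls,
        wk_nominal=wk_nominal,
        wk_true=wk_true,
        theta=theta,
        inflow=inflow,
        props=props,
        rng=rng,
    )


def apply_cteph(
    subject: SyntheticSubject,
    severity: float = 5.0,
    left_fraction: float = 0.8,
    stiffening: float = 2.0,
    flow_reduction: float = 0.85,
    seed: int | None = None,
    props: FluidProperties = FluidProperties(),
) -> SyntheticSubject:
    """Diseased state: left-dominant distal resistance increase with wall
    stiffening and reduced cardiac output.

    Left-lung terminal (Rp, Rd) are multiplied by ``severity`` and
    right-lung terminals by 1 + (1 - left_fraction)*(severity - 1);
    compliances are divided by the same per-outlet factor; every Eh/r0 is
    multiplied by ``stiffening``; the stroke volume is multiplied by
    ``flow_reduction`` (diseased subjects eject less).  Pseudo-measurements
    are regenerated and the LPA flow is recomputed from Q_MPA - Q_RPA.
    """
    if subject.scenario != "baseline":
        raise ValueError("CTEPH can only be applied to a baseline subject")
    if severity < 1:
        raise ValueError("severity must be >= 1")
    if not (0 <= left_fraction <= 1):
        raise ValueError("left_fraction must lie in [0, 1]")
    if stiffening < 1:
        raise ValueError("stiffening must be >= 1")
    if not (0 < flow_reduction <= 1):
        raise ValueError("flow_reduction must lie in (0, 1]")
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    net = subject.network.with_segments(
        [
            dc_replace(s, stiffness=(s.stiffness or 0.0) * stiffening)
            for s in subject.network.ordered_segments()
        ]
    )
    walls = {
        k: WallModel(
            stiffness=w.stiffness * stiffening, area_dia=w.area_dia, p_dia=w.p_dia
        )
        for k, w in subject.walls.items()
    }
    left_ids = subject.network.subtree_ids(subject.lpa_id)
    right_factor = 1.0 + (1.0 - left_fraction) * (severity - 1.0)
    wk_true = {}
    for tid, w in subject.windkessels_true.items():
        fac = severity if tid in left_ids else right_factor
        wk_true[tid] = Windkessel3(Rp=w.Rp * fac, Rd=w.Rd * fac, C=w.C / fac, Pout=w.Pout)
    cfg = subject.config
    inflow = generate_inflow(
        cfg.period, cfg.stroke_volume * flow_reduction, cfg.systole_fraction
    )
    return _measure(
        subject_id=subject.subject_id + "-cteph",
        scenario="cteph",
        cfg=subject.config,
        seed=subject.seed if seed is None else seed,
        net=net,
        walls=walls,
        wk_nominal=subject.windkessels_nominal,
        wk_true=wk_true,
        theta=subject.true_theta,
        inflow=inflow,
        props=props,
        rng=rng,
        baseline_id=subject.subject_id,
        stiffening=subject.stiffening * stiffening,
    )
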