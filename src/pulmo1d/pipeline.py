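"""End-to-end study replica: subject -> nominal init -> calibrate ->
simulate at the optimum -> shear metrics -> report bundle.

The pipeline runs either on a generated synthetic subject (its nominal
Windkessels are the reference the true scaling factors were defined
against) or on files (network + inflow + calibration data), in which case
the nominal Windkessels are constructed from the measurements exactly as
the calibration protocol prescribes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import CalibrationResult, ModelContext, calibrate
from .io import (
    save_calibration_data,
    save_inflow,
    save_parameters,
)
from .network import load_network, save_network, scale_extralobar_areas
from .shear import ShearSummary, shear_field, summarize_network, OSI_HIGH_DEFAULT, TAU_LOW_DEFAULT
from .solver import FluidProperties, SimulationConfig, uniform_walls
from .synthetic import SubjectConfig, SyntheticSubject, apply_cteph, make_baseline_subject
from .units import MMHG
from .wall import (
    HemodynamicSummary,
    mean_pa_pressure,
    nominal_windkessels_lung_split,
    parallel_resistance,
    stiffness_from_systole,
    total_compliance_from_decay,
    total_pvr,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "compare_states", "context_from_files"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``scenario`` + ``seed`` (synthetic route) or all three file
    paths (measurement route) must be provided.
    """

    scenario: str = "baseline"  # "baseline" | "cteph"
    seed: int = 0
    subject: SubjectConfig = SubjectConfig()
    severity: float = 5.0
    left_fraction: float = 0.8
    stiffening: float = 2.0
    flow_reduction: float = 0.85
    network_path: str | None = None
    data_path: str | None = None
    inflow_path: str | None = None
    n_starts: int = 10
    weighting: str = "absolute"
    tau_low: float = TAU_LOW_DEFAULT
    osi_high: float = OSI_HIGH_DEFAULT
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        """Build from a plain mapping (e.g. parsed YAML/JSON); the
        ``subject`` entry, if present, maps to :class:`SubjectConfig`."""
        doc = dict(doc)
        subject = doc.pop("subject", None)
        if subject is not None:
            doc["subject"] = SubjectConfig(**subject)
        return cls(**doc)

    def __post_init__(self) -> None:
        if self.scenario not in ("baseline", "cteph"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        paths = (self.network_path, self.data_path, self.inflow_path)
        if any(paths) and not all(paths):
            raise ValueError("file route needs network, data, and inflow paths together")
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


@dataclass
class ReportBundle:
    subject_id: str
    scenario: str
    seed: int
    theta: dict[str, float]
    cost: float
    r2: dict[str, float]
    scalars: dict[str, dict[str, float]]
    eh_r0_mmhg: float
    total_rp: float  # mmHg*s/mL
    total_rd: float
    total_c: float  # mL/mmHg
    shear: ShearSummary = field(repr=False, default=None)  # type: ignore[assignment]
    calibration: CalibrationResult = field(repr=False, default=None)  # type: ignore[assignment]
    baseline_id: str | None = None

    def summary_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "scenario": self.scenario,
            "seed": self.seed,
            "baseline_id": self.baseline_id,
            "eh_r0_mmhg": self.eh_r0_mmhg,
            "total_rp_mmhg_s_ml": self.total_rp,
            "total_rd_mmhg_s_ml": self.total_rd,
            "total_c_ml_mmhg": self.total_c,
            "phi_percent": self.shear.phi,
            "intralobar_tawss_dyn_cm2": self.shear.intralobar_tawss,
            "intralobar_osi": self.shear.intralobar_osi,
            "units": {
                "eh_r0": "mmHg",
                "resistance": "mmHg*s/mL",
                "compliance": "mL/mmHg",
                "tawss": "dyn/cm^2",
            },
        }
        for name, vals in self.shear.extralobar.items():
            d[f"tawss_{name.lower()}_dyn_cm2"] = vals["tawss"]
            d[f"osi_{name.lower()}"] = vals["osi"]
        return d


def nominal_context(
    net,
    data,
    inflow,
    p_wedge: float,
    period: float,
    t_dia: float,
    props: FluidProperties = FluidProperties(),
    dx_target: float = 0.3,
    periodicity_tol: float = 1e-3,
) -> ModelContext:
    """Measurement-driven nominal model setup (the calibration protocol).

    The MPA reference area is rescaled to the measured diastolic area, the
    wall stiffness is the analytic Eh/r0 from the systolic/diastolic pair
    (anchored at the measured diastolic pressure), total PVR comes from the
    mean-pressure formula, the left/right lung resistance split from the
    measured mean branch flows, and total compliance from the diastolic
    pressure decay.
    """
    net = scale_extralobar_areas(net, {"MPA": data.a_dia})
    f_mmhg = stiffness_from_systole(data.p_sys, data.p_dia, data.a_sys, data.a_dia)
    walls = uniform_walls(net, f_mmhg * MMHG, data.p_dia * MMHG)
    q_mean = inflow.mean
    p_mean = mean_pa_pressure(data.p_sys, data.p_dia)
    r_tot = total_pvr(p_mean, p_wedge, q_mean)
    summary = HemodynamicSummary(
        p_sys=data.p_sys,
        p_dia=data.p_dia,
        a_sys=data.a_sys,
        a_dia=data.a_dia,
        p_wedge=p_wedge,
        q_mean=q_mean,
        period=period,
        t_dia=t_dia,
    )
    c_tot = total_compliance_from_decay(summary, r_tot)
    wk_nominal = nominal_windkessels_lung_split(
        net,
        r_tot * MMHG,
        c_tot / MMHG,
        props.mu,
        p_wedge * MMHG,
        q_left_mean=float(data.q_lpa.q.mean()),
        q_right_mean=float(data.q_rpa.q.mean()),
    )
    lpa, rpa = net.root.children
    return ModelContext(
        net=net,
        walls=walls,
        windkessels=wk_nominal,
        inflow=inflow,
        props=props,
        config=SimulationConfig(
            cycle_length=period, dx_target=dx_target, periodicity_tol=periodicity_tol
        ),
        mpa_id=net.root_id,
        lpa_id=lpa,
        rpa_id=rpa,
    )


def context_from_files(
    network_path: str,
    data_path: str,
    inflow_path: str,
    props: FluidProperties = FluidProperties(),
    dx_target: float = 0.3,
    periodicity_tol: float = 1e-3,
):
    """Nominal model setup from measurement files; returns
    (ModelContext, CalibrationData, extras dict)."""
    from .io import load_calibration_data, load_inflow

    net = load_network(network_path)
    data, extras = load_calibration_data(data_path)
    inflow = load_inflow(inflow_path)
    ctx = nominal_context(
        net,
        data,
        inflow,
        p_wedge=extras["p_wedge"],
        period=extras["period"],
        t_dia=extras["t_dia"],
        props=props,
        dx_target=dx_target,
        periodicity_tol=periodicity_tol,
    )
    return ctx, data, extras


def _emit_subject_files(subject: SyntheticSubject, out: Path) -> None:
    save_network(subject.network, out / "network.json")
    save_inflow(subject.inflow, out / "inflow.csv", seed=subject.seed)
    save_parameters(
        subject.windkessels_true,
        {sid: w.stiffness for sid, w in subject.walls.items()},
        out / "parameters.json",
        seed=subject.seed,
    )
    save_calibration_data(
        subject.measurements,
        out / "calibration_data.json",
        p_wedge=subject.config.p_wedge,
        period=subject.config.period,
        t_dia=subject.summary.t_dia,
        seed=subject.seed,
    )


def run_pipeline(
    config: RunConfig, props: FluidProperties = FluidProperties()
) -> ReportBundle:
    """Execute synth/load -> nominal init -> calibrate -> simulate at the
    optimum -> metrics, writing the report bundle to ``config.out_dir`` if
    set.  Outputs are deterministic for a fixed config and seed."""
    t_start = time.perf_counter()
    timings: dict[str, float] = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.network_path is not None:
        ctx, data, extras = context_from_files(
            config.network_path, config.data_path, config.inflow_path, props
        )
        subject_id = Path(config.network_path).stem
        baseline_id = None
        p_wedge = extras["p_wedge"]
        period = extras["period"]
        t_dia = extras["t_dia"]
    else:
        subject = make_baseline_subject(config.subject, seed=config.seed, props=props)
        if config.scenario == "cteph":
            subject = apply_cteph(
                subject,
                severity=config.severity,
                left_fraction=config.left_fraction,
                stiffening=config.stiffening,
                flow_reduction=config.flow_reduction,
                props=props,
            )
        data = subject.measurements
        subject_id = subject.subject_id
        baseline_id = subject.baseline_id
        p_wedge = subject.config.p_wedge
        period = subject.config.period
        t_dia = subject.summary.t_dia
        # nominal Windkessels are rebuilt from the pseudo-measurements, the
        # same protocol the measurement route uses (not from ground truth)
        ctx = nominal_context(
            subject.network,
            data,
            subject.inflow,
            p_wedge=p_wedge,
            period=period,
            t_dia=t_dia,
            props=props,
            dx_target=subject.config.dx_target,
            periodicity_tol=subject.config.periodicity_tol,
        )
        if out is not None:
            _emit_subject_files(subject, out)
    timings["setup_s"] = time.perf_counter() - t_start

    t0 = time.perf_counter()
    result = calibrate(
        data, ctx, n_starts=config.n_starts, seed=config.seed, weighting=config.weighting
    )
    timings["calibrate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sol = ctx.simulate(result.theta)
    wk_hat = ctx.scaled_windkessels(result.theta)
    shear = summarize_network(
        shear_field(sol, props), ctx.net, tau_low=config.tau_low, osi_high=config.osi_high
    )
    timings["simulate_metrics_s"] = time.perf_counter() - t0

    bundle = ReportBundle(
        subject_id=subject_id,
        scenario=config.scenario,
        seed=config.seed,
        theta={"rp": result.theta.rp, "rd": result.theta.rd, "c": result.theta.c},
        cost=result.cost,
        r2=result.r2,
        scalars=result.scalars,
        eh_r0_mmhg=stiffness_from_systole(data.p_sys, data.p_dia, data.a_sys, data.a_dia),
        total_rp=parallel_resistance([w.Rp for w in wk_hat.values()]) / MMHG,
        total_rd=parallel_resistance([w.Rd for w in wk_hat.values()]) / MMHG,
        total_c=sum(w.C for w in wk_hat.values()) * MMHG,
        shear=shear,
        calibration=result,
        baseline_id=baseline_id,
    )

    if out is not None:
        result_doc = {
            "format": "pulmo1d-result",
            "package_version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
            "subject_id": subject_id,
            "theta": bundle.theta,
            "cost": bundle.cost,
            "r2": bundle.r2,
            "scalars": bundle.scalars,
            "weighting": config.weighting,
            "starts": [
                {
                    "start": {"rp": s.start.rp, "rd": s.start.rd, "c": s.start.c},
                    "theta": {"rp": s.theta.rp, "rd": s.theta.rd, "c": s.theta.c},
                    "cost": s.cost,
                    "success": s.success,
                }
                for s in result.starts
            ],
            "units": {"pressure": "mmHg", "area": "cm^2", "flow": "mL/s"},
        }
        with open(out / "result.json", "w") as fh:
            json.dump(result_doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "metrics.csv", "w") as fh:
            fh.write(f"# seed={config.seed}\n")
            fh.write("# units: length cm, tawss dyn/cm^2, osi dimensionless\n")
            shear.per_segment.to_csv(fh, index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(bundle.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        save_parameters(
            wk_hat,
            {sid: w.stiffness for sid, w in ctx.walls.items()},
            out / "parameters_calibrated.json",
            seed=config.seed,
        )
        timings["total_s"] = time.perf_counter() - t_start
        with open(out / "run.log", "w") as fh:
            fh.write(f"pulmo1d {__version__}\n")
            fh.write(f"subject={subject_id} scenario={config.scenario} seed={config.seed}\n")
            fh.write(
                f"p_wedge={p_wedge} mmHg, period={period} s, t_dia={t_dia} s\n"
            )
            fh.write(f"theta={bundle.theta} cost={bundle.cost!r}\n")
            for k, v in timings.items():
                fh.write(f"{k}={v:.3f}\n")
    return bundle


_COMPARE_KEYS = [
    "eh_r0_mmhg",
    "total_rp_mmhg_s_ml",
    "total_rd_mmhg_s_ml",
    "total_c_ml_mmhg",
    "tawss_mpa_dyn_cm2",
    "tawss_lpa_dyn_cm2",
    "tawss_rpa_dyn_cm2",
    "intralobar_tawss_dyn_cm2",
    "osi_mpa",
    "osi_lpa",
    "osi_rpa",
    "intralobar_osi",
    "phi_percent",
]


def compare_states(baseline: ReportBundle | dict, cteph: ReportBundle | dict) -> pd.DataFrame:
    """Paired baseline-vs-diseased differences for one subject lineage.

    Returns a table with columns (metric, baseline, cteph, delta, ratio).
    Raises if the two reports do not belong to the same subject.
    """
    b = baseline.summary_dict() if isinstance(baseline, ReportBundle) else baseline
    c = cteph.summary_dict() if isinstance(cteph, ReportBundle) else cteph
    if c.get("baseline_id") not in (b.get("subject_id"), None) or (
        c.get("baseline_id") is None and b.get("subject_id") != c.get("subject_id")
    ):
        raise ValueError(
            f"mismatched subject lineage: {b.get('subject_id')} vs "
            f"{c.get('baseline_id') or c.get('subject_id')}"
        )
    rows = []
    for key in _COMPARE_KEYS:
        if key not in b or key not in c:
            continue
        vb, vc = float(b[key]), float(c[key])
        rows.append(
            {
                "metric": key,
                "baseline": vb,
                "cteph": vc,
                "delta": vc - vb,
                "ratio": vc / vb if vb != 0 else float("inf") if vc > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
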