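"""Plain-text serialization for measurements, parameters, and solutions.

Every emitted file declares its units (and, where applicable, the
generating seed) so outputs are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationData, FlowSeries
from .solver import InflowWaveform, SolutionField
from .units import MMHG
from .wall import Windkessel3

__all__ = [
    "save_inflow",
    "load_inflow",
    "save_calibration_data",
    "load_calibration_data",
    "save_parameters",
    "load_parameters",
    "save_solution",
]


def _write_json(doc: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_inflow(inflow: InflowWaveform, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(f"# period_s={inflow.period!r}\n")
        fh.write("t_s,q_ml_s\n")
        t = np.linspace(0.0, inflow.period, inflow.q.size)
        for tk, qk in zip(t, inflow.q):
            fh.write(f"{float(tk)!r},{float(qk)!r}\n")


def load_inflow(path: str | Path) -> InflowWaveform:
    path = Path(path)
    period = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# period_s="):
                period = float(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    if period is None:
        period = float(df["t_s"].iloc[-1])
    return InflowWaveform(df["q_ml_s"].to_numpy(), period)


def save_calibration_data(
    data: CalibrationData,
    path: str | Path,
    p_wedge: float,
    period: float,
    t_dia: float,
    seed: int | None = None,
) -> None:
    doc = {
        "format": "pulmo1d-calibration-data",
        "units": {
            "pressure": "mmHg",
            "area": "cm^2",
            "flow": "mL/s",
            "time": "s",
        },
        "seed": seed,
        "p_sys": data.p_sys,
        "p_dia": data.p_dia,
        "a_sys": data.a_sys,
        "a_dia": data.a_dia,
        "p_wedge": p_wedge,
        "period": period,
        "t_dia": t_dia,
        "t": data.q_lpa.t.tolist(),
        "q_lpa": data.q_lpa.q.tolist(),
        "q_rpa": data.q_rpa.q.tolist(),
        "q_lpa_recomputed": data.q_lpa.recomputed,
        "q_rpa_recomputed": data.q_rpa.recomputed,
    }
    _write_json(doc, Path(path))


def load_calibration_data(path: str | Path) -> tuple[CalibrationData, dict]:
    """Returns (data, extras) where extras carries p_wedge/period/t_dia/seed."""
    with open(path) as fh:
        doc = json.load(fh)
    t = np.asarray(doc["t"], dtype=float)
    data = CalibrationData(
        p_sys=doc["p_sys"],
        p_dia=doc["p_dia"],
        a_sys=doc["a_sys"],
        a_dia=doc["a_dia"],
        q_lpa=FlowSeries(t, np.asarray(doc["q_lpa"], dtype=float), doc.get("q_lpa_recomputed", False)),
        q_rpa=FlowSeries(t, np.asarray(doc["q_rpa"], dtype=float), doc.get("q_rpa_recomputed", False)),
    )
    extras = {k: doc.get(k) for k in ("p_wedge", "period", "t_dia", "seed")}
    return data, extras


def save_parameters(
    windkessels: Mapping[str, Windkessel3],
    stiffness: Mapping[str, float],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Per-terminal Windkessel and per-segment Eh/r0, clinical units."""
    doc = {
        "format": "pulmo1d-parameters",
        "units": {
            "Rp": "mmHg*s/mL",
            "Rd": "mmHg*s/mL",
            "C": "mL/mmHg",
            "Pout": "mmHg",
            "eh_r0": "mmHg",
        },
        "seed": seed,
        "terminals": {
            tid: {
                "Rp": w.Rp / MMHG,
                "Rd": w.Rd / MMHG,
                "C": w.C * MMHG,
                "Pout": w.Pout / MMHG,
            }
            for tid, w in sorted(windkessels.items())
        },
        "stiffness": {sid: s / MMHG for sid, s in sorted(stiffness.items())},
    }
    _write_json(doc, Path(path))


def load_parameters(path: str | Path) -> tuple[dict[str, Windkessel3], dict[str, float]]:
    with open(path) as fh:
        doc = json.load(fh)
    wks = {
        tid: Windkessel3(
            Rp=v["Rp"] * MMHG, Rd=v["Rd"] * MMHG, C=v["C"] / MMHG, Pout=v["Pout"] * MMHG
        )
        for tid, v in doc["terminals"].items()
    }
    stiff = {sid: s * MMHG for sid, s in doc.get("stiffness", {}).items()}
    return wks, stiff


def save_solution(sol: SolutionField, path: str | Path, seed: int | None = None, stride: int = 8) -> None:
    """Long-format CSV export (x, t, P_mmHg, Q_mL_s, A_cm2) per segment.

    ``stride`` subsamples the time axis to keep files reviewable.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# units: x_cm, t_s, P_mmHg, Q_mL_s, A_cm2\n")
        fh.write("segment,x_cm,t_s,P_mmHg,Q_mL_s,A_cm2\n")
        tsel = np.arange(0, sol.t.size, stride)
        for sid in sorted(sol.segments):
            seg = sol.segments[sid]
            for j, x in enumerate(seg.x):
                for k in tsel:
                    fh.write(
                        f"{sid},{x:.6g},{sol.t[k]:.6g},"
                        f"{seg.P[j, k] / MMHG:.8g},{seg.Q[j, k]:.8g},{seg.A[j, k]:.8g}\n"
                    )
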