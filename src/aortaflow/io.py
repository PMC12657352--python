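"""File formats and run configuration.

Networks travel as JSON; divisions, steady results and metric tables
as CSV; iteration traces, Windkessel parameters and run manifests as
JSON.  Pressures are externally in mmHg, flows in mL·s⁻¹, resistances
in mmHg·s·mL⁻¹ and compliances in mL·mmHg⁻¹; geometry in cm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .estimation import (EstimationConfig, FlowDivision, IterationTrace,
                         Windkessel3)
from .network import (AorticNetwork, LumenTag, StenosisSpec, ValidationError,
                      VesselSegment)
from .steady import BloodProperties, SteadyResult
from .waveform import InletWaveform

__all__ = [
    "RunConfig",
    "read_network",
    "write_network",
    "read_waveform_csv",
    "write_waveform_csv",
    "write_division_csv",
    "read_division_csv",
    "write_steady_csv",
    "write_trace_json",
    "write_wk3_json",
    "read_wk3_json",
    "write_metrics_csv",
    "write_transient_csv",
    "run_manifest",
]


@dataclass
class RunConfig:
    """All tunables of the pipeline, loadable from YAML."""

    density: float = 1060.0            # kg·m⁻³
    viscosity: float = 0.0035          # Pa·s
    solver_tol: float = 1e-12
    max_newton: int = 100
    omega: float = 1.0
    max_iter: int = 50
    threshold: float = 0.01            # relative inlet-pressure discrepancy
    f_c: float = 0.056
    tau: float = 1.79                  # s
    n_steps_per_cycle: int = 1000
    n_cycles: int = 5
    venous_pressure: float = 0.0       # mmHg
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must be in (0, 1)")
        if self.solver_tol <= 0:
            raise ValidationError("solver_tol must be > 0")

    def blood(self) -> BloodProperties:
        return BloodProperties(self.density, self.viscosity)

    def estimation(self) -> EstimationConfig:
        return EstimationConfig(omega=self.omega, threshold=self.threshold,
                                max_iter=self.max_iter, f_c=self.f_c,
                                tau=self.tau,
                                venous_pressure=self.venous_pressure)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# network JSON


def write_network(network: AorticNetwork, path) -> None:
    doc = {
        "nodes": sorted(network.nodes),
        "segments": [_segment_to_json(s) for s in network.segments],
        "inlet": network.inlet_node,
        "outlets": dict(sorted(network.outlets.items())),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _segment_to_json(s: VesselSegment) -> dict:
    d = {"id": s.id, "from": s.from_node, "to": s.to_node,
         "length_cm": s.length, "radius_cm": s.radius,
         "lumen_tag": s.lumen_tag.value}
    if s.stenosis is not None:
        d["stenosis"] = {"area_ratio": s.stenosis.area_ratio,
                         "kt": s.stenosis.kt}
    return d


def read_network(path) -> AorticNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"invalid network JSON in {path}: {e}")
    for key in ("nodes", "segments", "inlet", "outlets"):
        if key not in doc:
            raise ValidationError(f"network JSON missing field {key!r}")
    segments = []
    for sd in doc["segments"]:
        for key in ("id", "from", "to", "length_cm", "radius_cm"):
            if key not in sd:
                raise ValidationError(
                    f"segment entry missing field {key!r}: {sd}")
        sten = None
        if sd.get("stenosis") is not None:
            st = sd["stenosis"]
            if "area_ratio" not in st:
                raise ValidationError(
                    f"stenosis entry missing field 'area_ratio': {sd}")
            sten = StenosisSpec(st["area_ratio"], st.get("kt", 1.52))
        segments.append(VesselSegment(
            sd["id"], sd["from"], sd["to"], sd["length_cm"], sd["radius_cm"],
            lumen_tag=LumenTag(sd.get("lumen_tag", "NONE")), stenosis=sten))
    return AorticNetwork(nodes=set(doc["nodes"]), segments=segments,
                         inlet_node=doc["inlet"], outlets=doc["outlets"])


# ---------------------------------------------------------------------------
# tabular outputs


def read_waveform_csv(path) -> InletWaveform:
    df = pd.read_csv(path)
    for col in ("time_s", "flow_mL_s"):
        if col not in df.columns:
            raise ValidationError(f"waveform CSV missing column {col!r}")
    return InletWaveform(df["time_s"].to_numpy(), df["flow_mL_s"].to_numpy())


def write_waveform_csv(waveform: InletWaveform, path) -> None:
    pd.DataFrame({"time_s": waveform.time, "flow_mL_s": waveform.flow}
                 ).to_csv(path, index=False)


def write_division_csv(division: FlowDivision, path) -> None:
    pd.DataFrame({"branch": division.branches(),
                  "fraction": [division[b] for b in division.branches()]}
                 ).to_csv(path, index=False)


def read_division_csv(path) -> FlowDivision:
    df = pd.read_csv(path)
    return FlowDivision(dict(zip(df["branch"], df["fraction"])))


def write_steady_csv(result: SteadyResult, path) -> None:
    branches = sorted(result.Q)
    pd.DataFrame({
        "branch": branches,
        "Q_mL_s": [result.Q[b] for b in branches],
        "P_out_mmHg": [result.P_out[b] for b in branches],
        "dP_mmHg": [result.dP[b] for b in branches],
    }).to_csv(path, index=False)
    Path(path).with_suffix(".summary.json").write_text(
        json.dumps({"P_in_mmHg": result.P_in}, indent=1) + "\n")


def write_trace_json(trace: IterationTrace, path) -> None:
    Path(path).write_text(json.dumps(
        {"converged": trace.converged, "n_iter": trace.n_iter,
         "records": trace.records}, indent=1) + "\n")


def write_wk3_json(wk_map: dict[str, Windkessel3], path) -> None:
    doc = {b: {"R_c_mmHg_s_mL": w.R_c, "R_p_mmHg_s_mL": w.R_p,
               "C_mL_mmHg": w.C} for b, w in sorted(wk_map.items())}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_wk3_json(path) -> dict[str, Windkessel3]:
    doc = json.loads(Path(path).read_text())
    return {b: Windkessel3(d["R_c_mmHg_s_mL"], d["R_p_mmHg_s_mL"],
                           d["C_mL_mmHg"]) for b, d in doc.items()}


def write_metrics_csv(ids, tawss_vals, osi_vals, rrt_vals, afi_vals,
                      path) -> None:
    pd.DataFrame({"point": ids, "TAWSS_Pa": tawss_vals, "OSI": osi_vals,
                  "RRT_inv_Pa": rrt_vals, "AFI": afi_vals}
                 ).to_csv(path, index=False)


def write_transient_csv(result, path) -> None:
    """Wide CSV: per-node pressure and per-segment flow series."""
    cols: dict[str, Any] = {"time_s": result.times}
    for i, n in enumerate(result.node_ids):
        cols[f"P_{n}_mmHg"] = result.node_pressure[:, i]
    for i, s in enumerate(result.segment_ids):
        cols[f"Q_{s}_mL_s"] = result.segment_flow[:, i]
    for i, b in enumerate(result.outlet_names):
        cols[f"Pc_{b}_mmHg"] = result.capacitor_pressure[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reproducibility


def run_manifest(config: RunConfig, seed: int | None = None) -> dict:
    """Manifest embedded next to every CLI output: config hash, package
    version and the seed in effect."""
    from . import __version__
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    return {"config": cfg, "config_sha256": digest,
            "aortaflow_version": __version__,
            "seed": config.seed if seed is None else seed}
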