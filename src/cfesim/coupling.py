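"""Workflow orchestration: FE resistance -> interface circuit -> field series.

The pipeline mirrors the measurement-to-prediction chain: (1) the tissue
load seen by the pulse generator is extracted from a stationary FE solve at
1 V; (2) the interface circuit is simulated against that load, yielding the
electrode boundary potential V(t); (3) the time-resolved field maps are the
unit FE solution (+1 V anodes / -1 V cathodes) scaled by V(t).  The scaling
shortcut is exact because the tissue model is linear and memoryless and the
Dirichlet pattern is fixed up to amplitude; a brute-force mode re-solves the
FE system per sample as an internal oracle.

Note on conventions: the potentials are applied symmetrically (+V on the
anode bank, -V on the cathode bank), so the FE anode-cathode span is 2 V(t)
while the one-port circuit delivers V(t) against the extracted resistance;
the consistency cross-check therefore asserts I_FE * R_tissue = 2 V(t).
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError, SolverError
from .geometry import TissueMesh, ElectrodeConfig, electrode_configuration
from .cpe_network import CPEInterfaceParams, synthesize_network
from .interface_circuit import (FaradaicParams, PulseSpec, CircuitResponse,
                                simulate_interface, DEFAULT_FARADAIC)
from .fem_poisson import (ConductivityMap, MembraneSpec, LinearSystem,
                          FieldSolution, assemble, solve_potential,
                          extract_resistance, electric_field_magnitude)

__all__ = ["SimulationPlan", "SimulationResult", "run_simulation",
           "configured_pipeline"]


@dataclass
class SimulationPlan:
    """Everything needed for one electroporation simulation."""

    mesh: TissueMesh
    config: ElectrodeConfig | str = "tandem"
    conductivities: ConductivityMap = field(default_factory=ConductivityMap)
    membranes: MembraneSpec = field(default_factory=MembraneSpec)
    cpe: CPEInterfaceParams = field(default_factory=CPEInterfaceParams)
    faradaic: FaradaicParams | None = field(
        default_factory=lambda: FaradaicParams())
    pulse: PulseSpec = field(default_factory=lambda: PulseSpec(
        amplitude=20.0, width=50e-3, rise_time=1e-3, fall_time=1e-3))
    sample_dt_ramp: float = 10e-6
    sample_dt_plateau: float = 1e-3
    circuit_dt_max: float = 1e-6
    read_point: str = "tissue"
    first_pulse_only: bool = True
    fe_method: str = "direct"

    def sample_times(self) -> np.ndarray:
        """Adaptive output samples: dense on the ramps, sparse on plateaus."""
        p = self.pulse
        n_pulses = 1 if self.first_pulse_only else p.n_pulses
        ts = []
        for k in range(n_pulses):
            t0 = k * p.period
            ts.append(np.arange(t0, t0 + p.rise_time + 1e-15, self.sample_dt_ramp))
            ts.append(np.arange(t0 + p.rise_time, t0 + p.width + 1e-15,
                                self.sample_dt_plateau))
            ts.append([t0 + p.width])  # end of plateau, always sampled
            ts.append(np.arange(t0 + p.width,
                                t0 + p.width + p.fall_time + 1e-15,
                                self.sample_dt_ramp))
            ts.append([t0 + p.width + p.fall_time])
        t = np.unique(np.concatenate([np.atleast_1d(np.asarray(x)) for x in ts]))
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("degenerate sample-time grid")
        return t


@dataclass
class SimulationResult:
    """Circuit response + unit field solution + per-sample scale factors.

    The field solution at sample i is ``unit_solution.scaled(scales[i])``
    (anodes at +scales[i] V, cathodes at -scales[i] V).
    """

    plan: SimulationPlan
    tissue_resistance: float
    response: CircuitResponse
    unit_solution: FieldSolution
    times: np.ndarray
    scales: np.ndarray
    system: LinearSystem

    def solution_at(self, i: int) -> FieldSolution:
        return self.unit_solution.scaled(float(self.scales[i]))

    @property
    def config(self) -> ElectrodeConfig:
        return electrode_configuration(self.plan.config)

    def plateau_index(self) -> int:
        """Sample index at the end of the first pulse plateau."""
        return int(np.argmin(np.abs(self.times - self.plan.pulse.width)))


def run_simulation(plan: SimulationPlan,
                   system: LinearSystem | None = None,
                   brute_force: bool = False,
                   brute_force_rtol: float = 1e-8) -> SimulationResult:
    """Run the full coupled workflow for one electrode configuration.

    With ``brute_force=True`` every sampled field solution is additionally
    recomputed by a fresh FE solve at the instantaneous electrode potential
    and compared against the superposition-scaled unit solution; any
    disagreement beyond `brute_force_rtol` raises SolverError.
    """
    cfg = electrode_configuration(plan.config)
    if system is None:
        system = assemble(plan.mesh, plan.conductivities, plan.membranes)

    R_tissue, half_sol = extract_resistance(
        plan.mesh, plan.conductivities, plan.membranes, cfg,
        system=system, method=plan.fe_method)
    unit = half_sol.scaled(2.0)  # +-0.5 V split -> +-1 V pattern

    network = synthesize_network(plan.cpe)
    response = simulate_interface(
        network, plan.cpe.R_s, plan.faradaic, R_tissue, plan.pulse,
        dt_max=plan.circuit_dt_max, read_point=plan.read_point,
        store_every=10)

    times = plan.sample_times()
    scales = np.interp(times, response.time, response.v_out)

    if brute_force:
        for t, s in zip(times, scales):
            dirichlet = {a: +s for a in cfg.anodes}
            dirichlet.update({c: -s for c in cfg.cathodes})
            ref = solve_potential(system, dirichlet, method=plan.fe_method)
            denom = max(np.max(np.abs(ref.potential)), 1e-12)
            err = np.max(np.abs(ref.potential - unit.potential * s)) / denom
            if err > brute_force_rtol:
                raise SolverError(
                    f"superposition mismatch at t={t:g}: rel err {err:.3e}")
            # circuit/FE current consistency (symmetric span = 2 V(t))
            i_fe = sum(ref.electrode_currents[a] for a in cfg.anodes)
            if abs(s) > 1e-9 and abs(i_fe * R_tissue - 2.0 * s) > 0.01 * 2.0 * abs(s):
                raise SolverError(
                    f"FE current inconsistent with circuit at t={t:g}")

    return SimulationResult(plan=plan, tissue_resistance=R_tissue,
                            response=response, unit_solution=unit,
                            times=times, scales=scales, system=system)


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

def configured_pipeline(config, out_dir=None) -> dict:
    """Run a TOML-configured simulation and write the artifact set.

    `config` is a path to a TOML file or an already-parsed dict (see
    cfesim.config for the schema).  Artifacts: circuit response CSV, VTU
    field snapshots (mid-ramp and end-of-plateau), field-area report CSV +
    JSON summary, and a manifest with a parameter hash.  Returns the
    manifest dict.
    """
    from .config import load_config, build_plan, config_digest
    from .fieldmap import bin_field_areas
    from .mesh_io import write_fields

    cfg_dict = load_config(config)
    plan, meta = build_plan(cfg_dict)
    out = Path(out_dir or cfg_dict.get("output", {}).get("directory", "cfesim_out"))
    out.mkdir(parents=True, exist_ok=True)

    result = run_simulation(plan)
    name = meta.get("name", "run")
    artifacts = {}

    circuit_csv = out / f"{name}_circuit.csv"
    result.response.to_csv(circuit_csv)
    artifacts["circuit_csv"] = circuit_csv.name

    emag_unit = electric_field_magnitude(result.unit_solution)
    snap_idx = {"midramp": int(np.argmin(np.abs(
        result.times - 0.5 * plan.pulse.rise_time))),
        "plateau": result.plateau_index()}
    for tag, i in snap_idx.items():
        sol = result.solution_at(i)
        path = out / f"{name}_field_{tag}.vtu"
        write_fields(path, plan.mesh,
                     point_data={"V": sol.potential},
                     cell_data={"E_mag_V_per_m": emag_unit * abs(result.scales[i])})
        artifacts[f"vtu_{tag}"] = path.name

    target = meta.get("target_surface", "basilar_membrane")
    report = None
    if target in plan.mesh.membranes or \
            target in plan.mesh.surface_names.values():
        report = bin_field_areas(result, plan.mesh, target,
                                 config_name=getattr(result.config, "name", name))
        rep_csv = out / f"{name}_areas.csv"
        report.to_csv(rep_csv)
        artifacts["area_csv"] = rep_csv.name
        summary = report.summary()
        with open(out / f"{name}_areas_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        artifacts["area_summary_json"] = f"{name}_areas_summary.json"

    manifest = {
        "name": name,
        "config_digest": config_digest(cfg_dict),
        "tissue_resistance_ohm": result.tissue_resistance,
        "plateau_potential_V": float(result.scales[result.plateau_index()]),
        "n_samples": int(result.times.size),
        "artifacts": artifacts,
    }
    with open(out / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
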