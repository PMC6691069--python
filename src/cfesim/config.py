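"""Run configuration: TOML schema, validation, and plan construction.

Every default reproduces the reference parameter set: the Table of tissue
conductivities, the optimized interface parameters (theta = 65.3 deg,
k = 1.18, 61 branches, R_s = 297 Ohm), the calibrated Faradaic branch, and
a single 20 V / 50 ms pulse with 1 ms rise and fall times.  Quantities carry
explicit unit suffixes in their key names (_um, _mm, _ms, _ohm, ...).

YAML input is accepted behind the ``allow_yaml`` flag of ``load_config``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import tomllib
from pathlib import Path

from .errors import FormatError, ValidationError
from .geometry import (ArraySpec, DuctSpec, build_duct_geometry,
                       build_slab_fixture, electrode_configuration)
from .cpe_network import CPEInterfaceParams
from .interface_circuit import FaradaicParams, PulseSpec
from .fem_poisson import ConductivityMap, MembraneSpec

__all__ = ["DEFAULT_CONFIG", "load_config", "build_plan", "config_digest",
           "bundled_config_path"]

DEFAULT_CONFIG: dict = {
    "run": {"name": "run", "target_surface": "basilar_membrane"},
    "geometry": {
        "kind": "duct",                   # duct | slab | msh
        "mesh_size_um": 100.0,
        "msh_path": "",
        "slab_dims_mm": [1.0, 1.0, 1.0],
        "slab_membrane": False,
        "duct_length_mm": 16.0,
        "spiral": False,
    },
    "array": {
        "electrode_diameter_um": 350.0,
        "electrode_length_um": 300.0,
        "gap_um": 300.0,
    },
    "electrodes": {"configuration": "tandem"},
    "conductivity_s_per_m": {
        "scala_tympani": 1.5,
        "scala_media": 1.5,
        "scala_vestibuli": 1.5,
        "soft_tissue": 0.25092,
        "partition": 0.017126,
    },
    "membranes": {
        "basilar_membrane": {"sigma_s_per_m": 0.2904, "thickness_um": 90.0},
        "reissner_membrane": {"sigma_s_per_m": 0.2904, "thickness_um": 20.0},
    },
    "cpe": {
        "theta_cpe_deg": 65.3,
        "k": 1.18,
        "n_branches": 61,
        "r_s_ohm": 297.0,
        "f_lo_hz": 0.1,
        "f_hi_hz": 10000.0,
        "calibration_frequency_hz": 0.1,
        "calibration_target_ohm": 100000.0,
    },
    "faradaic": {
        "enabled": True,
        "i_s_a": 1e-6,
        "n_ideality": 2.0,
        "v_t_v": 0.02585,
        "m0_ohm": 50.0,
        "q0_c": 1e-3,
        "m_min_ohm": 10.0,
    },
    "pulse": {
        "amplitude_v": 20.0,
        "width_ms": 50.0,
        "rise_time_ms": 1.0,
        "fall_time_ms": 1.0,
        "n_pulses": 1,
        "inter_pulse_gap_ms": 50.0,
    },
    "circuit": {"r_tissue_ohm": 522.0},    # used by circuit-only runs
    "simulation": {
        "read_point": "tissue",
        "circuit_dt_max_us": 1.0,
        "sample_dt_ramp_us": 10.0,
        "sample_dt_plateau_ms": 1.0,
    },
    "output": {"directory": "cfesim_out"},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            # membranes/conductivity tables accept arbitrary labels
            if path in ("membranes", "conductivity_s_per_m"):
                out[key] = copy.deepcopy(val)
                continue
            raise ValidationError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        elif isinstance(base[key], dict) != isinstance(val, dict):
            raise ValidationError(f"configuration key {here} has wrong type")
        else:
            out[key] = val
    return out


def load_config(source, allow_yaml: bool = False) -> dict:
    """Load and validate a config; values not given fall back to defaults."""
    if isinstance(source, dict):
        user = source
    else:
        p = Path(source)
        if not p.exists():
            raise FormatError(f"config file not found: {p}")
        if p.suffix in (".yaml", ".yml"):
            if not allow_yaml:
                raise FormatError("YAML config given without --yaml/allow_yaml")
            import yaml
            user = yaml.safe_load(p.read_text()) or {}
        else:
            with open(p, "rb") as fh:
                user = tomllib.load(fh)
    return _merge(DEFAULT_CONFIG, user)


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def make_cpe(cfg: dict) -> CPEInterfaceParams:
    c = cfg["cpe"]
    return CPEInterfaceParams(
        theta_cpe_deg=c["theta_cpe_deg"], k=c["k"],
        n_branches=int(c["n_branches"]), R_s=c["r_s_ohm"],
        f_lo=c["f_lo_hz"], f_hi=c["f_hi_hz"],
        calibration_frequency_hz=c["calibration_frequency_hz"],
        calibration_target_ohm=c["calibration_target_ohm"])


def make_faradaic(cfg: dict) -> FaradaicParams | None:
    f = cfg["faradaic"]
    if not f["enabled"]:
        return None
    return FaradaicParams(I_s=f["i_s_a"], n_ideality=f["n_ideality"],
                          V_T=f["v_t_v"], M_0=f["m0_ohm"], q_0=f["q0_c"],
                          M_min=f["m_min_ohm"])


def make_pulse(cfg: dict) -> PulseSpec:
    p = cfg["pulse"]
    return PulseSpec(amplitude=p["amplitude_v"],
                     width=p["width_ms"] * 1e-3,
                     rise_time=p["rise_time_ms"] * 1e-3,
                     fall_time=p["fall_time_ms"] * 1e-3,
                     n_pulses=int(p["n_pulses"]),
                     inter_pulse_gap=p["inter_pulse_gap_ms"] * 1e-3)


def make_mesh(cfg: dict):
    g = cfg["geometry"]
    h = g["mesh_size_um"] * 1e-6
    kind = g["kind"]
    if kind == "slab":
        dims = [d * 1e-3 for d in g["slab_dims_mm"]]
        return build_slab_fixture(dims=dims, mesh_size=h,
                                  membrane=bool(g["slab_membrane"]))
    if kind == "duct":
        a = cfg["array"]
        array = ArraySpec(electrode_diameter=a["electrode_diameter_um"] * 1e-6,
                          electrode_length=a["electrode_length_um"] * 1e-6,
                          gap=a["gap_um"] * 1e-6)
        duct = DuctSpec(length=g["duct_length_mm"] * 1e-3)
        return build_duct_geometry(array=array, duct=duct, mesh_size=h,
                                   spiral=bool(g["spiral"]))
    if kind == "msh":
        from .mesh_io import read_mesh
        if not g["msh_path"]:
            raise ValidationError("geometry.kind = 'msh' requires geometry.msh_path")
        return read_mesh(g["msh_path"])
    raise ValidationError(f"geometry.kind must be duct|slab|msh, got {kind!r}")


def build_plan(cfg: dict):
    """(SimulationPlan, meta dict) from a validated config."""
    from .coupling import SimulationPlan
    mesh = make_mesh(cfg)
    cond = ConductivityMap({k: float(v)
                            for k, v in cfg["conductivity_s_per_m"].items()})
    mem = MembraneSpec({k: (v["sigma_s_per_m"], v["thickness_um"] * 1e-6)
                        for k, v in cfg["membranes"].items()})
    sim = cfg["simulation"]
    plan = SimulationPlan(
        mesh=mesh,
        config=electrode_configuration(cfg["electrodes"]["configuration"]),
        conductivities=cond,
        membranes=mem,
        cpe=make_cpe(cfg),
        faradaic=make_faradaic(cfg),
        pulse=make_pulse(cfg),
        sample_dt_ramp=sim["sample_dt_ramp_us"] * 1e-6,
        sample_dt_plateau=sim["sample_dt_plateau_ms"] * 1e-3,
        circuit_dt_max=sim["circuit_dt_max_us"] * 1e-6,
        read_point=sim["read_point"],
    )
    meta = {"name": cfg["run"]["name"],
            "target_surface": cfg["run"]["target_surface"]}
    return plan, meta


def bundled_config_path(name: str) -> Path:
    """Path of a packaged demo configuration (slab_demo, duct_tandem, ...)."""
    p = Path(__file__).parent / "configs" / f"{name}.toml"
    if not p.exists():
        raise ValidationError(f"no bundled config named {name!r}")
    return p
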