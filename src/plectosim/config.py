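"""Configuration loading (TOML dialect) with validated defaults.

All defaults are in physical units at the boundary (nm, pN, K, Da) and are
converted to reduced units when an assembly is built.  Unknown keys and
inconsistent combinations (e.g. both a persistence length and an explicit
rigidity) are rejected with descriptive errors.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .dna_elasticity import ElasticParams
from .model_state import InvalidParameterError, make_unit_system
from .tweezers import Assembly, build_assembly, effective_radius

DEFAULTS: dict = {
    "units": {
        "b_nm": 3.4,
        "bp_per_cylinder": 10,
        "temperature_K": 300.0,
        "bp_mass_Da": 650.0,
    },
    "dna": {
        "persistence_length_nm": 50.0,
        "twist_persistence_length_nm": 95.0,
        "salt_mM": 100.0,
        "r_crystallographic_nm": 1.0,
        "g_b": None,   # explicit overrides (k_BT units)
        "g_t": None,
    },
    "chain": {
        "n_cylinders": 300,
        "bead": True,
        "bead_radius_nm": 34.0,
        "bead_mass": 4.0,
        "bead_inertia_radius": 2.0,
        "tangent_ends": True,
        "anchor": "weld",
    },
    "solver": {
        "erp": 0.8,
        "cfm": 1e-10,
        "sor_relaxation": 1.3,
        "sor_iterations": 60,
        "accept_tol": 1e-6,
        "force_direct": False,
    },
    "thermostat": {
        "mode": "global",
        "gamma": 10.0,
        "seed": 0,
    },
    "integrator": {
        "dt": 0.000592,
        "n_steps": 100_000,
        "output_stride": 100,
    },
    "collision": {
        "enabled": True,
        "cutoff_scale": 1.05,
    },
    "experiment": {
        "mode": "force_extension",
        "force_pN": [0.5],
        "turns": [0.0],
        "torque_kBT": [0.0],
        "equil_steps": 20_000,
        "sample_steps": 100_000,
        "ramp_rate": 0.05,
    },
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            out[key] = _merge_validate(dval, user.get(key, {}),
                                       f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    for key in user:
        if key not in defaults:
            raise InvalidParameterError(f"unknown config key: {path}{key}")
    return out


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[dict] = None) -> dict:
    """Load and validate a TOML config; missing keys take defaults.

    ``overrides`` (same nesting) wins over the file.  Cross-field checks:
    explicit rigidities conflict with persistence lengths; the turn ramp
    must stay below half a turn per step.
    """
    user: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    cfg = _merge_validate(DEFAULTS, user)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    dna = cfg["dna"]
    explicit = dna["g_b"] is not None or dna["g_t"] is not None
    in_file_lp = ("dna" in user and (
        "persistence_length_nm" in user["dna"]
        or "twist_persistence_length_nm" in user["dna"]))
    if explicit and in_file_lp:
        raise InvalidParameterError(
            "give either persistence lengths or explicit g_b/g_t, not both")
    ramp_turns_per_step = cfg["experiment"]["ramp_rate"] / 1000.0
    if ramp_turns_per_step >= 0.5:
        raise InvalidParameterError("ramp rate exceeds half a turn per step")
    for key in ("b_nm", "temperature_K", "bp_mass_Da"):
        if cfg["units"][key] <= 0:
            raise InvalidParameterError(f"units.{key} must be positive")
    return cfg


def assembly_from_config(cfg: dict, clamp: Optional[str] = None) -> Assembly:
    """Build the reduced-unit assembly described by a resolved config."""
    u = cfg["units"]
    units = make_unit_system(u["b_nm"], u["bp_per_cylinder"],
                             u["temperature_K"], u["bp_mass_Da"])
    dna = cfg["dna"]
    b_nm = u["b_nm"]
    if dna["g_b"] is not None or dna["g_t"] is not None:
        elastic = ElasticParams(g_b=dna["g_b"] or 0.0, g_t=dna["g_t"] or 0.0)
    else:
        elastic = ElasticParams.from_persistence_lengths(
            dna["persistence_length_nm"] / b_nm,
            dna["twist_persistence_length_nm"] / b_nm)
    r_eff_nm = effective_radius(dna["salt_mM"], dna["r_crystallographic_nm"])
    ch = cfg["chain"]
    return build_assembly(
        n_cyl=ch["n_cylinders"], radius=r_eff_nm / b_nm, elastic=elastic,
        bead=ch["bead"], bead_radius=ch["bead_radius_nm"] / b_nm,
        bead_mass=ch["bead_mass"],
        bead_inertia_radius=ch["bead_inertia_radius"],
        tangent_ends=ch["tangent_ends"], anchor=ch["anchor"], clamp=clamp,
        plane=cfg["collision"]["enabled"],
        collisions=cfg["collision"]["enabled"], units=units)


def dump_config(cfg: dict) -> str:
    """Serialize a resolved config back to TOML text (normalized order)."""
    lines = []
    for section, body in cfg.items():
        lines.append(f"[{section}]")
        for key, val in body.items():
            if val is None:
                continue
            if isinstance(val, bool):
                sval = "true" if val else "false"
            elif isinstance(val, str):
                sval = f'"{val}"'
            elif isinstance(val, list):
                sval = "[" + ", ".join(str(x) for x in val) + "]"
            else:
                sval = repr(val)
            lines.append(f"{key} = {sval}")
        lines.append("")
    return "\n".join(lines)
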