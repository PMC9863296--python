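"""YAML configuration: named coordinate maps, lineshape parameters, recipes.

Atom indices for the mechanism coordinates are supplied by configuration
rather than hardcoded, so the protocol applies to any switching unit with an
IR-active spectator mode, not only the azodicarboxamide numbering.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .coords import CoordinateSpec
from .lineshape import LineshapeParams
from .synth import ChirpProfile, ChirpSegment, CoordinateTarget, EnsembleRecipe

__all__ = ["load_coordinate_specs", "load_lineshape_params", "load_recipe"]


def load_coordinate_specs(path) -> dict[str, CoordinateSpec]:
    """Load named coordinates from YAML: ``name: {kind: dihedral, atoms: [i,j,k,l]}``."""
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, entry in data.items():
        out[name] = CoordinateSpec(name, entry["kind"], tuple(entry["atoms"]))
    return out


def load_lineshape_params(path) -> LineshapeParams:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("T1", "tau_max", "tau_step", "omega_step", "smooth_window"):
        if key in data:
            kwargs[key] = data[key]
    if "delta_t_grid" in data:
        kwargs["delta_t_grid"] = tuple(data["delta_t_grid"])
    if "omega_window" in data:
        kwargs["omega_window"] = tuple(data["omega_window"])
    return LineshapeParams(**kwargs)


def load_recipe(path) -> EnsembleRecipe:
    """Load an EnsembleRecipe from YAML."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("n_traj", "duration", "dt", "initial_state", "reference_omega", "freq_offset_sd", "seed", "with_energies"):
        if key in data:
            kwargs[key] = data[key]
    if "hop_schedule" in data:
        sched = {}
        for key, law in data["hop_schedule"].items():
            frm, to = (int(x) for x in str(key).split("-"))
            sched[(frm, to)] = tuple(law)
        kwargs["hop_schedule"] = sched
    if "excited_profile" in data:
        prof = data["excited_profile"]
        segments = [ChirpSegment(*seg) for seg in prof["segments"]]
        kwargs["excited_profile"] = ChirpProfile(
            segments,
            amplitude=prof.get("amplitude", 0.05),
            noise_sd=prof.get("noise_sd", 0.0),
        )
    if "coordinate_targets" in data:
        kwargs["coordinate_targets"] = [CoordinateTarget(**t) for t in data["coordinate_targets"]]
    return EnsembleRecipe(**kwargs)
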