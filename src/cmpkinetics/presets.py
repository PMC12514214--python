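"""Bundled parameter presets for the three experimental scenarios.

The JSON files under ``cmpkinetics/data`` carry the reference parameter
values for

* ``phase1_sgf_pepsin`` — two-step acid shrinkage in SGF (pH 2) with pepsin
  (relative-volume fit; v0 = 1);
* ``phase1_water_ph2`` — acid shrinkage in ultrapure water at pH 2, no
  pepsin (the second pulse sits at 540 s instead of 300 s);
* ``phase3_preacidified`` — pepsin decay of a particle pre-equilibrated in
  SGF at pH 2 (volumes in pL);
* ``system_sgf_pepsin`` — the full stock-and-flow configuration (fL units).
"""

from __future__ import annotations

import json
from importlib import resources

from .phases import Phase1Params, Phase3Params
from .systemdynamics import SystemModelConfig

__all__ = [
    "load_preset_dict",
    "phase1_sgf_pepsin",
    "phase1_water_ph2",
    "phase3_preacidified",
    "system_sgf_pepsin",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "phase1_sgf_pepsin",
    "phase1_water_ph2",
    "phase3_preacidified",
    "system_sgf_pepsin",
)


def load_preset_dict(name: str) -> dict:
    """Raw dict of a bundled preset file (see :data:`PRESET_NAMES`)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    ref = resources.files("cmpkinetics.data").joinpath(f"{name}.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def phase1_sgf_pepsin() -> Phase1Params:
    return Phase1Params.from_dict(load_preset_dict("phase1_sgf_pepsin"))


def phase1_water_ph2() -> Phase1Params:
    return Phase1Params.from_dict(load_preset_dict("phase1_water_ph2"))


def phase3_preacidified() -> Phase3Params:
    return Phase3Params.from_dict(load_preset_dict("phase3_preacidified"))


def system_sgf_pepsin() -> SystemModelConfig:
    return SystemModelConfig.from_dict(load_preset_dict("system_sgf_pepsin"))
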