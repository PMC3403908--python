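"""Density presets for the synthetic-panel generator.

Each preset is a YAML file of ``PanelSimConfig`` fields shipped with the
package.  They emulate the qualitative density ladder from sparse
genotyping arrays to deep whole-genome sequencing — sites per cM increases
and the MAF ascertainment floor drops down the ladder.  The specific
numbers are this package's own choices for desk-scale benchmarking, not
values taken from any study.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

from .simulate import PanelSimConfig

__all__ = ["available_presets", "load_preset", "preset_fields"]


def available_presets() -> list[str]:
    pkg = resources.files("ibdbench") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def preset_fields(name: str) -> dict:
    pkg = resources.files("ibdbench") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    fields = yaml.safe_load(text) or {}
    valid = {f.name for f in dataclasses.fields(PanelSimConfig)}
    unknown = set(fields) - valid
    if unknown:
        raise ValueError(f"preset {name!r} has unknown fields {sorted(unknown)}")
    return fields


def load_preset(name: str, **overrides) -> PanelSimConfig:
    """Build a :class:`PanelSimConfig` from a named preset plus overrides."""
    fields = preset_fields(name)
    fields.update(overrides)
    return PanelSimConfig(**fields)
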