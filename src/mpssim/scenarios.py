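"""Shipped scenario presets (YAML files under ``mpssim/presets``)."""

from __future__ import annotations

from importlib import resources
from typing import List

import yaml

from .config import ScenarioConfig


def preset_names() -> List[str]:
    root = resources.files("mpssim") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load one of the shipped scenarios by name (see :func:`preset_names`)."""
    path = resources.files("mpssim") / "presets" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no preset named {name!r}; available: {preset_names()}") from None
    return ScenarioConfig.model_validate(yaml.safe_load(text))
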