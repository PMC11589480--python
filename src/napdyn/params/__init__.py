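"""Packaged parameter fixtures.

Each fixture is a small JSON/YAML file with a one-line provenance note per
value.  Code refers to these by name so that measured constants (notably the
MpIAA turnover rate) are never hard-coded at call sites.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

import yaml


def _read_text(name: str) -> str:
    return resources.files(__package__).joinpath(name).read_text()


def load_mpiaa_decay() -> dict[str, Any]:
    """MpIAA-mScarlet-I turnover fixture (rate constant and half-life)."""
    return json.loads(_read_text("mpiaa_decay.json"))


def load_arf_shapes() -> dict[str, dict[str, float]]:
    """Per-ARF exponential-to-plateau decline shapes for the fold-change generator."""
    return yaml.safe_load(_read_text("arf_shapes.yaml"))


def load_nap_defaults() -> dict[str, Any]:
    """Default rate constants and affinities for the NAP competition model."""
    return json.loads(_read_text("nap_defaults.json"))
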