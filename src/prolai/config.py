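"""Run configuration: TOML key-value files over ModelConstants defaults.

An empty (or absent) config reproduces the default global
parameterisation; any subset of keys may be overridden. ``memory_days`` is
accepted as an alternative to ``alpha`` and mapped through α = 1/τ.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Optional, Tuple, Union

from .constants import ModelConstants
from .dynamics import alpha_from_memory_days

#: keys understood beyond the ModelConstants fields
EXTRA_KEYS = {"memory_days", "spin_up", "ai"}


def load_config(path: Optional[Union[str, Path]]) -> Tuple[ModelConstants,
                                                           dict]:
    """Parse a TOML config into (constants, extras).

    ``extras`` carries the non-constant keys (spin_up, ai) when present.
    Unknown keys raise; a missing path yields pure defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(ModelConstants)}
    unknown = set(raw) - known - EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "memory_days" in raw and "alpha" in raw:
        raise ValueError("give either alpha or memory_days, not both")
    extras = {k: raw.pop(k) for k in list(raw) if k in EXTRA_KEYS}
    if "memory_days" in extras:
        raw["alpha"] = alpha_from_memory_days(float(extras["memory_days"]))
    constants = ModelConstants(**raw)
    return constants, extras


def effective_config(constants: ModelConstants, extras: dict) -> dict:
    """Full effective configuration (defaults merged) for logging."""
    out = dataclasses.asdict(constants)
    out.update(extras)
    return out
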