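"""Packaged reference values: per-flavor cloud descriptors, sensory
lexicons, published region multipliers and default panel frequencies."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .cloud import CloudDescriptor2D

FLAVORS = ("jiang", "feng", "nong", "mild")


def _load(name: str) -> dict:
    with resources.files("cloudtongue.data").joinpath(name).open("r") as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def flavor_descriptors() -> dict[str, CloudDescriptor2D]:
    """Reference (Ex, En, He) per flavor, in PC-plane units."""
    raw = _load("table3_descriptors.json")
    return {
        flavor: CloudDescriptor2D.from_dict(d)
        for flavor, d in raw.items()
        if not flavor.startswith("_")
    }


@lru_cache(maxsize=None)
def lexicons() -> dict[str, tuple[str, ...]]:
    """Five taste-description words per flavor, ordered centre -> periphery."""
    raw = _load("lexicons.json")
    return {f: tuple(w) for f, w in raw.items() if not f.startswith("_")}


@lru_cache(maxsize=None)
def region_multipliers() -> dict[str, tuple[float, ...]]:
    """Published ellipse-boundary multipliers k1 < ... < k5 per flavor."""
    raw = _load("region_multipliers.json")
    return {f: tuple(k) for f, k in raw.items() if not f.startswith("_")}


@lru_cache(maxsize=None)
def panel_frequencies() -> dict[str, tuple[float, ...]]:
    """Default panel word-selection frequencies (%) aligned with lexicons()."""
    raw = _load("panel_defaults.json")
    return {f: tuple(v) for f, v in raw["frequencies_percent"].items()}


def panel_size() -> int:
    return int(_load("panel_defaults.json")["panel_size"])


def jiang_panel_counts() -> tuple[int, ...]:
    """The fully published jiang vote counts out of 40 panelists."""
    return tuple(_load("panel_defaults.json")["jiang_counts"])
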