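"""Word-frequency tables and nested elliptical regions in the PC plane.

Each flavor's five description words are ranked by the fraction of
panelists who chose them.  The most frequent word owns the central
ellipse of the flavor's cloud; each following word owns the annulus out
to the next quantile boundary.  Boundary multipliers come from the
standard-normal quantile of the cumulative word frequency: the i-th
boundary is at k_i entropies from the centre with

    k_i = Phi^-1(1/2 + cum_i / 200),    cum_i in percent,

and the outermost boundary is capped at 3 entropies, beyond which the
cloud's mass is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cloud import CloudDescriptor2D
from .errors import (
    DegenerateDataError,
    InvalidConfigError,
    InvalidValueError,
    RegionConstructionError,
)
from .preprocessing import PCPoint

__all__ = [
    "OUTSIDE",
    "WordFrequencyTable",
    "RegionSet",
    "sort_frequencies",
    "central_multiplier",
    "ring_multiplier",
    "build_region_set",
    "build_region_set_explicit",
    "locate",
]

#: Sentinel region index for points beyond the outer cap ellipse.
OUTSIDE = 0

DEFAULT_CAP = 3.0


@dataclass(frozen=True)
class WordFrequencyTable:
    """A flavor's sensory lexicon with panel vote counts."""

    flavor: str
    entries: tuple[tuple[str, int], ...]
    panel_size: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", tuple((str(w), int(c)) for w, c in self.entries)
        )
        if len(self.entries) != 5:
            raise InvalidConfigError(
                f"lexicon must have exactly 5 words, got {len(self.entries)}"
            )
        if self.panel_size < 1:
            raise InvalidConfigError("panel_size must be >= 1")
        counts = [c for _, c in self.entries]
        if any(c < 0 for c in counts):
            raise InvalidConfigError("counts must be non-negative")
        if sum(counts) != self.panel_size:
            raise InvalidConfigError(
                f"counts sum to {sum(counts)}, expected panel_size={self.panel_size}"
            )

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.entries)


def sort_frequencies(table: WordFrequencyTable) -> list[tuple[str, float]]:
    """(word, frequency%) pairs sorted descending; ties keep lexicon order."""
    freqs = [(w, 100.0 * c / table.panel_size) for w, c in table.entries]
    return sorted(freqs, key=lambda wf: -wf[1])  # sorted() is stable


def _quantile_multiplier(mass_percent: float, cap: float) -> float:
    if not 0.0 < mass_percent <= 100.0:
        raise InvalidValueError(
            f"central/cumulative mass must be in (0, 100], got {mass_percent}"
        )
    if mass_percent == 100.0:
        return float(cap)
    return float(norm.ppf(0.5 + mass_percent / 200.0))


def central_multiplier(n1: float, cap: float = DEFAULT_CAP) -> float:
    """Boundary multiplier k1 of the central ellipse holding n1% of votes."""
    return _quantile_multiplier(n1, cap)


def ring_multiplier(cumulative: float, cap: float = DEFAULT_CAP) -> float:
    """Boundary multiplier k_i at cumulative vote mass (percent)."""
    return _quantile_multiplier(cumulative, cap)


@dataclass(frozen=True)
class RegionSet:
    """Nested ellipse/annulus partition of the PC plane for one flavor.

    Region i is the ellipse of multiplier k_i minus the ellipse of
    multiplier k_{i-1}; region 1 is the full central ellipse, and the last
    multiplier is the hard outer cap.  Equal consecutive multipliers
    (arising from zero-frequency words) denote zero-width annuli whose
    word is retained but can never be selected.
    """

    center: tuple[float, float]
    scales: tuple[float, float]  # (En1, En2)
    multipliers: tuple[float, ...]
    words: tuple[str, ...]
    strict: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        object.__setattr__(self, "scales", tuple(float(v) for v in self.scales))
        object.__setattr__(self, "multipliers", tuple(float(k) for k in self.multipliers))
        object.__setattr__(self, "words", tuple(str(w) for w in self.words))
        if any(s <= 0 for s in self.scales):
            raise DegenerateDataError("region scales (entropies) must be positive")
        if len(self.words) != len(self.multipliers):
            raise RegionConstructionError("one word per multiplier required")
        if not self.multipliers or self.multipliers[0] <= 0:
            raise RegionConstructionError("multipliers must be positive")
        ks = np.asarray(self.multipliers)
        if self.strict:
            if not np.all(np.diff(ks) > 0):
                raise RegionConstructionError(
                    f"multipliers must be strictly increasing, got {self.multipliers}"
                )
        elif not np.all(np.diff(ks) >= 0):
            raise RegionConstructionError(
                f"multipliers must be non-decreasing, got {self.multipliers}"
            )

    @property
    def cap(self) -> float:
        return self.multipliers[-1]

    def semi_axes(self, i: int) -> tuple[float, float]:
        """Semi-axes (PC1, PC2) of the i-th boundary ellipse (1-based)."""
        k = self.multipliers[i - 1]
        return (k * self.scales[0], k * self.scales[1])

    def inequality_strings(self) -> list[str]:
        """Human-readable boundary inequalities, one per region."""
        cx, cy = self.center
        sx = f"(x{-cx:+.4f})^2"
        sy = f"(y{-cy:+.4f})^2"
        out = []
        for i in range(1, len(self.multipliers) + 1):
            a, b = self.semi_axes(i)
            inner = f"{sx}/{a:.4f}^2 + {sy}/{b:.4f}^2 <= 1"
            if i == 1:
                out.append(inner)
            else:
                pa, pb = self.semi_axes(i - 1)
                out.append(
                    f"{inner} and {sx}/{pa:.4f}^2 + {sy}/{pb:.4f}^2 > 1"
                )
        return out

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "scales": list(self.scales),
            "multipliers": list(self.multipliers),
            "words": list(self.words),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSet":
        return cls(
            tuple(d["center"]), tuple(d["scales"]),
            tuple(d["multipliers"]), tuple(d["words"]),
        )


def build_region_set(
    desc: CloudDescriptor2D,
    table: WordFrequencyTable,
    cap: float = DEFAULT_CAP,
) -> RegionSet:
    """Build the region set from vote frequencies via normal quantiles.

    Words are taken in frequency order; the boundary for the i-th word is
    the quantile multiplier of the cumulative frequency, with the last
    boundary forced to the cap.  Zero-frequency words yield zero-width
    annuli (tied multipliers) that can never be selected.
    """
    if desc.en[0] <= 0 or desc.en[1] <= 0:
        raise DegenerateDataError("region construction needs positive entropies")
    if cap <= 0:
        raise InvalidValueError("cap must be positive")
    sorted_freqs = sort_frequencies(table)
    words = [w for w, _ in sorted_freqs]
    cumulative = np.cumsum([f for _, f in sorted_freqs])
    multipliers = [
        min(ring_multiplier(c, cap), cap) for c in cumulative[:-1]
    ]
    multipliers.append(float(cap))
    if any(b < a for a, b in zip(multipliers, multipliers[1:])):
        raise RegionConstructionError(
            f"non-increasing multipliers from frequencies {sorted_freqs}"
        )
    return RegionSet(desc.ex, desc.en, tuple(multipliers), tuple(words))


def build_region_set_explicit(
    desc: CloudDescriptor2D,
    multipliers: Sequence[float],
    words: Sequence[str],
) -> RegionSet:
    """Build a region set from externally supplied boundary multipliers."""
    return RegionSet(
        desc.ex, desc.en, tuple(float(k) for k in multipliers),
        tuple(words), strict=True,
    )


def locate(regions: RegionSet, point: PCPoint | Sequence[float]) -> int:
    """Region index (1-based) of a PC-plane point; OUTSIDE beyond the cap.

    Returns the smallest i whose boundary ellipse contains the point;
    boundary points belong to the inner region.
    """
    x, y = float(point[0]), float(point[1])
    cx, cy = regions.center
    s1, s2 = regions.scales
    u = (x - cx) / s1
    v = (y - cy) / s2
    r = np.hypot(u, v)  # point is inside k-ellipse iff r <= k
    for i, k in enumerate(regions.multipliers, start=1):
        if r <= k:
            return i
    return OUTSIDE
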