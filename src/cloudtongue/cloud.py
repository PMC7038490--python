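"""Normal cloud model: digital characteristics, forward/backward generators,
and contribution-rate integrals.

A qualitative concept (here: the taste of one liquor flavor in the PC plane)
is represented by three digital characteristics per dimension:

* ``Ex`` — expected value, the centre of the concept;
* ``En`` — entropy, the spread/fuzziness scale;
* ``He`` — hyper-entropy, the uncertainty of ``En`` itself, which fattens
  the tails of the droplet distribution.

The *forward* generator draws cloud droplets (points with a certainty
degree mu) from ``(Ex, En, He)``; the *backward* generator estimates
``(Ex, En, He)`` from observed points via the sample mean, the first-order
absolute central moment and the sample variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidValueError,
)

__all__ = [
    "CloudDescriptor1D",
    "CloudDescriptor2D",
    "CloudDroplet",
    "DropletCloud",
    "backward_cloud_1d",
    "backward_cloud_2d",
    "forward_cloud_2d",
    "contribution_interval_1d",
    "total_contribution_2d",
]


@dataclass(frozen=True)
class CloudDescriptor1D:
    """Digital characteristics (Ex, En, He) of a 1-D normal cloud."""

    ex: float
    en: float
    he: float

    def __post_init__(self) -> None:
        for name in ("ex", "en", "he"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidValueError(f"{name} must be finite, got {v!r}")
        if self.en < 0:
            raise InvalidValueError(f"en must be >= 0, got {self.en}")
        if self.he < 0:
            raise InvalidValueError(f"he must be >= 0, got {self.he}")


@dataclass(frozen=True)
class CloudDescriptor2D:
    """A 2-D cloud descriptor: one :class:`CloudDescriptor1D` per PC axis."""

    dim1: CloudDescriptor1D
    dim2: CloudDescriptor1D

    @property
    def ex(self) -> tuple[float, float]:
        return (self.dim1.ex, self.dim2.ex)

    @property
    def en(self) -> tuple[float, float]:
        return (self.dim1.en, self.dim2.en)

    @property
    def he(self) -> tuple[float, float]:
        return (self.dim1.he, self.dim2.he)

    @classmethod
    def from_values(
        cls,
        ex: Sequence[float],
        en: Sequence[float],
        he: Sequence[float] = (0.0, 0.0),
    ) -> "CloudDescriptor2D":
        return cls(
            CloudDescriptor1D(float(ex[0]), float(en[0]), float(he[0])),
            CloudDescriptor1D(float(ex[1]), float(en[1]), float(he[1])),
        )

    def with_zero_he(self) -> "CloudDescriptor2D":
        """Copy of this descriptor with the hyper-entropy dropped."""
        return CloudDescriptor2D.from_values(self.ex, self.en)

    def to_dict(self) -> dict:
        return {
            "pc1": {"ex": self.dim1.ex, "en": self.dim1.en, "he": self.dim1.he},
            "pc2": {"ex": self.dim2.ex, "en": self.dim2.en, "he": self.dim2.he},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloudDescriptor2D":
        return cls(
            CloudDescriptor1D(**{k: float(v) for k, v in d["pc1"].items()}),
            CloudDescriptor1D(**{k: float(v) for k, v in d["pc2"].items()}),
        )


@dataclass(frozen=True)
class CloudDroplet:
    """One 2-D cloud droplet: coordinates plus certainty degree mu in (0, 1]."""

    x1: float
    x2: float
    mu: float


class DropletCloud:
    """A batch of 2-D cloud droplets stored as flat arrays.

    Behaves as a sequence of :class:`CloudDroplet`; the vectorised views
    ``x1``, ``x2``, ``mu`` and ``points`` (an ``(n, 2)`` array) are what the
    numeric pipeline consumes.
    """

    def __init__(self, x1: np.ndarray, x2: np.ndarray, mu: np.ndarray):
        self.x1 = np.asarray(x1, dtype=float)
        self.x2 = np.asarray(x2, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        if not (self.x1.shape == self.x2.shape == self.mu.shape):
            raise InvalidValueError("x1, x2, mu must have identical shapes")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x1, self.x2])

    def __len__(self) -> int:
        return self.x1.size

    def __getitem__(self, i: int) -> CloudDroplet:
        return CloudDroplet(float(self.x1[i]), float(self.x2[i]), float(self.mu[i]))

    def __iter__(self) -> Iterator[CloudDroplet]:
        for i in range(len(self)):
            yield self[i]


def backward_cloud_1d(values: Sequence[float]) -> CloudDescriptor1D:
    """Estimate (Ex, En, He) from a 1-D sample.

    Ex is the sample mean; En is sqrt(pi/2) times the mean absolute
    deviation from the mean; He is sqrt(S^2 - En^2) with S^2 the n-1
    sample variance.  When S^2 < En^2 (possible on finite samples) He is
    clamped to 0 with a warning rather than failing, which keeps the
    pipeline total.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError(
            f"backward cloud needs >= 2 values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidValueError("backward cloud input contains non-finite values")
    ex = float(x.mean())
    d = float(np.abs(x - ex).mean())
    en = float(np.sqrt(np.pi / 2.0) * d)
    s2 = float(x.var(ddof=1))
    gap = s2 - en * en
    if gap < 0.0:
        if en > 0.0:
            warnings.warn(
                "sample variance below En^2; clamping He to 0",
                RuntimeWarning,
                stacklevel=2,
            )
        he = 0.0
    else:
        he = float(np.sqrt(gap))
    return CloudDescriptor1D(ex, en, he)


def backward_cloud_2d(points: np.ndarray) -> CloudDescriptor2D:
    """Apply :func:`backward_cloud_1d` to each column of an ``(n, 2)`` array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidValueError(f"expected (n, 2) points, got shape {pts.shape}")
    return CloudDescriptor2D(
        backward_cloud_1d(pts[:, 0]), backward_cloud_1d(pts[:, 1])
    )


def _sample_entropy(
    en: float, he: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-droplet entropies En' ~ N(en, he^2), conditioned positive.

    Negative draws are resampled (not folded), preserving the normal law
    conditioned on En' > 0.  With he = 0 every droplet uses en exactly.
    """
    if he == 0.0:
        return np.full(n, en, dtype=float)
    enp = rng.normal(en, he, size=n)
    bad = enp <= 0.0
    while bad.any():
        enp[bad] = rng.normal(en, he, size=int(bad.sum()))
        bad = enp <= 0.0
    return enp


def forward_cloud_2d(
    desc: CloudDescriptor2D,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> DropletCloud:
    """Generate ``n`` 2-D cloud droplets from a descriptor.

    Per droplet and per dimension i: draw En'_i ~ N(en_i, he_i^2)
    (conditioned positive), then x_i ~ N(ex_i, En'_i^2).  The certainty
    degree is mu = exp(-sum_i (x_i - ex_i)^2 / (2 En'_i^2)); a dimension
    with en = he = 0 pins x_i at ex_i and contributes 0 to the exponent.
    """
    if n < 1:
        raise InvalidValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exponent = np.zeros(n, dtype=float)
    coords = []
    for d in (desc.dim1, desc.dim2):
        enp = _sample_entropy(d.en, d.he, n, rng)
        live = enp > 0.0
        x = np.full(n, d.ex, dtype=float)
        x[live] = rng.normal(d.ex, enp[live])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(live, (x - d.ex) ** 2 / (2.0 * enp**2), 0.0)
        exponent += term
        coords.append(x)
    mu = np.exp(-exponent)
    return DropletCloud(coords[0], coords[1], mu)


def contribution_interval_1d(
    desc: CloudDescriptor1D, a: float, b: float
) -> float:
    """Contribution of the interval [a, b] to the qualitative concept.

    Numerically integrates the 1-D contribution density — a Gaussian with
    standard deviation En centred at Ex (He does not enter the density;
    it acts only through droplet sampling).  Infinite bounds are allowed.
    """
    if desc.en <= 0.0:
        raise DegenerateDataError("contribution density undefined for en = 0")
    if a > b:
        raise InvalidValueError(f"need a <= b, got a={a}, b={b}")

    def density(x: float) -> float:
        return norm.pdf(x, loc=desc.ex, scale=desc.en)

    val, _ = integrate.quad(density, a, b, epsabs=1e-12, epsrel=1e-12)
    return float(val)


def total_contribution_2d(desc: CloudDescriptor2D, box_half_width: float = 8.0) -> float:
    """Total contribution rate C: the double integral of the 2-D cloud
    contribution density over the PC plane.

    Integrates numerically over a box of ``box_half_width`` entropies per
    dimension; for a normal density this captures all mass to well below
    1e-6, so the result is 1 within numerical tolerance.
    """
    en1, en2 = desc.en
    if en1 <= 0.0 or en2 <= 0.0:
        raise DegenerateDataError("total contribution undefined for zero entropy")
    ex1, ex2 = desc.ex

    def integrand(y: float, x: float) -> float:
        z = ((x - ex1) ** 2 / en1**2 + (y - ex2) ** 2 / en2**2) / 2.0
        return np.exp(-z) / (2.0 * np.pi * en1 * en2)

    val, _ = integrate.dblquad(
        integrand,
        ex1 - box_half_width * en1,
        ex1 + box_half_width * en1,
        lambda x: ex2 - box_half_width * en2,
        lambda x: ex2 + box_half_width * en2,
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return float(val)
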