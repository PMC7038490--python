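"""Seeded synthetic electronic-tongue data and sensory-panel votes.

No public e-tongue dataset exists for the four liquor flavors, so the
generator works backwards from the published latent structure: each
flavor's samples are drawn in the 2-D PC plane by the forward cloud law
of that flavor's descriptor, embedded into the 10 sensor channels with a
fixed random orthonormal loading, offset to plausible steady-state
potentials (mV), and perturbed by isotropic residual noise confined to
the 8 non-informative directions.  Pooled PCA on the result therefore
reproduces the reported variance profile by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import fixtures
from .cloud import CloudDescriptor2D, forward_cloud_2d
from .errors import InvalidConfigError
from .regions import WordFrequencyTable

__all__ = [
    "DEFAULT_RESIDUAL_SD",
    "SyntheticConfig",
    "PanelConfig",
    "generate_taste_dataset",
    "generate_panel_votes",
    "default_config",
    "default_panel_configs",
    "channel_loading",
]

#: Residual noise sd (mV) in the 8 non-informative channel directions.
#: Calibrated once, analytically, so that the expected pooled-PCA
#: cumulative two-component contribution equals 0.9825:
#: 8*sd^2 = tr(C_latent) * (1/0.9825 - 1), with C_latent the mixture
#: covariance implied by the reference flavor descriptors.
DEFAULT_RESIDUAL_SD = 1.3708

#: Fixed per-channel offsets (mV) so features resemble steady-state
#: potentials; arbitrary, and irrelevant after centering.
CHANNEL_OFFSETS = np.array(
    [12.0, -35.0, 48.0, 120.0, -8.0, 22.0, -60.0, 75.0, 5.0, -110.0]
)

CHANNEL_NAMES = tuple(f"ch{i:02d}" for i in range(1, 11))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative law for the synthetic e-tongue dataset."""

    per_flavor_descriptors: Mapping[str, CloudDescriptor2D]
    loading_seed: int = 20
    residual_sd: float = DEFAULT_RESIDUAL_SD
    samples_per_flavor: int = 20
    n_channels: int = 10

    def __post_init__(self) -> None:
        if not self.per_flavor_descriptors:
            raise InvalidConfigError("per_flavor_descriptors must be non-empty")
        if self.samples_per_flavor < 1:
            raise InvalidConfigError("samples_per_flavor must be positive")
        if self.residual_sd < 0:
            raise InvalidConfigError("residual_sd must be >= 0")
        if self.n_channels < 3:
            raise InvalidConfigError("n_channels must leave room for 2 latent axes")

    @property
    def flavors(self) -> tuple[str, ...]:
        return tuple(self.per_flavor_descriptors)


@dataclass(frozen=True)
class PanelConfig:
    """Word-selection law of one flavor's 40-member sensory panel."""

    flavor: str
    words: tuple[str, ...]
    probabilities: tuple[float, ...]
    panel_size: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", tuple(self.words))
        object.__setattr__(
            self, "probabilities", tuple(float(p) for p in self.probabilities)
        )
        if len(self.words) != 5 or len(self.probabilities) != 5:
            raise InvalidConfigError("exactly 5 words and 5 probabilities required")
        if any(p < 0 for p in self.probabilities):
            raise InvalidConfigError("probabilities must be non-negative")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise InvalidConfigError(
                f"probabilities sum to {sum(self.probabilities)!r}, expected 1"
            )
        if self.panel_size < 1:
            raise InvalidConfigError("panel_size must be >= 1")


def channel_loading(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seeded orthonormal channel basis: (loading, complement).

    ``loading`` is the n_channels x 2 embedding of the latent PC plane;
    ``complement`` spans the remaining non-informative directions.
    """
    rng = np.random.default_rng(config.loading_seed)
    g = rng.standard_normal((config.n_channels, config.n_channels))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
    return q[:, :2], q[:, 2:]


def generate_taste_dataset(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Generate the labelled feature table (one row per sample).

    Columns: ``sample_id``, ``flavor``, ``ch01``..``chNN``.  Deterministic
    given ``(config, seed)``; flavors are generated in mapping order with
    independent child seed streams.
    """
    loading, complement = channel_loading(config)
    offsets = (
        CHANNEL_OFFSETS
        if config.n_channels == CHANNEL_OFFSETS.size
        else np.zeros(config.n_channels)
    )
    children = np.random.SeedSequence(seed).spawn(len(config.flavors))
    rows, ids, labels = [], [], []
    for flavor, child in zip(config.flavors, children):
        desc = config.per_flavor_descriptors[flavor]
        rng = np.random.default_rng(child)
        latent = forward_cloud_2d(desc, config.samples_per_flavor, rng).points
        noise = rng.normal(
            0.0,
            config.residual_sd,
            size=(config.samples_per_flavor, complement.shape[1]),
        ) if config.residual_sd > 0 else np.zeros(
            (config.samples_per_flavor, complement.shape[1])
        )
        channels = latent @ loading.T + noise @ complement.T + offsets
        rows.append(channels)
        ids.extend(f"{flavor}-{i + 1:02d}" for i in range(config.samples_per_flavor))
        labels.extend([flavor] * config.samples_per_flavor)
    data = pd.DataFrame(np.vstack(rows), columns=list(CHANNEL_NAMES[: config.n_channels]))
    data.insert(0, "flavor", labels)
    data.insert(0, "sample_id", ids)
    return data


def generate_panel_votes(config: PanelConfig, seed: int) -> WordFrequencyTable:
    """Draw one panel's vote counts (multinomial over the 5 words)."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(config.panel_size, config.probabilities)
    return WordFrequencyTable(
        flavor=config.flavor,
        entries=tuple(zip(config.words, (int(c) for c in counts))),
        panel_size=config.panel_size,
    )


def default_config(**overrides) -> SyntheticConfig:
    """Default generator: 4 flavors x 20 replicates, reference descriptors."""
    params = dict(per_flavor_descriptors=dict(fixtures.flavor_descriptors()))
    params.update(overrides)
    return SyntheticConfig(**params)


def default_panel_configs() -> dict[str, PanelConfig]:
    """Default panel laws from the packaged word frequencies."""
    size = fixtures.panel_size()
    return {
        flavor: PanelConfig(
            flavor=flavor,
            words=fixtures.lexicons()[flavor],
            probabilities=tuple(f / 100.0 for f in freqs),
            panel_size=size,
        )
        for flavor, freqs in fixtures.panel_frequencies().items()
    }
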