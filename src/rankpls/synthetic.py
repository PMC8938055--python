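"""Synthetic ranked-data generation.

Two presets are provided, both built on a latent-Gaussian threshold model:
block-exchangeable correlated Gaussian latents are discretized column-wise
into ordinal codes by equal-probability quantile thresholds, and the latent
response is a linear combination of the informative latent columns plus
Gaussian noise, discretized into K ranks.

* :func:`generate_simulation_data` — the large simulation design: n = 1000,
  p = 100, fifty 3-level and fifty 4-level predictors, a 3-level response,
  correlated blocks of 10.
* :func:`generate_anc_like_data` — an antenatal-care-like design: n = 943,
  p = 43 with one strongly inter-correlated block of 16 covariates, mixed
  2-5 level predictors, and a skewed 3-level response labelled
  inadequate / intermediate / adequate.

Every generated dataset is accompanied by a :class:`TruthRecord` naming the
informative columns, so recovery of planted signal is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import RankedDataset, read_dataset, write_dataset
from .exceptions import ConfigError

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_simulation_data",
    "generate_anc_like_data",
    "read_dataset",
    "write_dataset",
]

ANC_LEVEL_LABELS = ("inadequate", "intermediate", "adequate")


@dataclass
class SimulationConfig:
    """Knobs of the latent-Gaussian ordinal generator.

    ``block_corr`` may be a single value for all blocks or one value per
    block; ``response_probs=None`` means equal-probability response ranks.
    """

    n: int = 1000
    p: int = 100
    levels_per_predictor: Sequence[int] = field(
        default_factory=lambda: (3,) * 50 + (4,) * 50
    )
    response_levels: int = 3
    n_informative: int = 10
    effect_size: float = 0.5
    block_corr: float | Sequence[float] = 0.5
    block_sizes: Sequence[int] = field(default_factory=lambda: (10,) * 10)
    noise_sd: float = 1.0
    response_probs: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.levels_per_predictor = tuple(int(v) for v in self.levels_per_predictor)
        self.block_sizes = tuple(int(v) for v in self.block_sizes)
        if sum(self.block_sizes) != self.p:
            raise ConfigError("block_sizes must sum to p")
        if len(self.levels_per_predictor) != self.p:
            raise ConfigError("levels_per_predictor must have length p")
        if any(v < 2 for v in self.levels_per_predictor):
            raise ConfigError("every predictor needs >= 2 levels")
        if self.response_levels < 2:
            raise ConfigError("response needs >= 2 levels")
        if not 0 <= self.n_informative <= self.p:
            raise ConfigError("n_informative outside 0..p")
        corrs = self.corr_per_block
        if any(not 0 <= r < 1 for r in corrs):
            raise ConfigError("block_corr must lie in [0, 1)")
        if self.response_probs is not None:
            probs = tuple(float(q) for q in self.response_probs)
            if len(probs) != self.response_levels or abs(sum(probs) - 1) > 1e-9:
                raise ConfigError("response_probs must be K probabilities summing to 1")
            self.response_probs = probs

    @property
    def corr_per_block(self) -> tuple[float, ...]:
        if np.isscalar(self.block_corr):
            return (float(self.block_corr),) * len(self.block_sizes)
        corrs = tuple(float(r) for r in self.block_corr)
        if len(corrs) != len(self.block_sizes):
            raise ConfigError("block_corr must be scalar or one value per block")
        return corrs

    def to_dict(self) -> dict:
        return {
            "n": self.n, "p": self.p,
            "levels_per_predictor": list(self.levels_per_predictor),
            "response_levels": self.response_levels,
            "n_informative": self.n_informative,
            "effect_size": self.effect_size,
            "block_corr": (self.block_corr if np.isscalar(self.block_corr)
                           else list(self.block_corr)),
            "block_sizes": list(self.block_sizes),
            "noise_sd": self.noise_sd,
            "response_probs": (None if self.response_probs is None
                               else list(self.response_probs)),
            "seed": self.seed,
        }


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset, for recovery tests."""

    informative: tuple[int, ...]
    effect_size: float
    noise_sd: float
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "informative": list(self.informative),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            informative=tuple(int(j) for j in d["informative"]),
            effect_size=float(d["effect_size"]),
            noise_sd=float(d["noise_sd"]),
            seed=int(d["seed"]),
        )


def _discretize(v: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Threshold a continuous vector into codes 1..K at empirical quantiles."""
    edges = np.quantile(v, np.cumsum(probs)[:-1])
    return (np.searchsorted(edges, v, side="left") + 1).astype(int)


def _latent_matrix(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-exchangeable correlated standard-normal latents."""
    cols = []
    for size, rho in zip(config.block_sizes, config.corr_per_block):
        shared = rng.standard_normal((config.n, 1))
        noise = rng.standard_normal((config.n, size))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise)
    return np.hstack(cols)


def generate_simulation_data(
    config: SimulationConfig | None = None,
) -> tuple[RankedDataset, TruthRecord]:
    """Generate an ordinal dataset from the latent-Gaussian threshold model.

    Returns the dataset plus a :class:`TruthRecord` naming the informative
    columns (by convention the first ``n_informative`` latents).
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    X = _latent_matrix(config, rng)

    eta = config.effect_size * X[:, : config.n_informative].sum(axis=1)
    eta = eta + config.noise_sd * rng.standard_normal(config.n)

    Z = np.empty((config.n, config.p))
    for j, L in enumerate(config.levels_per_predictor):
        Z[:, j] = _discretize(X[:, j], np.full(L, 1.0 / L))

    if config.response_probs is None:
        probs = np.full(config.response_levels, 1.0 / config.response_levels)
    else:
        probs = np.asarray(config.response_probs)
    y = _discretize(eta, probs)

    data = RankedDataset(Z=Z, y=y)
    truth = TruthRecord(
        informative=tuple(range(config.n_informative)),
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return data, truth


def anc_like_config(seed: int = 0) -> SimulationConfig:
    """The antenatal-care-like design: 943 x 43, one tight 16-covariate block."""
    block_sizes = (16, 9, 9, 9)
    block_corr = (0.8, 0.3, 0.3, 0.3)
    # mixed ordinal granularity, 2-5 levels, in a fixed repeating pattern
    pattern = (3, 4, 2, 5, 3, 4, 3, 5, 2, 4)
    levels = tuple(pattern[j % len(pattern)] for j in range(43))
    return SimulationConfig(
        n=943,
        p=43,
        levels_per_predictor=levels,
        response_levels=3,
        n_informative=10,
        effect_size=0.5,
        block_corr=block_corr,
        block_sizes=block_sizes,
        noise_sd=1.0,
        response_probs=(0.12, 0.36, 0.52),
        seed=seed,
    )


def generate_anc_like_data(seed: int = 0) -> tuple[RankedDataset, TruthRecord]:
    """Generate the antenatal-care-like multicollinear dataset.

    n = 943 women, 43 ordinal factors with a strongly correlated block of 16,
    and a skewed 3-rank response labelled inadequate / intermediate / adequate
    (mirroring visit-frequency ranks 0-3 / 4-7 / 8-9).
    """
    data, truth = generate_simulation_data(anc_like_config(seed))
    data.level_labels = list(ANC_LEVEL_LABELS)
    return data, truth
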