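"""Configuration objects for the simulation/analysis pipeline.

All randomness in the package flows from a single master seed through
:class:`numpy.random.SeedSequence` substreams, so that a configuration plus a
seed pins down every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a configuration object fails validation."""


#: Logistic scaling constant shared by generation and estimation.
DEFAULT_D = 1.0

#: The ten item pairs that receive injected local dependence by default.
DEFAULT_DEPENDENCE_PAIRS: tuple[tuple[int, int], ...] = (
    (70, 71), (38, 49), (1, 19), (59, 69), (5, 19),
    (12, 30), (13, 28), (50, 70), (8, 29), (13, 46),
)

_SQRT3 = math.sqrt(3.0)


@dataclass
class GeneratorConfig:
    """Settings for the synthetic three-category response generator.

    The defaults emulate a 300-case, 71-item rating study: latent ability
    increases with case ID, item difficulty increases with item ID, item
    discriminations average 2.93, category thresholds sit 0.44 below/above
    each item's difficulty midpoint, and ten designated item pairs carry
    injected local dependence through a Gaussian copula.
    """

    n_cases: int = 300
    n_items: int = 71
    n_categories: int = 3
    #: 'quantile' — deterministic standard-normal quantiles Φ⁻¹((i−½)/n)
    #: (default); 'uniform' — equally spaced grid on ``ability_bounds``
    #: (sd ≈ 1 with the default bounds ±√3); 'sampled' — sorted draws.
    ability_scheme: str = "quantile"
    ability_bounds: tuple[float, float] = (-_SQRT3, _SQRT3)
    difficulty_range: tuple[float, float] = (-1.3, 1.3)
    threshold_half_spread: float = 0.44
    discrimination_dist: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 2.43, "high": 3.43}
    )
    dependence_pairs: tuple[tuple[int, int], ...] = DEFAULT_DEPENDENCE_PAIRS
    dependence_rho: float = 0.8
    D: float = DEFAULT_D
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_items <= 0:
            raise ConfigError("n_cases and n_items must be positive")
        if self.n_categories != 3:
            raise ConfigError("only three-category responses are supported")
        if self.ability_scheme not in ("uniform", "quantile", "sampled"):
            raise ConfigError(f"unknown ability_scheme {self.ability_scheme!r}")
        lo, hi = self.difficulty_range
        if not lo < hi:
            raise ConfigError("difficulty_range must be increasing")
        if self.threshold_half_spread <= 0:
            raise ConfigError("threshold_half_spread must be positive")
        if not 0.0 <= self.dependence_rho < 1.0:
            raise ConfigError("dependence_rho must lie in [0, 1)")
        if not isinstance(self.discrimination_dist, dict) or "name" not in self.discrimination_dist:
            raise ConfigError("discrimination_dist must be a dict with a 'name'")
        self.dependence_pairs = tuple(
            (int(j), int(k)) for j, k in self.dependence_pairs
        )
        seen = set()
        for j, k in self.dependence_pairs:
            if j == k:
                raise ConfigError(f"dependence pair ({j},{k}) couples an item with itself")
            if not (1 <= j <= self.n_items and 1 <= k <= self.n_items):
                raise ConfigError(f"dependence pair ({j},{k}) references an invalid item ID")
            key = frozenset((j, k))
            if key in seen:
                raise ConfigError(f"dependence pair ({j},{k}) listed more than once")
            seen.add(key)


@dataclass
class ModelSpec:
    """Estimation settings for the graded response model."""

    model: str = "2pl"
    D: float = DEFAULT_D
    n_quadrature: int = 101
    quadrature_bounds: tuple[float, float] = (-5.0, 5.0)
    max_em_iterations: int = 500
    em_tolerance: float = 1e-5

    def __post_init__(self) -> None:
        if self.model not in ("1pl", "2pl"):
            raise ConfigError(f"unknown model {self.model!r} (expected '1pl' or '2pl')")
        if self.n_quadrature < 11:
            raise ConfigError("n_quadrature must be at least 11")
        lo, hi = self.quadrature_bounds
        if not math.isclose(lo, -hi):
            raise ConfigError("quadrature_bounds must be symmetric about 0")
        if self.D <= 0:
            raise ConfigError("D must be positive")


@dataclass
class PipelineConfig:
    """Top-level configuration for the end-to-end study pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    q3_threshold: float = 0.2
    strategies: tuple[str, ...] = ("max_cat1_prob", "item_information", "discrimination")
    top_k: int = 7
    parallel_reps: int = 100
    output_dir: str = "grmsim_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.q3_threshold < 1:
            raise ConfigError("q3_threshold must be in (0, 1)")
        if self.top_k <= 0:
            raise ConfigError("top_k must be positive")


def _as_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {k: _as_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_dict(v) for v in obj]  # type: ignore[return-value]
    if isinstance(obj, list):
        return [_as_dict(v) for v in obj]  # type: ignore[return-value]
    return obj


def config_to_json(config) -> str:
    """Serialize any config dataclass to canonical JSON."""
    return json.dumps(_as_dict(config), sort_keys=True, indent=2)


def config_hash(config) -> str:
    """Stable SHA-256 fingerprint of a configuration (provenance).

    Bookkeeping fields (output location, log level) are excluded so the hash
    identifies the scientific configuration, not where it ran.
    """
    d = _as_dict(config)
    d.pop("output_dir", None)
    d.pop("log_level", None)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _tupled(value):
    if isinstance(value, list):
        return tuple(_tupled(v) for v in value)
    return value


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    return GeneratorConfig(**{k: _tupled(v) for k, v in d.items()})


def model_spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(**{k: _tupled(v) for k, v in d.items()})


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    gen = d.pop("generator", {})
    model = d.pop("model", {})
    return PipelineConfig(
        generator=generator_config_from_dict(gen) if not isinstance(gen, GeneratorConfig) else gen,
        model=model_spec_from_dict(model) if not isinstance(model, ModelSpec) else model,
        **{k: _tupled(v) for k, v in d.items()},
    )


def pipeline_config_from_json(path_or_text: str) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON file path or JSON text."""
    text = path_or_text
    if not path_or_text.lstrip().startswith("{"):
        with open(path_or_text, "r", encoding="utf-8") as fh:
            text = fh.read()
    return pipeline_config_from_dict(json.loads(text))
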