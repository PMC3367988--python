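"""Run configuration: taxon parameters, crop geometry, pipeline defaults.

Coordinates are 0-based throughout, with ``x`` the pixel column and ``y`` the
pixel row.  Crop regions are half-open rectangles ``(x, y, width, height)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import yaml

#: Reserved class name for sediment/background samples.
BACKGROUND = "background"


class ConfigurationError(ValueError):
    """Raised when a label refers to an unknown taxon or a parameter is invalid."""


@dataclass(frozen=True)
class TaxonConfig:
    """Per-taxon geometric and detection parameters.

    Parameters
    ----------
    name:
        Taxon name (must match the label tables).
    d_taxon:
        Maximum pairwise distance (pixels) for two same-taxon expert labels to
        be considered marks of the same individual (clique fusion).
    match_distance:
        Maximum distance (pixels) for matching a detection centroid (or a
        second observer's label) to a gold-standard position.
    theta:
        Confidence threshold in [0, 1] used to binarize this taxon's
        confidence map.
    s_min:
        Minimum connected-blob size (pixels) for a detection to be emitted.
    """

    name: str
    d_taxon: float = 20.0
    match_distance: float = 20.0
    theta: float = 0.5
    s_min: int = 10

    def __post_init__(self) -> None:
        if self.d_taxon <= 0 or self.match_distance <= 0:
            raise ConfigurationError(
                f"taxon {self.name!r}: distances must be > 0"
            )
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError(
                f"taxon {self.name!r}: theta must lie in [0, 1]"
            )
        if self.s_min < 1:
            raise ConfigurationError(f"taxon {self.name!r}: s_min must be >= 1")


class TaxonSet:
    """Ordered collection of :class:`TaxonConfig`, keyed by name."""

    def __init__(self, configs: Iterable[TaxonConfig]):
        self._configs: dict[str, TaxonConfig] = {}
        for cfg in configs:
            if cfg.name in self._configs:
                raise ConfigurationError(f"duplicate taxon {cfg.name!r}")
            self._configs[cfg.name] = cfg

    def __getitem__(self, name: str) -> TaxonConfig:
        try:
            return self._configs[name]
        except KeyError:
            raise ConfigurationError(f"unknown taxon {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._configs

    def __iter__(self):
        return iter(self._configs.values())

    def __len__(self) -> int:
        return len(self._configs)

    @property
    def names(self) -> list[str]:
        return list(self._configs)

    def taxa(self, include_background: bool = True) -> list[str]:
        names = self.names
        if not include_background:
            names = [n for n in names if n != BACKGROUND]
        return names

    @classmethod
    def uniform(
        cls,
        names: Iterable[str],
        *,
        d_taxon: float = 20.0,
        match_distance: float = 20.0,
        theta: float = 0.5,
        s_min: int = 10,
    ) -> "TaxonSet":
        return cls(
            TaxonConfig(n, d_taxon=d_taxon, match_distance=match_distance,
                        theta=theta, s_min=s_min)
            for n in names
        )


@dataclass
class RunConfig:
    """Top-level pipeline configuration (see the YAML config format)."""

    taxa: list[dict] = field(default_factory=list)
    # field-of-view crop (x, y, width, height); the study geometry
    crop: tuple[int, int, int, int] = (1800, 300, 1500, 1800)
    # pre-processing
    kernel_size: int = 701
    peak_fraction: float = 0.5
    anchors: tuple[float, float, float] = (0.1, 0.5, 0.9)
    grayscale: str = "mean"  # or "rec601"
    # training
    k_min: int = 3
    boost_offset: int = 2
    background_per_image: int = 68
    background_min_distance: float = 40.0
    c_grid: list[float] = field(default_factory=lambda: [10.0 ** e for e in range(-3, 4)])
    gamma_grid: list[float] = field(default_factory=lambda: [10.0 ** e for e in range(-4, 3)])
    cv_folds: int = 4
    # detection
    theta_bg: float = 0.5
    stride: int = 1
    margin: int = 5
    # evaluation
    seed: int = 0

    def taxon_set(self) -> TaxonSet:
        return TaxonSet(TaxonConfig(**t) for t in self.taxa)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("crop", "anchors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def taxon_set_from_mapping(mapping: Mapping[str, Mapping]) -> TaxonSet:
    """Build a :class:`TaxonSet` from ``{name: {param: value}}``."""
    return TaxonSet(TaxonConfig(name=n, **dict(p)) for n, p in mapping.items())
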