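"""Run configuration shared by the command-line subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline thresholds and design parameters.

    All cut-offs live here so a run is fully described by one YAML file:
    tile geometry (``tile_k``, ``offset``), reactivity calling (``z_cut``,
    ``overlap_min``), induction detection (``z_low``, ``fold_min``),
    residue attribution (``effect_cut``), the alignment window used for
    allergen-level profile comparison, clustering choices, and the
    simulation seed.
    """

    tile_k: int = 16
    offset: int = 1
    z_cut: float = 3.0
    z_low: float = 1.0
    fold_min: float = 2.0
    overlap_min: int = 8
    effect_cut: float = 2.0
    pca_range: tuple[int, int] = (9, 95)
    distance: str = "euclidean"
    linkage: str = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        self.pca_range = tuple(self.pca_range)  # type: ignore[assignment]
        for name in ("tile_k", "offset", "overlap_min"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("z_cut", "z_low", "fold_min", "effect_cut"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.z_low >= self.z_cut:
            raise ConfigError("z_low must be below z_cut")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pca_range"] = list(self.pca_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
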