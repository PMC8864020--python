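"""Scenario-grid configuration: YAML loading, validation, defaults.

The default configuration is the full study grid: 50 parents in single-pair
mating, family sizes 80/160, clonal sizes N_R 1/6/12, marker densities
1/5/10 SNPs per cM on 2 x 120 cM chromosomes, 200 standard-Normal QTL at
h2 = 0.2, orchard sizes Ne 5/10/20/25, and 200 stochastic iterations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["GridConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class GridConfig:
    n_parents: int = 50
    family_sizes: tuple[int, ...] = (80, 160)
    n_ramets: tuple[int, ...] = (1, 6, 12)
    marker_densities: tuple[float, ...] = (1.0, 5.0, 10.0)
    ne_targets: tuple[int, ...] = (5, 10, 20, 25)
    n_chrom: int = 2
    chrom_length: float = 120.0
    n_qtl: int = 200
    h2: float = 0.2
    freq_min: float = 0.1
    freq_max: float = 0.9
    ld_decay_rate: float | None = None  # None = linkage-equilibrium founders
    qtl_on_markers: bool = False
    n_iterations: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        _positive = {
            "n_parents": self.n_parents,
            "n_chrom": self.n_chrom,
            "chrom_length": self.chrom_length,
            "n_qtl": self.n_qtl,
        }
        for key, val in _positive.items():
            if val <= 0:
                raise ValueError(f"config key '{key}' must be positive (got {val})")
        if self.ld_decay_rate is not None and self.ld_decay_rate <= 0:
            raise ValueError("config key 'ld_decay_rate' must be positive or null")
        if self.n_parents % 2:
            raise ValueError("config key 'n_parents' must be even (single-pair mating)")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("config key 'h2' must lie strictly between 0 and 1")
        if not (0.0 < self.freq_min < self.freq_max < 1.0):
            raise ValueError("config keys 'freq_min'/'freq_max' must satisfy 0 < min < max < 1")
        if self.n_iterations < 2:
            raise ValueError("config key 'n_iterations' must be >= 2")
        for name, seq in (
            ("family_sizes", self.family_sizes),
            ("n_ramets", self.n_ramets),
            ("marker_densities", self.marker_densities),
            ("ne_targets", self.ne_targets),
        ):
            if not seq:
                raise ValueError(f"config key '{name}' must be non-empty")
            if any(v <= 0 for v in seq):
                raise ValueError(f"config key '{name}' must contain positive values")
        if max(self.ne_targets) > self.n_parents // 2:
            raise ValueError(
                "config key 'ne_targets' exceeds the number of full-sib families "
                f"({self.n_parents // 2})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_TUPLE_KEYS = {
    "family_sizes": int,
    "n_ramets": int,
    "marker_densities": float,
    "ne_targets": int,
}
_SCALAR_KEYS = {
    "n_parents": int, "n_chrom": int, "n_qtl": int, "n_iterations": int, "seed": int,
    "chrom_length": float, "h2": float, "freq_min": float, "freq_max": float,
    "ld_decay_rate": float, "qtl_on_markers": bool,
}


def load_config(path: str | Path) -> GridConfig:
    """Read a YAML scenario file; missing keys take the study defaults.

    An empty file yields the full default grid.  Unknown keys and
    out-of-range values raise ValueError naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    kwargs = {}
    for key, val in raw.items():
        if key == "ld_decay_rate":
            kwargs[key] = None if val is None else float(val)
        elif key in _TUPLE_KEYS:
            if not isinstance(val, (list, tuple)):
                val = [val]
            kwargs[key] = tuple(_TUPLE_KEYS[key](v) for v in val)
        elif key in _SCALAR_KEYS:
            kwargs[key] = _SCALAR_KEYS[key](val)
        else:
            raise ValueError(f"unknown config key '{key}'")
    return GridConfig(**kwargs)


def dump_config(config: GridConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
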