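"""Run configuration for the pipeline commands.

A plain YAML mapping, validated into :class:`RunConfig` before any stage
runs; a serialized copy is written next to the outputs so every run is
reproducible from its own record.  CLI flags override config values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ECOLI_ASN_ACTIVE_SITE", "DEFAULT_PARAMS"]

#: Catalytic / substrate-binding residues of E. coli type II asparaginase
#: (mature-chain 1-based numbering), from structural annotation of the
#: enzyme's active site: the catalytic triad threonines and their
#: hydrogen-bonding partners.  Users analysing another enzyme must supply
#: their own list — active sites are input, never inferred.
ECOLI_ASN_ACTIVE_SITE: tuple[int, ...] = (12, 25, 58, 59, 89, 90, 162)

DEFAULT_PARAMS = {
    "probe_radius": 1.4,
    "n_points": 960,
    "rsasa_threshold": 0.5,
    "neighbor_radius": 5.0,
    "active_site_radius": 8.0,
    "interface_cutoff": 5.0,
    "aggregation": "max",
}


@dataclass
class RunConfig:
    structure: str = ""
    active_site_positions: list[int] = field(default_factory=list)
    probe_radius: float = 1.4
    n_points: int = 960
    rsasa_threshold: float = 0.5
    neighbor_radius: float = 5.0
    active_site_radius: float = 8.0
    interface_cutoff: float = 5.0
    aggregation: str = "max"
    panel_size: int = 10
    mutation_range: tuple[int, int] = (5, 60)
    seed: int = 0
    output_dir: str = "resurf_out"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 32:
            raise ValueError("n_points must be >= 32")
        if not 0 <= self.rsasa_threshold:
            raise ValueError("rsasa_threshold must be non-negative")
        self.mutation_range = tuple(self.mutation_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["mutation_range"] = list(self.mutation_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
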