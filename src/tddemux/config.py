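"""Pipeline configuration: every tunable in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pseudo_spectrum import CascadeParams

__all__ = ["NoiseParams", "DedupParams", "LinkParams", "PipelineConfig"]


@dataclass(frozen=True)
class NoiseParams:
    snr_ms1_r1: float = 3.0
    snr_ms2_r2: float = 1.0
    histogram_bins: int | None = None  # None = max(10, ceil(sqrt(n)))


@dataclass(frozen=True)
class DedupParams:
    ppm_tol: float = 10.0
    ppm_reference: str = "larger"  # ppm bound referenced to the larger mass


@dataclass(frozen=True)
class LinkParams:
    ppm_tol: float = 10.0
    max_cycle_gap: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated defaults for the whole demultiplexing workflow."""

    cascade: CascadeParams = field(default_factory=CascadeParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    dedup: DedupParams = field(default_factory=DedupParams)
    link: LinkParams = field(default_factory=LinkParams)
    label_ppm_tol: float = 10.0
    split_ratio: float = 0.7
    msalign_dialect: str = "minimal"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "cascade": CascadeParams,
            "noise": NoiseParams,
            "dedup": DedupParams,
            "link": LinkParams,
        }
        for f in fields(cls):
            if f.name not in data:
                continue
            if f.name in nested:
                kwargs[f.name] = nested[f.name](**data[f.name])
            else:
                kwargs[f.name] = data[f.name]
        return cls(**kwargs)
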