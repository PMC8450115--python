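"""Run configuration: strict YAML schema with CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import ConfigurationError
from ..ribo_quant import DEFAULT_OFFSETS, DEFAULT_TRIM


@dataclass
class RunConfig:
    """All thresholds and filters a workflow run depends on.

    Defaults carry the analysis thresholds used throughout: fold change 2,
    alpha 0.05, CBI cuts 0.3/0.15, length strata 600/300 aa, 500-gene
    windows.
    """

    run_dir: str | None = None
    out_dir: str = "codonflux_out"
    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    trim: tuple[int, int] = DEFAULT_TRIM
    min_mean_reads: float = 0.5
    min_total_reads: int = 64
    min_mrna_tpm: float = 1.0
    window: int = 500
    step: int = 1
    fc_threshold: float = 2.0
    alpha: float = 0.05
    cbi_high: float = 0.3
    cbi_low: float = 0.15
    group_size: int = 1000
    strata_long_aa: float = 600.0
    strata_short_aa: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.trim = tuple(self.trim)  # type: ignore[assignment]
        if len(self.trim) != 2 or any(t < 0 for t in self.trim):
            raise ConfigurationError(f"invalid trim {self.trim}")
        if self.window < 3:
            raise ConfigurationError("window must be >= 3")
        if self.fc_threshold <= 1:
            raise ConfigurationError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        self.offsets = {int(k): int(v) for k, v in self.offsets.items()}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["trim"] = list(self.trim)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
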