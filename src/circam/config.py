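"""Tool configuration: a flat TOML file of defaults, overridable by CLI flags.

Reproducible runs want a recorded configuration, so randomized commands
take their seed from here (or an explicit --seed); implicit nondeterminism
is refused at the CLI.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import DomainError
from .geometry import STANDARD_FORMATS


@dataclass
class ToolConfig:
    """Flat key-value configuration for the circam CLI."""

    catalog: list[float] = field(default_factory=lambda: list(STANDARD_FORMATS))
    aspect: str = "4:3"
    jpeg_quality: int = 90
    fill: int = 0
    seed: int | None = None
    draws: int = 100
    verbosity: str = "warning"

    @classmethod
    def load(cls, path: str | Path) -> "ToolConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.jpeg_quality < 1 or cfg.jpeg_quality > 100:
            raise DomainError("jpeg_quality must be in [1, 100]")
        if sorted(cfg.catalog) != list(cfg.catalog):
            raise DomainError("catalog must be ascending")
        return cfg
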