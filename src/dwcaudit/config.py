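"""Run configuration for the audit CLI.

A config file is YAML with any subset of the keys below; command-line
options override file values.  Unknown keys are rejected so typos fail
loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .value_audits import DEFAULT_DATUM_MAP


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class AuditConfig:
    ala: str = ""                     # ALA-style TSV path
    gbif: str = ""                    # DwC-A directory or zip path
    out: str = "."                    # output directory
    terms: list[str] = field(default_factory=lambda: ["identifiedBy", "locality"])
    amended_threshold: int = 2
    overrides: str = ""               # fail-match overrides TSV path
    datum_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DATUM_MAP))
    primary_types: list[str] = field(
        default_factory=lambda: ["holotype", "lectotype", "neotype", "syntype"]
    )
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | None, **cli_overrides) -> "AuditConfig":
        data: dict = {}
        if path:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in cli_overrides.items():
            if value not in (None, "", ()):
                data[key] = value
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        if cfg.amended_threshold < 0:
            raise ConfigError("amended_threshold must be >= 0")
        return cfg
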