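"""User configuration: JSON file at ~/.geo-mcp/config.json.

Loading is forgiving by design — a missing or partially invalid file falls
back to defaults with a warning, never an aborted startup. Only a file that
exists but cannot be decoded at all raises :class:`ConfigError`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from ..errors import ConfigError

DEFAULT_CONFIG_PATH = Path.home() / ".geo-mcp" / "config.json"
NCBI_EUTILS_BASE_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

# Printed policy constants: inter-request delay and the keyed per-second ceiling.
DEFAULT_MIN_INTERVAL = 0.1  # seconds between any two requests
DEFAULT_KEYED_RPS_CEILING = 10  # requests per second with an API key

DEFAULT_TIMEOUTS = {
    "search": 30.0,  # seconds, per E-utilities request
    "download": 300.0,  # seconds, per archive transfer
    "discovery": 10.0,  # seconds, breadcrumb page fetch
    "executor": 30.0,  # seconds, direct endpoint execution
}


class ConfigWarning(UserWarning):
    """Emitted when configuration falls back to defaults."""


class EutilsConfig(BaseModel):
    """Runtime configuration for E-utilities access and downloads.

    ``email`` is required by the upstream service on every request; the
    placeholder default keeps offline testing functional but triggers a
    warning when no config file supplies a real address. An ``api_key``
    activates the keyed rate ceiling (10 requests/second).
    """

    model_config = ConfigDict(extra="ignore")

    email: str = "anonymous@example.org"
    api_key: Optional[str] = None
    base_url: str = NCBI_EUTILS_BASE_URL
    min_interval: float = Field(default=DEFAULT_MIN_INTERVAL, gt=0)
    rps_ceiling_with_key: int = Field(default=DEFAULT_KEYED_RPS_CEILING, gt=0)
    download_dir: Path = Path.home() / ".geo-mcp" / "downloads"
    timeouts: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TIMEOUTS))
    fallback_active: bool = False  # true when defaults substituted for a missing file

    @field_validator("timeouts")
    @classmethod
    def _fill_missing_timeouts(cls, v: dict[str, float]) -> dict[str, float]:
        merged = dict(DEFAULT_TIMEOUTS)
        merged.update({k: float(x) for k, x in v.items() if float(x) > 0})
        return merged

    @property
    def keyed(self) -> bool:
        return bool(self.api_key)


def load_config(path: Path | str | None = None) -> EutilsConfig:
    """Load configuration from ``path`` (default ~/.geo-mcp/config.json).

    Absent file → full defaults plus a :class:`ConfigWarning`. Present file
    with some invalid fields → defaults substituted per-field, with a
    warning naming them. A file that cannot be read or decoded as a whole
    raises :class:`ConfigError`.
    """
    path = Path(path) if path is not None else DEFAULT_CONFIG_PATH
    if not path.exists():
        warnings.warn(
            f"config file {path} not found; using defaults (set email for NCBI compliance)",
            ConfigWarning,
            stacklevel=2,
        )
        return EutilsConfig(fallback_active=True)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"config file {path} is unreadable: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a JSON object")

    dropped: list[str] = []
    cfg = None
    candidate = dict(raw)
    candidate.pop("fallback_active", None)
    while cfg is None:
        try:
            cfg = EutilsConfig(**candidate)
        except Exception as exc:  # pydantic ValidationError: drop offending fields
            bad = {str(e["loc"][0]) for e in getattr(exc, "errors", lambda: [])() if e["loc"]}
            if not bad or not bad & set(candidate):
                raise ConfigError(f"config file {path} is invalid: {exc}") from exc
            for field in bad & set(candidate):
                candidate.pop(field)
                dropped.append(field)
    if dropped:
        warnings.warn(
            f"config fields {sorted(dropped)} invalid in {path}; defaults substituted",
            ConfigWarning,
            stacklevel=2,
        )
        cfg.fallback_active = True
    return cfg
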