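"""Pure safety decisions: path confinement and admission control.

Both functions are deliberately side-effect-free so they can be fuzzed
against brute-force oracles; the manager applies them before any I/O.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass
from pathlib import Path, PurePosixPath

from ..errors import PathError

GIB = 1024**3
MIB = 1024**2

DEFAULT_PER_FILE_LIMIT = 5 * GIB
DEFAULT_TOTAL_LIMIT = 10 * GIB
DEFAULT_MAX_CONCURRENT = 3
DEFAULT_REQUEST_TIMEOUT = 300.0  # seconds
DEFAULT_FREE_SPACE_MARGIN = 100 * MIB


@dataclass(frozen=True)
class DownloadPolicy:
    """Safety limits governing admission and transfer of one download."""

    root_dir: Path
    per_file_limit: int = DEFAULT_PER_FILE_LIMIT
    total_limit: int = DEFAULT_TOTAL_LIMIT
    max_concurrent: int = DEFAULT_MAX_CONCURRENT
    request_timeout: float = DEFAULT_REQUEST_TIMEOUT
    free_space_margin: int = DEFAULT_FREE_SPACE_MARGIN

    def __post_init__(self):
        for name in ("per_file_limit", "total_limit", "max_concurrent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.request_timeout <= 0:
            raise ValueError("request_timeout must be strictly positive")


def validate_path(root: Path | str, candidate: str) -> Path:
    """Confine ``candidate`` lexically within ``root``.

    Relative segments are resolved purely lexically (no filesystem access,
    no symlink following — confinement must hold even for paths that do not
    exist yet). Absolute candidates and any path whose normalized form
    escapes the root raise :class:`PathError`: a security rejection, not an
    I/O failure.
    """
    root_path = Path(root)
    norm_root = posixpath.normpath(root_path.as_posix())
    cand = str(candidate).replace("\\", "/")
    if PurePosixPath(cand).is_absolute() or (len(cand) > 1 and cand[1] == ":"):
        raise PathError(f"absolute paths are not allowed: {candidate!r}")
    combined = posixpath.normpath(posixpath.join(norm_root, cand))
    prefix = norm_root.rstrip("/") + "/"
    if combined != norm_root and not combined.startswith(prefix):
        raise PathError(f"path {candidate!r} escapes download root {root!s}")
    return Path(combined)


def admit_job(
    policy: DownloadPolicy,
    advertised_size: int,
    current_usage: int,
    free_space: int,
) -> tuple[bool, str | None]:
    """Admission decision for one transfer: ``(admitted, reason)``.

    Rejection reasons are checked in a fixed order and the first applicable
    one is reported: ``per_file`` (file exceeds the per-file limit), then
    ``total`` (storage budget exhausted), then ``disk`` (insufficient free
    space including the safety margin).
    """
    if advertised_size > policy.per_file_limit:
        return False, "per_file"
    if current_usage + advertised_size > policy.total_limit:
        return False, "total"
    if free_space < advertised_size + policy.free_space_margin:
        return False, "disk"
    return True, None
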