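"""Shared exception taxonomy.

Every error a caller can meaningfully react to gets its own class; transport
layers translate these into structured error responses rather than letting
them crash the server loop.
"""

from __future__ import annotations


class BiocrumbsError(Exception):
    """Base class for all package errors."""


class BreadcrumbValidationError(BiocrumbsError):
    """A breadcrumb payload violates the schema.

    ``paths`` lists every violated field path in dotted form
    (e.g. ``service.name``, ``endpoints.0.method``).
    """

    def __init__(self, message: str, paths: list[str] | None = None):
        super().__init__(message)
        self.paths: list[str] = paths or []


class SerializationError(BiocrumbsError):
    """A document cannot be embedded as an HTML comment safely."""


class UnsupportedMethodError(BiocrumbsError):
    """HTTP verb outside the supported set (GET, POST, PUT, DELETE)."""


class FetchTimeoutError(BiocrumbsError):
    """A network request exceeded its deadline."""


class NetworkError(BiocrumbsError):
    """Connection-level failure after retries were exhausted."""


class ConfigError(BiocrumbsError):
    """Config file exists but cannot be read or decoded as a whole."""


class UpstreamError(BiocrumbsError):
    """E-utilities answered with a non-2xx status after retries."""

    def __init__(self, message: str, status_code: int | None = None):
        super().__init__(message)
        self.status_code = status_code


class ParseError(BiocrumbsError):
    """Upstream body could not be parsed in any accepted retmode."""


class PathError(BiocrumbsError):
    """Security rejection: a candidate path escapes the allowed root."""


class FormatError(BiocrumbsError):
    """Structurally impossible SOFT input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class NotFoundError(BiocrumbsError):
    """Unknown identifier (job id, tool name)."""
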