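"""Breadcrumb document schema and all-or-nothing validation.

The canonical key spellings are ``service.name``, ``service.version``,
``mcp_available.status``, ``mcp_available.redirect_url`` and
``endpoints[].{method,url,concept,concept_iris,params,example}``. Concept
tags are plain strings (e.g. ``search_data``, ``download_file``) with an
optional ``concept_iris`` list for ontology identifiers; membership in a
controlled vocabulary is deliberately not enforced.
"""

from __future__ import annotations

from typing import Any, Literal, Mapping, Optional
from urllib.parse import urlparse

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from ..errors import BreadcrumbValidationError

VALUE_TYPES = ("string", "integer", "number", "boolean", "array")
HTTP_METHODS = ("GET", "POST", "PUT", "DELETE")


class _Model(BaseModel):
    model_config = ConfigDict(extra="ignore", frozen=True)


class ServiceIdentity(_Model):
    """Who the service is: both fields must be non-empty."""

    name: str = Field(min_length=1)
    version: str = Field(min_length=1)


class McpAvailability(_Model):
    """Whether a native MCP endpoint exists; if so, where."""

    status: bool
    redirect_url: Optional[str] = None

    @model_validator(mode="after")
    def _redirect_required_when_available(self) -> "McpAvailability":
        if self.status:
            if not self.redirect_url:
                raise ValueError("redirect_url is required when status is true")
            parsed = urlparse(self.redirect_url)
            if not (parsed.scheme and parsed.netloc):
                raise ValueError("redirect_url must be an absolute URL")
        return self


class ParameterSpec(_Model):
    """One endpoint parameter; value_type is drawn from a closed set."""

    name: str = Field(min_length=1)
    value_type: Literal["string", "integer", "number", "boolean", "array"]
    required: bool = False
    description: Optional[str] = None


class EndpointSpec(_Model):
    """One fallback API endpoint with its semantic concept tag."""

    method: Literal["GET", "POST", "PUT", "DELETE"]
    url: str = Field(min_length=1)
    concept: str = Field(min_length=1)
    concept_iris: Optional[list[str]] = None
    params: list[ParameterSpec] = Field(default_factory=list)
    example: Optional[str] = None

    @field_validator("params")
    @classmethod
    def _param_names_unique(cls, v: list[ParameterSpec]) -> list[ParameterSpec]:
        names = [p.name for p in v]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {', '.join(dupes)}")
        return v


class BreadcrumbDocument(_Model):
    """A validated breadcrumb: identity, MCP availability, endpoint specs.

    ``endpoints`` may be empty only when ``mcp_available.status`` is true
    (a service that is fully MCP-native need not advertise fallbacks).
    """

    service: ServiceIdentity
    mcp_available: McpAvailability
    endpoints: list[EndpointSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _endpoints_or_native(self) -> "BreadcrumbDocument":
        if not self.endpoints and not self.mcp_available.status:
            raise ValueError("endpoints may be empty only when mcp_available.status is true")
        return self

    def to_mapping(self) -> dict[str, Any]:
        """Canonical plain-dict form (None-valued optionals dropped)."""
        return self.model_dump(exclude_none=True)


def validate_document(raw: Mapping[str, Any]) -> BreadcrumbDocument:
    """Validate an untyped mapping into a :class:`BreadcrumbDocument`.

    Validation is all-or-nothing: any violation raises
    :class:`BreadcrumbValidationError` whose ``paths`` attribute names every
    violated field path in dotted form. Never crashes on arbitrary input.
    """
    if not isinstance(raw, Mapping):
        raise BreadcrumbValidationError(
            f"breadcrumb payload must be a JSON object, got {type(raw).__name__}",
            paths=["<root>"],
        )
    try:
        return BreadcrumbDocument.model_validate(dict(raw))
    except ValidationError as exc:
        paths = []
        for err in exc.errors():
            loc = ".".join(str(part) for part in err["loc"]) or "<root>"
            paths.append(loc)
        detail = "; ".join(
            f"{p}: {e['msg']}" for p, e in zip(paths, exc.errors())
        )
        raise BreadcrumbValidationError(
            f"invalid breadcrumb document ({detail})", paths=paths
        ) from exc
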