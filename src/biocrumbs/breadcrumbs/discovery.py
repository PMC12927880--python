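"""Discovery with graceful degradation, endpoint execution and enumeration.

The degradation ladder is strict and total: native MCP availability dominates
breadcrumb endpoint exposure, which dominates the manual-exploration notice;
a present-but-malformed breadcrumb yields an informative error rather than
silently falling through to "no breadcrumbs".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Union

from ..errors import (
    BreadcrumbValidationError,
    FetchTimeoutError,
    NetworkError,
    UnsupportedMethodError,
)
from ..http_util import (
    DEFAULT_DISCOVERY_TIMEOUT,
    DEFAULT_EXECUTOR_TIMEOUT,
    FetchPolicy,
    HttpResult,
    fetch,
)
from .comment import extract_candidates
from .model import HTTP_METHODS, BreadcrumbDocument, validate_document


@dataclass(frozen=True)
class McpRedirect:
    """A native MCP endpoint exists; use it instead of any fallback."""

    redirect_url: str
    recommendation: str


@dataclass(frozen=True)
class ApiSpecification:
    """Breadcrumb endpoints reconstructed into API documentation."""

    document: BreadcrumbDocument
    rendered_docs: str


@dataclass(frozen=True)
class ManualExplorationRequired:
    """No machine-actionable metadata found on the page."""

    message: str


@dataclass(frozen=True)
class DiscoveryError:
    """Breadcrumbs present but unusable, or the fetch itself failed."""

    message: str
    cause: str  # "validation" | "network" | "timeout"


DiscoveryOutcome = Union[McpRedirect, ApiSpecification, ManualExplorationRequired, DiscoveryError]


def render_docs(doc: BreadcrumbDocument) -> str:
    """Deterministic plain-text endpoint listing (one endpoint per line)."""
    lines = [f"Service: {doc.service.name} v{doc.service.version}"]
    for ep in doc.endpoints:
        required = [p.name for p in ep.params if p.required]
        optional = [p.name for p in ep.params if not p.required]
        parts = [f"{ep.method} {ep.url}", f"concept={ep.concept}"]
        if required:
            parts.append("required=" + ",".join(required))
        if optional:
            parts.append("optional=" + ",".join(optional))
        if ep.example:
            parts.append(f"example={ep.example}")
        lines.append("  " + " | ".join(parts))
    return "\n".join(lines)


def decide(page: str) -> DiscoveryOutcome:
    """Pure decision function mapping a fetched page to exactly one outcome.

    First valid breadcrumb wins; later candidates (valid or not) are
    redundant copies by convention. Candidates that are all malformed yield a
    DiscoveryError naming the first failure — never a silent fallback.
    """
    candidates = extract_candidates(page)
    if not candidates:
        return ManualExplorationRequired(
            message="No breadcrumb metadata found: manual exploration required."
        )
    first_error: str | None = None
    for payload in candidates:
        try:
            raw = json.loads(payload)
        except json.JSONDecodeError as exc:
            if first_error is None:
                first_error = f"breadcrumb payload is not valid JSON: {exc}"
            continue
        try:
            doc = validate_document(raw)
        except BreadcrumbValidationError as exc:
            if first_error is None:
                first_error = str(exc)
            continue
        if doc.mcp_available.status:
            return McpRedirect(
                redirect_url=doc.mcp_available.redirect_url,
                recommendation=(
                    f"Native MCP endpoint available at {doc.mcp_available.redirect_url}; "
                    "prefer the full MCP integration over breadcrumb fallbacks."
                ),
            )
        return ApiSpecification(document=doc, rendered_docs=render_docs(doc))
    return DiscoveryError(message=first_error or "no usable breadcrumb", cause="validation")


def discover(
    url: str,
    timeout: float = DEFAULT_DISCOVERY_TIMEOUT,
    policy: FetchPolicy | None = None,
) -> DiscoveryOutcome:
    """Fetch ``url`` under the discovery policy, then run :func:`decide`.

    Defaults: 10 s deadline, 2 retries with exponential backoff (0.5 s, 1 s)
    on connection errors and 5xx, up to 5 redirects followed.
    """
    policy = policy or FetchPolicy(timeout=timeout)
    try:
        result = fetch(url, policy=policy)
    except FetchTimeoutError as exc:
        return DiscoveryError(message=str(exc), cause="timeout")
    except NetworkError as exc:
        return DiscoveryError(message=str(exc), cause="network")
    if result.status_code >= 400:
        return DiscoveryError(
            message=f"service answered HTTP {result.status_code} for {url}",
            cause="network",
        )
    return decide(result.text or "")


def execute_endpoint(
    url: str,
    method: str,
    params: Mapping[str, object] | None = None,
    timeout: float = DEFAULT_EXECUTOR_TIMEOUT,
) -> HttpResult:
    """Direct request to a discovered endpoint with automatic serialization.

    GET/DELETE carry ``params`` as URL-encoded query pairs; POST/PUT send
    them as a JSON body. The raw :class:`HttpResult` is returned without
    interpretation (401/403 included). Default deadline: 30 s, no retries.
    """
    verb = method.upper()
    if verb not in HTTP_METHODS:
        raise UnsupportedMethodError(
            f"unsupported method {method!r}; supported: {', '.join(HTTP_METHODS)}"
        )
    policy = FetchPolicy(timeout=timeout, retries=0, backoffs=())
    if verb in ("GET", "DELETE"):
        return fetch(url, method=verb, params=params, policy=policy)
    return fetch(url, method=verb, json_body=dict(params or {}), policy=policy)


def list_endpoints(
    url: str,
    timeout: float = DEFAULT_DISCOVERY_TIMEOUT,
    policy: FetchPolicy | None = None,
) -> tuple[list[dict[str, str]], str]:
    """Quick endpoint enumeration: (projection, note).

    The projection is non-empty only for the ApiSpecification outcome; the
    other outcomes return an empty list with an explanatory note.
    """
    outcome = discover(url, timeout=timeout, policy=policy)
    if isinstance(outcome, ApiSpecification):
        listing = [
            {"method": ep.method, "url": ep.url, "concept": ep.concept}
            for ep in outcome.document.endpoints
        ]
        return listing, f"{len(listing)} endpoint(s) discovered."
    if isinstance(outcome, McpRedirect):
        return [], outcome.recommendation
    if isinstance(outcome, ManualExplorationRequired):
        return [], outcome.message
    return [], f"discovery failed ({outcome.cause}): {outcome.message}"
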