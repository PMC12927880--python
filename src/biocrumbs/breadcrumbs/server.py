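"""The three-tool breadcrumb discovery service.

Tools: ``discover_service`` (degradation ladder), ``call_endpoint`` (direct
execution with automatic parameter serialization), ``list_service_endpoints``
(quick enumeration). All three are thin wrappers over the library functions.
"""

from __future__ import annotations

import base64
from dataclasses import asdict
from typing import Mapping

from ..http_util import DEFAULT_DISCOVERY_TIMEOUT, DEFAULT_EXECUTOR_TIMEOUT, FetchPolicy
from ..registry import ToolDescriptor, ToolRegistry, ToolResponse, error_response, wrap_response
from .discovery import (
    ApiSpecification,
    DiscoveryError,
    ManualExplorationRequired,
    McpRedirect,
    discover,
    execute_endpoint,
    list_endpoints,
)

BREADCRUMB_TOOL_NAMES = ("discover_service", "call_endpoint", "list_service_endpoints")

_URL_PARAM = {"type": "string", "description": "Absolute service URL"}

_DESCRIPTORS = (
    ToolDescriptor(
        name="discover_service",
        description="Fetch a service page, extract breadcrumb metadata and "
        "apply the degradation ladder: native MCP redirect, else "
        "API specification, else manual exploration notice.",
        input_schema={
            "type": "object",
            "properties": {"url": _URL_PARAM},
            "required": ["url"],
        },
        output_schema={
            "type": "object",
            "properties": {
                "outcome": {
                    "type": "string",
                    "enum": ["mcp_redirect", "api_specification",
                             "manual_exploration_required", "discovery_error"],
                },
            },
            "required": ["outcome"],
        },
        concepts=("search_data",),
    ),
    ToolDescriptor(
        name="call_endpoint",
        description="Direct HTTP request to a discovered endpoint "
        "(GET/POST/PUT/DELETE) with automatic parameter serialization.",
        input_schema={
            "type": "object",
            "properties": {
                "url": _URL_PARAM,
                "method": {"type": "string", "enum": ["GET", "POST", "PUT", "DELETE"]},
                "params": {"type": "object"},
                "timeout": {"type": "number", "description": "Seconds (default 30)"},
            },
            "required": ["url", "method"],
        },
        output_schema={
            "type": "object",
            "properties": {
                "status_code": {"type": "integer"},
                "headers": {"type": "object"},
                "body_text": {"type": ["string", "null"]},
            },
            "required": ["status_code"],
        },
        concepts=("execute_endpoint",),
    ),
    ToolDescriptor(
        name="list_service_endpoints",
        description="Quick endpoint enumeration for multi-step workflows: "
        "method, URL and concept tag per discovered endpoint.",
        input_schema={
            "type": "object",
            "properties": {"url": _URL_PARAM},
            "required": ["url"],
        },
        output_schema={
            "type": "object",
            "properties": {
                "endpoints": {"type": "array"},
                "note": {"type": "string"},
            },
            "required": ["endpoints", "note"],
        },
        concepts=("search_data",),
    ),
)


def outcome_payload(outcome) -> dict:
    if isinstance(outcome, McpRedirect):
        return {"outcome": "mcp_redirect", **asdict(outcome)}
    if isinstance(outcome, ApiSpecification):
        return {
            "outcome": "api_specification",
            "document": outcome.document.to_mapping(),
            "rendered_docs": outcome.rendered_docs,
        }
    if isinstance(outcome, ManualExplorationRequired):
        return {"outcome": "manual_exploration_required", **asdict(outcome)}
    assert isinstance(outcome, DiscoveryError)
    return {"outcome": "discovery_error", **asdict(outcome)}


def build_breadcrumbs_registry(
    discovery_timeout: float = DEFAULT_DISCOVERY_TIMEOUT,
    executor_timeout: float = DEFAULT_EXECUTOR_TIMEOUT,
    fetch_policy: FetchPolicy | None = None,
) -> ToolRegistry:
    """Wire the three descriptors to live handlers."""

    def handle_discover(args: Mapping) -> ToolResponse:
        url = str(args.get("url", "")).strip()
        if not url:
            return error_response("parameter 'url' is required", "invalid_params")
        outcome = discover(url, timeout=discovery_timeout, policy=fetch_policy)
        payload = outcome_payload(outcome)
        return wrap_response(payload, summary=_outcome_summary(outcome))

    def handle_call(args: Mapping) -> ToolResponse:
        url = str(args.get("url", "")).strip()
        method = str(args.get("method", "GET"))
        if not url:
            return error_response("parameter 'url' is required", "invalid_params")
        result = execute_endpoint(
            url,
            method,
            params=args.get("params") or {},
            timeout=float(args.get("timeout", executor_timeout)),
        )
        payload = {
            "status_code": result.status_code,
            "headers": result.headers,
            "body_text": result.text,
            "elapsed": result.elapsed,
        }
        if result.text is None:
            payload["body_base64"] = base64.b64encode(result.body).decode("ascii")
        return wrap_response(payload, summary=f"HTTP {result.status_code} from {method} {url}")

    def handle_list(args: Mapping) -> ToolResponse:
        url = str(args.get("url", "")).strip()
        if not url:
            return error_response("parameter 'url' is required", "invalid_params")
        listing, note = list_endpoints(url, timeout=discovery_timeout, policy=fetch_policy)
        return wrap_response({"endpoints": listing, "note": note}, summary=note)

    return ToolRegistry(
        name="breadcrumbs",
        descriptors=_DESCRIPTORS,
        handlers={
            "discover_service": handle_discover,
            "call_endpoint": handle_call,
            "list_service_endpoints": handle_list,
        },
    )


def _outcome_summary(outcome) -> str:
    if isinstance(outcome, McpRedirect):
        return f"Native MCP available: {outcome.redirect_url}"
    if isinstance(outcome, ApiSpecification):
        return f"{len(outcome.document.endpoints)} API endpoint(s) reconstructed from breadcrumbs"
    if isinstance(outcome, ManualExplorationRequired):
        return outcome.message
    return f"Discovery failed ({outcome.cause}): {outcome.message}"
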