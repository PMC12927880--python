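"""MCP tool primitives: descriptors, wrapped responses, and a dispatch registry.

A :class:`ToolDescriptor` carries the JSON Schema contract and concept tags
for one tool; a :class:`ToolRegistry` pairs descriptors with handlers and is
what both transports (stdio and HTTP) serve, guaranteeing identical
advertisements across deployment modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

from .errors import BiocrumbsError, NotFoundError

PROTOCOL_VERSION = "2024-11-05"


@dataclass(frozen=True)
class ToolDescriptor:
    """One MCP tool: name, description, input/output schemas, concept tags."""

    name: str
    description: str
    input_schema: dict[str, Any]
    output_schema: dict[str, Any]
    concepts: tuple[str, ...] = ()

    def to_mcp(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "description": self.description,
            "inputSchema": self.input_schema,
        }


@dataclass(frozen=True)
class ContentBlock:
    """One MCP text block: a human-readable summary line over a JSON payload."""

    summary: str
    payload: Any

    @property
    def json_text(self) -> str:
        return json.dumps(self.payload, sort_keys=True, ensure_ascii=False)

    @property
    def text(self) -> str:
        return f"{self.summary}\n{self.json_text}"

    @staticmethod
    def parse(text: str) -> Any:
        """Recover the payload from a rendered block."""
        _, _, body = text.partition("\n")
        return json.loads(body)


@dataclass(frozen=True)
class ToolResponse:
    """Structured result wrapped for MCP TextContent delivery."""

    content: tuple[ContentBlock, ...]
    is_error: bool = False

    def to_mcp(self) -> dict[str, Any]:
        return {
            "content": [{"type": "text", "text": b.text} for b in self.content],
            "isError": self.is_error,
        }


def wrap_response(payload: Any, summary: str | None = None) -> ToolResponse:
    """Wrap a serializable payload with a deterministic summary line.

    Invariant: ``ContentBlock.parse(wrap_response(p).content[0].text) == p``
    for any JSON-serializable payload.
    """
    if summary is None:
        summary = _summarize(payload)
    return ToolResponse(content=(ContentBlock(summary=summary, payload=payload),))


def error_response(message: str, category: str = "error") -> ToolResponse:
    """Structured error: a human-readable message, never a transport crash."""
    block = ContentBlock(summary=f"Error ({category}): {message}",
                         payload={"error": category, "message": message})
    return ToolResponse(content=(block,), is_error=True)


def _summarize(payload: Any) -> str:
    if isinstance(payload, Mapping):
        counted = {
            k: len(v) for k, v in sorted(payload.items()) if isinstance(v, (list, tuple))
        }
        if counted:
            total = sum(counted.values())
            detail = ", ".join(f"{k}: {n}" for k, n in counted.items())
            return f"{total} result(s) ({detail})"
        return f"result with {len(payload)} field(s)"
    if isinstance(payload, (list, tuple)):
        return f"{len(payload)} result(s)"
    return "result"


ToolHandler = Callable[[Mapping[str, Any]], ToolResponse]


@dataclass
class ToolRegistry:
    """Descriptor list plus handler dispatch; stable across transports."""

    name: str
    descriptors: tuple[ToolDescriptor, ...]
    handlers: dict[str, ToolHandler] = field(default_factory=dict)

    def __post_init__(self):
        missing = {d.name for d in self.descriptors} - set(self.handlers)
        if missing:
            raise ValueError(f"descriptors without handlers: {sorted(missing)}")

    def list_tools(self) -> list[ToolDescriptor]:
        return list(self.descriptors)

    def call(self, tool_name: str, arguments: Mapping[str, Any]) -> ToolResponse:
        """Dispatch one tool call; every failure becomes a structured response."""
        handler = self.handlers.get(tool_name)
        if handler is None:
            raise NotFoundError(f"unknown tool: {tool_name}")
        try:
            return handler(arguments or {})
        except BiocrumbsError as exc:
            return error_response(str(exc), category=type(exc).__name__)
        except Exception as exc:  # defensive: tool bugs must not kill the server
            return error_response(f"{type(exc).__name__}: {exc}", category="internal")
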