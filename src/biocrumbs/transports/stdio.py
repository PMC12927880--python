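"""MCP stdio transport: newline-delimited JSON-RPC 2.0 frames.

The message handler is a pure function over (registry, frame) so the
protocol is testable without processes or pipes; :func:`serve_stdio` is the
loop that binds it to a pair of streams. Malformed frames are answered with
protocol-level errors — the server only stops when its input stream closes.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from typing import Any, Mapping, Optional, TextIO

from ..errors import NotFoundError
from ..registry import PROTOCOL_VERSION, ToolRegistry

PARSE_ERROR = -32700
INVALID_REQUEST = -32600
METHOD_NOT_FOUND = -32601
INVALID_PARAMS = -32602


@dataclass(frozen=True)
class ServerCapabilities:
    """Advertisement sent during initialization, identical on every transport."""

    protocol_version: str
    tool_registry: tuple
    transport: str

    def to_mcp(self, server_name: str) -> dict[str, Any]:
        return {
            "protocolVersion": self.protocol_version,
            "capabilities": {"tools": {"listChanged": False}},
            "serverInfo": {"name": server_name, "version": "0.1.0"},
        }


def capabilities(registry: ToolRegistry, transport: str) -> ServerCapabilities:
    return ServerCapabilities(
        protocol_version=PROTOCOL_VERSION,
        tool_registry=tuple(registry.list_tools()),
        transport=transport,
    )


def _error(msg_id, code: int, message: str) -> dict[str, Any]:
    return {"jsonrpc": "2.0", "id": msg_id, "error": {"code": code, "message": message}}


def _result(msg_id, result: Mapping[str, Any]) -> dict[str, Any]:
    return {"jsonrpc": "2.0", "id": msg_id, "result": dict(result)}


def handle_message(registry: ToolRegistry, line: str) -> Optional[dict[str, Any]]:
    """Answer one JSON-RPC frame; None for notifications (no reply owed)."""
    try:
        frame = json.loads(line)
    except json.JSONDecodeError as exc:
        return _error(None, PARSE_ERROR, f"parse error: {exc}")
    if not isinstance(frame, dict) or frame.get("jsonrpc") != "2.0" or "method" not in frame:
        return _error(frame.get("id") if isinstance(frame, dict) else None,
                      INVALID_REQUEST, "not a JSON-RPC 2.0 request")
    method = frame["method"]
    msg_id = frame.get("id")
    params = frame.get("params") or {}
    is_notification = "id" not in frame

    if method == "initialize":
        reply = _result(msg_id, capabilities(registry, "stdio").to_mcp(registry.name))
    elif method in ("notifications/initialized", "initialized"):
        return None
    elif method == "tools/list":
        reply = _result(msg_id, {"tools": [d.to_mcp() for d in registry.list_tools()]})
    elif method == "tools/call":
        name = params.get("name")
        if not name:
            reply = _error(msg_id, INVALID_PARAMS, "tools/call requires a 'name' parameter")
        else:
            try:
                response = registry.call(name, params.get("arguments") or {})
                reply = _result(msg_id, response.to_mcp())
            except NotFoundError as exc:
                reply = _error(msg_id, INVALID_PARAMS, str(exc))
    elif method == "ping":
        reply = _result(msg_id, {})
    else:
        reply = _error(msg_id, METHOD_NOT_FOUND, f"unknown method: {method}")
    return None if is_notification else reply


def serve_stdio(
    registry: ToolRegistry,
    instream: TextIO | None = None,
    outstream: TextIO | None = None,
) -> None:
    """Serve ``registry`` over newline-delimited JSON-RPC until EOF."""
    instream = instream if instream is not None else sys.stdin
    outstream = outstream if outstream is not None else sys.stdout
    for line in instream:
        line = line.strip()
        if not line:
            continue
        reply = handle_message(registry, line)
        if reply is not None:
            outstream.write(json.dumps(reply) + "\n")
            outstream.flush()
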