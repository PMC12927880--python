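"""HTTP deployment mode: one REST route per tool, OpenAPI description,
CORS headers on every response, Server-Sent Events for download progress,
and a /health liveness probe.

Implemented on the standard library's threading HTTP server so the mode has
no framework dependency; route dispatch is mechanical (schema-driven) —
``POST /tools/<tool_name>`` with a JSON body mirroring the tool's input
schema.
"""

from __future__ import annotations

import json
import threading
import time
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional

from ..downloads.manager import DownloadManager
from ..errors import NotFoundError
from ..registry import PROTOCOL_VERSION, ToolRegistry

_CORS_HEADERS = {
    "Access-Control-Allow-Origin": "*",
    "Access-Control-Allow-Methods": "GET, POST, OPTIONS",
    "Access-Control-Allow-Headers": "Content-Type",
}

SSE_HEARTBEAT_INTERVAL = 1.0  # seconds between progress frames while running


def openapi_document(registry: ToolRegistry) -> dict:
    """Machine-readable API description: one operation per tool."""
    paths = {}
    for desc in registry.list_tools():
        paths[f"/tools/{desc.name}"] = {
            "post": {
                "operationId": desc.name,
                "summary": desc.description,
                "requestBody": {
                    "content": {"application/json": {"schema": desc.input_schema}},
                    "required": True,
                },
                "responses": {
                    "200": {
                        "description": "Tool response",
                        "content": {"application/json": {"schema": desc.output_schema}},
                    }
                },
                "tags": list(desc.concepts),
            }
        }
    paths["/health"] = {"get": {"operationId": "health", "summary": "Liveness probe",
                                "responses": {"200": {"description": "Status record"}}}}
    return {
        "openapi": "3.1.0",
        "info": {"title": f"{registry.name} MCP HTTP gateway", "version": "0.1.0"},
        "paths": paths,
    }


class HttpTransport:
    """Threaded HTTP server over a tool registry (plus optional downloads)."""

    def __init__(
        self,
        registry: ToolRegistry,
        port: int = 0,
        manager: Optional[DownloadManager] = None,
        config_fallback_active: bool = False,
    ):
        self.registry = registry
        self.manager = manager
        self.config_fallback_active = config_fallback_active
        handler = self._make_handler()
        self._server = ThreadingHTTPServer(("127.0.0.1", port), handler)
        self._thread: Optional[threading.Thread] = None

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    @property
    def base_url(self) -> str:
        return f"http://127.0.0.1:{self.port}"

    def health(self) -> dict:
        """Liveness, registry size and config-load state."""
        return {
            "status": "ok" if self.registry.list_tools() else "degraded",
            "tool_count": len(self.registry.list_tools()),
            "protocol_version": PROTOCOL_VERSION,
            "config_fallback_active": self.config_fallback_active,
        }

    def start(self) -> "HttpTransport":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def __enter__(self) -> "HttpTransport":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    # -- request handling ----------------------------------------------

    def _make_handler(self):
        transport = self

        class Handler(BaseHTTPRequestHandler):
            protocol_version = "HTTP/1.1"

            def log_message(self, *args):  # keep test output clean
                pass

            def _send_json(self, status: int, payload: dict) -> None:
                body = json.dumps(payload).encode("utf-8")
                self.send_response(status)
                for k, v in _CORS_HEADERS.items():
                    self.send_header(k, v)
                self.send_header("Content-Type", "application/json")
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def do_OPTIONS(self):
                self.send_response(204)
                for k, v in _CORS_HEADERS.items():
                    self.send_header(k, v)
                self.send_header("Content-Length", "0")
                self.end_headers()

            def do_GET(self):
                if self.path == "/health":
                    self._send_json(200, transport.health())
                elif self.path in ("/openapi.json", "/openapi"):
                    self._send_json(200, openapi_document(transport.registry))
                elif self.path == "/tools":
                    self._send_json(
                        200,
                        {"tools": [d.to_mcp() for d in transport.registry.list_tools()]},
                    )
                elif self.path == "/events":
                    self._serve_events()
                else:
                    self._send_json(404, {"error": "not_found", "message": self.path})

            def do_POST(self):
                if not self.path.startswith("/tools/"):
                    self._send_json(404, {"error": "not_found", "message": self.path})
                    return
                tool_name = self.path[len("/tools/"):]
                length = int(self.headers.get("Content-Length") or 0)
                raw = self.rfile.read(length) if length else b"{}"
                try:
                    arguments = json.loads(raw) if raw.strip() else {}
                    if not isinstance(arguments, dict):
                        raise ValueError("request body must be a JSON object")
                except (json.JSONDecodeError, ValueError) as exc:
                    self._send_json(400, {"error": "bad_request", "message": str(exc)})
                    return
                try:
                    response = transport.registry.call(tool_name, arguments)
                except NotFoundError as exc:
                    self._send_json(404, {"error": "unknown_tool", "message": str(exc)})
                    return
                self._send_json(200, response.to_mcp())

            def _serve_events(self):
                self.send_response(200)
                for k, v in _CORS_HEADERS.items():
                    self.send_header(k, v)
                self.send_header("Content-Type", "text/event-stream")
                self.send_header("Cache-Control", "no-cache")
                self.end_headers()
                try:
                    transport._stream_events(self.wfile)
                except (BrokenPipeError, ConnectionResetError):
                    pass

        return Handler

    def _stream_events(self, wfile) -> None:
        """Emit download-progress events: on every state/byte change and at a
        1 s heartbeat while jobs run; ends when no job is queued/running."""

        def frame(payload: dict) -> bytes:
            return f"data: {json.dumps(payload)}\n\n".encode("utf-8")

        manager = self.manager
        if manager is None:
            wfile.write(frame({"event": "idle", "message": "no download manager attached"}))
            return
        last_seen: dict[str, tuple] = {}
        last_emit: dict[str, float] = {}
        idle_polls = 0
        while True:
            active = False
            now = time.monotonic()
            for job in manager.jobs():
                snap = job.snapshot()
                key = (snap["state"], snap["bytes_done"])
                changed = last_seen.get(job.job_id) != key
                running = snap["state"] in ("queued", "running")
                heartbeat_due = running and (
                    now - last_emit.get(job.job_id, 0.0) >= SSE_HEARTBEAT_INTERVAL
                )
                if changed or heartbeat_due:
                    last_seen[job.job_id] = key
                    last_emit[job.job_id] = now
                    wfile.write(frame(snap))
                    wfile.flush()
                if running:
                    active = True
            if not active:
                idle_polls += 1
                if idle_polls >= 2:
                    wfile.write(frame({"event": "stream_end"}))
                    wfile.flush()
                    return
            else:
                idle_polls = 0
            time.sleep(min(SSE_HEARTBEAT_INTERVAL, 0.05))


def serve_http(
    registry: ToolRegistry,
    port: int = 8080,
    manager: Optional[DownloadManager] = None,
    config_fallback_active: bool = False,
) -> None:
    """Blocking entry point for the HTTP deployment mode."""
    transport = HttpTransport(
        registry, port=port, manager=manager,
        config_fallback_active=config_fallback_active,
    )
    transport.start()
    try:
        while True:
            time.sleep(3600)
    except KeyboardInterrupt:
        transport.stop()
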