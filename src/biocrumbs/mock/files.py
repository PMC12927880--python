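"""Controllable file server for download-policy tests.

Each catalog entry controls the advertised Content-Length independently of
the bytes actually served, which lets the printed multi-gigabyte limits be
exercised with spoofed headers instead of materialized payloads. Per-chunk
delays make the concurrency bound observable, and the server counts
simultaneous in-flight transfers as ground truth.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional


@dataclass
class FileCatalogEntry:
    """One servable artifact.

    ``advertised_size`` of None omits the Content-Length header entirely
    (unknown-length stream); a spoofed value may exceed ``len(payload)``.
    """

    payload: bytes
    advertised_size: Optional[int] = -1  # -1 → honest length
    delay_per_chunk: float = 0.0
    chunk_size: int = 1024

    def advertised(self) -> Optional[int]:
        if self.advertised_size == -1:
            return len(self.payload)
        return self.advertised_size


class MockFileServer:
    """Serves a name→entry catalog; tracks peak concurrent transfers."""

    def __init__(self, catalog: dict[str, FileCatalogEntry], port: int = 0):
        self.catalog = catalog
        self.active = 0
        self.max_active = 0
        self.bytes_served: dict[str, int] = {}
        self._lock = threading.Lock()
        self._server = ThreadingHTTPServer(("127.0.0.1", port), self._make_handler())
        self._thread: Optional[threading.Thread] = None

    @property
    def base_url(self) -> str:
        return f"http://127.0.0.1:{self._server.server_address[1]}"

    def start(self) -> "MockFileServer":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def __enter__(self):
        return self.start()

    def __exit__(self, *exc):
        self.stop()

    def _enter_transfer(self):
        with self._lock:
            self.active += 1
            self.max_active = max(self.max_active, self.active)

    def _leave_transfer(self):
        with self._lock:
            self.active -= 1

    def _make_handler(self):
        mock = self

        class Handler(BaseHTTPRequestHandler):
            protocol_version = "HTTP/1.1"

            def log_message(self, *args):
                pass

            def _lookup(self) -> Optional[FileCatalogEntry]:
                return mock.catalog.get(self.path.lstrip("/"))

            def do_HEAD(self):
                entry = self._lookup()
                if entry is None:
                    self.send_response(404)
                    self.send_header("Content-Length", "0")
                    self.end_headers()
                    return
                self.send_response(200)
                advertised = entry.advertised()
                if advertised is not None:
                    self.send_header("Content-Length", str(advertised))
                self.end_headers()

            def do_GET(self):
                entry = self._lookup()
                if entry is None:
                    body = b"not found"
                    self.send_response(404)
                    self.send_header("Content-Length", str(len(body)))
                    self.end_headers()
                    self.wfile.write(body)
                    return
                mock._enter_transfer()
                try:
                    self.send_response(200)
                    advertised = entry.advertised()
                    if advertised is not None:
                        self.send_header("Content-Length", str(advertised))
                    else:
                        # unknown length: close-delimited body
                        self.send_header("Connection", "close")
                        self.close_connection = True
                    self.end_headers()
                    name = self.path.lstrip("/")
                    served = 0
                    for start in range(0, len(entry.payload), entry.chunk_size):
                        if start and entry.delay_per_chunk:
                            # sleep between chunks, never after the last one, so
                            # the handler does not outlive the client's read
                            time.sleep(entry.delay_per_chunk)
                        chunk = entry.payload[start : start + entry.chunk_size]
                        try:
                            self.wfile.write(chunk)
                            self.wfile.flush()
                        except (BrokenPipeError, ConnectionResetError):
                            break
                        served += len(chunk)
                        with mock._lock:
                            mock.bytes_served[name] = served
                finally:
                    mock._leave_transfer()

        return Handler
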