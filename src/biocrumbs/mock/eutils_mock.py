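"""Scripted E-utilities emulator and scenario page server.

The script maps query terms to (count, uids) and uids to summary records;
unknown terms answer an empty UID list, exactly like the live service does
for unmatched queries. Failure injections (status code, garbage body,
delay) are consumed per-route in FIFO order, which makes retry schedules
observable from the script alone.
"""

from __future__ import annotations

import json
import threading
import time
import urllib.parse
from collections import deque
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional

from ..eutils.client import EsummaryRecord


@dataclass
class Injection:
    """One scripted failure: served before normal behavior on its route."""

    status: int = 500
    body: bytes = b"upstream unavailable"
    delay: float = 0.0


@dataclass
class EutilsScript:
    """Deterministic behavior table for the emulator."""

    terms: dict[str, tuple[int, list[str]]] = field(default_factory=dict)
    summaries: dict[str, EsummaryRecord] = field(default_factory=dict)
    injections: dict[str, deque] = field(default_factory=dict)
    pages: dict[str, str] = field(default_factory=dict)

    def inject(self, route: str, *failures: Injection) -> None:
        self.injections.setdefault(route, deque()).extend(failures)

    def validate(self) -> None:
        for term, (_, uids) in self.terms.items():
            for uid in uids:
                if uid not in self.summaries:
                    raise ValueError(f"scripted uid {uid} (term {term!r}) has no summary")


# The transcript terms: four refinement attempts answer empty lists before the
# broad term matches; UID→accession pairs are a harness convention.
_TRANSCRIPT_EMPTY_TERMS = (
    "microglia depletion mouse",
    "microglia PLX3397 mouse",
    "CSF1R inhibitor mouse brain",
    "microglia mouse brain",
)

_TRANSCRIPT_RECORDS = [
    ("200299005", "GSE299005", "Post-TBI microglia depletion (snRNA-seq)"),
    ("200279739", "GSE279739", "Microglia repopulation time course"),
    ("200271535", "GSE271535", "Microglia innate immune memory after CSF1R depletion (RNA-seq)"),
    ("200270935", "GSE270935", "Companion ATAC-seq dataset"),
    ("200292830", "GSE292830", "PLX3397-mediated depletion with monocyte replacement"),
    ("200288018", "GSE288018", "Krabbe disease model with microglia replacement"),
]


def default_transcript_script() -> EutilsScript:
    """The scripted search behavior used across the test suite."""
    script = EutilsScript()
    for term in _TRANSCRIPT_EMPTY_TERMS:
        script.terms[term] = (0, [])
    uids = [uid for uid, _, _ in _TRANSCRIPT_RECORDS]
    script.terms["microglia depletion"] = (len(uids), uids)
    for uid, accession, title in _TRANSCRIPT_RECORDS:
        script.summaries[uid] = EsummaryRecord(
            uid=uid,
            accession=accession,
            title=title,
            summary=f"Mouse study: {title.lower()}",
            organism="Mus musculus",
            entry_type="GSE",
        )
    script.validate()
    return script


class MockEutilsServer:
    """Local emulator exposing ESearch/ESummary-shaped routes and test pages."""

    def __init__(self, script: EutilsScript, port: int = 0):
        self.script = script
        self.requests: list[str] = []  # observed paths, for retry assertions
        self._lock = threading.Lock()
        handler = self._make_handler()
        self._server = ThreadingHTTPServer(("127.0.0.1", port), handler)
        self._thread: Optional[threading.Thread] = None

    @property
    def base_url(self) -> str:
        return f"http://127.0.0.1:{self._server.server_address[1]}"

    def start(self) -> "MockEutilsServer":
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

    def _pop_injection(self, route: str) -> Optional[Injection]:
        with self._lock:
            queue = self.script.injections.get(route)
            if queue:
                return queue.popleft()
        return None

    def _make_handler(self):
        mock = self

        class Handler(BaseHTTPRequestHandler):
            protocol_version = "HTTP/1.1"

            def log_message(self, *args):
                pass

            def _send(self, status: int, body: bytes, content_type="application/json"):
                self.send_response(status)
                self.send_header("Content-Type", content_type)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def do_GET(self):
                parsed = urllib.parse.urlparse(self.path)
                route = parsed.path
                with mock._lock:
                    mock.requests.append(self.path)
                injection = mock._pop_injection(route)
                if injection is not None:
                    if injection.delay:
                        time.sleep(injection.delay)
                    self._send(injection.status, injection.body)
                    return
                params = dict(urllib.parse.parse_qsl(parsed.query))
                if route.endswith("/esearch.fcgi"):
                    self._esearch(params)
                elif route.endswith("/esummary.fcgi"):
                    self._esummary(params)
                elif route in mock.script.pages:
                    self._send(200, mock.script.pages[route].encode("utf-8"), "text/html")
                else:
                    self._send(404, b'{"error": "unknown route"}')

            def _esearch(self, params):
                term = params.get("term", "")
                retmax = int(params.get("retmax", "20"))
                count, uids = mock.script.terms.get(term, (0, []))
                body = json.dumps(
                    {
                        "esearchresult": {
                            "count": str(count),
                            "retmax": str(retmax),
                            "idlist": list(uids[:retmax]),
                            "querytranslation": term,
                        }
                    }
                ).encode("utf-8")
                self._send(200, body)

            def _esummary(self, params):
                uids = [u for u in params.get("id", "").split(",") if u]
                result: dict = {"uids": []}
                for uid in uids:
                    record = mock.script.summaries.get(uid)
                    if record is None:
                        result[uid] = {"error": "cannot get document summary"}
                        continue
                    result["uids"].append(uid)
                    result[uid] = {
                        "uid": record.uid,
                        "accession": record.accession,
                        "title": record.title,
                        "summary": record.summary,
                        "taxon": record.organism or "",
                        "entrytype": record.entry_type or "",
                    }
                self._send(200, json.dumps({"result": result}).encode("utf-8"))

        return Handler
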