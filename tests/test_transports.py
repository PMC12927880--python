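"""Both deployment modes: stdio JSON-RPC framing, HTTP gateway, equivalence."""

import io
import json
import socket
import threading
import urllib.request

import pytest

from biocrumbs.breadcrumbs.server import BREADCRUMB_TOOL_NAMES, build_breadcrumbs_registry
from biocrumbs.downloads.manager import DownloadManager
from biocrumbs.downloads.policy import DownloadPolicy
from biocrumbs.eutils.client import EutilsClient
from biocrumbs.eutils.ratelimit import RateLimiter
from biocrumbs.geo.tools import build_geo_registry
from biocrumbs.mock.files import FileCatalogEntry, MockFileServer
from biocrumbs.transports.http import HttpTransport, openapi_document
from biocrumbs.transports.stdio import handle_message, serve_stdio


def fast_client(cfg):
    return EutilsClient(cfg, limiter=RateLimiter(sleep=lambda s: None))


def rpc(method, params=None, msg_id=1):
    frame = {"jsonrpc": "2.0", "id": msg_id, "method": method}
    if params is not None:
        frame["params"] = params
    return json.dumps(frame)


class TestStdio:
    def test_initialize_advertises_capabilities(self):
        registry = build_breadcrumbs_registry()
        reply = handle_message(registry, rpc("initialize"))
        assert reply["result"]["protocolVersion"]
        assert "tools" in reply["result"]["capabilities"]
        assert reply["result"]["serverInfo"]["name"] == "breadcrumbs"

    def test_tools_list_counts(self, mock_cfg):
        geo = build_geo_registry(client=fast_client(mock_cfg))
        crumbs = build_breadcrumbs_registry()
        geo_tools = handle_message(geo, rpc("tools/list"))["result"]["tools"]
        crumb_tools = handle_message(crumbs, rpc("tools/list"))["result"]["tools"]
        assert len(geo_tools) == 8
        assert len(crumb_tools) == 3
        assert [t["name"] for t in crumb_tools] == list(BREADCRUMB_TOOL_NAMES)

    def test_tools_call_dispatches(self, mock_cfg):
        geo = build_geo_registry(client=fast_client(mock_cfg))
        reply = handle_message(
            geo,
            rpc("tools/call", {"name": "search_geo",
                               "arguments": {"term": "microglia depletion", "retmax": 5}}),
        )
        text = reply["result"]["content"][0]["text"]
        assert "200299005" in text

    def test_unknown_tool_is_structured_error(self):
        registry = build_breadcrumbs_registry()
        reply = handle_message(registry, rpc("tools/call", {"name": "no_such_tool"}))
        assert "error" in reply
        assert "unknown tool" in reply["error"]["message"]

    def test_unknown_method_answered_not_crashed(self):
        registry = build_breadcrumbs_registry()
        reply = handle_message(registry, rpc("bogus/method"))
        assert reply["error"]["code"] == -32601

    @pytest.mark.parametrize(
        "frame",
        ["not json at all", "{}", '{"jsonrpc": "1.0", "method": "x", "id": 1}', '[1,2,3]'],
    )
    def test_malformed_frames_get_protocol_errors(self, frame):
        registry = build_breadcrumbs_registry()
        reply = handle_message(registry, frame)
        assert reply["error"]["code"] in (-32700, -32600)

    def test_serve_loop_survives_malformed_frames(self):
        registry = build_breadcrumbs_registry()
        lines = [
            "garbage",
            rpc("initialize"),
            '{"jsonrpc": "2.0", "method": "notifications/initialized"}',
            rpc("tools/list", msg_id=2),
        ]
        out = io.StringIO()
        serve_stdio(registry, io.StringIO("\n".join(lines) + "\n"), out)
        replies = [json.loads(line) for line in out.getvalue().splitlines()]
        # parse error + initialize + tools/list; the notification is silent
        assert len(replies) == 3
        assert replies[0]["error"]["code"] == -32700
        assert len(replies[2]["result"]["tools"]) == 3


def http_json(url, payload=None, method=None):
    data = json.dumps(payload).encode() if payload is not None else None
    req = urllib.request.Request(url, data=data, method=method or ("POST" if data else "GET"),
                                 headers={"Content-Type": "application/json"})
    try:
        with urllib.request.urlopen(req, timeout=10) as resp:
            return resp.status, dict(resp.headers), json.loads(resp.read())
    except urllib.error.HTTPError as exc:
        return exc.code, dict(exc.headers), json.loads(exc.read())


@pytest.fixture()
def geo_http(transcript_server, mock_cfg):
    registry = build_geo_registry(client=fast_client(mock_cfg))
    with HttpTransport(registry) as transport:
        yield transport


class TestHttp:
    def test_health_reports_tool_count(self, geo_http):
        status, _, payload = http_json(f"{geo_http.base_url}/health")
        assert status == 200
        assert payload["status"] == "ok"
        assert payload["tool_count"] == 8

    def test_health_flags_config_fallback(self, transcript_server, mock_cfg):
        registry = build_geo_registry(client=fast_client(mock_cfg))
        with HttpTransport(registry, config_fallback_active=True) as transport:
            _, _, payload = http_json(f"{transport.base_url}/health")
        assert payload["config_fallback_active"] is True

    def test_openapi_lists_one_operation_per_tool(self, geo_http):
        status, _, doc = http_json(f"{geo_http.base_url}/openapi.json")
        assert status == 200
        tool_paths = [p for p in doc["paths"] if p.startswith("/tools/")]
        assert len(tool_paths) == 8
        assert doc["paths"]["/tools/search_geo"]["post"]["requestBody"]["content"][
            "application/json"]["schema"]["required"] == ["term"]

    def test_cors_preflight_and_headers(self, geo_http):
        req = urllib.request.Request(f"{geo_http.base_url}/tools", method="OPTIONS")
        with urllib.request.urlopen(req, timeout=10) as resp:
            assert resp.status == 204
            assert resp.headers["Access-Control-Allow-Origin"] == "*"
        _, headers, _ = http_json(f"{geo_http.base_url}/health")
        assert headers["Access-Control-Allow-Origin"] == "*"

    def test_tool_route_dispatches(self, geo_http):
        status, _, payload = http_json(
            f"{geo_http.base_url}/tools/search_geo",
            {"term": "microglia depletion", "retmax": 5},
        )
        assert status == 200
        assert "200299005" in payload["content"][0]["text"]

    def test_unknown_tool_route_404(self, geo_http):
        status, _, payload = http_json(f"{geo_http.base_url}/tools/nope", {"term": "x"})
        assert status == 404
        assert payload["error"] == "unknown_tool"

    def test_malformed_body_400_then_still_responsive(self, geo_http):
        req = urllib.request.Request(
            f"{geo_http.base_url}/tools/search_geo", data=b"{broken", method="POST")
        with pytest.raises(urllib.error.HTTPError) as exc_info:
            urllib.request.urlopen(req, timeout=10)
        assert exc_info.value.code == 400
        status, _, payload = http_json(f"{geo_http.base_url}/health")
        assert status == 200 and payload["status"] == "ok"

    def test_sse_stream_emits_progress_then_terminal(self, tmp_path):
        catalog = {"GSE42": FileCatalogEntry(payload=b"z" * 4096,
                                             delay_per_chunk=0.05, chunk_size=512)}
        with MockFileServer(catalog) as files:
            manager = DownloadManager(
                DownloadPolicy(root_dir=tmp_path / "dl", free_space_margin=1,
                               request_timeout=10),
                url_template=files.base_url + "/GSE{tail}",
            )
            manager.url_template = files.base_url + "/GSE42"
            registry = build_breadcrumbs_registry()
            with HttpTransport(registry, manager=manager) as transport:
                events = []

                def consume():
                    req = urllib.request.Request(f"{transport.base_url}/events")
                    with urllib.request.urlopen(req, timeout=15) as resp:
                        for raw in resp:
                            line = raw.decode().strip()
                            if line.startswith("data: "):
                                events.append(json.loads(line[6:]))
                                if events[-1].get("event") == "stream_end":
                                    return

                consumer = threading.Thread(target=consume, daemon=True)
                consumer.start()
                job = manager.download_geo_data("GSE42")
                manager.wait_all(timeout=20)
                consumer.join(timeout=20)
        assert job.state == "completed"
        progress = [e for e in events if e.get("job_id") == job.job_id]
        assert any(e["state"] in ("queued", "running") for e in progress)
        assert progress[-1]["state"] == "completed"
        assert events[-1]["event"] == "stream_end"


class TestTransportEquivalence:
    def test_stdio_and_http_payloads_identical(self, transcript_server, mock_cfg):
        """For a fixed mock backend, tools/call over stdio and the HTTP route
        return payload-identical tool results."""
        registry = build_geo_registry(client=fast_client(mock_cfg))
        cases = [
            ("search_geo", {"term": "microglia depletion", "retmax": 10}),
            ("search_geo", {"term": "microglia PLX3397 mouse", "retmax": 5}),
            ("search_geo_series", {"term": "aging brain"}),
        ]
        with HttpTransport(registry) as transport:
            for name, arguments in cases:
                stdio_reply = handle_message(
                    registry, rpc("tools/call", {"name": name, "arguments": arguments}))
                _, _, http_reply = http_json(
                    f"{transport.base_url}/tools/{name}", arguments)
                assert stdio_reply["result"] == http_reply

    def test_both_transports_expose_identical_descriptors(self, mock_cfg):
        registry = build_geo_registry(client=fast_client(mock_cfg))
        stdio_tools = handle_message(registry, rpc("tools/list"))["result"]["tools"]
        with HttpTransport(registry) as transport:
            _, _, via_http = http_json(f"{transport.base_url}/tools")
        assert stdio_tools == via_http["tools"]

    def test_crash_resistance_corpus(self, geo_http):
        """A corpus of malformed requests leaves the server responsive."""
        base = geo_http.base_url
        for path, data in [
            ("/tools/search_geo", b"\x00\x01binary"),
            ("/tools/", b"{}"),
            ("/nowhere", None),
            ("/tools/search_geo", b"[1,2]"),
        ]:
            req = urllib.request.Request(
                base + path, data=data, method="POST" if data else "GET")
            try:
                urllib.request.urlopen(req, timeout=10).read()
            except urllib.error.HTTPError:
                pass
        status, _, payload = http_json(f"{base}/health")
        assert status == 200
        assert payload["status"] == "ok"
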