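"""Minimal synchronous HTTP client used by every network-facing module.

Built on :mod:`urllib.request` so the package has no HTTP-client dependency.
Retry/backoff and redirect limits are grouped in :class:`FetchPolicy`; tests
inject zero backoffs to keep the suite fast while exercising the schedule.
"""

from __future__ import annotations

import json
import socket
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import FetchTimeoutError, NetworkError

DEFAULT_DISCOVERY_TIMEOUT = 10.0  # seconds
DEFAULT_EXECUTOR_TIMEOUT = 30.0  # seconds


@dataclass
class HttpResult:
    """Completed HTTP exchange. Timeouts and aborts raise instead."""

    status_code: int
    headers: dict[str, str]
    body: bytes
    elapsed: float
    url: str = ""

    @property
    def text(self) -> str | None:
        """Body decoded as UTF-8 when possible, else None."""
        try:
            return self.body.decode("utf-8")
        except UnicodeDecodeError:
            return None

    def json(self):
        return json.loads(self.body.decode("utf-8"))


@dataclass
class FetchPolicy:
    """Retry, redirect and deadline policy for one logical fetch.

    Retries apply only to connection errors and 5xx responses; 4xx responses
    are returned verbatim (the caller interprets them).
    """

    timeout: float = DEFAULT_DISCOVERY_TIMEOUT
    retries: int = 2
    backoffs: tuple[float, ...] = (0.5, 1.0)
    max_redirects: int = 5
    sleep: Callable[[float], None] = field(default=time.sleep, repr=False)


class _BoundedRedirectHandler(urllib.request.HTTPRedirectHandler):
    def __init__(self, limit: int):
        self.limit = limit
        self.seen = 0

    def redirect_request(self, req, fp, code, msg, headers, newurl):
        self.seen += 1
        if self.seen > self.limit:
            raise urllib.error.URLError(f"more than {self.limit} redirects")
        return super().redirect_request(req, fp, code, msg, headers, newurl)


def fetch(
    url: str,
    method: str = "GET",
    params: Mapping[str, object] | None = None,
    json_body: Mapping[str, object] | None = None,
    headers: Mapping[str, str] | None = None,
    policy: FetchPolicy | None = None,
) -> HttpResult:
    """Perform one HTTP exchange under ``policy``.

    GET/DELETE parameters are URL-encoded into the query string; a
    ``json_body`` is serialized as a JSON request body. 5xx responses and
    connection errors are retried per the policy; the final failure raises
    :class:`NetworkError` or :class:`FetchTimeoutError`.
    """
    policy = policy or FetchPolicy()
    if params:
        encoded = urllib.parse.urlencode({k: str(v) for k, v in params.items()})
        sep = "&" if urllib.parse.urlparse(url).query else "?"
        url = f"{url}{sep}{encoded}"
    data = None
    req_headers = dict(headers or {})
    if json_body is not None:
        data = json.dumps(json_body).encode("utf-8")
        req_headers.setdefault("Content-Type", "application/json")

    attempts = policy.retries + 1
    last_exc: Exception | None = None
    for attempt in range(attempts):
        opener = urllib.request.build_opener(_BoundedRedirectHandler(policy.max_redirects))
        request = urllib.request.Request(url, data=data, headers=req_headers, method=method)
        start = time.monotonic()
        try:
            with opener.open(request, timeout=policy.timeout) as resp:
                body = resp.read()
                return HttpResult(
                    status_code=resp.status,
                    headers={k.lower(): v for k, v in resp.headers.items()},
                    body=body,
                    elapsed=time.monotonic() - start,
                    url=resp.geturl(),
                )
        except urllib.error.HTTPError as exc:
            body = exc.read()
            result = HttpResult(
                status_code=exc.code,
                headers={k.lower(): v for k, v in exc.headers.items()},
                body=body,
                elapsed=time.monotonic() - start,
                url=url,
            )
            if exc.code < 500:
                return result
            last_exc = exc
            last_result = result
        except (TimeoutError, socket.timeout) as exc:
            raise FetchTimeoutError(f"request to {url} exceeded {policy.timeout}s") from exc
        except urllib.error.URLError as exc:
            if isinstance(exc.reason, (TimeoutError, socket.timeout)):
                raise FetchTimeoutError(f"request to {url} exceeded {policy.timeout}s") from exc
            last_exc = exc
            last_result = None
        if attempt < attempts - 1:
            idx = min(attempt, len(policy.backoffs) - 1)
            if policy.backoffs:
                policy.sleep(policy.backoffs[idx])
    if last_result is not None:
        return last_result  # exhausted retries on 5xx: surface the final response
    raise NetworkError(f"request to {url} failed after {attempts} attempts: {last_exc}")
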