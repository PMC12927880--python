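"""ESearch/ESummary client with retmode fallback and an error taxonomy.

Responses are requested as JSON and re-parsed as XML when the JSON parse
fails (older mirrors and some error pages answer XML regardless of the
requested retmode). An empty UID list is a normal result, structurally
distinct from an :class:`UpstreamError`.
"""

from __future__ import annotations

import json
import urllib.parse
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from ..errors import ParseError, UpstreamError
from ..http_util import FetchPolicy, fetch
from .config import EutilsConfig
from .ratelimit import RateLimiter

GEO_DATABASES = ("gds", "geoprofiles")


class EsearchRequest(BaseModel):
    """One ESearch query against a GEO database."""

    model_config = ConfigDict(frozen=True)

    db: Literal["gds", "geoprofiles"] = "gds"
    term: str = Field(min_length=1)
    retmax: int = Field(default=20, ge=1)
    retstart: int = Field(default=0, ge=0)


@dataclass(frozen=True)
class EsearchResult:
    """UID list for a query; ``uids`` may be empty without error."""

    count: int
    uids: tuple[str, ...]
    translated_query: Optional[str] = None


@dataclass(frozen=True)
class EsummaryRecord:
    """Per-UID document summary projected to the fields the tools use."""

    uid: str
    accession: str
    title: str = ""
    summary: str = ""
    organism: Optional[str] = None
    entry_type: Optional[str] = None

    @property
    def accession_kind(self) -> str:
        """series|samples|platforms|datasets|other by accession prefix."""
        prefix = self.accession.strip().upper()[:3]
        return {
            "GSE": "series",
            "GSM": "samples",
            "GPL": "platforms",
            "GDS": "datasets",
        }.get(prefix, "other")


def build_esearch_url(req: EsearchRequest, cfg: EutilsConfig) -> str:
    """Deterministic, percent-encoded ESearch URL (pure request construction)."""
    params = {
        "db": req.db,
        "term": req.term,
        "retmax": str(req.retmax),
        "retstart": str(req.retstart),
        "retmode": "json",
        "email": cfg.email,
    }
    if cfg.api_key:
        params["api_key"] = cfg.api_key
    return f"{cfg.base_url}/esearch.fcgi?{urllib.parse.urlencode(params)}"


def _search_policy(cfg: EutilsConfig) -> FetchPolicy:
    # one retry on 5xx/connection error, then UpstreamError
    return FetchPolicy(timeout=cfg.timeouts["search"], retries=1, backoffs=(0.5,))


def _parse_esearch_body(body: bytes) -> EsearchResult:
    try:
        data = json.loads(body)
        res = data["esearchresult"]
        return EsearchResult(
            count=int(res["count"]),
            uids=tuple(str(u) for u in res.get("idlist", [])),
            translated_query=res.get("querytranslation"),
        )
    except (json.JSONDecodeError, KeyError, TypeError, ValueError):
        pass
    try:
        root = ET.fromstring(body)
        count = int(root.findtext("Count", default="0"))
        uids = tuple(el.text or "" for el in root.findall("IdList/Id"))
        return EsearchResult(count=count, uids=uids, translated_query=root.findtext("QueryTranslation"))
    except ET.ParseError as exc:
        raise ParseError(f"ESearch body is neither JSON nor XML: {exc}") from exc


def _record_from_json(uid: str, item: dict) -> EsummaryRecord:
    return EsummaryRecord(
        uid=uid,
        accession=str(item.get("accession", "")).strip().upper(),
        title=str(item.get("title", "")),
        summary=str(item.get("summary", "")),
        organism=item.get("taxon") or item.get("organism"),
        entry_type=item.get("entrytype"),
    )


def _parse_esummary_body(body: bytes, requested: Sequence[str]) -> tuple[list[EsummaryRecord], list[str]]:
    try:
        data = json.loads(body)
        result = data["result"]
        records, missing = [], []
        for uid in requested:
            item = result.get(str(uid))
            if isinstance(item, dict) and "error" not in item:
                records.append(_record_from_json(str(uid), item))
            else:
                missing.append(str(uid))
        return records, missing
    except (json.JSONDecodeError, KeyError, TypeError):
        pass
    try:
        root = ET.fromstring(body)
    except ET.ParseError as exc:
        raise ParseError(f"ESummary body is neither JSON nor XML: {exc}") from exc
    by_uid: dict[str, EsummaryRecord] = {}
    for docsum in root.findall("DocSum"):
        uid = docsum.findtext("Id", default="")
        items = {
            el.get("Name"): (el.text or "")
            for el in docsum.findall("Item")
        }
        by_uid[uid] = EsummaryRecord(
            uid=uid,
            accession=items.get("Accession", "").strip().upper(),
            title=items.get("title", ""),
            summary=items.get("summary", ""),
            organism=items.get("taxon"),
            entry_type=items.get("entryType"),
        )
    records = [by_uid[str(u)] for u in requested if str(u) in by_uid]
    missing = [str(u) for u in requested if str(u) not in by_uid]
    return records, missing


@dataclass
class EutilsClient:
    """Stateful client pairing a config with one shared rate limiter."""

    cfg: EutilsConfig
    limiter: RateLimiter = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.limiter is None:
            self.limiter = RateLimiter(
                min_interval=self.cfg.min_interval,
                ceiling=self.cfg.rps_ceiling_with_key,
                keyed=self.cfg.keyed,
            )

    def esearch(self, req: EsearchRequest) -> EsearchResult:
        self.limiter.wait_for_slot()
        return esearch(req, self.cfg)

    def esummary(self, uids: Sequence[str], db: str = "gds") -> tuple[list[EsummaryRecord], list[str]]:
        self.limiter.wait_for_slot()
        return esummary(uids, db, self.cfg)


def esearch(req: EsearchRequest, cfg: EutilsConfig) -> EsearchResult:
    """Issue one ESearch GET; an empty UID list is a normal outcome.

    The caller is responsible for rate-limit slot acquisition (see
    :class:`EutilsClient` for the batteries-included path).
    """
    result = fetch(build_esearch_url(req, cfg), policy=_search_policy(cfg))
    if result.status_code >= 300:
        raise UpstreamError(
            f"ESearch answered HTTP {result.status_code} for term {req.term!r}",
            status_code=result.status_code,
        )
    parsed = _parse_esearch_body(result.body)
    if len(parsed.uids) > req.retmax:
        parsed = EsearchResult(parsed.count, parsed.uids[: req.retmax], parsed.translated_query)
    return parsed


def esummary(
    uids: Sequence[str], db: str, cfg: EutilsConfig
) -> tuple[list[EsummaryRecord], list[str]]:
    """One batched ESummary request.

    Returns ``(records, unresolved)``: one record per resolvable UID in the
    requested order, plus the UIDs the upstream could not resolve (reported,
    never dropped silently).
    """
    if not uids:
        raise ValueError("esummary requires a non-empty uid list")
    params = {
        "db": db,
        "id": ",".join(str(u) for u in uids),
        "retmode": "json",
        "email": cfg.email,
    }
    if cfg.api_key:
        params["api_key"] = cfg.api_key
    url = f"{cfg.base_url}/esummary.fcgi?{urllib.parse.urlencode(params)}"
    result = fetch(url, policy=_search_policy(cfg))
    if result.status_code >= 300:
        raise UpstreamError(
            f"ESummary answered HTTP {result.status_code} for {len(uids)} uid(s)",
            status_code=result.status_code,
        )
    return _parse_esummary_body(result.body, [str(u) for u in uids])
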