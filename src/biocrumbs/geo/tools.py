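"""The eight GEO tools: six targeted searches plus two download-management
tools, with accession categorization and response wrapping.

Search dispatch rewrites the query per tool: record-type-targeted tools
append a GEO entry-type filter for the ``gds`` database, while the profiles
tool routes to the ``geoprofiles`` database. A search returning zero UIDs is
a well-formed zero-hit response, never an error.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

from ..errors import NotFoundError
from ..eutils.client import EsearchRequest, EsummaryRecord, EutilsClient
from ..eutils.config import EutilsConfig
from ..registry import (
    ToolDescriptor,
    ToolRegistry,
    ToolResponse,
    error_response,
    wrap_response,
)

if TYPE_CHECKING:
    from ..downloads.manager import DownloadManager

DEFAULT_RETMAX = 20
RETMAX_CAP = 500

SEARCH_TOOL_NAMES = (
    "search_geo",
    "search_geo_profiles",
    "search_geo_datasets",
    "search_geo_series",
    "search_geo_samples",
    "search_geo_platforms",
)
DOWNLOAD_TOOL_NAMES = ("download_geo_data", "get_download_status")
GEO_TOOL_NAMES = SEARCH_TOOL_NAMES + DOWNLOAD_TOOL_NAMES

# tool -> (database, entry-type filter appended to the term; None = verbatim)
_SEARCH_ROUTING: dict[str, tuple[str, str | None]] = {
    "search_geo": ("gds", None),
    "search_geo_profiles": ("geoprofiles", None),
    "search_geo_datasets": ("gds", "gds[Entry Type]"),
    "search_geo_series": ("gds", "gse[Entry Type]"),
    "search_geo_samples": ("gds", "gsm[Entry Type]"),
    "search_geo_platforms": ("gds", "gpl[Entry Type]"),
}

_BUCKETS = ("series", "samples", "platforms", "datasets", "other")
_PREFIX_TO_BUCKET = {"GSE": "series", "GSM": "samples", "GPL": "platforms", "GDS": "datasets"}


@dataclass
class CategorizedResults:
    """GEO records partitioned by accession prefix; buckets are disjoint."""

    series: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    platforms: list = field(default_factory=list)
    datasets: list = field(default_factory=list)
    other: list = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {b: len(getattr(self, b)) for b in _BUCKETS}

    def to_payload(self) -> dict:
        def item(entry):
            return asdict(entry) if isinstance(entry, EsummaryRecord) else entry

        return {b: [item(e) for e in getattr(self, b)] for b in _BUCKETS}


def categorize_accessions(accessions: Iterable) -> CategorizedResults:
    """Partition accessions (strings or records) into the five GEO buckets.

    Matching is on the trimmed, uppercased form: GSE→series, GSM→samples,
    GPL→platforms, GDS→datasets, anything else→other. Total: never raises.
    """
    result = CategorizedResults()
    for entry in accessions:
        key = entry.accession if isinstance(entry, EsummaryRecord) else str(entry)
        canonical = key.strip().upper()
        bucket = _PREFIX_TO_BUCKET.get(canonical[:3], "other")
        getattr(result, bucket).append(entry)
    return result


def _search_descriptor(name: str, target: str) -> ToolDescriptor:
    return ToolDescriptor(
        name=name,
        description=f"Search NCBI GEO for {target}. Returns UIDs with "
        "record summaries categorized by accession type.",
        input_schema={
            "type": "object",
            "properties": {
                "term": {"type": "string", "description": "Entrez query term"},
                "retmax": {
                    "type": "integer",
                    "description": f"Maximum records (default {DEFAULT_RETMAX}, cap {RETMAX_CAP})",
                    "minimum": 1,
                    "maximum": RETMAX_CAP,
                },
            },
            "required": ["term"],
        },
        output_schema={
            "type": "object",
            "properties": {
                "count": {"type": "integer"},
                "uids": {"type": "array", "items": {"type": "string"}},
                "categorized": {"type": "object"},
            },
            "required": ["count", "uids", "categorized"],
        },
        concepts=("search_data",),
    )


def _download_descriptors() -> list[ToolDescriptor]:
    return [
        ToolDescriptor(
            name="download_geo_data",
            description="Download the SOFT family archive and XML metadata for "
            "a GEO accession under the configured safety policy "
            "(size limits, disk check, bounded concurrency).",
            input_schema={
                "type": "object",
                "properties": {
                    "accession": {"type": "string", "description": "GSE/GSM/GPL/GDS accession"},
                },
                "required": ["accession"],
            },
            output_schema={
                "type": "object",
                "properties": {"job_id": {"type": "string"}, "state": {"type": "string"}},
                "required": ["job_id", "state"],
            },
            concepts=("download_file",),
        ),
        ToolDescriptor(
            name="get_download_status",
            description="Report the state and byte progress of one download "
            "job, or of all known jobs when no id is given.",
            input_schema={
                "type": "object",
                "properties": {
                    "job_id": {"type": "string", "description": "Omit for all jobs"},
                },
                "required": [],
            },
            output_schema={
                "type": "object",
                "properties": {"jobs": {"type": "array"}},
                "required": ["jobs"],
            },
            concepts=("download_status",),
        ),
    ]


_TARGETS = {
    "search_geo": "any record type (series, samples, platforms, curated datasets)",
    "search_geo_profiles": "gene expression profiles",
    "search_geo_datasets": "curated datasets (GDS)",
    "search_geo_series": "experimental series (GSE)",
    "search_geo_samples": "individual samples (GSM)",
    "search_geo_platforms": "platform definitions (GPL)",
}

_DESCRIPTORS: tuple[ToolDescriptor, ...] = tuple(
    [_search_descriptor(name, _TARGETS[name]) for name in SEARCH_TOOL_NAMES]
    + _download_descriptors()
)


def list_tools() -> list[ToolDescriptor]:
    """The eight-tool registry, constant across calls and transports."""
    return list(_DESCRIPTORS)


def _rewrite_term(tool_name: str, term: str) -> tuple[str, str]:
    db, entry_filter = _SEARCH_ROUTING[tool_name]
    if entry_filter:
        return db, f"({term}) AND {entry_filter}"
    return db, term


def run_search_tool(
    tool_name: str,
    term: str,
    retmax: int = DEFAULT_RETMAX,
    cfg: EutilsConfig | None = None,
    client: EutilsClient | None = None,
) -> ToolResponse:
    """Dispatch one search tool call: ESearch, then one ESummary batch when
    UIDs exist, then categorize and wrap.

    Upstream failures surface as structured error responses.
    """
    if tool_name not in SEARCH_TOOL_NAMES:
        raise NotFoundError(f"unknown search tool: {tool_name}")
    if not term or not str(term).strip():
        return error_response("parameter 'term' is required and must be non-empty", "invalid_params")
    retmax = int(retmax)
    if not 1 <= retmax <= RETMAX_CAP:
        return error_response(
            f"retmax must be between 1 and {RETMAX_CAP}, got {retmax}", "invalid_params"
        )
    if client is None:
        client = EutilsClient(cfg or EutilsConfig())

    db, routed_term = _rewrite_term(tool_name, str(term))
    result = client.esearch(EsearchRequest(db=db, term=routed_term, retmax=retmax))

    records: list[EsummaryRecord] = []
    unresolved: list[str] = []
    if result.uids:
        records, unresolved = client.esummary(result.uids, db=db)
    categorized = categorize_accessions(records)

    payload = {
        "tool": tool_name,
        "db": db,
        "term": str(term),
        "count": result.count,
        "uids": list(result.uids),
        "categorized": categorized.to_payload(),
        "unresolved_uids": unresolved,
    }
    if not result.uids:
        summary = f"0 results for {term!r} in {db} (empty id list; not an error)"
    else:
        sizes = ", ".join(f"{k}: {v}" for k, v in categorized.sizes().items() if v)
        summary = f"{len(result.uids)} of {result.count} result(s) for {term!r} in {db} ({sizes})"
    return wrap_response(payload, summary=summary)


def build_geo_registry(
    cfg: EutilsConfig | None = None,
    client: EutilsClient | None = None,
    manager: "DownloadManager | None" = None,
) -> ToolRegistry:
    """Wire the eight descriptors to live handlers.

    Download tools require a :class:`DownloadManager`; without one they
    answer with a structured configuration error (search tools still work,
    which keeps read-only deployments possible).
    """
    cfg = cfg or EutilsConfig()
    the_client = client or EutilsClient(cfg)

    def search_handler(tool_name: str):
        def handle(args: Mapping) -> ToolResponse:
            return run_search_tool(
                tool_name,
                term=args.get("term", ""),
                retmax=args.get("retmax", DEFAULT_RETMAX),
                client=the_client,
            )

        return handle

    def download_handler(args: Mapping) -> ToolResponse:
        if manager is None:
            return error_response("download manager not configured", "configuration")
        accession = str(args.get("accession", "")).strip().upper()
        job = manager.download_geo_data(accession)
        return wrap_response(
            {"job_id": job.job_id, "accession": job.accession, "state": job.state},
            summary=f"download {job.state} for {job.accession} (job {job.job_id})",
        )

    def status_handler(args: Mapping) -> ToolResponse:
        if manager is None:
            return error_response("download manager not configured", "configuration")
        job_id = args.get("job_id")
        statuses = manager.get_download_status(job_id)
        payload = {"jobs": statuses}
        return wrap_response(payload, summary=f"{len(statuses)} job(s)")

    handlers = {name: search_handler(name) for name in SEARCH_TOOL_NAMES}
    handlers["download_geo_data"] = download_handler
    handlers["get_download_status"] = status_handler
    return ToolRegistry(name="geo", descriptors=_DESCRIPTORS, handlers=handlers)
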