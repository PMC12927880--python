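# Methods

This note documents the protocols, defaults and design choices behind
`biocrumbs`: what is normative, what is configurable, and what the offline
test harness does and does not demonstrate.

## Breadcrumb format

A breadcrumb is an HTML comment whose first non-whitespace token is the
sentinel `mcp-breadcrumb`, followed by a single JSON object. The grammar is
deliberately regex-extractable (`<!--\s*mcp-breadcrumb\b(.*?)-->`): the
format targets existing, often static, service pages where asking operators
to run a parser-friendly templating pipeline is unrealistic. Canonical keys
are `service.{name,version}`, `mcp_available.{status,redirect_url}` and
`endpoints[].{method,url,concept,concept_iris,params,example}`.

Validation is all-or-nothing: a document with any invalid field yields no
partial result, and the error names every violated field path (so an agent
can report precisely what is wrong). pydantic v2 implements the schema;
unknown extra keys are ignored for forward compatibility, while required
fields, closed enumerations (HTTP verbs, parameter value types), the
redirect-URL obligation when `status` is true, and per-endpoint parameter
name uniqueness are enforced.

Two hazards of comment-embedded JSON are handled explicitly:

* **Comment-terminator corruption.** A payload string containing `-->`
  would end the comment early. The embedder rewrites `-->` to `--\u003e`
  inside the serialized payload; since a bare `>` cannot occur outside JSON
  string literals, the substitution is loss-free and `json.loads` restores
  the original text. Round-trip identity is property-tested over randomized
  documents with hostile descriptions.
* **Redundant copies.** Pages may carry several breadcrumbs. The first
  candidate that parses and validates wins, deterministically; trailing
  candidates are ignored. A page whose candidates are all malformed yields
  a validation error naming the first failure.

`concept` is a plain string tag with an optional `concept_iris` list for
ontology identifiers. Membership in a controlled vocabulary (EDAM,
Bioschemas, Schema.org) is intentionally not enforced: the tags are
attachment points, and enforcing a vocabulary at the format layer would
couple the format to one ontology's release cycle.

## Discovery ladder

`decide` is a pure, total function from page text to exactly one of four
outcomes, in strict priority order: `McpRedirect` (when
`mcp_available.status` is true — even if fallback endpoints are also
present), `ApiSpecification` (valid endpoints, status false),
`DiscoveryError` (breadcrumbs present but unusable), and
`ManualExplorationRequired` (no breadcrumbs at all). Malformed-but-present
dominating absent matters operationally: a broken breadcrumb is a service
bug someone should hear about, not a reason to pretend the page was bare.

`discover` wraps `decide` with the network policy: 10 s deadline, at most
5 HTTP redirects, and 2 retries with exponential backoff (0.5 s, 1 s)
applied only to connection errors and 5xx responses — bounded worst-case
latency while still absorbing transient failures. `execute_endpoint`
(30 s default deadline, no retries) serializes parameters by verb:
query-string pairs for GET/DELETE, a JSON body for POST/PUT; other verbs
are rejected. JSON (rather than form encoding) for POST bodies is a
normative choice here. Responses, including 401/403, are returned verbatim:
breadcrumbs document that authentication exists but cannot perform it.

## E-utilities client and rate limiting

Configuration lives in JSON at `~/.geo-mcp/config.json`. Loading never
aborts startup: a missing file produces full defaults plus a warning, a
partially invalid file has the offending fields replaced by defaults
(warned, and flagged in `/health`); only a wholly undecodable file raises.
The `email` field is required by NCBI on every request; the placeholder
default exists so the offline harness works, and the warning tells
operators to set a real address.

Rate limiting enforces two constraints jointly: consecutive requests are
spaced at least `min_interval` = 0.1 s apart, and with an API key at most
10 grants fall in any sliding 1-second window. The 0.1 s interval already
implies ≤ 10 requests per second, so the window ceiling only binds if an
operator lowers the interval; both knobs are kept because they express
different upstream obligations (politeness spacing vs. a hard keyed
allowance). NCBI's published unkeyed allowance is 3 requests/second, which
is stricter than a blanket 0.1 s spacing; the interval is
operator-configurable upward for deployments that need strict unkeyed
compliance, and the default follows the 0.1 s convention. The scheduling
core (`acquire_slot`) is a pure function over explicit state and a
caller-supplied monotonic timestamp, tested against a brute-force
earliest-feasible-slot scanner on an exact centisecond grid — no wall-clock
sleeps in tests.

ESearch/ESummary are requested with `retmode=json` and fall back to XML
parsing when the JSON parse fails. An empty UID list is a normal result,
structurally distinct from an upstream error; tool responses say "0
results … not an error" explicitly because agent loops treat the two very
differently (reformulate vs. back off). ESummary reports unresolvable UIDs
in a side list rather than dropping them. Each request gets one retry on
5xx/connection failure, then raises.

## GEO tool suite

The registry holds exactly eight descriptors. Search tools rewrite queries
per target: profiles route to the `geoprofiles` database; series, samples,
platforms and curated datasets stay on `gds` with an appended entry-type
filter (`gse[Entry Type]` etc.); the universal `search_geo` passes the term
through. `retmax` defaults to 20 with a hard cap of 500 per call. When a
search returns UIDs, exactly one batched ESummary call enriches them (two
upstream calls per tool call, deterministic), and records are partitioned
into five buckets by the trimmed, uppercased accession prefix. The
partition is total and exact by construction and is fuzz-tested for
disjointness and exhaustiveness. Categorization keys on ESummary accession
strings, not numeric UIDs, whose prefix semantics are undocumented.

Responses wrap a canonical-JSON payload under a one-line human-readable
summary (MCP text content). The payload always round-trips:
`ContentBlock.parse(block.text)` recovers it exactly.

## Download safety

Admission is decided before any byte is written, checking three
inequalities in fixed order — per-file limit (5 GB), total storage budget
(10 GB, measured by an on-disk scan of the download root so the budget is a
storage property that survives restarts), and free disk space (advertised
size plus a 100 MB margin). The advertised size comes from a HEAD request;
servers that advertise nothing are admitted conservatively, and the
transfer is aborted the moment written bytes exceed the per-file limit.
Partial files are written to a `.part` name and removed on failure, so a
rejected or failed job leaves zero bytes. Target paths are confined
lexically to the download root (`validate_path` normalizes relative
segments without touching the filesystem, since the path may not exist
yet); escapes raise a security error, fuzz-tested against an independent
canonicalization oracle. Transfers run on worker threads behind a
semaphore (three by default) — the observable contract is the concurrency
bound, and a thread pool meets it with far less machinery than an async
reactor while keeping the manager usable from synchronous tool handlers.
Each completed job stores `family.soft.gz` plus a `metadata.xml` rendered
from the accession's ESummary record (best-effort; the archive is the
primary artifact). Metadata files count toward the storage budget
(conservative reading of the limit).

The archive URL template is configurable (defaulting to the GEO FTP series
layout) so tests point it at the local mock file server; the live layout is
deliberately outside the test surface.

The SOFT reader covers the family-file subset: `^` entity headers, `!`
attributes (accumulating repeated keys), `#` column definitions, and
tab-separated table rows between `table_begin`/`table_end` markers.
Structurally impossible input (an attribute before any entity) raises with
the line number. A paired writer exists so the generator→writer→reader
round-trip is testable exactly; the reader is not a general GEO parser.

## Transports

Both servers expose the same registry object over MCP stdio
(newline-delimited JSON-RPC 2.0; protocol version pinned to `2024-11-05`)
and an HTTP gateway (`POST /tools/<name>` with a JSON body mirroring the
tool's input schema, plus `/tools`, `/openapi.json`, `/health`, `/events`).
Transport equivalence — payload-identical results for the same call — is
asserted in tests. Tool-level failures become structured error responses;
malformed frames get JSON-RPC protocol errors; the process only exits on a
closed input stream. The SSE route emits a job snapshot on every
state/byte change and at a 1 s heartbeat while jobs run, then a terminal
`stream_end` frame once no job is active. The HTTP mode exposes download
tools as well as search, keeping the two transports' registries identical.
Both servers are implemented on the standard library's threading HTTP
server and a hand-rolled JSON-RPC loop, keeping the deployment surface
dependency-free.

## Mock harness

The harness emulates the three external surfaces: (i) deterministic
scenario pages — no breadcrumb, valid endpoints, truncated-JSON breadcrumb,
native-MCP redirect, plus a hybrid (endpoints and status true) that pins
the ladder's priority; (ii) a scripted E-utilities backend mapping terms to
UID lists and UIDs to summary records, with FIFO failure injections
(status, body, delay) that make retry schedules observable; (iii) a file
server whose advertised content length is spoofable independently of the
bytes served — multi-gigabyte limits are exercised with headers, never
materialized payloads — with per-chunk delays so the concurrency bound is
measurable. The default script reproduces an autonomous-refinement search
session: four specific terms answer empty lists, the broad term
"microglia depletion" answers UIDs beginning 200299005, 200279739, mapped
to mouse-brain series records (GSE299005, GSE279739, GSE271535, …). The
UID→accession pairing is a harness convention chosen for plausibility.

What passing tests show: the protocol logic — validation, the ladder,
scheduling, admission, categorization, framing — is correct against
faithful local emulations. What they do not show: behavior against live
NCBI quirks (rate-limit headers, maintenance pages, schema drift),
JavaScript-rendered pages (out of scope for comment extraction), or
real multi-gigabyte transfer performance.

## Numerical and sizing choices

Test and acceptance problem sizes (hundreds of fuzz cases per oracle,
tens of property examples, kilobyte-scale mock payloads) are chosen so the
whole suite runs in well under a minute on one CPU while every code path —
including retries, aborts and concurrency — is still exercised; agreement
rates at these sizes are already exact (1.0), so larger samples would add
runtime, not information. Timeouts in tests are shortened via injected
policies rather than by changing defaults, so the printed defaults remain
the tested configuration surface.

## Known limitations

* Breadcrumb extraction is regex-based by design and inherits the format's
  fragility to dynamic content generation.
* No authentication flows, cookies or OAuth; no resumable downloads,
  supplementary-file retrieval or checksum verification.
* Concept tags are uncontrolled strings; ontology alignment is carried but
  not validated.
* No provenance/audit logging of tool invocations.
* The HTTP mode has no authentication or TLS; it is intended to sit behind
  a reverse proxy in real deployments.
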