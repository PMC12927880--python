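# biocrumbs

A machine-actionable service layer for bioinformatics web resources, built
around the Model Context Protocol (MCP). Most bioinformatics web servers are
designed for human readers; autonomous research agents built on large
language models need machine-readable contracts instead. `biocrumbs`
provides two such contracts, plus everything needed to test them offline:

1. **Breadcrumbs** — a lightweight JSON metadata format embedded as HTML
   comments in service pages. A breadcrumb advertises the service's identity
   (`service.name`, `service.version`), whether a native MCP endpoint exists
   (`mcp_available.status`, with a `redirect_url`), and a list of fallback
   API endpoints, each carrying an HTTP method, a semantic concept tag
   (e.g. `search_data`, `download_file`), typed parameter schemas and an
   example URL. A three-tool discovery server applies a strict **graceful
   degradation ladder** to any URL:

   * native MCP advertised → redirect recommendation (highest priority),
   * valid endpoint breadcrumbs → reconstructed API documentation,
   * no breadcrumbs → "manual exploration required" notice,
   * breadcrumbs present but malformed → informative validation error,
     never a silent failure.

2. **A GEO MCP tool suite** — eight tools over NCBI's Gene Expression
   Omnibus via the E-utilities API: six targeted searches (`search_geo`,
   `search_geo_profiles`, `search_geo_datasets`, `search_geo_series`,
   `search_geo_samples`, `search_geo_platforms`) that route queries to the
   `gds`/`geoprofiles` databases with entry-type filters and categorize
   results by accession prefix (GSE→series, GSM→samples, GPL→platforms,
   GDS→datasets), and two data-management tools (`download_geo_data`,
   `get_download_status`) that retrieve SOFT family archives under safety
   controls: path confinement, 5 GB per-file / 10 GB total storage limits,
   disk-space verification, at most three parallel transfers, and a 300 s
   transfer timeout. Requests are spaced 0.1 s apart for NCBI compliance,
   with a 10 requests/second ceiling when an API key is configured.

Both tool registries serve over two transports with identical
advertisements: MCP **stdio** (newline-delimited JSON-RPC) for desktop MCP
clients, and an **HTTP gateway** with OpenAPI documentation, CORS headers,
Server-Sent Events for download progress, and a `/health` probe.

A bundled **mock harness** (`biocrumbs.mock`) emulates service pages in the
four discovery scenarios, a scripted E-utilities backend, and a controllable
file server (spoofable content length, per-chunk delays), so the entire
package is testable with no network access.

## Worked example

Search the scripted GEO backend and inspect the categorized result:

```python
from biocrumbs.eutils.client import EutilsClient
from biocrumbs.eutils.config import EutilsConfig
from biocrumbs.geo.tools import build_geo_registry
from biocrumbs.mock.eutils_mock import MockEutilsServer, default_transcript_script
from biocrumbs.registry import ContentBlock

with MockEutilsServer(default_transcript_script()) as server:
    cfg = EutilsConfig(email="you@lab.org", base_url=server.base_url)
    registry = build_geo_registry(client=EutilsClient(cfg))

    r = registry.call("search_geo", {"term": "microglia depletion mouse", "retmax": 5})
    print(r.content[0].summary)
    r = registry.call("search_geo", {"term": "microglia depletion", "retmax": 10})
    print(r.content[0].summary)
    payload = ContentBlock.parse(r.content[0].text)
    print(payload["uids"][:2])
```

prints

```
0 results for 'microglia depletion mouse' in gds (empty id list; not an error)
6 of 6 result(s) for 'microglia depletion' in gds (series: 6)
['200299005', '200279739']
```

The first line shows empty-result neutrality: a query with no hits is a
well-formed zero-hit response that an agent can react to by reformulating,
not an error. The second query returns six UIDs, all categorized into the
series bucket (their summaries carry GSE accessions such as GSE271535).

Run the servers from a shell:

```bash
biocrumbs geo stdio          # MCP stdio mode for desktop clients
biocrumbs geo http --port 8080
biocrumbs crumbs stdio       # breadcrumb discovery server
```

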