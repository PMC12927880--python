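"""Deterministic breadcrumb scenario pages.

The four kinds map one-to-one onto the discovery validation matrix:
``none`` → manual exploration, ``valid`` → API specification, ``malformed``
→ informative discovery error, ``redirect`` → native-MCP redirect. A fifth
``hybrid`` kind (valid endpoints AND status true) exercises ladder priority.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from ..breadcrumbs.comment import SENTINEL, render_comment
from ..breadcrumbs.model import (
    BreadcrumbDocument,
    EndpointSpec,
    McpAvailability,
    ParameterSpec,
    ServiceIdentity,
)

SCENARIO_KINDS = ("none", "valid", "malformed", "redirect")

_EXPECTED = {
    "none": "ManualExplorationRequired",
    "valid": "ApiSpecification",
    "malformed": "DiscoveryError",
    "redirect": "McpRedirect",
    "hybrid": "McpRedirect",
}


@dataclass(frozen=True)
class Scenario:
    kind: str
    page: str
    expected_outcome: str


def example_document(mcp_available: bool = False) -> BreadcrumbDocument:
    """A small transcriptomics-flavoured service description."""
    availability = (
        McpAvailability(status=True, redirect_url="https://example.org/mcp")
        if mcp_available
        else McpAvailability(status=False)
    )
    return BreadcrumbDocument(
        service=ServiceIdentity(name="ExampleExpressionAtlas", version="2.1.0"),
        mcp_available=availability,
        endpoints=[
            EndpointSpec(
                method="GET",
                url="/api/search",
                concept="search_data",
                params=[
                    ParameterSpec(name="gene", value_type="string", required=True,
                                  description="Gene symbol"),
                    ParameterSpec(name="limit", value_type="integer", required=False),
                ],
                example="/api/search?gene=BDNF&limit=5",
            ),
            EndpointSpec(
                method="GET",
                url="/api/download",
                concept="download_file",
                params=[
                    ParameterSpec(name="dataset", value_type="string", required=True),
                ],
            ),
        ],
    )


def _html(body_comment: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><title>Example Expression Atlas</title></head>\n"
        "<body>\n<h1>Example Expression Atlas</h1>\n"
        "<p>Interactive exploration of curated expression datasets.</p>\n"
        f"{body_comment}\n"
        "</body></html>\n"
    )


def build_page(kind: str) -> Scenario:
    """Deterministic page text for one scenario kind (plus ``hybrid``)."""
    if kind == "none":
        return Scenario(kind, _html(""), _EXPECTED[kind])
    if kind == "valid":
        comment = render_comment(example_document(mcp_available=False))
        return Scenario(kind, _html(comment), _EXPECTED[kind])
    if kind == "malformed":
        truncated = json.dumps(example_document().to_mapping())[:-25]
        comment = f"<!-- {SENTINEL}\n{truncated}\n-->"
        return Scenario(kind, _html(comment), _EXPECTED[kind])
    if kind == "redirect":
        doc = BreadcrumbDocument(
            service=ServiceIdentity(name="ExampleExpressionAtlas", version="2.1.0"),
            mcp_available=McpAvailability(status=True, redirect_url="https://example.org/mcp"),
            endpoints=[],
        )
        return Scenario(kind, _html(render_comment(doc)), _EXPECTED[kind])
    if kind == "hybrid":
        comment = render_comment(example_document(mcp_available=True))
        return Scenario(kind, _html(comment), _EXPECTED[kind])
    raise ValueError(f"unknown scenario kind: {kind!r}")
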