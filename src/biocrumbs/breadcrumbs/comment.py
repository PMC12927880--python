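"""Normative comment grammar: embedding and extraction.

A breadcrumb is an HTML comment whose first non-whitespace token is the
sentinel ``mcp-breadcrumb`` followed by a single JSON object. Extraction is
regex-based and total: it never raises, whatever the input looks like.
"""

from __future__ import annotations

import json
import re

from ..errors import SerializationError
from .model import BreadcrumbDocument

SENTINEL = "mcp-breadcrumb"

# Non-greedy up to the first comment terminator; DOTALL so payloads may span lines.
_COMMENT_RE = re.compile(r"<!--\s*" + re.escape(SENTINEL) + r"\b(.*?)-->", re.DOTALL)

# "-->" can only occur inside JSON string literals, so a textual substitution
# of ">" for its \u escape is loss-free: json.loads maps it straight back.
_TERMINATOR_ESCAPE = ("-->", "--\\u003e")


def render_comment(doc: BreadcrumbDocument) -> str:
    """Serialize ``doc`` as one sentinel-marked HTML comment.

    The JSON payload is canonical (sorted keys, no None-valued optionals) and
    any comment-terminator sequence inside string values is escaped so the
    comment cannot be truncated by an HTML parser.
    """
    payload = json.dumps(doc.to_mapping(), sort_keys=True, ensure_ascii=False)
    payload = payload.replace(*_TERMINATOR_ESCAPE)
    if "-->" in payload:
        raise SerializationError("payload still contains a comment terminator after escaping")
    return f"<!-- {SENTINEL}\n{payload}\n-->"


def extract_candidates(html: str) -> list[str]:
    """Return every sentinel-marked comment payload in document order.

    Total function: arbitrary (even non-markup) text yields a possibly empty
    list, never an exception. Payloads are returned as raw text; parsing and
    validation are the caller's job.
    """
    if not isinstance(html, str):
        try:
            html = html.decode("utf-8", errors="replace")
        except AttributeError:
            return []
    return [m.group(1).strip() for m in _COMMENT_RE.finditer(html)]
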