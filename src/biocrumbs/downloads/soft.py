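"""Minimal reader/writer for GEO's SOFT (Simple Omnibus Format in Text).

SOFT is line-oriented: ``^TYPE = id`` opens an entity, ``!key = value``
attaches an attribute to the most recent entity, ``#column = description``
declares a table column, and unprefixed tab-separated lines are table rows.
This reader covers the family-file subset the download manager retrieves;
it is not a general GEO parser.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import FormatError


@dataclass
class SoftEntity:
    """One ^-delimited entity with its attributes and optional data table."""

    entity_type: str
    entity_id: str
    attributes: dict[str, list[str]] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)
    table: list[list[str]] = field(default_factory=list)

    def attribute(self, key: str) -> str | None:
        values = self.attributes.get(key)
        return values[0] if values else None


@dataclass
class SoftDocument:
    entities: list[SoftEntity] = field(default_factory=list)

    def by_type(self, entity_type: str) -> list[SoftEntity]:
        return [e for e in self.entities if e.entity_type.upper() == entity_type.upper()]


def _split_kv(line: str) -> tuple[str, str]:
    key, sep, value = line.partition("=")
    return key.strip(), value.strip() if sep else ""


def parse_soft_lines(lines) -> SoftDocument:
    doc = SoftDocument()
    current: SoftEntity | None = None
    in_table = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        marker = line[0]
        if marker == "^":
            etype, eid = _split_kv(line[1:])
            if not etype:
                raise FormatError("entity header without a type", lineno)
            current = SoftEntity(entity_type=etype, entity_id=eid)
            doc.entities.append(current)
            in_table = False
        elif marker == "!":
            if current is None:
                raise FormatError("attribute line before any entity header", lineno)
            key, value = _split_kv(line[1:])
            if key.endswith("_table_begin"):
                in_table = True
            elif key.endswith("_table_end"):
                in_table = False
            else:
                current.attributes.setdefault(key, []).append(value)
        elif marker == "#":
            if current is None:
                raise FormatError("column definition before any entity header", lineno)
            key, _ = _split_kv(line[1:])
            current.columns.append(key)
        else:
            if current is None:
                raise FormatError("data row before any entity header", lineno)
            row = line.split("\t")
            if in_table and current.table and len(row) != len(current.table[0]):
                raise FormatError(
                    f"table row has {len(row)} column(s), expected {len(current.table[0])}",
                    lineno,
                )
            if in_table:
                # first in-table row may be a header repeating the # columns
                if not current.table and current.columns and row == current.columns:
                    continue
                current.table.append(row)
            else:
                # unknown line type: preserve raw, keyed by marker
                current.attributes.setdefault("_raw", []).append(line)
    return doc


def read_soft(path: Path | str) -> SoftDocument:
    """Parse a SOFT file (plain text or gzip) into a :class:`SoftDocument`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8", errors="replace") as handle:
        return parse_soft_lines(handle)


def write_soft(doc: SoftDocument, path: Path | str) -> Path:
    """Serialize a document back to SOFT (gzip when the path ends in .gz)."""
    path = Path(path)
    lines: list[str] = []
    for entity in doc.entities:
        lines.append(f"^{entity.entity_type} = {entity.entity_id}")
        for key, values in entity.attributes.items():
            if key == "_raw":
                lines.extend(values)
                continue
            for value in values:
                lines.append(f"!{key} = {value}")
        for col in entity.columns:
            lines.append(f"#{col} = ")
        if entity.table:
            prefix = entity.entity_type.lower()
            lines.append(f"!{prefix}_table_begin")
            lines.extend("\t".join(row) for row in entity.table)
            lines.append(f"!{prefix}_table_end")
    text = "\n".join(lines) + "\n"
    if path.suffix == ".gz":
        with gzip.open(path, "wt", encoding="utf-8") as handle:
            handle.write(text)
    else:
        path.write_text(text, encoding="utf-8")
    return path
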