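"""Execution of extraction specifications against patient summaries.

Two dialects are supported, mirroring the two content models:

* ``path`` — an XPath 1.0 expression evaluated on the CCD-like XML document
  tree; one extracted value per matched node, in document order, grouped by
  the nearest ancestor element carrying an ``ID`` attribute (the clinical
  entry).
* ``graph_pattern`` — a SPARQL SELECT with a basic graph pattern (optional
  equality FILTER) evaluated on the RDF rendering; the query must project
  ``?entry`` and ``?value`` and may project ``?codeSystem``.

Values are coerced to the owning data element's value-domain datatype
(dates ISO-8601, quantities numeric); a coercion failure is a data-quality
error naming the entry.  Zero matches is a legitimate empty result, never an
error: sparse warehouses produce legitimately empty columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from functools import lru_cache
from typing import Any

from lxml import etree
from rdflib.plugins.sparql import prepareQuery

from .errors import DataQualityError, SpecError
from .mdr import DataElement, ExtractionSpec, Registry
from .model import GraphSummary, PatientSummary, XmlSummary, local_id

DOCUMENT_ENTRY = "document"


@dataclass(frozen=True)
class ExtractedValue:
    """One typed value pulled out of a patient summary."""

    entry_id: str
    element_id: str
    value: Any
    code_system_id: str | None = None


@dataclass
class EntryRow:
    """Per-entry join of several elements' extracted values."""

    entry_id: str
    values: dict[str, ExtractedValue | None]


# ---------------------------------------------------------------------------
# dialect executors
# ---------------------------------------------------------------------------


def _nearest_entry_id(node: etree._Element | None) -> str:
    while node is not None:
        entry_id = node.get("ID")
        if entry_id:
            return entry_id
        node = node.getparent()
    return DOCUMENT_ENTRY


def execute_path_spec(
    doc: XmlSummary, spec: ExtractionSpec, element_id: str = ""
) -> list[ExtractedValue]:
    """Evaluate an XPath spec on an XML summary.

    Attribute matches named ``code`` pick up the sibling ``codeSystem``
    attribute as the value's code system.
    """
    if spec.dialect != "path":
        raise SpecError(f"dialect {spec.dialect!r} is not a path dialect")
    try:
        results = doc.root.xpath(spec.script)
    except etree.XPathError as exc:
        raise SpecError(f"malformed XPath script: {exc}") from exc
    if not isinstance(results, list):
        raise SpecError(
            "path spec must select nodes, not a computed "
            f"{type(results).__name__}"
        )
    out: list[ExtractedValue] = []
    for node in results:
        code_system = None
        if hasattr(node, "getparent"):  # attribute or element
            parent = node.getparent()
            if getattr(node, "is_attribute", False):
                raw = str(node)
                if node.attrname == "code" and parent is not None:
                    code_system = parent.get("codeSystem")
                entry_id = _nearest_entry_id(parent)
            else:  # element node: use its text content
                raw = (node.text or "").strip()
                entry_id = _nearest_entry_id(node)
        else:
            raw, entry_id = str(node), DOCUMENT_ENTRY
        out.append(
            ExtractedValue(
                entry_id=entry_id,
                element_id=element_id,
                value=raw,
                code_system_id=code_system,
            )
        )
    return out


@lru_cache(maxsize=256)
def _prepare(script: str):
    try:
        query = prepareQuery(script)
    except Exception as exc:  # rdflib raises several parse error types
        raise SpecError(f"malformed graph-pattern script: {exc}") from exc
    if query.algebra.name != "SelectQuery":
        raise SpecError("graph-pattern spec must be a SELECT query")
    projected = {str(v) for v in query.algebra["PV"]}
    if not {"entry", "value"} <= projected:
        raise SpecError(
            "graph-pattern spec must project ?entry and ?value, "
            f"projects {sorted(projected)}"
        )
    return query


def execute_graph_spec(
    graph: GraphSummary, spec: ExtractionSpec, element_id: str = ""
) -> list[ExtractedValue]:
    """Evaluate a SPARQL basic-graph-pattern spec on a graph summary.

    One value per solution binding; solutions are ordered by (entry id,
    value) for determinism, which is stable across rendering back ends.
    """
    if spec.dialect != "graph_pattern":
        raise SpecError(
            f"dialect {spec.dialect!r} is not a graph-pattern dialect"
        )
    query = _prepare(spec.script)
    out: list[ExtractedValue] = []
    for sol in graph.graph.query(query):
        entry = sol["entry"]
        value = sol["value"]
        if entry is None or value is None:
            continue
        code_system = None
        try:
            if sol["codeSystem"] is not None:
                code_system = str(sol["codeSystem"])
        except KeyError:
            pass
        out.append(
            ExtractedValue(
                entry_id=local_id(str(entry)),
                element_id=element_id,
                value=str(value),
                code_system_id=code_system,
            )
        )
    out.sort(key=lambda v: (v.entry_id, str(v.value)))
    return out


# ---------------------------------------------------------------------------
# typed coercion and element-level extraction
# ---------------------------------------------------------------------------


def coerce_value(raw: Any, element: DataElement, entry_id: str) -> Any:
    datatype = element.value_domain.datatype
    try:
        if datatype == "date":
            return raw if isinstance(raw, date) else date.fromisoformat(
                str(raw)[:10]
            )
        if datatype == "quantity":
            return float(raw)
        if datatype == "boolean":
            text = str(raw).strip().lower()
            if text in ("true", "y", "yes", "1"):
                return True
            if text in ("false", "n", "no", "0"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        return str(raw)
    except (TypeError, ValueError) as exc:
        raise DataQualityError(
            f"entry {entry_id!r}: value {raw!r} does not parse as "
            f"{datatype} for element {element.id}"
        ) from exc


def extract(
    registry: Registry,
    element_id: str,
    patient: PatientSummary,
    content_model_id: str,
) -> list[ExtractedValue]:
    """Resolve the element's extraction spec over the semantic-link chain and
    execute it on the given rendering, coercing values to the element's
    declared datatype."""
    element = registry.get_data_element(element_id)
    spec, _chain = registry.resolve_extraction_spec(
        element_id, content_model_id
    )
    if spec.dialect == "path":
        if not isinstance(patient, XmlSummary):
            raise SpecError(
                "path spec requires a document-tree payload, got "
                f"{type(patient).__name__}"
            )
        raw_values = execute_path_spec(patient, spec, element_id)
    else:
        if not isinstance(patient, GraphSummary):
            raise SpecError(
                "graph-pattern spec requires a triple-graph payload, got "
                f"{type(patient).__name__}"
            )
        raw_values = execute_graph_spec(patient, spec, element_id)
    out = []
    for ev in raw_values:
        out.append(
            ExtractedValue(
                entry_id=ev.entry_id,
                element_id=element_id,
                value=coerce_value(ev.value, element, ev.entry_id),
                code_system_id=ev.code_system_id
                or element.value_domain.code_system_id,
            )
        )
    return out


def extract_entries(
    registry: Registry,
    object_class_id: str,
    element_ids: list[str],
    patient: PatientSummary,
    content_model_id: str,
    extractor=None,
) -> list[EntryRow]:
    """Per-entry join of several elements of one object class.

    A schema item such as "condition code + condition date" needs the code
    and the date of the *same* clinical entry; values are therefore joined on
    entry id, never cross-joined.  Entries missing one element get an
    explicit None in that slot.  Row order follows first appearance.
    """
    for element_id in element_ids:
        element = registry.get_data_element(element_id)
        if element.object_class_id != object_class_id:
            raise ValueError(
                f"element {element_id} belongs to object class "
                f"{element.object_class_id}, not {object_class_id}"
            )
    if extractor is None:
        extractor = extract
    rows: dict[str, EntryRow] = {}
    for element_id in element_ids:
        for ev in extractor(registry, element_id, patient, content_model_id):
            row = rows.setdefault(
                ev.entry_id,
                EntryRow(
                    entry_id=ev.entry_id,
                    values={e: None for e in element_ids},
                ),
            )
            if row.values.get(element_id) is None:
                row.values[element_id] = ev
    return list(rows.values())
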