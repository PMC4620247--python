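"""In-process semantic metadata registry (MDR) for common data elements.

The registry stores abstract data-element definitions in ISO/IEC 11179 style
(object class, data element, value domain), each optionally carrying
content-model-specific extraction specifications (XPath for document trees,
SPARQL basic graph patterns for triple graphs) and SKOS semantic links to
counterpart elements in peer registries (``skos:exactMatch``).

Retrieval follows the information content of the IHE Data Element Exchange
contract — element id in, full metadata plus extraction specification out —
as a plain in-process API.  Peer registries from one dump are federated into
a single in-memory store; exactMatch links are stored directionally but
traversed symmetrically, so an element authored in a research vocabulary
(e.g. an SDTM variable) resolves transitively to the extraction
specification held by a clinical-care element (e.g. a HITSP C154 entry with
an XPath binding to CCD documents).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .errors import NotFoundError, RegistryLoadError, ResolutionError
from .model import CCD_XML, CIM_RDF

DATATYPES = ("code", "date", "quantity", "text", "boolean")
LINK_PREDICATES = ("exactMatch", "notation")
DIALECTS = ("graph_pattern", "path")
ANCHORS = ("entry", "document")

#: dialect each built-in content model accepts (unknown models are not checked)
_MODEL_DIALECTS = {CIM_RDF: "graph_pattern", CCD_XML: "path"}


@dataclass(frozen=True)
class ValueDomain:
    datatype: str
    code_system_id: str | None = None
    unit: str | None = None
    permissible_values: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SemanticLink:
    predicate: str
    target_element_id: str


@dataclass(frozen=True)
class ExtractionSpec:
    content_model_id: str
    dialect: str
    script: str
    anchor: str = "entry"


@dataclass(frozen=True)
class DataElement:
    id: str
    name: str
    definition: str
    object_class_id: str
    value_domain: ValueDomain
    extraction_specs: tuple[ExtractionSpec, ...] = ()
    links: tuple[SemanticLink, ...] = ()

    def spec_for(self, content_model_id: str) -> ExtractionSpec | None:
        for spec in self.extraction_specs:
            if spec.content_model_id == content_model_id:
                return spec
        return None


@dataclass
class ObjectClass:
    id: str
    name: str
    element_ids: list[str] = field(default_factory=list)


@dataclass
class Registry:
    """Federated in-memory metadata registry (one or more peer registries
    loaded from a single dump)."""

    registry_ids: list[str] = field(default_factory=list)
    elements: dict[str, DataElement] = field(default_factory=dict)
    object_classes: dict[str, ObjectClass] = field(default_factory=dict)
    #: element id -> registry id it was declared in
    registry_of: dict[str, str] = field(default_factory=dict)

    # -- retrieval (DEX-style metadata-source contract) ------------------

    def get_data_element(self, element_id: str) -> DataElement:
        try:
            return self.elements[element_id]
        except KeyError:
            raise NotFoundError(f"unknown data element: {element_id}") from None

    def list_object_classes(self, registry_id: str) -> list[ObjectClass]:
        if registry_id not in self.registry_ids:
            raise NotFoundError(f"unknown registry: {registry_id}")
        out = [
            oc
            for oc in self.object_classes.values()
            if any(self.registry_of[e] == registry_id for e in oc.element_ids)
            or oc.id.split(":", 1)[0] == registry_id
        ]
        return sorted(out, key=lambda oc: oc.id)

    def list_elements(self, object_class_id: str) -> list[DataElement]:
        try:
            oc = self.object_classes[object_class_id]
        except KeyError:
            raise NotFoundError(
                f"unknown object class: {object_class_id}"
            ) from None
        return sorted(
            (self.elements[e] for e in oc.element_ids), key=lambda e: e.id
        )

    # -- semantic link traversal ----------------------------------------

    def _neighbors(self, element_id: str) -> set[str]:
        """exactMatch neighbourhood, symmetric closure of stored links."""
        out = {
            link.target_element_id
            for link in self.elements[element_id].links
            if link.predicate == "exactMatch"
        }
        for other in self.elements.values():
            for link in other.links:
                if (
                    link.predicate == "exactMatch"
                    and link.target_element_id == element_id
                ):
                    out.add(other.id)
        out.discard(element_id)
        return out

    def resolve_extraction_spec(
        self, element_id: str, content_model_id: str
    ) -> tuple[ExtractionSpec, list[str]]:
        """Find the nearest extraction spec for ``content_model_id`` over the
        symmetric exactMatch graph starting at ``element_id``.

        Breadth-first traversal; the first spec-bearing element on the
        shortest chain wins, ties at equal depth broken by lexicographic
        element-id order.  Returns the spec and the traversal chain including
        both endpoints (length 1 when the element itself carries the spec).
        """
        start = self.get_data_element(element_id).id
        parent: dict[str, str | None] = {start: None}
        frontier = [start]
        visited_order: list[str] = []
        while frontier:
            for node in frontier:  # frontier is sorted: deterministic ties
                visited_order.append(node)
                if self.elements[node].spec_for(content_model_id) is not None:
                    chain = [node]
                    while parent[chain[-1]] is not None:
                        chain.append(parent[chain[-1]])  # type: ignore[arg-type]
                    chain.reverse()
                    spec = self.elements[node].spec_for(content_model_id)
                    assert spec is not None
                    return spec, chain
            nxt: set[str] = set()
            for node in frontier:
                for nb in self._neighbors(node):
                    if nb not in parent:
                        parent[nb] = node
                        nxt.add(nb)
            frontier = sorted(nxt)
        raise ResolutionError(
            f"no extraction spec for content model {content_model_id!r} "
            f"reachable from {element_id!r}; searched: {visited_order}"
        )

    def transitive_matches(self, element_id: str) -> set[str]:
        """The exactMatch-connected component of ``element_id`` (symmetric-
        transitive closure), excluding the element itself."""
        start = self.get_data_element(element_id).id
        seen = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nb in self._neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        seen.discard(start)
        return seen


# ---------------------------------------------------------------------------
# dump dialect (JSON) load / dump
# ---------------------------------------------------------------------------


def _parse_value_domain(raw: dict, element_id: str) -> ValueDomain:
    datatype = raw.get("datatype")
    if datatype not in DATATYPES:
        raise RegistryLoadError(
            f"{element_id}: invalid value-domain datatype {datatype!r}"
        )
    code_system = raw.get("code_system")
    if datatype == "code" and not code_system:
        raise RegistryLoadError(
            f"{element_id}: datatype 'code' requires a code_system"
        )
    pv = raw.get("permissible_values")
    return ValueDomain(
        datatype=datatype,
        code_system_id=code_system,
        unit=raw.get("unit"),
        permissible_values=tuple(pv) if pv is not None else None,
    )


def load_registry(source: str | Path | IO[str] | dict) -> Registry:
    """Load a registry dump (JSON file path, open file, or parsed dict).

    All peer registries in the dump are federated into one store.  Every
    invariant is validated up front; violations raise
    :class:`RegistryLoadError` naming the offending element ids.
    """
    if isinstance(source, dict):
        raw = source
    elif isinstance(source, (str, Path)):
        raw = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        raw = json.load(source)

    reg = Registry()
    declared_classes: dict[str, str] = {}
    for raw_reg in raw.get("registries", []):
        registry_id = raw_reg.get("registry_id")
        if not registry_id:
            raise RegistryLoadError("registry without registry_id")
        if registry_id in reg.registry_ids:
            raise RegistryLoadError(f"duplicate registry id: {registry_id}")
        reg.registry_ids.append(registry_id)
        for raw_oc in raw_reg.get("object_classes", []):
            declared_classes[raw_oc["id"]] = raw_oc.get(
                "name", raw_oc["id"].rsplit(":", 1)[-1]
            )
        for raw_el in raw_reg.get("elements", []):
            el_id = raw_el.get("id")
            if not el_id:
                raise RegistryLoadError(f"element without id in {registry_id}")
            if el_id in reg.elements:
                raise RegistryLoadError(f"duplicate element id: {el_id}")
            specs = []
            seen_models: set[str] = set()
            for raw_spec in raw_el.get("extraction_specs", []):
                model = raw_spec["content_model"]
                dialect = raw_spec["dialect"]
                if dialect not in DIALECTS:
                    raise RegistryLoadError(
                        f"{el_id}: invalid dialect {dialect!r}"
                    )
                expected = _MODEL_DIALECTS.get(model)
                if expected is not None and dialect != expected:
                    raise RegistryLoadError(
                        f"{el_id}: dialect {dialect!r} incompatible with "
                        f"content model {model!r} (expected {expected!r})"
                    )
                if model in seen_models:
                    raise RegistryLoadError(
                        f"{el_id}: more than one extraction spec for "
                        f"content model {model!r}"
                    )
                seen_models.add(model)
                anchor = raw_spec.get("anchor", "entry")
                if anchor not in ANCHORS:
                    raise RegistryLoadError(
                        f"{el_id}: invalid anchor {anchor!r}"
                    )
                specs.append(
                    ExtractionSpec(
                        content_model_id=model,
                        dialect=dialect,
                        script=raw_spec["script"],
                        anchor=anchor,
                    )
                )
            links = []
            for raw_link in raw_el.get("links", []):
                predicate = raw_link["predicate"]
                if predicate not in LINK_PREDICATES:
                    raise RegistryLoadError(
                        f"{el_id}: invalid link predicate {predicate!r}"
                    )
                links.append(
                    SemanticLink(
                        predicate=predicate,
                        target_element_id=raw_link["target"],
                    )
                )
            element = DataElement(
                id=el_id,
                name=raw_el.get("name", el_id),
                definition=raw_el.get("definition", ""),
                object_class_id=raw_el["object_class"],
                value_domain=_parse_value_domain(
                    raw_el.get("value_domain", {}), el_id
                ),
                extraction_specs=tuple(specs),
                links=tuple(links),
            )
            reg.elements[el_id] = element
            reg.registry_of[el_id] = registry_id

    # object classes: declared ones first, then auto-registered from elements
    for oc_id, name in declared_classes.items():
        reg.object_classes[oc_id] = ObjectClass(id=oc_id, name=name)
    for element in reg.elements.values():
        oc_id = element.object_class_id
        if oc_id not in reg.object_classes:
            reg.object_classes[oc_id] = ObjectClass(
                id=oc_id, name=oc_id.rsplit(":", 1)[-1]
            )
        reg.object_classes[oc_id].element_ids.append(element.id)

    # dangling link targets (must resolve within the federated store)
    dangling = sorted(
        f"{el.id} -> {link.target_element_id}"
        for el in reg.elements.values()
        for link in el.links
        if link.target_element_id not in reg.elements
    )
    if dangling:
        raise RegistryLoadError(
            "dangling semantic link target(s): " + "; ".join(dangling)
        )
    return reg


def dump_registry(reg: Registry) -> dict:
    """Serialize a registry back to the dump dialect.

    ``load_registry(dump_registry(load_registry(x)))`` preserves all fields;
    the emitted structure is deterministic (insertion order of elements,
    stable key order) so dumping twice yields identical JSON text.
    """
    registries = []
    for registry_id in reg.registry_ids:
        element_ids = [
            e for e, r in reg.registry_of.items() if r == registry_id
        ]
        classes = sorted(
            {reg.elements[e].object_class_id for e in element_ids}
        )
        registries.append(
            {
                "registry_id": registry_id,
                "object_classes": [
                    {"id": c, "name": reg.object_classes[c].name}
                    for c in classes
                ],
                "elements": [
                    _dump_element(reg.elements[e]) for e in element_ids
                ],
            }
        )
    return {"registries": registries}


def _dump_element(el: DataElement) -> dict:
    vd: dict = {"datatype": el.value_domain.datatype}
    if el.value_domain.code_system_id is not None:
        vd["code_system"] = el.value_domain.code_system_id
    if el.value_domain.unit is not None:
        vd["unit"] = el.value_domain.unit
    if el.value_domain.permissible_values is not None:
        vd["permissible_values"] = list(el.value_domain.permissible_values)
    out: dict = {
        "id": el.id,
        "name": el.name,
        "definition": el.definition,
        "object_class": el.object_class_id,
        "value_domain": vd,
    }
    if el.extraction_specs:
        out["extraction_specs"] = [
            {
                "content_model": s.content_model_id,
                "dialect": s.dialect,
                "script": s.script,
                "anchor": s.anchor,
            }
            for s in el.extraction_specs
        ]
    if el.links:
        out["links"] = [
            {"predicate": link.predicate, "target": link.target_element_id}
            for link in el.links
        ]
    return out


def dump_registry_json(reg: Registry) -> str:
    return json.dumps(dump_registry(reg), indent=2, ensure_ascii=False) + "\n"


def validate_permissible(reg: Registry, element_id: str, value: str) -> bool:
    """True iff ``value`` is admissible for the element's value domain
    (membership in permissible_values when such a list is declared)."""
    vd = reg.get_data_element(element_id).value_domain
    if vd.permissible_values is None:
        return True
    return value in vd.permissible_values


def iter_specs(reg: Registry) -> Iterable[tuple[str, ExtractionSpec]]:
    for el in reg.elements.values():
        for spec in el.extraction_specs:
            yield el.id, spec
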