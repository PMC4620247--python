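"""Data-collection-set schemas: definition, validation and evaluation.

A schema is an ordered list of named items (the columns of the final
analysis table).  Each item binds one or more data elements of a single
object class — optionally fixing a coded value, e.g. the MedDRA preferred
term a condition must match — and a derivation that turns the per-entry
extracted values into one typed cell per patient:

``VALUE``
    the single extracted value (conflicting duplicates are a data-quality
    error);
``FIRST_DATE``
    earliest entry date among entries matching the bound code;
``EXISTS_BEFORE`` / ``EXISTS_AFTER``
    "Y"/"N" comparing entry dates to an index date taken from another item
    (strictly before / on-or-after);
``MEAN_IN_WINDOW``
    arithmetic mean of quantity values dated in the half-open window
    ``(index - window_days, index]``;
``LAST_VALUE_BEFORE``
    the value with maximal date ``<= index``;
``DATE_OFFSET``
    index date plus a fixed number of days;
``MIN_DATE``
    minimum over other items' dates and literal date constants.

Items may reference other items (the index of a windowed calculation, the
candidates of a minimum); the engine derives the dependency graph, rejects
cycles, and evaluates items in a stable topological order.  Code matching
between a bound research code (MedDRA) and warehouse-coded entries
(ICD-9-CM) goes through the terminology server; unmatched warehouse codes
simply do not qualify.  Zero qualifying entries yield an explicit null,
never an error — sparse warehouses are the norm, not a failure mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import DataQualityError, NotFoundError, SchemaValidationError
from .extraction import EntryRow, extract, extract_entries
from .mdr import Registry, validate_permissible
from .model import PatientSummary
from .terminology import TerminologyServer

FUNCTIONS = (
    "VALUE",
    "FIRST_DATE",
    "LAST_VALUE_BEFORE",
    "MEAN_IN_WINDOW",
    "EXISTS_BEFORE",
    "EXISTS_AFTER",
    "DATE_OFFSET",
    "MIN_DATE",
)

#: functions whose semantics need an index-date reference to another item
_INDEXED = (
    "LAST_VALUE_BEFORE",
    "MEAN_IN_WINDOW",
    "EXISTS_BEFORE",
    "EXISTS_AFTER",
)


@dataclass(frozen=True)
class ElementBinding:
    element_id: str
    fixed_code: str | None = None
    fixed_system: str | None = None


@dataclass(frozen=True)
class Derivation:
    function: str
    index_item: str | None = None
    window_days: int | None = None
    offset_days: int | None = None
    base_date: date | None = None  # DATE_OFFSET on a constant
    candidate_items: tuple[str, ...] = ()
    constants: tuple[date, ...] = ()

    def references(self) -> tuple[str, ...]:
        refs = list(self.candidate_items)
        if self.index_item:
            refs.append(self.index_item)
        return tuple(refs)


@dataclass
class SchemaItem:
    name: str
    bindings: list[ElementBinding]
    derivation: Derivation

    @property
    def depends_on(self) -> tuple[str, ...]:
        return self.derivation.references()


@dataclass
class DataCollectionSetSchema:
    items: list[SchemaItem]
    content_model_id: str | None = None

    def item(self, name: str) -> SchemaItem:
        for it in self.items:
            if it.name == name:
                return it
        raise NotFoundError(f"unknown schema item: {name}")


@dataclass
class DataCollectionSet:
    """The populated per-patient table plus column → element-id metadata."""

    data: pd.DataFrame
    column_elements: dict[str, list[str]] = field(default_factory=dict)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.data.to_csv(path, index=True, index_label="PatientID", na_rep="")
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps(self.column_elements, indent=2) + "\n",
                encoding="utf-8",
            )


# ---------------------------------------------------------------------------
# schema loading and validation
# ---------------------------------------------------------------------------


def load_schema(
    source: str | Path | dict,
    registry: Registry | None = None,
) -> DataCollectionSetSchema:
    """Read a schema definition (YAML or JSON file, or parsed dict).

    With a registry, value bindings are checked against the element value
    domains (code datatype, permissible values)."""
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
    items = []
    for raw_item in raw.get("items", []):
        bindings = []
        for raw_b in raw_item.get("elements", []):
            bindings.append(
                ElementBinding(
                    element_id=raw_b["element"],
                    fixed_code=_opt_str(raw_b.get("code")),
                    fixed_system=raw_b.get("system"),
                )
            )
        raw_d = raw_item.get("derivation", {})
        function = raw_d.get("function", "VALUE")
        if function not in FUNCTIONS:
            raise SchemaValidationError(
                f"item {raw_item.get('name')!r}: unknown derivation "
                f"function {function!r}"
            )
        derivation = Derivation(
            function=function,
            index_item=raw_d.get("index"),
            window_days=raw_d.get("window_days"),
            offset_days=raw_d.get("offset_days"),
            base_date=_opt_date(raw_d.get("base_date")),
            candidate_items=tuple(raw_d.get("candidates", [])),
            constants=tuple(
                _opt_date(c) for c in raw_d.get("constants", [])
            ),
        )
        items.append(
            SchemaItem(
                name=raw_item["name"],
                bindings=bindings,
                derivation=derivation,
            )
        )
    schema = DataCollectionSetSchema(
        items=items, content_model_id=raw.get("content_model")
    )
    _check_schema(schema, registry)
    return schema


def _opt_str(v) -> str | None:
    return None if v is None else str(v)


def _opt_date(v) -> date | None:
    if v is None:
        return None
    return v if isinstance(v, date) else date.fromisoformat(str(v))


def _check_schema(
    schema: DataCollectionSetSchema, registry: Registry | None
) -> None:
    names = [it.name for it in schema.items]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise SchemaValidationError(f"duplicate item names: {sorted(dupes)}")
    for it in schema.items:
        if it.derivation.function in _INDEXED and not it.derivation.index_item:
            raise SchemaValidationError(
                f"item {it.name!r}: {it.derivation.function} requires an "
                "index item reference"
            )
        for dep in it.depends_on:
            if dep not in names:
                raise SchemaValidationError(
                    f"item {it.name!r} depends on unknown item {dep!r}"
                )
        if registry is not None:
            for b in it.bindings:
                element = registry.get_data_element(b.element_id)
                if b.fixed_code is not None:
                    if element.value_domain.datatype != "code":
                        raise SchemaValidationError(
                            f"item {it.name!r}: fixed code bound to "
                            f"non-code element {b.element_id}"
                        )
                    if not validate_permissible(
                        registry, b.element_id, b.fixed_code
                    ):
                        raise SchemaValidationError(
                            f"item {it.name!r}: code {b.fixed_code!r} is not "
                            f"permissible for {b.element_id}"
                        )


def validate_schema(schema: DataCollectionSetSchema) -> list[SchemaItem]:
    """Topologically ordered evaluation plan, stable among valid orders
    (ties broken by declaration order).  Cycles and unknown dependencies are
    validation errors."""
    _check_schema(schema, None)
    order = {it.name: i for i, it in enumerate(schema.items)}
    ts: TopologicalSorter = TopologicalSorter()
    for it in schema.items:
        ts.add(it.name, *it.depends_on)
    try:
        ts.prepare()
    except CycleError as exc:
        raise SchemaValidationError(
            f"dependency cycle among schema items: {exc.args[1]}"
        ) from exc
    plan: list[str] = []
    while ts.is_active():
        ready = sorted(ts.get_ready(), key=order.__getitem__)
        plan.extend(ready)
        ts.done(*ready)
    return [schema.item(name) for name in plan]


# ---------------------------------------------------------------------------
# calculation options (value-domain driven)
# ---------------------------------------------------------------------------

_OPTIONS_BY_DATATYPE = {
    "date": ("VALUE", "FIRST_DATE", "DATE_OFFSET", "MIN_DATE"),
    "quantity": ("VALUE", "MEAN_IN_WINDOW", "LAST_VALUE_BEFORE"),
    "code": ("VALUE", "EXISTS_BEFORE", "EXISTS_AFTER"),
    "text": ("VALUE",),
    "boolean": ("VALUE",),
}


def calculation_options(registry: Registry, element_id: str) -> list[str]:
    """Derivation functions applicable to an element, driven by its value
    domain's datatype."""
    element = registry.get_data_element(element_id)
    return list(_OPTIONS_BY_DATATYPE[element.value_domain.datatype])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _binding_roles(
    registry: Registry, item: SchemaItem
) -> tuple[list[ElementBinding], str | None, str | None]:
    """Split bindings into code filters and the date / value roles.

    Bindings carrying a fixed code act as entry filters.  The first
    date-typed binding provides entry dates; the value role is the first
    unfixed non-date binding, falling back to the date binding for purely
    date-valued items."""
    filters = [b for b in item.bindings if b.fixed_code is not None]
    date_el = None
    value_el = None
    for b in item.bindings:
        datatype = registry.get_data_element(b.element_id).value_domain.datatype
        if datatype == "date" and date_el is None:
            date_el = b.element_id
        elif b.fixed_code is None and value_el is None:
            value_el = b.element_id
    if value_el is None:
        value_el = date_el
    return filters, date_el, value_el


def _qualifying_rows(
    rows: list[EntryRow],
    filters: list[ElementBinding],
    registry: Registry,
    terminology: TerminologyServer,
) -> list[EntryRow]:
    out = []
    for row in rows:
        ok = True
        for f in filters:
            ev = row.values.get(f.element_id)
            system = f.fixed_system or registry.get_data_element(
                f.element_id
            ).value_domain.code_system_id
            if (
                ev is None
                or system is None
                or ev.code_system_id is None
                or not terminology.codes_match(
                    f.fixed_code, system, str(ev.value), ev.code_system_id
                )
            ):
                ok = False
                break
        if ok:
            out.append(row)
    return out


def evaluate_item(
    item: SchemaItem,
    patient: PatientSummary,
    context: dict[str, Any],
    registry: Registry,
    terminology: TerminologyServer,
    content_model_id: str,
    extractor=None,
) -> Any:
    """Evaluate one schema item for one patient.

    ``context`` maps already-evaluated item names to their cells; all
    dependencies of ``item`` must be present."""
    for dep in item.depends_on:
        if dep not in context:
            raise SchemaValidationError(
                f"item {item.name!r}: dependency {dep!r} not yet evaluated"
            )
    d = item.derivation

    if d.function == "DATE_OFFSET":
        base = context[d.index_item] if d.index_item else d.base_date
        if base is None or d.offset_days is None:
            return None
        return base + timedelta(days=d.offset_days)

    if d.function == "MIN_DATE":
        candidates = [
            context[c] for c in d.candidate_items if context[c] is not None
        ]
        candidates.extend(d.constants)
        return min(candidates) if candidates else None

    # remaining functions work on extracted entries
    if not item.bindings:
        return None
    object_class = registry.get_data_element(
        item.bindings[0].element_id
    ).object_class_id
    rows = extract_entries(
        registry,
        object_class,
        [b.element_id for b in item.bindings],
        patient,
        content_model_id,
        extractor=extractor,
    )
    filters, date_el, value_el = _binding_roles(registry, item)
    rows = _qualifying_rows(rows, filters, registry, terminology)

    def dates() -> list[date]:
        if date_el is None:
            return []
        return [
            row.values[date_el].value
            for row in rows
            if row.values.get(date_el) is not None
        ]

    def dated_values() -> list[tuple[date, Any, str]]:
        if date_el is None or value_el is None:
            return []
        return [
            (
                row.values[date_el].value,
                row.values[value_el].value,
                row.entry_id,
            )
            for row in rows
            if row.values.get(date_el) is not None
            and row.values.get(value_el) is not None
        ]

    index = context[d.index_item] if d.index_item else None

    if d.function == "VALUE":
        values = [
            row.values[value_el].value
            for row in rows
            if value_el is not None and row.values.get(value_el) is not None
        ]
        distinct = sorted({str(v) for v in values})
        if not distinct:
            return None
        if len(distinct) > 1:
            raise DataQualityError(
                f"item {item.name!r}: conflicting duplicate values "
                f"{distinct}"
            )
        return values[0]

    if d.function == "FIRST_DATE":
        ds = dates()
        return min(ds) if ds else None

    if d.function == "EXISTS_BEFORE":
        if index is None:
            return None
        return "Y" if any(dt < index for dt in dates()) else "N"

    if d.function == "EXISTS_AFTER":
        if index is None:
            return None
        return "Y" if any(dt >= index for dt in dates()) else "N"

    if d.function == "MEAN_IN_WINDOW":
        if index is None or d.window_days is None:
            return None
        lo = index - timedelta(days=d.window_days)
        vals = [
            float(v) for dt, v, _ in dated_values() if lo < dt <= index
        ]
        # exact summation: the mean must not depend on entry order, which
        # differs between content-model renderings
        return math.fsum(vals) / len(vals) if vals else None

    if d.function == "LAST_VALUE_BEFORE":
        if index is None:
            return None
        eligible = [
            (dt, v, eid) for dt, v, eid in dated_values() if dt <= index
        ]
        if not eligible:
            return None
        # deterministic tie-break on equal dates: value then entry id
        dt, v, _ = max(eligible, key=lambda t: (t[0], str(t[1]), t[2]))
        return v

    raise SchemaValidationError(f"unknown function {d.function!r}")


def populate(
    schema: DataCollectionSetSchema,
    cohort: list[tuple[str, PatientSummary]],
    registry: Registry,
    terminology: TerminologyServer,
    content_model_id: str | None = None,
) -> DataCollectionSet:
    """Populate the data collection set: one row per cohort patient, one
    column per schema item, evaluated in dependency order.

    ``cohort`` is a list of ``(patient_id, summary)`` pairs, the summaries
    all rendered in ``content_model_id``.  Errors raised while evaluating an
    item are annotated with the patient id and item name."""
    model = content_model_id or schema.content_model_id
    if model is None:
        raise SchemaValidationError("no content model specified")
    plan = validate_schema(schema)
    records: list[dict[str, Any]] = []
    index: list[str] = []
    for patient_id, summary in cohort:
        cache: dict[str, list] = {}

        def cached_extract(reg, element_id, pat, mod):
            if element_id not in cache:
                cache[element_id] = extract(reg, element_id, pat, mod)
            return cache[element_id]

        context: dict[str, Any] = {}
        for item in plan:
            try:
                context[item.name] = evaluate_item(
                    item,
                    summary,
                    context,
                    registry,
                    terminology,
                    model,
                    extractor=cached_extract,
                )
            except DataQualityError as exc:
                raise DataQualityError(
                    f"patient {patient_id!r}, item {item.name!r}: {exc}"
                ) from exc
        records.append({it.name: context[it.name] for it in schema.items})
        index.append(patient_id)
    frame = pd.DataFrame(
        records, index=index, columns=[it.name for it in schema.items]
    )
    frame = frame.astype(object).where(pd.notna(frame), None)
    column_elements = {
        it.name: [b.element_id for b in it.bindings] for it in schema.items
    }
    return DataCollectionSet(data=frame, column_elements=column_elements)
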