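"""Schema validation, derivations, and data-collection-set population."""

from __future__ import annotations

import random
from datetime import date

import pytest

from pmsst import populate, study_schema, sample_schema
from pmsst.errors import DataQualityError, SchemaValidationError
from pmsst.schema_engine import (
    DataCollectionSetSchema,
    Derivation,
    ElementBinding,
    SchemaItem,
    calculation_options,
    evaluate_item,
    load_schema,
    validate_schema,
)
from pmsst.synth import render_graph, render_xml

from conftest import make_patient


def item(name, function="VALUE", index=None, candidates=(), bindings=(), **params):
    return SchemaItem(
        name=name,
        bindings=list(bindings),
        derivation=Derivation(
            function=function,
            index_item=index,
            candidate_items=tuple(candidates),
            window_days=params.get("window_days"),
            offset_days=params.get("offset_days"),
            base_date=params.get("base_date"),
            constants=tuple(params.get("constants", ())),
        ),
    )


def mh_bindings(code=None):
    out = [ElementBinding("SDTM:MH.MHPTCD", fixed_code=code, fixed_system="MedDRA")]
    out.append(ElementBinding("SDTM:MH.MHSTDTC"))
    return out


def evaluate(registry, terminology, it, patient, context=None, model="CIM-RDF"):
    summary = render_graph(patient) if model == "CIM-RDF" else render_xml(patient)
    return evaluate_item(
        it, summary, context or {}, registry, terminology, model
    )


# ---------------------------------------------------------------------------
# validation and planning
# ---------------------------------------------------------------------------


def test_index_dependency_is_evaluated_first(registry):
    schema = sample_schema(registry)
    plan = [it.name for it in validate_schema(schema)]
    assert plan.index("DateOfACS") < plan.index("CHFBeforeACS")
    assert plan.index("DateOfACS") < plan.index("CHFAfterACS")


def test_independent_items_keep_declaration_order():
    schema = DataCollectionSetSchema(items=[item("B"), item("A"), item("C")])
    assert [it.name for it in validate_schema(schema)] == ["B", "A", "C"]


def test_cycle_is_a_validation_error():
    schema = DataCollectionSetSchema(
        items=[
            item("A", "DATE_OFFSET", index="B", offset_days=1),
            item("B", "DATE_OFFSET", index="A", offset_days=1),
        ]
    )
    with pytest.raises(SchemaValidationError, match="cycle"):
        validate_schema(schema)


def test_unknown_dependency_is_a_validation_error():
    schema = DataCollectionSetSchema(
        items=[item("A", "DATE_OFFSET", index="Ghost", offset_days=1)]
    )
    with pytest.raises(SchemaValidationError, match="Ghost"):
        validate_schema(schema)


def test_duplicate_item_names_rejected():
    schema = DataCollectionSetSchema(items=[item("A"), item("A")])
    with pytest.raises(SchemaValidationError, match="duplicate"):
        validate_schema(schema)


def test_fixed_code_must_be_permissible(registry):
    raw = {
        "items": [
            {
                "name": "Bad",
                "elements": [{"element": "SDTM:DM.DMSEX", "code": "X"}],
                "derivation": {"function": "VALUE"},
            }
        ]
    }
    with pytest.raises(SchemaValidationError, match="permissible"):
        load_schema(raw, registry)


def test_calculation_options_follow_value_domain(registry):
    assert "FIRST_DATE" in calculation_options(registry, "SDTM:MH.MHSTDTC")
    assert "MEAN_IN_WINDOW" in calculation_options(registry, "SDTM:VS.VSORRES")
    assert "EXISTS_BEFORE" in calculation_options(registry, "SDTM:MH.MHPTCD")
    assert calculation_options(registry, "SDTM:MH.MHPTCD") == [
        "VALUE",
        "EXISTS_BEFORE",
        "EXISTS_AFTER",
    ]


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------


def test_start_date_is_thirty_days_after_the_event(registry, terminology):
    """An event on 5 July 2007 stabilizes on 4 August 2007."""
    it = item("STARTDATE", "DATE_OFFSET", index="DateOfACS", offset_days=30)
    cell = evaluate(
        registry,
        terminology,
        it,
        make_patient(),
        context={"DateOfACS": date(2007, 7, 5)},
    )
    assert cell == date(2007, 8, 4)


def test_windowed_mean_uses_only_in_window_values(registry, terminology):
    """BP 120 at index-100d and 130 at index-200d are averaged; 140 at
    index-400d falls outside the 365-day window."""
    index = date(2008, 1, 1)
    patient = make_patient(
        observations=[
            ("SYSBP", 120, "2007-09-23"),  # index - 100 d
            ("SYSBP", 130, "2007-06-15"),  # index - 200 d
            ("SYSBP", 140, "2006-11-27"),  # index - 400 d
        ]
    )
    it = item(
        "MeanBP",
        "MEAN_IN_WINDOW",
        index="Idx",
        window_days=365,
        bindings=[
            ElementBinding("SDTM:VS.VSTESTCD", "SYSBP", "LOCAL-OBS"),
            ElementBinding("SDTM:VS.VSORRES"),
            ElementBinding("SDTM:VS.VSDTC"),
        ],
    )
    for model in ("CIM-RDF", "CCD-XML"):
        assert (
            evaluate(registry, terminology, it, patient, {"Idx": index}, model)
            == 125.0
        )


def test_exists_before_is_strict_and_defaults_to_no(registry, terminology):
    it = item(
        "CHFBefore",
        "EXISTS_BEFORE",
        index="Idx",
        bindings=mh_bindings("10007559"),
    )
    no_chf = make_patient(conditions=[("410.0", "2007-07-05")])
    assert (
        evaluate(registry, terminology, it, no_chf, {"Idx": date(2007, 7, 5)})
        == "N"
    )
    chf_same_day = make_patient(conditions=[("428.0", "2007-07-05")])
    assert (
        evaluate(
            registry, terminology, it, chf_same_day, {"Idx": date(2007, 7, 5)}
        )
        == "N"
    )
    chf_before = make_patient(conditions=[("428.0", "2007-07-04")])
    assert (
        evaluate(
            registry, terminology, it, chf_before, {"Idx": date(2007, 7, 5)}
        )
        == "Y"
    )


def test_exists_after_includes_the_index_day(registry, terminology):
    it = item(
        "CHFAfter",
        "EXISTS_AFTER",
        index="Idx",
        bindings=mh_bindings("10007559"),
    )
    chf = make_patient(conditions=[("428.0", "2009-05-01")])
    assert (
        evaluate(registry, terminology, it, chf, {"Idx": date(2009, 5, 1)})
        == "Y"
    )
    assert (
        evaluate(registry, terminology, it, chf, {"Idx": date(2009, 5, 2)})
        == "N"
    )


def test_zero_entry_aggregations_yield_null(registry, terminology):
    empty = make_patient()
    mean_item = item(
        "Mean",
        "MEAN_IN_WINDOW",
        index="Idx",
        window_days=365,
        bindings=[
            ElementBinding("SDTM:VS.VSTESTCD", "SYSBP", "LOCAL-OBS"),
            ElementBinding("SDTM:VS.VSORRES"),
            ElementBinding("SDTM:VS.VSDTC"),
        ],
    )
    assert (
        evaluate(registry, terminology, mean_item, empty, {"Idx": date(2008, 1, 1)})
        is None
    )
    first_item = item("First", "FIRST_DATE", bindings=mh_bindings("10007559"))
    assert evaluate(registry, terminology, first_item, empty) is None


def test_first_date_picks_minimum_matching_entry(registry, terminology):
    patient = make_patient(
        conditions=[
            ("428.0", "2009-06-01"),
            ("428.0", "2008-02-01"),
            ("410.0", "2007-01-01"),  # different code: must not count
        ]
    )
    it = item("FirstCHF", "FIRST_DATE", bindings=mh_bindings("10007559"))
    assert evaluate(registry, terminology, it, patient) == date(2008, 2, 1)


def test_last_value_before_takes_maximal_dated_value(registry, terminology):
    patient = make_patient(
        observations=[
            ("WEIGHT", 80, "2006-01-01"),
            ("WEIGHT", 78, "2007-03-01"),
            ("WEIGHT", 99, "2008-01-01"),  # after index
        ]
    )
    it = item(
        "LastWeight",
        "LAST_VALUE_BEFORE",
        index="Idx",
        bindings=[
            ElementBinding("SDTM:VS.VSTESTCD", "WEIGHT", "LOCAL-OBS"),
            ElementBinding("SDTM:VS.VSORRES"),
            ElementBinding("SDTM:VS.VSDTC"),
        ],
    )
    assert (
        evaluate(registry, terminology, it, patient, {"Idx": date(2007, 6, 1)})
        == 78.0
    )


def test_min_date_over_candidates_and_constants(registry, terminology):
    it = item(
        "LASTDATE",
        "MIN_DATE",
        candidates=("Death", "Transfer"),
        constants=(date(2011, 12, 31),),
    )
    ctx = {"Death": date(2010, 5, 1), "Transfer": None}
    assert evaluate(registry, terminology, it, make_patient(), ctx) == date(2010, 5, 1)
    ctx = {"Death": None, "Transfer": None}
    assert evaluate(registry, terminology, it, make_patient(), ctx) == date(2011, 12, 31)


def test_value_with_conflicting_duplicates_is_data_quality_error(
    registry, terminology
):
    patient = make_patient(
        conditions=[("410.0", "2007-01-01"), ("428.0", "2008-01-01")]
    )
    it = item(
        "Code",
        "VALUE",
        bindings=[ElementBinding("SDTM:MH.MHPTCD")],
    )
    with pytest.raises(DataQualityError, match="conflicting"):
        evaluate(registry, terminology, it, patient)


def test_missing_dependency_is_engine_error(registry, terminology):
    it = item("X", "DATE_OFFSET", index="NotYet", offset_days=1)
    with pytest.raises(SchemaValidationError, match="NotYet"):
        evaluate_item(
            it,
            render_graph(make_patient()),
            {},
            registry,
            terminology,
            "CIM-RDF",
        )


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def test_populated_table_has_published_schema_columns(registry, terminology):
    schema = sample_schema(registry)
    patient = make_patient(conditions=[("410.0", "2007-07-05")])
    dcs = populate(
        schema, [("P1", render_graph(patient))], registry, terminology, "CIM-RDF"
    )
    assert list(dcs.data.columns) == [
        "Sex",
        "DateOfACS",
        "DateOfAMI",
        "DateOfUnstableAngina",
        "CHFBeforeACS",
        "CHFAfterACS",
    ]
    row = dcs.data.loc["P1"]
    assert row["Sex"] == "F"
    # the ACS grouping term matches the MI warehouse code via the crosswalk
    assert row["DateOfACS"] == date(2007, 7, 5)
    assert row["DateOfAMI"] == date(2007, 7, 5)
    assert row["DateOfUnstableAngina"] is None
    assert row["CHFBeforeACS"] == "N"


def test_empty_cohort_keeps_full_header(registry, terminology):
    schema = sample_schema(registry)
    dcs = populate(schema, [], registry, terminology, "CIM-RDF")
    assert dcs.data.shape == (0, 6)
    assert list(dcs.data.columns) == [it.name for it in schema.items]


def test_population_is_order_insensitive_among_valid_plans(
    registry, terminology
):
    """Shuffling item declarations (a different valid topological order)
    must not change any cell."""
    schema = study_schema(registry)
    patient = make_patient(
        conditions=[("410.0", "2007-07-05"), ("428.0", "2009-01-01")],
        observations=[("SYSBP", 120, "2007-05-01"), ("WEIGHT", 80, "2006-01-01")],
    )
    cohort = [("P1", render_graph(patient))]
    baseline = populate(schema, cohort, registry, terminology, "CIM-RDF")
    rng = random.Random(5)
    for _ in range(5):
        items = list(schema.items)
        rng.shuffle(items)
        shuffled = DataCollectionSetSchema(
            items=items, content_model_id=schema.content_model_id
        )
        dcs = populate(shuffled, cohort, registry, terminology, "CIM-RDF")
        for col in baseline.data.columns:
            assert dcs.data.loc["P1", col] == baseline.data.loc["P1", col] or (
                dcs.data.loc["P1", col] is None
                and baseline.data.loc["P1", col] is None
            )


def test_adding_an_item_does_not_change_existing_columns(registry, terminology):
    schema = sample_schema(registry)
    patient = make_patient(conditions=[("410.0", "2007-07-05")])
    cohort = [("P1", render_graph(patient))]
    before = populate(schema, cohort, registry, terminology, "CIM-RDF")
    extended = DataCollectionSetSchema(
        items=list(schema.items)
        + [item("STARTDATE", "DATE_OFFSET", index="DateOfACS", offset_days=30)],
        content_model_id=schema.content_model_id,
    )
    after = populate(extended, cohort, registry, terminology, "CIM-RDF")
    for col in before.data.columns:
        assert after.data.loc["P1", col] == before.data.loc["P1", col] or (
            after.data.loc["P1", col] is None
            and before.data.loc["P1", col] is None
        )


def test_csv_round_trip_writes_nulls_as_empty_fields(
    registry, terminology, tmp_path
):
    schema = sample_schema(registry)
    patient = make_patient(conditions=[("410.0", "2007-07-05")])
    dcs = populate(
        schema, [("P1", render_graph(patient))], registry, terminology, "CIM-RDF"
    )
    out = tmp_path / "dcs.csv"
    sidecar = tmp_path / "cols.json"
    dcs.to_csv(out, sidecar)
    text = out.read_text()
    header = text.splitlines()[0].split(",")
    assert header == ["PatientID"] + list(dcs.data.columns)
    assert ",," in text  # null cell written as an empty field
    import json

    meta = json.loads(sidecar.read_text())
    assert meta["DateOfACS"] == ["SDTM:MH.MHPTCD", "SDTM:MH.MHSTDTC"]
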