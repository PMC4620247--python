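"""Access to the packaged fixture resources (registry dump, terminology
tables, schema definitions, frozen ground truth)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .mdr import Registry, load_registry
from .schema_engine import DataCollectionSetSchema, load_schema
from .terminology import TerminologyServer, load_terminology


def data_path(name: str) -> Path:
    return Path(str(resources.files("pmsst").joinpath("data", name)))


def default_registry() -> Registry:
    return load_registry(data_path("registry.json"))


def default_terminology() -> TerminologyServer:
    return load_terminology(data_path("concepts.csv"), data_path("concept_map.csv"))


def fixture_truth():
    """Frozen ground truth of the 50-patient reference population
    (``n_patients=50, seed=42``); the records themselves are regenerated
    from the same seed."""
    from .synth import GroundTruth

    return GroundTruth.from_json(
        data_path("fixture_truth_n50_seed42.json").read_text(encoding="utf-8")
    )


def sample_schema(registry: Registry | None = None) -> DataCollectionSetSchema:
    return load_schema(data_path("schema_sample.yaml"), registry)


def study_schema(registry: Registry | None = None) -> DataCollectionSetSchema:
    return load_schema(data_path("schema_study.yaml"), registry)
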