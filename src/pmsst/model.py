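"""Canonical patient model and the two content-model renderings.

A :class:`PatientRecord` is the warehouse-neutral longitudinal record: patient
demographics plus coded condition entries and quantitative observation
entries.  The same record can be rendered as an RDF graph (``CIM-RDF``, a toy
common-information-model vocabulary in the spirit of the SALUS CIM) or as a
CCD-like XML document (``CCD-XML``).  The extraction engine never sees the
canonical record — only one of the renderings — which is what makes the
dual-rendering equivalence tests meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from lxml import etree
from rdflib import Graph, Namespace

# Content-model identifiers used throughout registries and configs.
CIM_RDF = "CIM-RDF"
CCD_XML = "CCD-XML"
CONTENT_MODELS = (CIM_RDF, CCD_XML)

#: Toy common-information-model vocabulary for the RDF rendering.
CIM = Namespace("http://example.org/pmsst/cim#")

#: URI prefixes for patient and entry nodes; entry ids are the local parts.
PATIENT_URI_PREFIX = "urn:patient:"
ENTRY_URI_PREFIX = "urn:entry:"


@dataclass(frozen=True)
class ConditionEntry:
    """One coded diagnosis/problem entry (warehouse-coded, e.g. ICD-9-CM)."""

    entry_id: str
    code: str
    code_system: str
    start_date: date


@dataclass(frozen=True)
class ObservationEntry:
    """One dated quantitative measurement (BP, weight, HbA1c, ...)."""

    entry_id: str
    code: str
    code_system: str
    value: float
    unit: str
    obs_date: date


@dataclass
class PatientRecord:
    """Canonical longitudinal patient record."""

    patient_id: str
    sex: str  # "F" / "M"
    birth_date: date
    registration_date: date
    death_date: date | None = None
    transfer_out_date: date | None = None
    conditions: list[ConditionEntry] = field(default_factory=list)
    observations: list[ObservationEntry] = field(default_factory=list)


@dataclass
class GraphSummary:
    """RDF rendering of one patient summary (a set of triples plus the
    patient subject node).  Serializable to/from Turtle."""

    graph: Graph
    patient_subject: str

    def serialize(self) -> str:
        return self.graph.serialize(format="turtle")

    @classmethod
    def from_turtle(cls, text: str) -> "GraphSummary":
        g = Graph()
        g.parse(data=text, format="turtle")
        subjects = sorted(
            str(s) for s in g.subjects(predicate=None, object=CIM.Patient)
        )
        if len(subjects) != 1:
            raise ValueError(
                f"graph summary must contain exactly one patient subject, "
                f"found {len(subjects)}"
            )
        return cls(graph=g, patient_subject=subjects[0])


@dataclass
class XmlSummary:
    """CCD-like XML rendering of one patient summary."""

    root: etree._Element

    def serialize(self) -> str:
        return etree.tostring(
            self.root, pretty_print=True, encoding="unicode"
        )

    @classmethod
    def from_string(cls, text: str) -> "XmlSummary":
        return cls(root=etree.fromstring(text.encode("utf-8")))


#: Either rendering, as accepted by the extraction engine.
PatientSummary = GraphSummary | XmlSummary


def local_id(uri_or_node: str) -> str:
    """Local identifier of a patient/entry URI (``urn:entry:P1-c1`` → ``P1-c1``)."""
    s = str(uri_or_node)
    for prefix in (ENTRY_URI_PREFIX, PATIENT_URI_PREFIX):
        if s.startswith(prefix):
            return s[len(prefix):]
    return s.rsplit(":", 1)[-1] if ":" in s else s
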