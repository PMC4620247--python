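"""Seeded synthetic EHR population with known ground truth.

The generator emulates, at desk scale, a regional longitudinal warehouse of
the kind the surveillance use case runs on: patients register with the
system at some date, may suffer a first acute coronary syndrome (ACS) event
(acute MI or unstable angina, warehouse-coded in ICD-9-CM), may die within
the 30-day stabilization window, may develop congestive heart failure (CHF)
after the event (exponential waiting time at a configured hazard), may
carry prevalent CHF or type-2 diabetes beforehand, and accrue noisy
scheduled observations (blood pressure, weight, HbA1c).  Whole observation
streams are missing for a configurable share of patients, emulating
warehouses whose data is not fully structured.

Every patient is emitted as a canonical :class:`~pmsst.model.PatientRecord`
together with a per-patient ground truth (first in-window ACS date,
eligibility verdict and failing filter, CHF flags, windowed BP mean, last
weight) that is recomputed from the emitted record itself — no latent
generator state leaks into it — so independent brute-force scripts can
verify it.  The same record renders losslessly into both content models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
from lxml import etree
from rdflib import Graph, Literal, RDF, URIRef

from .errors import ConfigError
from .model import (
    CIM,
    ENTRY_URI_PREFIX,
    PATIENT_URI_PREFIX,
    ConditionEntry,
    GraphSummary,
    ObservationEntry,
    PatientRecord,
    XmlSummary,
)

#: warehouse (ICD-9-CM) coding of the use-case conditions
ICD9 = "ICD9CM"
CODE_ACUTE_MI = "410.0"
CODE_UNSTABLE_ANGINA = "411.1"
CODE_CHF = "428.0"
CODE_T2D = "250.00"
ACS_WAREHOUSE_CODES = (CODE_ACUTE_MI, CODE_UNSTABLE_ANGINA)

OBS_SYSTEM = "LOCAL-OBS"
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ObsStream:
    code: str
    unit: str
    rate_per_year: float
    mean: float
    sd: float
    missing_prob: float


def _default_streams() -> dict[str, ObsStream]:
    # sparse BP/HbA1c streams emulate the mostly-unstructured vitals
    # sections real warehouses were observed to have
    return {
        "sysbp": ObsStream("SYSBP", "mmHg", 2.0, 130.0, 15.0, 0.70),
        "diabp": ObsStream("DIABP", "mmHg", 2.0, 80.0, 10.0, 0.70),
        "weight": ObsStream("WEIGHT", "kg", 1.0, 75.0, 12.0, 0.30),
        "hba1c": ObsStream("HBA1C", "%", 1.5, 7.0, 1.0, 0.40),
    }


@dataclass
class GeneratorConfig:
    n_patients: int = 50
    seed: int = 42
    sex_female_prob: float = 0.3822
    birth_year_range: tuple[int, int] = (1920, 1990)
    registration_range: tuple[date, date] = (date(1995, 1, 1), date(2004, 12, 31))
    annual_acs_incidence: float = 0.15
    post_acs_fatality_prob: float = 0.12
    chf_hazard_per_1000py: float = 5.0
    chf_before_prevalence: float = 0.10
    t2d_prevalence: float = 0.30
    acs_recurrence_prob: float = 0.20
    background_death_prob: float = 0.15
    transfer_out_prob: float = 0.08
    obs_streams: dict[str, ObsStream] = field(default_factory=_default_streams)
    data_end: date = date(2014, 12, 31)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        probs = {
            "sex_female_prob": self.sex_female_prob,
            "post_acs_fatality_prob": self.post_acs_fatality_prob,
            "chf_before_prevalence": self.chf_before_prevalence,
            "t2d_prevalence": self.t2d_prevalence,
            "acs_recurrence_prob": self.acs_recurrence_prob,
            "background_death_prob": self.background_death_prob,
            "transfer_out_prob": self.transfer_out_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.annual_acs_incidence < 0 or self.chf_hazard_per_1000py < 0:
            raise ConfigError("rates must be >= 0")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigError("birth_year_range reversed")
        if self.registration_range[0] > self.registration_range[1]:
            raise ConfigError("registration_range reversed")
        for name, stream in self.obs_streams.items():
            if stream.rate_per_year < 0 or not 0 <= stream.missing_prob <= 1:
                raise ConfigError(f"invalid observation stream {name!r}")


@dataclass
class PatientTruth:
    """Ground truth for one patient, recomputable from the emitted record."""

    patient_id: str
    sex: str
    first_acs_in_window: date | None
    eligible: bool
    failing_filter: str | None
    start_date: date | None
    last_date: date | None
    age_at_acs: int | None
    chf_before: bool
    first_chf_after: date | None
    sysbp_mean_365: float | None
    last_weight_before: float | None
    death_date: date | None
    transfer_out_date: date | None


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, date):
                return o.isoformat()
            raise TypeError(type(o))

        return json.dumps(
            {pid: asdict(t) for pid, t in sorted(self.patients.items())},
            indent=2,
            default=default,
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        gt = cls()
        date_fields = {
            "first_acs_in_window",
            "start_date",
            "last_date",
            "first_chf_after",
            "death_date",
            "transfer_out_date",
        }
        for pid, t in raw.items():
            for k in date_fields:
                if t.get(k) is not None:
                    t[k] = date.fromisoformat(t[k])
            gt.patients[pid] = PatientTruth(**t)
        return gt


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _uniform_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, span + 1)))


def generate(config: GeneratorConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a reproducible population from the configured processes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    truth = GroundTruth()
    for i in range(config.n_patients):
        record = _generate_patient(rng, config, f"P{i + 1:05d}")
        patients.append(record)
        truth.patients[record.patient_id] = compute_truth(record)
    return patients, truth


def _generate_patient(
    rng: np.random.Generator, cfg: GeneratorConfig, pid: str
) -> PatientRecord:
    sex = "F" if rng.random() < cfg.sex_female_prob else "M"
    birth = _uniform_date(
        rng,
        date(cfg.birth_year_range[0], 1, 1),
        date(cfg.birth_year_range[1], 12, 31),
    )
    reg = _uniform_date(rng, *cfg.registration_range)

    death: date | None = None
    if rng.random() < cfg.background_death_prob:
        death = _uniform_date(rng, reg + timedelta(days=365), date(2015, 12, 31))
    transfer: date | None = None
    if rng.random() < cfg.transfer_out_prob:
        transfer = _uniform_date(rng, reg + timedelta(days=365), date(2015, 12, 31))

    def censor() -> date:
        c = cfg.data_end
        if death is not None:
            c = min(c, death)
        if transfer is not None:
            c = min(c, transfer)
        return c

    conditions: list[ConditionEntry] = []
    seq = 0

    def add_condition(code: str, when: date) -> None:
        nonlocal seq
        seq += 1
        conditions.append(
            ConditionEntry(
                entry_id=f"{pid}-c{seq}",
                code=code,
                code_system=ICD9,
                start_date=when,
            )
        )

    # first ACS: exponential waiting time from registration
    acs: date | None = None
    if cfg.annual_acs_incidence > 0:
        wait_years = rng.exponential(1.0 / cfg.annual_acs_incidence)
        candidate = reg + timedelta(days=max(1, round(wait_years * DAYS_PER_YEAR)))
        if candidate <= censor():
            acs = candidate
            mi = rng.random() < 0.6  # MI somewhat more frequent than UA
            add_condition(CODE_ACUTE_MI if mi else CODE_UNSTABLE_ANGINA, acs)
            if rng.random() < cfg.post_acs_fatality_prob:
                death = acs + timedelta(days=int(rng.integers(1, 31)))
            if rng.random() < cfg.acs_recurrence_prob:
                gap = rng.uniform(0.5, 5.0)
                second = acs + timedelta(days=round(gap * DAYS_PER_YEAR))
                if second <= censor():
                    add_condition(
                        CODE_ACUTE_MI if rng.random() < 0.6 else CODE_UNSTABLE_ANGINA,
                        second,
                    )

    # prevalent CHF / T2D before the (potential) ACS
    prevalent_end = (acs - timedelta(days=1)) if acs else min(censor(), date(2011, 12, 31))
    if rng.random() < cfg.chf_before_prevalence and prevalent_end > reg:
        add_condition(CODE_CHF, _uniform_date(rng, reg, prevalent_end))
    if rng.random() < cfg.t2d_prevalence and prevalent_end > reg:
        add_condition(CODE_T2D, _uniform_date(rng, reg, prevalent_end))

    # incident CHF after the stabilized ACS: exponential at the configured
    # hazard (per 1000 person-years), right-censored by death/transfer
    if acs is not None and cfg.chf_hazard_per_1000py > 0:
        start = acs + timedelta(days=30)
        wait_years = rng.exponential(1000.0 / cfg.chf_hazard_per_1000py)
        chf_date = start + timedelta(
            days=max(1, round(wait_years * DAYS_PER_YEAR))
        )
        if chf_date <= censor():
            add_condition(CODE_CHF, chf_date)

    # scheduled noisy observations
    observations: list[ObservationEntry] = []
    obs_end = min(censor(), cfg.data_end)
    span_years = max(0.0, (obs_end - reg).days / DAYS_PER_YEAR)
    oseq = 0
    for name in sorted(cfg.obs_streams):
        stream = cfg.obs_streams[name]
        if rng.random() < stream.missing_prob:
            continue
        n_visits = int(rng.poisson(stream.rate_per_year * span_years))
        days = sorted(
            int(d) for d in rng.integers(0, max(1, (obs_end - reg).days + 1), n_visits)
        )
        values = rng.normal(stream.mean, stream.sd, n_visits)
        for offset, value in zip(days, values):
            oseq += 1
            observations.append(
                ObservationEntry(
                    entry_id=f"{pid}-o{oseq}",
                    code=stream.code,
                    code_system=OBS_SYSTEM,
                    value=round(float(value), 1),
                    unit=stream.unit,
                    obs_date=reg + timedelta(days=offset),
                )
            )

    return PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_date=birth,
        registration_date=reg,
        death_date=death,
        transfer_out_date=transfer,
        conditions=conditions,
        observations=observations,
    )


# ---------------------------------------------------------------------------
# ground truth (recomputed from the emitted record)
# ---------------------------------------------------------------------------

_ACCRUAL = (date(2005, 1, 1), date(2011, 12, 31))
_STUDY_END = date(2011, 12, 31)


def compute_truth(record: PatientRecord) -> PatientTruth:
    """Recompute the study quantities for one record, straight from its
    entries (the selection rules restated in their plainest form)."""
    acs_dates = sorted(
        c.start_date
        for c in record.conditions
        if c.code in ACS_WAREHOUSE_CODES
    )
    first_acs = acs_dates[0] if acs_dates else None
    in_window = (
        first_acs is not None and _ACCRUAL[0] <= first_acs <= _ACCRUAL[1]
    )

    failing: str | None = None
    start = last = None
    age = None
    if not in_window:
        failing = "no_first_acs_in_window"
    else:
        assert first_acs is not None
        age = first_acs.year - record.birth_date.year - (
            (first_acs.month, first_acs.day)
            < (record.birth_date.month, record.birth_date.day)
        )
        start = first_acs + timedelta(days=30)
        last = min(
            d
            for d in (record.death_date, record.transfer_out_date, _STUDY_END)
            if d is not None
        )
        if record.registration_date > first_acs - timedelta(days=365):
            failing = "insufficient_history"
        elif record.death_date is not None and record.death_date <= start:
            failing = "death_within_30d"
        elif age < 18:
            failing = "age_under_18"
        elif last < start:
            failing = "no_followup_time"

    index = first_acs if in_window else None
    chf_dates = sorted(
        c.start_date for c in record.conditions if c.code == CODE_CHF
    )
    chf_before = index is not None and any(d < index for d in chf_dates)
    first_chf_after = None
    if index is not None and start is not None:
        after = [d for d in chf_dates if d >= start]
        first_chf_after = after[0] if after else None

    sysbp_mean = None
    last_weight = None
    if index is not None:
        window_lo = index - timedelta(days=365)
        bp = [
            o.value
            for o in record.observations
            if o.code == "SYSBP" and window_lo < o.obs_date <= index
        ]
        sysbp_mean = sum(bp) / len(bp) if bp else None
        weights = [
            (o.obs_date, o.value, o.entry_id)
            for o in record.observations
            if o.code == "WEIGHT" and o.obs_date <= index
        ]
        if weights:
            last_weight = max(weights, key=lambda t: (t[0], str(t[1]), t[2]))[1]

    return PatientTruth(
        patient_id=record.patient_id,
        sex=record.sex,
        first_acs_in_window=index,
        eligible=failing is None and in_window,
        failing_filter=failing,
        start_date=start if in_window else None,
        last_date=last if in_window else None,
        age_at_acs=age,
        chf_before=chf_before,
        first_chf_after=first_chf_after,
        sysbp_mean_365=sysbp_mean,
        last_weight_before=last_weight,
        death_date=record.death_date,
        transfer_out_date=record.transfer_out_date,
    )


# ---------------------------------------------------------------------------
# renderings
# ---------------------------------------------------------------------------


def render_graph(record: PatientRecord) -> GraphSummary:
    """RDF rendering in the toy common-information-model vocabulary."""
    g = Graph()
    g.bind("cim", CIM)
    subject = URIRef(PATIENT_URI_PREFIX + record.patient_id)
    g.add((subject, RDF.type, CIM.Patient))
    g.add((subject, CIM.id, Literal(record.patient_id)))
    g.add((subject, CIM.gender, Literal(record.sex)))
    g.add((subject, CIM.birthDate, Literal(record.birth_date.isoformat())))
    g.add(
        (subject, CIM.registrationDate, Literal(record.registration_date.isoformat()))
    )
    if record.death_date is not None:
        g.add((subject, CIM.deathDate, Literal(record.death_date.isoformat())))
    if record.transfer_out_date is not None:
        g.add(
            (
                subject,
                CIM.transferOutDate,
                Literal(record.transfer_out_date.isoformat()),
            )
        )
    for c in record.conditions:
        node = URIRef(ENTRY_URI_PREFIX + c.entry_id)
        g.add((subject, CIM.hasCondition, node))
        g.add((node, RDF.type, CIM.Condition))
        g.add((node, CIM.code, Literal(c.code)))
        g.add((node, CIM.codeSystem, Literal(c.code_system)))
        g.add((node, CIM.startDate, Literal(c.start_date.isoformat())))
    for o in record.observations:
        node = URIRef(ENTRY_URI_PREFIX + o.entry_id)
        g.add((subject, CIM.hasObservation, node))
        g.add((node, RDF.type, CIM.Observation))
        g.add((node, CIM.code, Literal(o.code)))
        g.add((node, CIM.codeSystem, Literal(o.code_system)))
        g.add((node, CIM.value, Literal(f"{o.value:g}")))
        g.add((node, CIM.unit, Literal(o.unit)))
        g.add((node, CIM.startDate, Literal(o.obs_date.isoformat())))
    return GraphSummary(graph=g, patient_subject=str(subject))


def render_xml(record: PatientRecord) -> XmlSummary:
    """CCD-like XML rendering (sections → entries → coded acts/observations)."""
    root = etree.Element("ClinicalDocument")
    record_target = etree.SubElement(root, "recordTarget")
    role = etree.SubElement(record_target, "patientRole", ID=record.patient_id)
    patient = etree.SubElement(role, "patient")
    etree.SubElement(
        patient, "administrativeGenderCode", code=record.sex, codeSystem="SEX"
    )
    etree.SubElement(patient, "birthTime", value=record.birth_date.isoformat())
    etree.SubElement(
        patient, "registrationTime", value=record.registration_date.isoformat()
    )
    if record.death_date is not None:
        etree.SubElement(
            patient, "deathTime", value=record.death_date.isoformat()
        )
    if record.transfer_out_date is not None:
        etree.SubElement(
            patient, "recordEndTime", value=record.transfer_out_date.isoformat()
        )
    component = etree.SubElement(root, "component")
    body = etree.SubElement(component, "structuredBody")

    problems = etree.SubElement(
        etree.SubElement(body, "component"), "section", code="PROBLEMS"
    )
    for c in record.conditions:
        entry = etree.SubElement(problems, "entry", ID=c.entry_id)
        act = etree.SubElement(entry, "act")
        obs = etree.SubElement(act, "observation")
        etree.SubElement(obs, "code", code=c.code, codeSystem=c.code_system)
        etree.SubElement(obs, "effectiveTime", value=c.start_date.isoformat())

    results = etree.SubElement(
        etree.SubElement(body, "component"), "section", code="RESULTS"
    )
    for o in record.observations:
        entry = etree.SubElement(results, "entry", ID=o.entry_id)
        obs = etree.SubElement(entry, "observation")
        etree.SubElement(obs, "code", code=o.code, codeSystem=o.code_system)
        etree.SubElement(obs, "value", value=f"{o.value:g}", unit=o.unit)
        etree.SubElement(obs, "effectiveTime", value=o.obs_date.isoformat())
    return XmlSummary(root=root)


def write_population(
    patients: list[PatientRecord],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write one Turtle and one XML file per patient plus the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for record in patients:
        (out / f"{record.patient_id}.ttl").write_text(
            render_graph(record).serialize(), encoding="utf-8"
        )
        (out / f"{record.patient_id}.xml").write_text(
            render_xml(record).serialize(), encoding="utf-8"
        )
    (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
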