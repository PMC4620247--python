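# Methods

## Overview

`pmsst` is a metadata-driven extraction engine plus a small
pharmacoepidemiology layer.  Its pipeline is: (1) load a federated
metadata registry of common data elements (CDEs); (2) select a cohort from
canonical patient records; (3) for each schema column, resolve the bound
research-vocabulary element (SDTM) over `skos:exactMatch` links to an
extraction specification executable on the source's content model, run it,
and join values per clinical entry; (4) apply the column's derivation to
produce one typed cell per patient; (5) report stratified incidence rates
on the resulting table.

## Registry and link resolution

Elements follow ISO/IEC 11179 concepts: object class, data element, value
domain.  `exactMatch` links are stored directionally (SDTM→SALUS-style
CDEs, SALUS→HITSP-style CDEs, mirroring how such mappings are authored)
but *traversed symmetrically*, since SKOS `exactMatch` is symmetric by
definition.  Resolution is breadth-first from the requested element; the
first element on a shortest chain carrying a spec for the requested
content model wins.  Ties at equal depth are broken by lexicographic
element id — the choice among equally short chains is semantically
arbitrary (exactMatch asserts interchangeability), so the tie-break exists
purely for determinism and is flagged here as a convention, not a claim.
Correctness of the shortest-chain property is tested against exhaustive
path enumeration on random registries of up to 20 elements.

The registry dump is a single JSON document; loading validates all
invariants up front (unique ids, resolvable link targets, one spec per
element/content-model pair, dialect/payload compatibility) and
`load(dump(load(x)))` preserves every field.

## Content models and extraction

Two toy but structurally faithful content models exercise the
model-agnostic design (the method only requires *some* two concrete
models):

* **CIM-RDF** — an RDF vocabulary with classes Patient / Condition /
  Observation and predicates `code`, `codeSystem`, `startDate`, `value`,
  `unit`, `gender`, …  Extraction specs are SPARQL SELECT queries over a
  basic graph pattern, required to project `?entry` and `?value`
  (optionally `?codeSystem`), executed by rdflib with prepared-query
  caching.
* **CCD-XML** — a document tree preserving the section → entry → act /
  observation nesting of CCD-style summaries.  Specs are XPath 1.0
  expressions executed by lxml; an attribute match named `code` picks up
  the sibling `codeSystem` attribute.

Every extracted value is grouped by its clinical entry (`?entry` binding,
or nearest XML ancestor carrying an `ID`); a schema item that needs the
code *and* the date of the same event joins on entry id and never
cross-joins.  Values are coerced to the owning element's value-domain
datatype (ISO-8601 dates, float quantities); a coercion failure is a
data-quality error naming the entry.  Zero matches is an empty result,
never an error: sparse warehouses legitimately produce empty columns.

## Terminology

Concept lookup, case-insensitive prefix (type-ahead) search, and a
symmetric concept map.  Matching a research code (MedDRA preferred term)
to a warehouse code (ICD-9-CM) is **single-hop** by design: multi-hop
chaining across maps silently broadens clinical meaning.  One-to-many maps
are allowed — the ACS grouping term maps to both the acute-MI and the
unstable-angina ICD-9 codes — and every target counts as a match.
Unmapped warehouse codes simply fail to match; they are not errors.  The
shipped fixtures hold ~20 concepts per system; NCI is registered as an
empty system (research value domains may reference it, but no fixture
codes are defined).

## Schema engine

Dependencies between items (index dates of windowed calculations,
candidates of minima) are derived from the derivations and evaluated in a
stable topological order (ties by declaration order); cycles are rejected.
Numerical/temporal conventions, chosen once for determinism:

* "over 12 months before" = half-open window `(index − 365 d, index]`,
  day granularity; "12 months" is fixed at 365 days rather than calendar
  arithmetic.
* "before" an index date is strict (`<`); "after" is on-or-after (`>=`),
  applied to the stabilized start of follow-up where one exists.
* `MEAN_IN_WINDOW` uses exact summation (`math.fsum`), so the mean cannot
  depend on the order entries happen to arrive in — a requirement for
  bit-identical tables across content models.
* `LAST_VALUE_BEFORE` breaks equal-date ties by (date, value, entry id).
* Missing data yields explicit nulls end to end; any aggregation over zero
  qualifying entries is null, except the existence derivations, which
  answer "N" when no matching entry exists and null only when the index
  date itself is missing.
* `VALUE` over conflicting duplicates is a data-quality error; over
  duplicates of the same value it returns that value.

The shipped `schema_sample.yaml` carries the six published sample columns
(sex; ACS, acute-MI and unstable-angina event dates; CHF before/after the
index event, coded with MedDRA 10051592, 10000891, 10002388, 10007559).
In that six-column sample, the only available index is the ACS event date,
so its "after" column is anchored there; the full `schema_study.yaml` adds
the follow-up anchors (`STARTDATE`, `LASTDATE`), death/transfer dates, the
first-CHF event date, and the windowed BP/HbA1c/weight calculations, and
anchors "CHF after" at `STARTDATE`.  On generator output the two
conventions agree, because no CHF event is generated inside the 30-day
stabilization gap.  The "CHF time indicator" element is read as the
condition entry's start date.

## Cohort selection

Selection rules run in their stated order, each exclusion attributed to
the first failing rule: (1) first ACS event (acute MI or unstable angina,
matched through the terminology server) inside the 2005–2011 accrual
window — an earlier ACS disqualifies entirely, since the in-window event
is then not a *first* event (a `prior_acs_disqualifies` switch relaxes
this); (2) at least 365 days between registration and the event;
(3) death within 30 days of the event; (4) age under 18 in completed
years at the event.  One additional trailing rule is the package's own:
members whose `LASTDATE` (min of death, transfer-out, study end) precedes
`STARTDATE` — possible when a patient transfers out during the 30-day
stabilization gap — contribute no follow-up and are excluded as
`no_followup_time`, which keeps person-time non-negative by construction.

Incidence: person-time per patient runs from `STARTDATE` to
`min(event, LASTDATE)`; events count in `(STARTDATE, LASTDATE]`; rates
are per 1000 person-years with a 365-day year.  Patients whose event date
is on or before `STARTDATE` are prevalent cases and are removed from the
risk set (they would otherwise contribute negative or zero time while
carrying an uncountable event).

## Synthetic population

The generator emulates a longitudinal regional warehouse at desk scale.
Per patient: sex Bernoulli(0.3822 female — the demographic share reported
for the deployment population this design targets); birth year uniform
1920–1990; registration uniform 1995–2004; first ACS by exponential
waiting time from registration at 0.15/year (chosen, together with the
registration range, so that roughly a quarter of patients have a first
event inside the 2005–2011 window and the eligibility filters all fire);
60 % of ACS events are acute MI, the rest unstable angina; 20 % recur
0.5–5 years later; 12 % die within 30 days of the event; background death
15 % and transfer-out 8 % at uniform dates; prevalent CHF 10 % and T2D
30 % before the event; incident CHF after `STARTDATE` by exponential
waiting time at 5/1000 person-years (inside the 2.3–11.9 band reported
for diabetic populations).  Observation streams (systolic/diastolic BP
2/yr, weight 1/yr, HbA1c 1.5/yr; Gaussian values rounded to one decimal)
are dropped wholesale per patient with probability 0.70/0.70/0.30/0.40,
emulating warehouses whose vitals sections are largely unstructured —
which is why sparsely populated and entirely empty columns are a designed
outcome, not a failure.

Events dated after death or transfer-out are never recorded (the
warehouse cannot see them), which implements right-censoring exactly;
condition and observation dates therefore never exceed the censoring
date, and the incidence estimator is unbiased for the configured hazard.

Ground truth (first in-window ACS, eligibility verdict and failing
filter, CHF flags, windowed BP mean, last weight) is recomputed from the
*emitted records*, never from latent generator state, so independent
brute-force passes over the records must — and in the tests do —
reproduce it.  A frozen ground-truth JSON for the 50-patient seed-42
reference population is shipped; the records themselves are regenerated
from the seed and pinned byte-identical by a determinism test.

What the generator does **not** model: drug exposure and treatment
regimens, realistic ICD-9 breadth, correlated comorbidity structure,
calendar trends, or million-patient scale.  Passing tests therefore
demonstrate the engine's correctness on structurally faithful data, not
clinical realism of any particular estimate.

## Test design and problem sizes

Cross-model equivalence is checked on 200 seeded patients over the full
study schema; registry properties against brute-force oracles on random
registries of ≤ 20 elements; eligibility against an independent
restatement of the rules at n = 2000; female share at n = 10 000 (three
binomial standard errors).  Parameter recovery for the CHF hazard runs
end to end (generate → select → populate → rate) at n = 2000: a
single-population check at the default 5/1000 PY must land within three
standard errors of the configured hazard, and a 20-seed consistency check
requires the mean estimate within 5 % of the configured hazard.  The
consistency check runs at an elevated hazard of 40/1000 PY: at 5/1000 PY
this design accrues only ~200 events across 20 seeds, making the sampling
error of the mean (~7–8 %) larger than the 5 % band — the band would test
luck, not consistency — whereas at 40/1000 PY (~1300 events, ~3 %
sampling error) it tests the estimator.  The acceptance script instead
reports a pooled estimate at the default 5/1000 PY over five populations,
where pooling keeps the sampling error of a point report acceptable.

## Known limitations

* The graph dialect is a SPARQL subset (BGP + equality filters); OPTIONAL,
  UNION and property paths are out of scope, as is full CDA validation.
* Federation is in-memory: peer registries load into one store; no HTTP
  registry protocol or registry versioning/workflow.
* Incidence reporting is crude rates with no confidence intervals beyond
  what a consumer can derive from the reported events and person-years;
  no survival modelling or competing risks.
* Code matching is exact-or-mapped; no terminology hierarchy (MedDRA
  SOC/HLGT/HLT or ICD-9 chapter structure).
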