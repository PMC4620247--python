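# pmsst

**Common-data-element driven extraction of analysis-ready tables from
heterogeneous EHR patient summaries**, with cohort selection and
incidence-rate reporting for postmarketing drug-surveillance studies.

## The problem

Observational safety studies need per-patient tables ("data collection
sets") whose columns are defined in the researcher's own vocabulary —
typically CDISC SDTM variables such as `MH.MHPTCD` (coded medical-history
condition) or `DM.DMSEX` (sex) — while the underlying EHR sources expose
patient summaries in whatever content model they happen to use: an XML
document dialect in the spirit of HL7/ASTM CCD, or an RDF common
information model.

`pmsst` solves this interoperability problem at the metadata level.  Every
variable is an abstract **common data element (CDE)** held in an ISO/IEC
11179-style **semantic metadata registry** together with:

* a **value domain** (datatype, code system, permissible values),
* content-model-specific **extraction specifications** (XPath scripts for
  document trees, SPARQL basic graph patterns for triple graphs), and
* **`skos:exactMatch` links** to counterpart elements in peer registries.

To evaluate a schema column the engine resolves the researcher's SDTM
element over the symmetric link graph to the *nearest* element carrying an
extraction spec for the source's content model — e.g.

```
SDTM:MH.MHPTCD → SALUS:Condition.ProblemCode.CD            (SPARQL, RDF model)
SDTM:MH.MHPTCD → SALUS:Condition.ProblemCode.CD → HITSP:7.04   (XPath, XML model)
```

— executes it, joins code/date values per clinical entry, bridges research
codes (MedDRA preferred terms) to warehouse codes (ICD-9-CM) through a
terminology server, and applies the column's derivation:

| derivation | semantics |
|---|---|
| `VALUE` | the single extracted value |
| `FIRST_DATE` | earliest entry date matching the bound code |
| `EXISTS_BEFORE` / `EXISTS_AFTER` | "Y"/"N" vs. an index date (strict before / on-or-after) |
| `MEAN_IN_WINDOW` | mean of values dated in `(index − w, index]` |
| `LAST_VALUE_BEFORE` | value with maximal date ≤ index |
| `DATE_OFFSET`, `MIN_DATE` | index-date arithmetic |

The epidemiology layer implements the ACS/CHF surveillance use case:
select patients with a first acute-coronary-syndrome event (acute MI or
unstable angina) in 2005–2011, require one year of history, exclude
30-day deaths and patients under 18, set `STARTDATE = ACS + 30 d` and
`LASTDATE = min(death, transfer-out, 2011-12-31)`, and report crude
incidence rates per 1000 person-years,

```
rate = 1000 · events / Σᵢ (min(eventᵢ, LASTDATEᵢ) − STARTDATEᵢ) / 365,
```

with events counted in `(STARTDATE, LASTDATE]`.

A seeded synthetic-population generator emulates a longitudinal regional
warehouse at desk scale with full per-patient ground truth, and renders
every canonical record into *both* content models — which is what makes the
central claim testable: the populated table must be identical, cell for
cell, whichever content model the source speaks.

## Worked example

```bash
pmsst run-study --n 200 --seed 7 --out study_out
cat study_out/summary.txt
```

prints (numbers from this exact invocation):

```
population simulated: 200 (seed 7)
cohort members: 44
exclusions: no_first_acs_in_window=149, insufficient_history=1, death_within_30d=6, age_under_18=0, no_followup_time=0
female share of cohort: 38.64%
Sex  events  person_years  rate_per_1000py
  F       0     52.369863              0.0
  M       0    104.989041              0.0
```

Of 200 simulated patients, 44 form the ACS cohort; the remaining 156 are
accounted to the first selection rule they fail.  38.64 % of the cohort is
female (the generator's configured female share is 38.22 %).  At the
default congestive-heart-failure hazard of 5/1000 person-years, 157
person-years of follow-up are expected to contain fewer than one event, so
the small demo reports a zero rate — run larger populations (see below)
for a stable estimate.  `study_out/data_collection_set.csv` holds the
populated table (one row per cohort member, one column per schema item,
nulls as empty fields) with `dcs_columns.json` mapping columns back to
SDTM element ids.

Other entry points:

```bash
pmsst describe-element SDTM:MH.MHPTCD   # metadata, mapping chain, options
pmsst generate --n 50 --seed 42 --out pop/   # Turtle + XML + ground truth
pmsst cohort --n 2000 --seed 1          # eligibility accounting only
```

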