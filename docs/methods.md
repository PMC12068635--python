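# Methods

This note documents the models, rules and numerical choices behind
`cohortforge`, in the order data flows through the engine.

## Data model

Four normalized study tables (participants, cancer events,
hospitalization events, survey responses) plus a covariate catalog are
the engine's sole input. Internally every domain table is a
string-typed table with ISO-8601 dates, so CSV serialization is the
identity: `read(write(t)) = t` byte-for-byte on re-serialization. Two
kinds of missingness are distinguished: an empty cell is plain missing
(nonresponse), while the reserved sentinel `.D` marks
missing-by-design — cells a participant could never have filled in,
e.g. survey-wave items after death. The distinction is analytically
meaningful (structural absence is not informative nonresponse) and is
enforced, not merely carried: the wide presentation table re-derives the
`.D` mask from each participant's survey-date pattern.

The presentation table is a one-row-per-participant, column-oriented
extract — participant fields, cancer events flattened to the first *k*
primaries by sequence number (*k* = 3 by default; multiple primaries are
rare, and the flattening depth is configurable), derived BMI, and every
cataloged survey covariate. It mirrors the warehouse-to-OLAP split of
production platforms: selection logic only ever reads this wide layer.

User-entered dates are accepted as `MM/DD/YYYY` at input boundaries
(spec files, wizard prompts) and normalized to ISO immediately; nothing
downstream ever sees the US form.

## Synthetic cohort generator

The generator emulates the *structure* of a large women's health cohort,
not its epidemiology. Defaults are fixed study conditions:

| parameter | default | rationale |
|---|---|---|
| enrollment window | 1995-10-27 … 1999-08-20 | first/last baseline survey dates of the emulated study |
| follow-up waves | 5, at 2/5/10/16/21 y after enrollment ± 150 d | "up to five follow-up surveys" |
| wave response probability | 0.8 per wave | plausible panel response; produces never-responders (~0.03 %) and partial responders |
| survey covariates | 1200 across 6 questionnaires | reported codebook width |
| cancer hazard | 0.012 /person-year | ≈ quarter of the cohort with cancer after ~25 y, the reported order of magnitude |
| mortality hazard | 0.013 /person-year | ≈ 28 % dead, as reported |
| hospitalization rate | 0.07 admissions/person-year | most participants hospitalized at least once over follow-up |
| surgery-code fraction | 0.05 | enough organ-surgery admissions for censoring paths to be exercised |
| item nonresponse | 3 % per present cell | distinguishes plain missing from `.D` |
| simulation horizon | 2023-12-31 | ~25 years of follow-up |

Event waiting times are exponential (constant hazard) from enrollment;
second and third primaries use 0.3 × the first-primary hazard. Constant
hazards are deliberately simple: they give closed-form expectations
(`P(event by t) = 1 − e^{−ht}`) against which the generator is tested to
±3 Monte-Carlo standard errors, and every hazard is a config knob so
tests can force corner cases (a zero hazard gives the degenerate
no-event cohort exactly). What the generator does **not** model — and
therefore what passing tests do not establish about real data — includes
age-specific incidence, secular trends, correlated covariates,
informative nonresponse, and registry reporting lag.

Determinism: output is a pure function of the config (seed included).
Survey values are generated in fixed 16,384-participant chunks, each
chunk seeded by `(seed, 7, chunk_index)`, so the in-memory and
streamed-to-disk paths emit identical bytes and the full-scale table
(133,477 × 1200) never has to reside in memory. Each participant's
`end_of_linkage` is the day after the last simulated event date, shared
cohort-wide, standing in for an administrative linkage cutoff.

Cancer events carry ICD-O-3 topography/morphology pairs drawn from a
14-site pool (breast-weighted), stage, grade and sequence number;
hospitalizations carry ICD diagnosis codes and procedure codes from a
small bundled pool. The bundled organ-surgery code sets (ICD-9-CM-style
procedure prefixes for bilateral mastectomy, hysterectomy, bilateral
oophorectomy) are pluggable defaults — real deployments must supply
curated code sets via the same CSV interface.

Deterministic scenario patches (`inject_scenario`) add the edge cases
the rules must handle: same-day diagnosis and death, prevalent cancer at
baseline, surgery preceding a breast-cancer diagnosis, a never-responder,
and a second primary. Every patch revalidates the tables and is rejected
with the validation report if it would break an invariant.

## Endpoint resolution

All code matching is **normalized prefix matching**: uppercase, strip,
drop dots, then leading-substring comparison (`C50` matches `C50.9`).
The platform this emulates does not publish matching semantics; prefix
matching is the least surprising convention for ICD hierarchies and is
monotone (a superset of prefixes never matches fewer events), which the
suite verifies as a property.

The SEER site-group recode ships as a small editable subset (breast,
uterus, ovary, colon, rectum, lung, cervix, kidney, bladder, thyroid,
pancreas, skin, plus histology-driven lymphoma / leukemia / melanoma
groups). Histology ranges are applied before site ranges, as in the
public recode definition; unmapped pairs fall through to `"other"`. A
full recode table can be substituted via the same CSV grammar.

Per-participant resolution returns the *earliest* qualifying event;
same-day ties go to the lowest sequence number (first primary).
Mortality endpoints qualify dead participants whose cause matches any
prefix, with the empty prefix set meaning all-cause. A hospitalization
phenotype qualifies a participant when their n-th qualifying admission
occurs (diagnosis prefix match in any listed — or principal-only —
position, stay ≥ the minimum), dated at that admission. The
`any_listed` default reflects that claims data rarely order diagnoses
reliably.

## Cohort construction

Exit resolution takes, per included participant, the earliest of the
candidate dates at or after start: qualifying event (only if within
`[start, end_of_study]`), first non-endpoint cancer (when other-cancer
censoring is on), earliest endpoint-organ surgery, death, and the
administrative candidate `min(end_of_study, end_of_linkage)`, which is
always present. Same-date ties use the fixed precedence
`event > other_cancer > surgery > death > admin_censor` — chosen (the
source platform is silent) to favor sensitivity of event capture and
keep output deterministic.

Design decisions worth calling out:

* **Person-time** is integer days over `[start, exit]`,
  `person_days = exit − start`; zero-day follow-up is excluded and
  logged. No time unit is prescribed upstream; days are exact and unit
  conversions are the analyst's.
* **Prevalent cancer** is any cancer diagnosed strictly before the
  *chosen* start date, not only before baseline — consistent with
  arbitrary fixed start dates.
* **Surgery censoring** is forced on for breast / uterus / ovary
  endpoints (an endpoint may touch several groups, e.g. the prefix `C5`;
  censoring then uses the earliest surgery across the touched groups).
  A surgery on or before the start date excludes the participant
  outright ("prior endpoint-organ surgery" in the attrition log): organ
  removal before follow-up begins means no organ at risk, and it keeps
  the invariant that no row's exit postdates that participant's surgery.
* **Participants entering at a later survey wave** with a cancer between
  baseline and that wave are excluded by the prevalent rule (not
  censored at the event); the alternative reading would count
  pre-entry events as outcomes.
* **Phenotype-list endpoints** in a cohort design use the first
  phenotype to drive exit/status; every phenotype contributes an
  indicator/date column pair, resolved over the full claims history.
* **Cross-sectional design** (our construction; only the design name is
  prescribed): rows are participants enrolled on/before and alive at
  the reference date with linkage coverage; the endpoint indicator
  marks a qualifying event on/before that date; no person-time columns.
  Without an endpoint section the extract is covariate-only.

The attrition log satisfies, for every run, the accounting identity
`source_n − Σ excluded = rows`, which the acceptance suite checks across
50 random specs. Frequency summaries work on any prefix of a spec
(endpoint alone, endpoint + start, …) and count explicit `<missing>` and
`<missing-by-design>` buckets so categorical counts always sum to the
eligible n.

## Covariate catalog

Selection is a pure function of (catalog, selectors): union of selector
matches, deduplicated, in catalog order, with the essential set appended
— hence idempotent and order-insensitive, and every dataset's column set
is a superset of the essential 62. The 62-count is a configuration
contract enforced wherever the essential set is consumed; the synthetic
catalog's concrete essential list is 11 participant-domain fields,
derived BMI, height/weight/smoking, and 47 generic survey items (the upstream
study does not publish its list; only the examples — key dates, BMI,
smoking status — are fixed). `participant_id` and `cause_of_death`
travel as engine-documented columns instead of catalog entries because
the catalog's type grammar (categorical-with-labels / continuous / date
/ flag) cannot honestly describe an opaque key or a free ICD string.

BMI is `weight / height²` (kg, m) from self-reported values; missing or
non-positive height propagates to missing, never an error. Synthetic
surveys are metric; imperial conversion would be a catalog-level derived
recipe, off by default.

## Deliverables and versioning

Six files per run, routed read-only data (`dataset.csv`, `formats.sas`)
vs project (`read_data.sas`, `read_data.R`, `dictionary.csv`,
`summary.md`), with SHA-256 checksums in a `manifest.json`. Versions are
`v1, v2, …` per project, allocated atomically by directory creation;
existing versions are never written again (read-only permission bits
plus refuse-overwrite at the application layer — filesystem ACLs are a
deployment concern). Tampering is detectable by re-verifying manifest
checksums.

The summary is markdown rather than PDF: deterministic, diffable,
dependency-free. Reader scripts are validated structurally (every
dataset column declared exactly once, versioned relative paths that
resolve against the data root) rather than by executing SAS or R — the
package takes no runtime dependency on either. Dictionary ↔ dataset is
a strict bijection; an undocumentable column is a hard error, not a
silent omission. Deliverables are byte-identical for identical
(dataset, spec, catalog) except the summary's timestamp line and the
embedded version counter.

Custom-data excerpts join on the universal key (`participant_id`); the
generated join script is a left join preserving dataset row count, and
the validation report flags unknown and duplicated keys.

## Selection specs, revision, CLI

A spec has six sections (endpoint, start, censoring, covariates,
custom-data, metadata), is schema-versioned, and round-trips through
JSON or YAML. Partial specs are legal and load with per-section
completeness flags (interim progress). Revision replaces exactly one
section and returns a new immutable document — revise-then-run is
byte-identical to running the equivalent hand-written spec, which the
acceptance suite asserts. Both specs and datasets are versioned (the
upstream description of "automated version control" does not say
which; versioning both is strictly safer). Concurrency is reduced to a
contract: version directories are allocated atomically, so concurrent
generation attempts serialize or fail cleanly.

The CLI mirrors the six-step wizard in the terminal (with a back
command per page) and runs headless from a spec file; the two paths
produce identical data deliverables.

## Problem sizes and tolerances

The test suite runs three cohort scales: unit (100 participants) for
semantics, 1,000 participants for oracle-equivalence and monotonicity
sweeps, desk (10,000) for accounting and end-to-end runs; the
full-scale preset (133,477 × 1200) is generated streaming and checked
structurally. Oracle equivalence is exact equality against an
independent pure-Python linear scan (20 random specs × 1,000
participants); statistical fidelity checks use ±3 Monte-Carlo standard
errors at n = 10,000. Ties, degenerate inputs (empty cohorts, zero
hazards, zero-day follow-up) and both missingness kinds are covered by
construction in the fixtures.

## Known limitations

No nested case-control matching; no ICD-9↔ICD-10 cross-walking; no
behavior-code (in-situ vs invasive) filtering for cancer endpoints —
whether the emulated platform treats in-situ disease as
endpoint-eligible is unstated, so the engine deliberately leaves
behavior out of the matching grammar rather than guess; no live
database connectivity or incremental linkage refresh; the SEER recode
subset covers common sites only. The synthetic cohort's realism caveats
are listed above: results on it demonstrate correctness of the
selection logic, not epidemiological plausibility.
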