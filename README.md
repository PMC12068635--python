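# cohortforge

Self-service cohort selection for large prospective studies.

Epidemiological cohorts accumulate decades of survey waves and registry
linkages (cancer, hospitalization, mortality), but each research project
needs only a custom slice: a time-to-event dataset defined by an
endpoint, a start-of-follow-up rule, censoring rules and a covariate
selection. Assembling those slices by hand is slow and error-prone.
`cohortforge` automates the whole cohort-selection workflow as a library
plus a small CLI, exercised entirely on a bundled synthetic cohort
generator, so every piece is testable without any controlled-access
data.

It is written for data teams of prospective cohort studies and for
methodologists who want a fully reproducible reference implementation of
cohort selection: declarative specs in, analysis-ready datasets plus
documentation out.

## The model

For participant *i* with start of follow-up `s_i` (baseline survey, a
later survey wave, or a fixed calendar date), follow-up ends at

```
e_i = min( t_event , t_other-cancer , t_surgery , t_death , t_admin )
```

the earliest of: the first endpoint-qualifying event, a cancer other
than the endpoint (optional), an organ-removing surgery (automatic for
breast / uterus / ovary endpoints: bilateral mastectomy, hysterectomy,
bilateral oophorectomy, found in linked hospitalization claims), death,
and the administrative end of study. Same-date ties resolve by that
fixed precedence; person-time is `e_i − s_i` in days. Eligibility is
applied sequentially and logged (valid start, alive at start,
prevalent-cancer exclusion, prior endpoint-organ surgery, custom
criteria), yielding an attrition table whose exclusions always sum back
to the source population.

Endpoints are computable phenotypes in ICD terms:

* **cancer** — ICD-O-3 topography prefixes and/or SEER site-group
  labels, optionally narrowed by morphology codes;
* **mortality** — ICD cause-of-death prefixes (empty set = all-cause);
* **hospitalization phenotypes** — ICD diagnosis prefixes with
  length-of-stay and admission-count requirements, several concurrently.

Every dataset automatically carries a fixed 62-member essential
covariate set (key dates, vital status, BMI, smoking status, core
baseline items) plus whatever the covariate selectors add, and every
completed run emits six deliverables: the CSV dataset, a value-label
formats file, a SAS-style data call, an R reader script, a data
dictionary covering exactly the dataset's columns, and a selection
summary — the first two routed to a read-only, versioned data directory.

## Worked example

```python
from cohortforge import default_config, generate_cohort, run_pipeline
from cohortforge.selection import SelectionSpec

tables = generate_cohort(default_config("unit", seed=1))   # 100 women

spec = SelectionSpec({
    "endpoint":  {"type": "cancer", "site_prefixes": ["C50"]},
    "start":     {"rule": "baseline"},
    "censoring": {"end_of_study": "12/31/2015"},           # MM/DD/YYYY ok
    "covariates": {"selectors": [{"section": "diet"}]},
    "custom_data": None,
    "metadata":  {"project": "demo", "design": "cohort"},
})

manifest = run_pipeline(spec, tables, "proj", "release")
print(manifest.version_id, len(manifest.entries))
```

prints `1 6`: the first retained version of the project, with all six
deliverables written. On this seed the attrition log reads

```
              criterion                  n_excluded  n_remaining
source population                                 0          100
no valid start of follow-up                       0          100
not alive at start of follow-up                   0          100
prevalent cancer at start of follow-up            0          100
prior endpoint-organ surgery                      0          100
zero days of follow-up                            0          100
```

and the dataset's exit statuses are
`{'admin_censor': 63, 'death': 20, 'other_cancer': 11, 'event': 5,
'surgery': 1}` — five incident breast cancers, one woman censored at a
bilateral mastectomy that preceded any diagnosis.

The same run works from a shell:

```
cohortforge simulate --preset desk --seed 42 --out tables/
cohortforge run --spec spec.yaml --data tables/ --project proj/
cohortforge select --out spec.yaml      # interactive six-step wizard
```

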