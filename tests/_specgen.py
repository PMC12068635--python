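"""Random selection-spec generator for oracle and accounting tests."""

from __future__ import annotations

from cohortforge.selection import SelectionSpec

SITE_CHOICES = ["C50", "C5", "C34", "C18", "C4", "C56", "C3", "C7", "C16", "C73"]
GROUP_CHOICES = ["Breast", "Ovary", "Lung and Bronchus", "Colon",
                 "Melanoma of the Skin", "Corpus Uteri"]
HIST_CHOICES = ["8070", "85", "8140", "8500"]
CAUSE_CHOICES = [["C"], ["I"], ["C50", "I21"], []]
DX_CHOICES = ["I21", "I50", "E11", "J44", "N39"]
SECTION_CHOICES = ["diet", "smoking", "anthropometry", "medical_history"]


def random_endpoint(rng) -> dict:
    u = rng.random()
    if u < 0.6:
        ep = {"type": "cancer",
              "site_prefixes": sorted(rng.choice(
                  SITE_CHOICES, size=rng.integers(1, 3), replace=False).tolist())}
        if rng.random() < 0.3:
            ep["seer_groups"] = sorted(rng.choice(
                GROUP_CHOICES, size=rng.integers(1, 3), replace=False).tolist())
        if rng.random() < 0.25:
            ep["histology_exclude"] = [str(rng.choice(HIST_CHOICES))]
        elif rng.random() < 0.2:
            ep["histology_include"] = [str(rng.choice(["8", "85", "80"]))]
        return ep
    if u < 0.8:
        return {"type": "mortality",
                "cause_prefixes": CAUSE_CHOICES[rng.integers(0, len(CAUSE_CHOICES))]}
    return {"type": "phenotypes", "phenotypes": [{
        "name": "pheno_a",
        "diagnosis_prefixes": sorted(rng.choice(
            DX_CHOICES, size=rng.integers(1, 3), replace=False).tolist()),
        "min_length_of_stay": int(rng.integers(0, 4)),
        "min_qualifying_admissions": int(rng.integers(1, 3)),
        "position_rule": "principal_only" if rng.random() < 0.3 else "any_listed",
    }]}


def random_spec(rng, project: str = "randspec") -> SelectionSpec:
    endpoint = random_endpoint(rng)
    u = rng.random()
    if u < 0.5:
        start = {"rule": "baseline"}
    elif u < 0.8:
        start = {"rule": "survey_k", "k": int(rng.integers(2, 5))}
    else:
        year = int(rng.integers(2000, 2011))
        start = {"rule": "fixed_date", "date": f"{year}-06-15"}
    censoring = {
        "end_of_study": f"{int(rng.integers(2005, 2021))}-12-31",
        "censor_other_cancers": bool(rng.random() < 0.7),
        "auto_surgery_censoring": True,
        "exclude_prevalent_cancer": bool(rng.random() < 0.8),
    }
    selectors = []
    if rng.random() < 0.5:
        selectors.append({"section": str(rng.choice(SECTION_CHOICES))})
    if rng.random() < 0.3:
        selectors.append({"questionnaire": int(rng.integers(1, 4))})
    return SelectionSpec({
        "endpoint": endpoint,
        "start": start,
        "censoring": censoring,
        "covariates": {"selectors": selectors},
        "custom_data": None,
        "metadata": {"project": project, "design": "cohort"},
    })


def oracle_params(spec: SelectionSpec) -> dict:
    """Translate a SelectionSpec into the plain-dict form the brute-force
    oracle consumes."""
    ep = spec.endpoint
    etype = ep["type"]
    endpoint = ep.get("phenotypes") if etype == "phenotypes" else ep
    return {
        "endpoint_type": etype,
        "endpoint": endpoint,
        "start_rule": spec.start,
        "end_of_study": spec.censoring["end_of_study"],
        "censor_other_cancers": spec.censoring.get("censor_other_cancers", True),
        "exclude_prevalent_cancer": spec.censoring.get("exclude_prevalent_cancer", True),
    }
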