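"""Independent brute-force oracle for endpoint and exit resolution.

Pure-Python per-participant linear scans over row dicts; deliberately
shares no code path with the package implementation (no pandas, no
vectorization).  SEER site groups are taken from the stored
``seer_group`` column rather than recomputed, so group matching is also
an independent route.
"""

from __future__ import annotations

from datetime import date


def _norm(code: str) -> str:
    return code.strip().upper().replace(".", "")


def _match_prefix(code: str, prefixes) -> bool:
    c = _norm(code)
    return any(c.startswith(_norm(p)) for p in prefixes)


def rows(frame) -> list[dict]:
    return frame.to_dict("records")


def cancer_matches(row: dict, ep: dict) -> bool:
    hit = False
    if ep.get("site_prefixes") and _match_prefix(row["site_code"], ep["site_prefixes"]):
        hit = True
    if not hit and ep.get("seer_groups") and row["seer_group"] in ep["seer_groups"]:
        hit = True
    if not hit:
        return False
    if ep.get("histology_include") and not _match_prefix(
            row["histology_code"], ep["histology_include"]):
        return False
    if ep.get("histology_exclude") and _match_prefix(
            row["histology_code"], ep["histology_exclude"]):
        return False
    return True


def first_qualifying_cancer(cancer_rows: list[dict], ep: dict):
    best = None
    for row in cancer_rows:
        if not cancer_matches(row, ep):
            continue
        key = (row["diagnosis_date"], int(row["sequence_number"]))
        if best is None or key < best[0]:
            best = (key, row)
    return None if best is None else best[1]


def phenotype_date(hosp_rows: list[dict], pheno: dict):
    """Admission date of the n-th qualifying admission, or None."""
    qualifying = []
    for row in sorted(hosp_rows, key=lambda r: r["admission_date"]):
        codes = [c for c in row["diagnosis_codes"].split(";") if c]
        if pheno.get("position_rule", "any_listed") == "principal_only":
            codes = codes[:1]
        if not any(_match_prefix(c, pheno["diagnosis_prefixes"]) for c in codes):
            continue
        los = int(row["length_of_stay"]) if row["length_of_stay"] else 0
        if los < pheno.get("min_length_of_stay", 0):
            continue
        qualifying.append(row["admission_date"])
    n = pheno.get("min_qualifying_admissions", 1)
    return qualifying[n - 1] if len(qualifying) >= n else None


SURGERY_PREFIXES = {
    "breast": ("85.42", "85.44", "85.46", "85.48"),
    "uterus": ("68.3", "68.4", "68.5", "68.6", "68.7", "68.9"),
    "ovary": ("65.51", "65.53", "65.61", "65.63"),
}

ORGAN_SITES = {"breast": ("C50",), "uterus": ("C53", "C54", "C55"),
               "ovary": ("C56",)}
ORGAN_GROUPS = {"breast": ("Breast",),
                "uterus": ("Cervix Uteri", "Corpus Uteri", "Uterus NOS"),
                "ovary": ("Ovary",)}


def surgery_groups_for(ep: dict | None, endpoint_type: str) -> list[str]:
    if endpoint_type != "cancer" or ep is None:
        return []
    groups = []
    for g, sites in ORGAN_SITES.items():
        touched = False
        for p in ep.get("site_prefixes", []):
            pn = _norm(p)
            if any(pn.startswith(_norm(s)) or _norm(s).startswith(pn) for s in sites):
                touched = True
        if set(ep.get("seer_groups", [])) & set(ORGAN_GROUPS[g]):
            touched = True
        if touched:
            groups.append(g)
    return groups


def surgery_date(hosp_rows: list[dict], groups) -> str | None:
    prefixes = [p for g in groups for p in SURGERY_PREFIXES[g]]
    best = None
    for row in hosp_rows:
        codes = [c for c in row["procedure_codes"].split(";") if c]
        if any(_match_prefix(c, prefixes) for c in codes):
            if best is None or row["admission_date"] < best:
                best = row["admission_date"]
    return best


def resolve_participant(participant: dict, cancer_rows: list[dict],
                        hosp_rows: list[dict], spec: dict):
    """Full per-participant linear-scan resolution.

    ``spec`` keys: endpoint_type, endpoint (dict or list for phenotypes),
    start_rule {"rule", "k", "date"}, end_of_study, censor_other_cancers,
    exclude_prevalent_cancer.

    Returns ("excluded", reason) or ("row", start, exit, status).
    """
    # start of follow-up
    rule = spec["start_rule"]
    if rule["rule"] == "baseline":
        start = participant["enrollment_date"]
    elif rule["rule"] == "survey_k":
        start = participant[f"survey{rule['k']}_date"] or None
    else:
        start = rule["date"]
        if participant["enrollment_date"] > start:
            start = None
        elif participant["date_of_death"] and participant["date_of_death"] < start:
            start = None
        elif participant["end_of_linkage"] < start:
            start = None
    if not start or start > spec["end_of_study"]:
        return ("excluded", "start")

    death = participant["date_of_death"] or None
    if death and death <= start:
        return ("excluded", "dead")

    if spec.get("exclude_prevalent_cancer", True):
        for row in cancer_rows:
            if row["diagnosis_date"] < start:
                return ("excluded", "prevalent")

    groups = surgery_groups_for(
        spec.get("endpoint"), spec["endpoint_type"])
    surg = surgery_date(hosp_rows, groups) if groups else None
    if surg is not None and surg <= start:
        return ("excluded", "prior_surgery")

    admin = min(spec["end_of_study"], participant["end_of_linkage"])
    candidates = [(admin, "admin_censor")]

    event = None
    if spec["endpoint_type"] == "cancer":
        hit = first_qualifying_cancer(cancer_rows, spec["endpoint"])
        if hit is not None:
            event = hit["diagnosis_date"]
    elif spec["endpoint_type"] == "mortality":
        if death:
            causes = spec["endpoint"].get("cause_prefixes", [])
            if not causes or (participant["cause_of_death"]
                              and _match_prefix(participant["cause_of_death"], causes)):
                event = death
    elif spec["endpoint_type"] == "phenotypes":
        event = phenotype_date(hosp_rows, spec["endpoint"][0])
    if event is not None and start <= event <= admin:
        candidates.append((event, "event"))

    if spec.get("censor_other_cancers", True):
        for row in cancer_rows:
            if spec["endpoint_type"] == "cancer" and cancer_matches(
                    row, spec["endpoint"]):
                continue
            if row["diagnosis_date"] >= start:
                candidates.append((row["diagnosis_date"], "other_cancer"))

    if surg is not None and surg >= start:
        candidates.append((surg, "surgery"))
    if death and death >= start:
        candidates.append((death, "death"))

    precedence = {"event": 0, "other_cancer": 1, "surgery": 2,
                  "death": 3, "admin_censor": 4}
    exit_date, status = min(candidates, key=lambda c: (c[0], precedence[c[1]]))
    if (date.fromisoformat(exit_date) - date.fromisoformat(start)).days <= 0:
        return ("excluded", "zero_days")
    return ("row", start, exit_date, status)


def resolve_all(tables, spec: dict) -> dict[str, tuple]:
    """Oracle dataset: participant_id -> (start, exit, status) for the
    participants a linear scan includes."""
    cancers_by_pid: dict[str, list[dict]] = {}
    for row in rows(tables.cancers):
        cancers_by_pid.setdefault(row["participant_id"], []).append(row)
    hosp_by_pid: dict[str, list[dict]] = {}
    for row in rows(tables.hospitalizations):
        hosp_by_pid.setdefault(row["participant_id"], []).append(row)

    out = {}
    for participant in rows(tables.participants):
        pid = participant["participant_id"]
        result = resolve_participant(
            participant, cancers_by_pid.get(pid, []), hosp_by_pid.get(pid, []), spec)
        if result[0] == "row":
            out[pid] = result[1:]
    return out
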