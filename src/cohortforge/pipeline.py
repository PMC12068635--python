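"""End-to-end orchestration: endpoint resolution → eligibility → exit
resolution → dataset assembly → deliverable generation, with per-stage
logging.  Re-running an unchanged spec yields a new version with
identical data checksums."""

from __future__ import annotations

import logging
from pathlib import Path

from .cohort import build_cohort_dataset, build_cross_sectional_dataset
from .deliverables import DeliverableManifest, generate_deliverables
from .errors import CohortForgeError
from .selection import SelectionSpec
from .study_model import StudyTables, validate_tables

logger = logging.getLogger("cohortforge")


def run_pipeline(spec: SelectionSpec, tables: StudyTables,
                 project_dir, data_dir,
                 validate: bool = True) -> DeliverableManifest:
    """Execute a complete selection spec and write the six deliverables.

    Any stage error propagates wrapped with the stage name; partial
    outputs are rolled back by the deliverables layer.
    """
    stage = "validate tables"
    try:
        if validate:
            report = validate_tables(tables)
            if not report.ok:
                raise CohortForgeError(f"input tables are invalid:\n{report}")
            logger.info("stage=%s ok participants=%d", stage, len(tables.participants))

        stage = "build dataset"
        if spec.design == "cross_sectional":
            dataset, attrition = build_cross_sectional_dataset(tables, spec)
        else:
            dataset, attrition = build_cohort_dataset(tables, spec)
        logger.info("stage=%s rows=%d columns=%d", stage, len(dataset),
                    len(dataset.columns))
        for label, excluded, remaining in attrition.rows:
            logger.info("attrition criterion=%r excluded=%d remaining=%d",
                        label, excluded, remaining)

        stage = "generate deliverables"
        manifest = generate_deliverables(dataset, spec, tables.catalog,
                                         attrition, project_dir, data_dir)
        logger.info("stage=%s version=%d files=%d", stage,
                    manifest.version_id, len(manifest.entries))
        return manifest
    except CohortForgeError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def run_pipeline_from_paths(spec_path, tables_dir, project_dir,
                            data_dir) -> DeliverableManifest:
    from .study_model import read_tables
    spec = SelectionSpec.load(Path(spec_path))
    tables = read_tables(tables_dir)
    return run_pipeline(spec, tables, project_dir, data_dir)
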