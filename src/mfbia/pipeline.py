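"""End-to-end analysis pipeline: fit → quality screen → derive → compare.

Given a cohort manifest and its spectrum files the pipeline fits each
recording, screens it, derives the eight muscle parameters, z-scores them
against the normative table, and runs the gender and pooled-age contrasts
per muscle × parameter.  The JSON report is deterministic for fixed
inputs (no timestamps) and validates against the schema shipped in
``mfbia/data/report.schema.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

from .exceptions import IncompleteDesignError, MfbiaError
from .fitting import ColeModel
from .io import read_manifest, read_spectrum
from .reference import PARAMETERS, load_reference, zscore_against_reference
from .spectra import MUSCLES
from .stats import Cohort, ComparisonResult, SubjectRecord, age_contrast, gender_contrast

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "validate_report", "write_report"]


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    manifest: Path
    output_dir: Path
    alpha_fixed: float | None = None
    significance_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    report_format: str = "json"  # "json" or "tsv" (json always written)
    rmse_fraction: float = 0.05
    min_arc_coverage: float = 0.5


class RecordingReport(BaseModel):
    subject_id: str
    muscle: str
    side: str
    gender: str
    accepted: bool
    reasons: list[str]
    cole: dict[str, float]
    derived: dict[str, float]
    zscores: dict[str, float]


class ContrastReport(BaseModel):
    parameter: str
    muscle: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test_used: str
    statistic: float
    p_value: float
    percent_change: int
    significant: bool


class ErrorEntry(BaseModel):
    spectrum_file: str
    error: str


class PipelineReport(BaseModel):
    """Machine-readable result of one pipeline run."""

    n_recordings: int
    n_accepted: int
    recordings: list[RecordingReport]
    gender_contrasts: list[ContrastReport]
    age_contrasts: list[ContrastReport]
    errors: list[ErrorEntry]


def _round_map(d: dict[str, float], digits: int = 1) -> dict[str, float]:
    # Display precision follows the normative tables: Ω/kHz/degrees to 0.1.
    return {k: round(float(v), digits) for k, v in d.items()}


def _contrast_report(c: ComparisonResult) -> ContrastReport:
    return ContrastReport(
        parameter=c.parameter,
        muscle=c.muscle,
        group_a=c.group_a_label,
        group_b=c.group_b_label,
        n_a=c.n_a,
        n_b=c.n_b,
        test_used=c.test_used,
        statistic=round(c.statistic, 4),
        p_value=float(f"{c.p_value:.6g}"),
        percent_change=c.percent_change,
        significant=c.significant,
    )


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full analysis over a cohort manifest; write and return the report.

    Per-recording failures are recorded and skipped; the run aborts only
    on configuration errors (missing manifest, bad columns).
    """
    manifest = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    reference = load_reference()

    recordings: list[RecordingReport] = []
    errors: list[ErrorEntry] = []
    subjects: dict[str, SubjectRecord] = {}

    for _, row in manifest.iterrows():
        spath = str(row["spectrum_file"])
        try:
            spectrum = read_spectrum(base / spath)
            results = ColeModel(spectrum).fit(alpha_fixed=config.alpha_fixed)
            quality = results.quality(
                rmse_fraction=config.rmse_fraction, min_arc_coverage=config.min_arc_coverage
            )
            derived = results.derived()
            muscle, gender = str(row["muscle"]), str(row["gender"])
            zs = zscore_against_reference(derived, muscle, gender, reference)
            recordings.append(
                RecordingReport(
                    subject_id=str(row["subject_id"]),
                    muscle=muscle,
                    side=str(row["side"]),
                    gender=gender,
                    accepted=quality.accepted,
                    reasons=list(quality.reasons),
                    cole=_round_map(
                        {
                            "r0": results.params.r0,
                            "rinf": results.params.rinf,
                            "fc": results.params.fc,
                            "alpha": round(results.params.alpha, 4),
                        },
                        digits=4,
                    ),
                    derived=_round_map(derived.as_dict()),
                    zscores={p: round(v["z"], 3) for p, v in zs.items()},
                )
            )
            if quality.accepted:
                sid = str(row["subject_id"])
                if sid not in subjects:
                    subjects[sid] = SubjectRecord(
                        subject_id=sid,
                        gender=gender,
                        age=float(row["age"]),
                        weight_kg=float(row["weight_kg"]),
                        height_m=float(row["height_m"]),
                        recordings={},
                    )
                subjects[sid].recordings[(muscle, str(row["side"]))] = derived
        except MfbiaError as err:
            errors.append(ErrorEntry(spectrum_file=spath, error=str(err)))

    cohort = Cohort(list(subjects.values()))
    muscles_present = sorted(
        {m for s in cohort.subjects for (m, _) in s.recordings}, key=MUSCLES.index
    )
    gender_rows: list[ContrastReport] = []
    age_rows: list[ContrastReport] = []
    for muscle in muscles_present:
        for parameter in PARAMETERS:
            try:
                gender_rows.append(_contrast_report(gender_contrast(cohort, muscle, parameter)))
            except (IncompleteDesignError, MfbiaError):
                pass
            for gender in ("men", "women"):
                try:
                    age_rows.append(
                        _contrast_report(age_contrast(cohort, muscle, parameter, gender))
                    )
                except (IncompleteDesignError, MfbiaError):
                    pass

    report = PipelineReport(
        n_recordings=len(recordings),
        n_accepted=sum(r.accepted for r in recordings),
        recordings=recordings,
        gender_contrasts=gender_rows,
        age_contrasts=age_rows,
        errors=errors,
    )
    write_report(report, config.output_dir, fmt=config.report_format)
    return report


def write_report(report: PipelineReport, output_dir, fmt: str = "json") -> None:
    """Write report.json (always) and TSV contrast tables when requested."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.model_dump_json(indent=1))
    if fmt == "tsv":
        import pandas as pd

        for name, rows in (
            ("gender_contrasts", report.gender_contrasts),
            ("age_contrasts", report.age_contrasts),
        ):
            pd.DataFrame([r.model_dump() for r in rows]).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False
            )


def validate_report(path) -> PipelineReport:
    """Parse and validate a report.json against the report model/schema."""
    return PipelineReport.model_validate_json(Path(path).read_text())


def report_schema() -> dict:
    """The JSON schema the shipped ``report.schema.json`` is generated from."""
    return PipelineReport.model_json_schema()
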