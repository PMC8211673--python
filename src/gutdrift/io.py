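"""Readers and writers for abundance tables, metadata, matrices and reports.

All formats are plain delimited text (TSV canonical, CSV accepted by file
extension).  The abundance table is wide: first column ``sample_id``, one
column per bacterial family, rows near-unit-sum relative abundances.  The
metadata table carries ``sample_id``, ``subject_id``, ``year_index`` and
optional covariate columns (age, sex, bmi, smoker, alcohol and the
``lcs_intake_days_per_week_{1m,5y,10y}`` frequencies).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    INTAKE_WINDOWS,
    CompositionProfile,
    LongitudinalCohort,
    SampleRecord,
    SubjectCovariates,
)
from .distances import DistanceMatrix
from .errors import GutdriftError
from .stability import StabilityReport

_COVARIATE_COLUMNS = ("age", "sex", "bmi", "smoker", "alcohol")


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _as_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise GutdriftError(f"cannot interpret {value!r} as a boolean")


def _covariates_from_row(row: pd.Series) -> SubjectCovariates:
    def num(col):
        v = row.get(col)
        return None if v is None or pd.isna(v) else float(v)

    intake = {}
    for window in INTAKE_WINDOWS:
        v = row.get(f"lcs_intake_days_per_week_{window}")
        if v is not None and not pd.isna(v):
            intake[window] = float(v)
    sex = row.get("sex")
    return SubjectCovariates(
        age=num("age"),
        sex=None if sex is None or pd.isna(sex) else str(sex),
        bmi=num("bmi"),
        smoker=_as_bool(row.get("smoker")),
        alcohol=_as_bool(row.get("alcohol")),
        lcs_intake_days_per_week=intake,
    )


def read_abundance_table(
    path: str | Path, metadata_path: str | Path
) -> LongitudinalCohort:
    """Read a wide abundance table plus metadata into a validated cohort.

    Rows whose sum is within 1e-6 of 1 are renormalized to exactly 1;
    anything further off raises.  Families keep the header order.  Every
    abundance row must be described in the metadata and vice versa.
    """
    ab = pd.read_csv(path, sep=_sep(path))
    if ab.columns[0] != "sample_id":
        raise GutdriftError(
            f"first abundance column must be 'sample_id', got {ab.columns[0]!r}"
        )
    meta = pd.read_csv(metadata_path, sep=_sep(metadata_path))
    required = {"sample_id", "subject_id", "year_index"}
    if not required.issubset(meta.columns):
        raise GutdriftError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    families = tuple(ab.columns[1:])
    if len(families) < 2:
        raise GutdriftError("abundance table needs at least 2 family columns")

    unknown = set(ab["sample_id"]) - set(meta.index)
    if unknown:
        raise GutdriftError(f"samples missing from metadata: {sorted(unknown)}")
    extra = set(meta.index) - set(ab["sample_id"])
    if extra:
        raise GutdriftError(f"metadata rows without abundances: {sorted(extra)}")

    samples = []
    for _, row in ab.iterrows():
        sid = str(row["sample_id"])
        profile = CompositionProfile.from_raw(families, row[list(families)].to_numpy())
        mrow = meta.loc[sid]
        samples.append(
            SampleRecord(
                sample_id=sid,
                subject_id=str(mrow["subject_id"]),
                year_index=int(mrow["year_index"]),
                profile=profile,
            )
        )
    covariates = {}
    for sid, mrow in meta.iterrows():
        subject = str(mrow["subject_id"])
        if subject not in covariates and any(
            c in meta.columns
            for c in _COVARIATE_COLUMNS
            + tuple(f"lcs_intake_days_per_week_{w}" for w in INTAKE_WINDOWS)
        ):
            covariates[subject] = _covariates_from_row(mrow)
    return LongitudinalCohort(samples, covariates)


def write_cohort(
    cohort: LongitudinalCohort,
    abundance_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a cohort back to the wide abundance + metadata pair."""
    families = list(cohort.family_names)
    ab = pd.DataFrame(
        cohort.abundance_matrix(), columns=families
    )
    ab.insert(0, "sample_id", [r.sample_id for r in cohort.samples])
    ab.to_csv(abundance_path, sep=_sep(abundance_path), index=False)

    rows = []
    for rec in cohort.samples:
        row: dict = {
            "sample_id": rec.sample_id,
            "subject_id": rec.subject_id,
            "year_index": rec.year_index,
        }
        cov = cohort.covariates.get(rec.subject_id)
        if cov is not None:
            row.update(
                age=cov.age, sex=cov.sex, bmi=cov.bmi,
                smoker=cov.smoker, alcohol=cov.alcohol,
            )
            for window, days in cov.lcs_intake_days_per_week.items():
                row[f"lcs_intake_days_per_week_{window}"] = days
        rows.append(row)
    pd.DataFrame(rows).to_csv(metadata_path, sep=_sep(metadata_path), index=False)


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Square labeled delimited text; symmetric input is re-validated."""
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.labels), columns=list(matrix.labels)
    )
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_distance_matrix(path: str | Path, metric_name: str = "jsd") -> DistanceMatrix:
    frame = pd.read_csv(path, sep=_sep(path), index_col=0)
    labels = tuple(str(c) for c in frame.columns)
    if tuple(str(i) for i in frame.index) != labels:
        raise GutdriftError("distance-matrix rows and columns disagree")
    values = frame.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # heal last-digit roundtrip asymmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values, metric_name)


def write_stability_report(report: StabilityReport, path: str | Path) -> None:
    """One tidy row per subject; missing distances are empty fields."""
    out = report.table.copy()
    out.insert(0, "threshold", report.threshold)
    out.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_stability_report(path: str | Path) -> StabilityReport:
    frame = pd.read_csv(path, sep=_sep(path), index_col="subject_id",
                        keep_default_na=False, na_values=[""])
    if "threshold" not in frame.columns:
        raise GutdriftError("not a stability report: missing 'threshold' column")
    threshold = float(frame["threshold"].iloc[0])
    table = frame.drop(columns="threshold")
    scored = table.dropna(subset=["jsd_23"])
    contingency = None
    if len(scored):
        cc = int(((scored.class_12 == "changed") & (scored.class_23 == "changed")).sum())
        cs = int(((scored.class_12 == "changed") & (scored.class_23 == "stable")).sum())
        sc = int(((scored.class_12 == "stable") & (scored.class_23 == "changed")).sum())
        ss = int(((scored.class_12 == "stable") & (scored.class_23 == "stable")).sum())
        contingency = np.array([[cc, cs], [sc, ss]])
    return StabilityReport(threshold=threshold, table=table, contingency=contingency)
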