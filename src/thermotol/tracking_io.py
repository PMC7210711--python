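"""CSV dialect for tracking exports: runs, subjects and velocity traces.

Three long-format UTF-8 CSV files with '.' decimal separator:

* ``runs.csv``      — run_id, temperature_C, label
* ``subjects.csv``  — subject_id, run_id, beaker_id, size_group,
  body_length_mm, intro_offset_s [, well_id]
* ``traces.csv``    — subject_id, run_id, well_id, sample_time_s,
  velocity_mm_s

Sample times are on the recording clock (video starts after the last
subject is introduced; each subject's introduction offset lives in
subjects.csv only) and are printed with three decimals so 1/3-s sampling
round-trips exactly to that precision.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "DEFAULT_ASSAY_RANGE_C",
]

DEFAULT_ASSAY_RANGE_C = (35.0, 40.0)

RUN_COLUMNS = ["run_id", "temperature_C", "label"]
SUBJECT_COLUMNS = [
    "subject_id", "run_id", "beaker_id", "size_group",
    "body_length_mm", "intro_offset_s",
]
TRACE_COLUMNS = ["subject_id", "run_id", "well_id", "sample_time_s", "velocity_mm_s"]

SIZE_GROUPS = {"small", "large"}


class FormatError(ValueError):
    """A file does not conform to the CSV dialect (e.g. missing column)."""


class IntegrityError(ValueError):
    """Tables violate referential integrity or a type invariant."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing column(s) {missing}")


def _read_csv(path: str | os.PathLike, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, required, name)
    return df


def read_dataset(
    runs_path: str | os.PathLike,
    subjects_path: str | os.PathLike,
    traces_path: str | os.PathLike | None = None,
    validate: bool = True,
    assay_range_C: tuple[float, float] | None = DEFAULT_ASSAY_RANGE_C,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and type the run/subject/trace tables; check cross-references.

    Raises FormatError for missing columns or unparseable numbers and
    IntegrityError (naming the offending rows) for orphan references or
    invariant violations.  ``traces_path`` may be None when only metadata is
    needed.
    """
    runs = _read_csv(runs_path, RUN_COLUMNS, "runs")
    subjects = _read_csv(subjects_path, SUBJECT_COLUMNS, "subjects")
    traces = None
    if traces_path is not None:
        traces = _read_csv(traces_path, TRACE_COLUMNS, "traces")

    try:
        runs["temperature_C"] = runs["temperature_C"].astype(float)
        subjects["body_length_mm"] = subjects["body_length_mm"].astype(float)
        subjects["intro_offset_s"] = subjects["intro_offset_s"].astype(float)
        if traces is not None:
            traces["sample_time_s"] = traces["sample_time_s"].astype(float)
            traces["velocity_mm_s"] = traces["velocity_mm_s"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in numeric column: {exc}") from None

    if traces is not None:
        traces = traces.sort_values(
            ["run_id", "subject_id", "sample_time_s"], kind="mergesort"
        ).reset_index(drop=True)
    if validate:
        validate_dataset(runs, subjects, traces, assay_range_C=assay_range_C)
    return runs, subjects, traces


def validate_dataset(
    runs: pd.DataFrame,
    subjects: pd.DataFrame,
    traces: pd.DataFrame | None = None,
    assay_range_C: tuple[float, float] | None = DEFAULT_ASSAY_RANGE_C,
) -> None:
    """Check every table invariant; raise IntegrityError naming offenders."""
    if runs["run_id"].duplicated().any():
        dups = sorted(runs.loc[runs["run_id"].duplicated(), "run_id"])
        raise IntegrityError(f"duplicate run_id(s): {dups}")
    if subjects["subject_id"].duplicated().any():
        dups = sorted(subjects.loc[subjects["subject_id"].duplicated(), "subject_id"])
        raise IntegrityError(f"duplicate subject_id(s): {dups}")

    if assay_range_C is not None:
        lo, hi = assay_range_C
        bad = runs[(runs["temperature_C"] < lo) | (runs["temperature_C"] > hi)]
        if len(bad):
            raise IntegrityError(
                f"temperature outside assay range [{lo}, {hi}] in run(s): "
                f"{sorted(bad['run_id'])}"
            )

    orphan_runs = sorted(set(subjects["run_id"]) - set(runs["run_id"]))
    if orphan_runs:
        raise IntegrityError(f"subjects reference unknown run_id(s): {orphan_runs}")

    bad_group = subjects[~subjects["size_group"].isin(SIZE_GROUPS)]
    if len(bad_group):
        raise IntegrityError(
            "invalid size_group for subject(s): "
            f"{sorted(bad_group['subject_id'])} (expected one of {sorted(SIZE_GROUPS)})"
        )
    bad_len = subjects[~(subjects["body_length_mm"] > 0)]
    if len(bad_len):
        raise IntegrityError(
            f"non-positive body_length_mm for subject(s): {sorted(bad_len['subject_id'])}"
        )
    bad_off = subjects[subjects["intro_offset_s"] < 0]
    if len(bad_off):
        raise IntegrityError(
            f"negative intro_offset_s for subject(s): {sorted(bad_off['subject_id'])}"
        )

    if traces is None or len(traces) == 0:
        return
    orphan_subj = sorted(set(traces["subject_id"]) - set(subjects["subject_id"]))
    if orphan_subj:
        raise IntegrityError(f"traces reference unknown subject_id(s): {orphan_subj}")
    v = traces["velocity_mm_s"].to_numpy()
    if not np.isfinite(v).all() or (v < 0).any():
        bad = traces.loc[~np.isfinite(v) | (v < 0), "subject_id"].unique()
        raise IntegrityError(
            f"non-finite or negative velocity for subject(s): {sorted(bad)}"
        )
    if not np.isfinite(traces["sample_time_s"].to_numpy()).all():
        raise IntegrityError("non-finite sample_time_s in traces")
    # strictly increasing sample times per subject (tables arrive sorted)
    grp = traces.groupby("subject_id", sort=False)["sample_time_s"]
    nondec = grp.apply(lambda s: bool((np.diff(s.to_numpy()) <= 0).any()))
    if nondec.any():
        raise IntegrityError(
            "non-increasing sample times for subject(s): "
            f"{sorted(nondec[nondec].index)}"
        )


def _fmt_col(s: pd.Series, fmt: str) -> pd.Series:
    return s.map(lambda x: fmt.format(x))


def write_dataset(
    runs: pd.DataFrame,
    subjects: pd.DataFrame,
    traces: pd.DataFrame | None,
    runs_path: str | os.PathLike,
    subjects_path: str | os.PathLike,
    traces_path: str | os.PathLike | None = None,
) -> None:
    """Write the tables in the dialect with deterministic row order.

    Rows are sorted (runs by run_id; subjects by run_id, subject_id; traces
    by run_id, subject_id, sample_time_s).  Times carry three decimals,
    velocities and body lengths six significant digits.
    """
    runs = runs.sort_values("run_id", kind="mergesort")
    out = runs[RUN_COLUMNS].copy()
    out["temperature_C"] = _fmt_col(out["temperature_C"].astype(float), "{:.3f}")
    out.to_csv(runs_path, index=False)

    subjects = subjects.sort_values(["run_id", "subject_id"], kind="mergesort")
    cols = SUBJECT_COLUMNS + (["well_id"] if "well_id" in subjects.columns else [])
    out = subjects[cols].copy()
    out["body_length_mm"] = _fmt_col(out["body_length_mm"].astype(float), "{:.6g}")
    out["intro_offset_s"] = _fmt_col(out["intro_offset_s"].astype(float), "{:.3f}")
    out.to_csv(subjects_path, index=False)

    if traces is None:
        return
    if traces_path is None:
        raise ValueError("traces given but no traces_path")
    traces = traces.sort_values(
        ["run_id", "subject_id", "sample_time_s"], kind="mergesort"
    )
    out = traces[TRACE_COLUMNS].copy()
    out["sample_time_s"] = _fmt_col(out["sample_time_s"].astype(float), "{:.3f}")
    out["velocity_mm_s"] = _fmt_col(out["velocity_mm_s"].astype(float), "{:.6g}")
    out.to_csv(traces_path, index=False)
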