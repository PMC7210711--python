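"""Time-to-immobilisation (T_imm) detection from velocity traces.

T_imm is the time from a subject's introduction into the heated well until
its swimming velocity is *last* observed above a threshold.  Velocity traces
are clocked from the start of video recording, which begins only after the
last subject of a run has been introduced, so each subject's introduction
offset is added back:

    timm_min = (intro_offset_s + time of last qualifying sample) / 60

A qualifying sample is one that begins a bout of at least
``min_bout_samples`` consecutive supra-threshold samples (with the default
of 1 this is literally the last sample above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DetectionConfig",
    "TimmEstimate",
    "EmptyTraceError",
    "estimate_timm",
    "detect_batch",
    "FLAG_OK",
    "FLAG_NEVER_MOVED",
    "FLAG_RIGHT_CENSORED",
    "FLAG_GAP_WARNING",
]

FLAG_OK = "ok"
FLAG_NEVER_MOVED = "never_moved"
FLAG_RIGHT_CENSORED = "right_censored"
FLAG_GAP_WARNING = "gap_warning"

#: flags whose estimates feed the TDTC / mixed-model stages
USABLE_FLAGS = (FLAG_OK, FLAG_GAP_WARNING)


class EmptyTraceError(ValueError):
    """An empty trace is an input error, distinct from a never-moving subject."""


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the T_imm detector.

    velocity_threshold_mm_s: speed above which a sample counts as swimming.
    min_bout_samples: consecutive supra-threshold samples required for a
        crossing to count (1 = the literal last supra-threshold sample).
    max_gap_s: largest tolerated gap between samples before the estimate is
        flagged with a gap warning.
    """

    velocity_threshold_mm_s: float = 1.0
    min_bout_samples: int = 1
    max_gap_s: float = 2.0

    def validate(self) -> None:
        if self.velocity_threshold_mm_s <= 0:
            raise ValueError("velocity_threshold_mm_s must be > 0")
        if self.min_bout_samples < 1:
            raise ValueError("min_bout_samples must be >= 1")
        if self.max_gap_s <= 0:
            raise ValueError("max_gap_s must be > 0")


@dataclass(frozen=True)
class TimmEstimate:
    """Detected time-to-immobilisation for one subject.

    ``timm_min`` is None when the subject was never observed above
    threshold (flag ``never_moved``).
    """

    subject_id: str
    timm_min: float | None
    flag: str

    @property
    def usable(self) -> bool:
        return self.flag in USABLE_FLAGS


def estimate_timm(
    trace: pd.DataFrame,
    intro_offset_s: float,
    config: DetectionConfig | None = None,
    subject_id: str = "",
) -> TimmEstimate:
    """Estimate T_imm from one subject's velocity trace.

    ``trace`` needs columns ``sample_time_s`` (strictly increasing) and
    ``velocity_mm_s``.  Flag precedence: never_moved > right_censored >
    gap_warning > ok.
    """
    config = config or DetectionConfig()
    config.validate()
    if len(trace) == 0:
        raise EmptyTraceError(f"empty trace for subject {subject_id!r}")
    if intro_offset_s < 0:
        raise ValueError("intro_offset_s must be >= 0")

    times = np.asarray(trace["sample_time_s"], dtype=float)
    vel = np.asarray(trace["velocity_mm_s"], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"sample times not strictly increasing for {subject_id!r}")

    above = vel > config.velocity_threshold_mm_s
    m = config.min_bout_samples
    if m == 1:
        qualifies = above
    else:
        # sample i qualifies if it starts >= m consecutive supra-threshold samples
        window = np.lib.stride_tricks.sliding_window_view(above, m)
        qualifies = np.zeros_like(above)
        qualifies[: len(window)] = window.all(axis=1)

    if not qualifies.any():
        return TimmEstimate(subject_id, None, FLAG_NEVER_MOVED)

    last = int(np.flatnonzero(qualifies)[-1])
    timm_min = (intro_offset_s + times[last]) / 60.0

    if len(above) >= m and above[-m:].all():
        flag = FLAG_RIGHT_CENSORED
    elif len(times) > 1 and np.max(np.diff(times)) > config.max_gap_s:
        flag = FLAG_GAP_WARNING
    else:
        flag = FLAG_OK
    return TimmEstimate(subject_id, timm_min, flag)


def detect_batch(
    subjects: pd.DataFrame,
    traces: pd.DataFrame,
    config: DetectionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the detector over every subject of a dataset.

    Traces are re-sorted by sample time internally, so input row order is
    irrelevant.  Returns (estimates, qc): estimates has one row per subject
    (subject_id, timm_min, flag); qc counts subjects per flag plus
    ``n_usable`` (subjects whose estimate feeds the downstream models —
    never-moving and right-censored subjects are excluded).
    """
    config = config or DetectionConfig()
    traces = traces.sort_values(["subject_id", "sample_time_s"], kind="mergesort")
    by_subject = dict(iter(traces.groupby("subject_id", sort=False)))

    rows = []
    for row in subjects.itertuples(index=False):
        tr = by_subject.get(row.subject_id)
        if tr is None or len(tr) == 0:
            raise EmptyTraceError(f"no trace rows for subject {row.subject_id!r}")
        est = estimate_timm(tr, row.intro_offset_s, config, subject_id=row.subject_id)
        rows.append({"subject_id": est.subject_id, "timm_min": est.timm_min,
                     "flag": est.flag})
    estimates = pd.DataFrame(rows, columns=["subject_id", "timm_min", "flag"])

    counts = estimates["flag"].value_counts().to_dict()
    qc = {flag: int(counts.get(flag, 0))
          for flag in (FLAG_OK, FLAG_GAP_WARNING, FLAG_RIGHT_CENSORED,
                       FLAG_NEVER_MOVED)}
    qc["n_subjects"] = int(len(estimates))
    qc["n_usable"] = int(estimates["flag"].isin(USABLE_FLAGS).sum())
    return estimates, qc
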