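"""Synthetic heat-tolerance assays for *Daphnia*-style knock-down experiments.

Generates complete experiments — run metadata, subject metadata and
velocity traces — with the statistical structure the downstream analysis
assumes: knock-down times that follow the thermal death time relationship

    log10 t = beta0 + beta_T * T + beta_S * S + beta_TS * T * S
              + u_beaker + u_run + eps

on the log10-minutes scale, with crossed Gaussian random intercepts for
source beaker and measuring run, and i.i.d. Gaussian residuals per subject.
The assay protocol is emulated in detail: a fixed panel of exposure
temperatures, several measuring runs per temperature, twenty subjects per
run drawn as one small and one large individual from each source beaker,
staggered introduction into the heated wells over a few minutes, and video
tracking (velocity in mm/s) that starts only after the last introduction.

The latent knock-down time of each subject (``TrueKnockdown``) is carried
alongside the observable tables so that detection and model fitting can be
validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "TrueKnockdown",
    "generate_experiment",
    "generate_traces",
    "simulate_trace",
    "compress_time",
    "truths_to_json",
    "truths_from_json",
]


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig violates one of its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters of a synthetic heat-tolerance experiment.

    Times are log10 minutes; temperatures are °C; body sizes are mm (gut
    length). Defaults reproduce the published assay design: exposure
    temperatures 35–40 °C in 1 °C steps, 14 measuring runs (3,2,2,2,2,3 per
    temperature), 20 subjects per run (10 small + 10 large, one of each per
    source beaker), 10 beakers, introduction staggered over 3–6 min, and
    3 Hz velocity sampling.

    The default coefficients put the mean small subject at log10 t = 1.1 at
    40 °C (≈ 12.6 min, with the briefest large-subject knock-downs around
    5 min) and ≈ 2240 min (> 15 h) at 35 °C, with temperature sensitivity
    z = −1/beta_T ≈ 2.2 °C and a negative size effect on elevation.
    """

    temperatures: tuple[float, ...] = (35.0, 36.0, 37.0, 38.0, 39.0, 40.0)
    runs_per_temperature: tuple[int, ...] = (3, 2, 2, 2, 2, 3)
    subjects_per_run: int = 20
    n_beakers: int = 10

    # fixed effects on log10 minutes
    beta0: float = 19.2368
    beta_T: float = -0.45
    beta_S: float = -0.12
    beta_TS: float = 0.0

    # variance components (SDs on log10 minutes)
    sigma_beaker: float = 0.05
    sigma_run: float = 0.05
    sigma_resid: float = 0.10

    # body-size distributions (truncated normal, mm)
    size_small_mean: float = 1.14
    size_small_sd: float = 0.12
    size_small_range: tuple[float, float] = (0.92, 1.51)
    size_large_mean: float = 2.70
    size_large_sd: float = 0.15
    size_large_range: tuple[float, float] = (2.37, 3.17)

    # protocol timing
    intro_window_s: tuple[float, float] = (180.0, 360.0)
    sample_rate_hz: float = 3.0
    trace_tail_s: float = 60.0  # recording margin after the last knock-down

    # active-swimming process: alternating move/pause bouts; move speeds
    # lognormal (median 5 mm/s); sub-threshold tracking jitter elsewhere
    move_speed_median_mm_s: float = 5.0
    move_speed_sigma_log: float = 0.35
    move_bout_s: tuple[float, float] = (0.5, 2.0)
    pause_bout_s: tuple[float, float] = (0.1, 0.7)
    jitter_ceiling_mm_s: float = 0.3

    seed: int = 0

    def validate(self) -> None:
        if len(self.temperatures) != len(self.runs_per_temperature):
            raise ConfigurationError(
                "temperatures and runs_per_temperature must have equal length"
            )
        if any(k < 1 for k in self.runs_per_temperature):
            raise ConfigurationError("runs_per_temperature entries must be >= 1")
        if self.subjects_per_run < 2 or self.subjects_per_run % 2:
            raise ConfigurationError(
                "subjects_per_run must be even (two equal size groups); got "
                f"{self.subjects_per_run}"
            )
        if self.n_beakers < 1:
            raise ConfigurationError("n_beakers must be >= 1")
        if self.beta_T >= 0:
            raise ConfigurationError(
                "beta_T must be negative: knock-down time decreases with temperature"
            )
        for name in ("sigma_beaker", "sigma_run", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be > 0")
        lo, hi = self.intro_window_s
        if not lo < hi:
            raise ConfigurationError("intro_window_s must satisfy min < max")
        s_lo, s_hi = self.size_small_range
        l_lo, l_hi = self.size_large_range
        if not (s_lo < s_hi and l_lo < l_hi):
            raise ConfigurationError("size ranges must be non-degenerate")
        if s_hi >= l_lo:
            raise ConfigurationError(
                "small and large size ranges must not overlap "
                f"(small up to {s_hi}, large from {l_lo})"
            )
        if self.jitter_ceiling_mm_s < 0:
            raise ConfigurationError("jitter_ceiling_mm_s must be >= 0")

    @property
    def n_runs(self) -> int:
        return int(sum(self.runs_per_temperature))

    @property
    def n_subjects(self) -> int:
        return self.n_runs * self.subjects_per_run

    def z_true(self) -> float:
        """Generating temperature sensitivity coefficient, −1/beta_T (°C)."""
        return -1.0 / self.beta_T


@dataclass(frozen=True)
class TrueKnockdown:
    """Latent truth for one subject: minutes from introduction to knock-down."""

    subject_id: str
    t_true_min: float

    def __post_init__(self) -> None:
        if not self.t_true_min > 0:
            raise ValueError("t_true_min must be > 0")


def compress_time(config: SyntheticConfig, factor: float) -> SyntheticConfig:
    """Rescale every knock-down time (and the introduction window) by `factor`.

    Shifts the TDTC elevation by log10(factor) and scales the introduction
    window, leaving temperature sensitivity, size effects, noise structure
    and the relative introduction stagger unchanged.  Used to run trace-level
    experiments at a short absolute time scale.
    """
    if factor <= 0:
        raise ConfigurationError("factor must be > 0")
    lo, hi = config.intro_window_s
    return dataclasses.replace(
        config,
        beta0=config.beta0 + math.log10(factor),
        intro_window_s=(lo * factor, hi * factor),
    )


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    # Deterministic sub-stream per (purpose, run, subject): adding runs or
    # subjects never perturbs draws of earlier ones.
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _draw_sizes(
    rng: np.random.Generator, n: int, mean: float, sd: float, rng_mm: tuple[float, float]
) -> np.ndarray:
    lo, hi = rng_mm
    if sd <= 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_experiment(
    config: SyntheticConfig | None = None, with_traces: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, list[TrueKnockdown]]:
    """Generate one complete synthetic experiment.

    Returns ``(runs, subjects, traces, truths)``.  ``runs`` has one row per
    measuring run (run_id, temperature_C, label); ``subjects`` one row per
    individual (subject_id, run_id, beaker_id, size_group, body_length_mm,
    intro_offset_s, well_id); ``traces`` the long-format velocity table (or
    None when ``with_traces`` is False — the full-scale default produces
    multi-hour recordings at 3 Hz, tens of millions of rows); ``truths`` the
    latent knock-down times used only for validation.

    Each run draws one small and one large subject per beaker (when
    subjects_per_run == 2·n_beakers; otherwise beakers are recycled as evenly
    as possible).  Introduction is staggered evenly over a uniformly drawn
    3–6 min window, small group first, so the video (which starts at the last
    introduction) rarely misses the less heat-tolerant large subjects.
    Deterministic given ``config.seed``.
    """
    config = config or SyntheticConfig()
    config.validate()

    u_beaker = _rng(config, 0).normal(0.0, config.sigma_beaker, config.n_beakers)
    beaker_ids = [f"B{i + 1:02d}" for i in range(config.n_beakers)]

    run_rows = []
    subj_rows = []
    truths: list[TrueKnockdown] = []

    n_per_group = config.subjects_per_run // 2
    run_index = 0
    for temp, n_runs_t in zip(config.temperatures, config.runs_per_temperature):
        for rep in range(n_runs_t):
            run_id = f"R{run_index + 1:02d}"
            rng = _rng(config, 1, run_index)
            u_run = rng.normal(0.0, config.sigma_run)
            run_rows.append(
                {"run_id": run_id, "temperature_C": float(temp),
                 "label": f"T{temp:g}_rep{rep + 1}"}
            )

            # one small and one large individual per beaker, beaker order shuffled
            order_small = rng.permutation(config.n_beakers)
            order_large = rng.permutation(config.n_beakers)
            beakers_small = [beaker_ids[order_small[i % config.n_beakers]]
                             for i in range(n_per_group)]
            beakers_large = [beaker_ids[order_large[i % config.n_beakers]]
                             for i in range(n_per_group)]

            sizes_small = _draw_sizes(rng, n_per_group, config.size_small_mean,
                                      config.size_small_sd, config.size_small_range)
            sizes_large = _draw_sizes(rng, n_per_group, config.size_large_mean,
                                      config.size_large_sd, config.size_large_range)

            # staggered introduction: small group first, evenly spaced over D
            D = rng.uniform(*config.intro_window_s)
            n = config.subjects_per_run
            offsets = D * (n - 1 - np.arange(n)) / (n - 1)

            groups = ["small"] * n_per_group + ["large"] * n_per_group
            beakers = beakers_small + beakers_large
            sizes = np.concatenate([sizes_small, sizes_large])
            eps = rng.normal(0.0, config.sigma_resid, n)

            for j in range(n):
                subject_id = f"{run_id}-{j + 1:02d}"
                S = float(sizes[j])
                b_idx = beaker_ids.index(beakers[j])
                log10_t = (
                    config.beta0
                    + config.beta_T * temp
                    + config.beta_S * S
                    + config.beta_TS * temp * S
                    + u_beaker[b_idx]
                    + u_run
                    + eps[j]
                )
                subj_rows.append(
                    {
                        "subject_id": subject_id,
                        "run_id": run_id,
                        "beaker_id": beakers[j],
                        "size_group": groups[j],
                        "body_length_mm": S,
                        "intro_offset_s": float(offsets[j]),
                        "well_id": f"W{j + 1:02d}",
                    }
                )
                truths.append(TrueKnockdown(subject_id, float(10.0 ** log10_t)))
            run_index += 1

    runs = pd.DataFrame(run_rows)
    subjects = pd.DataFrame(subj_rows)
    traces = generate_traces(runs, subjects, truths, config) if with_traces else None
    return runs, subjects, traces, truths


# ---------------------------------------------------------------------------
# velocity traces
# ---------------------------------------------------------------------------

def _bout_boundaries(
    rng: np.random.Generator, config: SyntheticConfig, horizon_s: float
) -> np.ndarray:
    """Cumulative end-times of alternating move/pause bouts covering [0, horizon]."""
    mean_cycle = (sum(config.move_bout_s) + sum(config.pause_bout_s)) / 2.0
    bounds = [np.empty(0)]
    total = 0.0
    while total <= horizon_s:
        k = max(16, int((horizon_s - total) / mean_cycle * 1.3) + 4)
        moves = rng.uniform(*config.move_bout_s, size=k)
        pauses = rng.uniform(*config.pause_bout_s, size=k)
        chunk = total + np.cumsum(np.column_stack([moves, pauses]).ravel())
        bounds.append(chunk)
        total = chunk[-1]
    return np.concatenate(bounds)


def simulate_trace(
    t_true_min: float,
    intro_offset_s: float,
    recording_duration_s: float,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one subject's velocity trace on the recording clock.

    The subject is introduced ``intro_offset_s`` seconds before recording
    starts and loses locomotory function ``t_true_min`` minutes after its own
    introduction, i.e. at recording time ``t_true_min*60 − intro_offset_s``
    (which may be negative: such a subject is never seen moving).  Before
    knock-down, velocity follows alternating move/pause bouts with move
    speeds well above the detection threshold; pauses and everything after
    knock-down are sub-threshold tracking jitter.

    Returns a DataFrame with columns ``sample_time_s`` and ``velocity_mm_s``
    sampled at ``config.sample_rate_hz``.
    """
    config = config or SyntheticConfig()
    if t_true_min <= 0:
        raise ValueError("t_true_min must be > 0")
    if intro_offset_s < 0 or recording_duration_s < 0:
        raise ValueError("offsets and durations must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    dt = 1.0 / config.sample_rate_hz
    n = int(math.floor(recording_duration_s / dt)) + 1
    times = np.arange(n) * dt
    intro_clock = times + intro_offset_s
    t_knock_s = t_true_min * 60.0

    moving = intro_clock < t_knock_s
    velocity = rng.uniform(0.0, config.jitter_ceiling_mm_s, size=n)
    if moving.any():
        horizon = min(t_knock_s, intro_clock[moving][-1]) + 1.0
        bounds = _bout_boundaries(rng, config, horizon)
        # even-indexed intervals (0, b0], (b1, b2], ... are move bouts
        idx = np.searchsorted(bounds, intro_clock[moving], side="left")
        in_move = idx % 2 == 0
        speeds = rng.lognormal(
            mean=math.log(config.move_speed_median_mm_s),
            sigma=config.move_speed_sigma_log,
            size=int(in_move.sum()),
        )
        mv = velocity[moving]
        mv[in_move] = speeds
        velocity[moving] = mv
    return pd.DataFrame({"sample_time_s": times, "velocity_mm_s": velocity})


def generate_traces(
    runs: pd.DataFrame,
    subjects: pd.DataFrame,
    truths: Sequence[TrueKnockdown],
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Velocity traces for every subject of an experiment.

    Each run is recorded from the last introduction until
    ``config.trace_tail_s`` seconds after the run's final knock-down; all
    subjects of a run share that recording duration, as a fixed overhead
    camera would.
    """
    config = config or SyntheticConfig()
    t_true = {t.subject_id: t.t_true_min for t in truths}
    pieces = []
    run_order = {rid: i for i, rid in enumerate(runs["run_id"])}
    for run_id, grp in subjects.groupby("run_id", sort=False):
        knock_rec = grp["subject_id"].map(t_true).to_numpy() * 60.0 - grp[
            "intro_offset_s"
        ].to_numpy()
        duration = max(float(knock_rec.max()), 0.0) + config.trace_tail_s
        for j, row in enumerate(grp.itertuples(index=False)):
            rng = _rng(config, 2, run_order[run_id], j)
            tr = simulate_trace(
                t_true[row.subject_id], row.intro_offset_s, duration, config, rng
            )
            tr.insert(0, "subject_id", row.subject_id)
            tr.insert(1, "run_id", run_id)
            tr.insert(2, "well_id", row.well_id)
            pieces.append(tr)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# truth sidecar (JSON, for tests and recovery reports)
# ---------------------------------------------------------------------------

def truths_to_json(truths: Sequence[TrueKnockdown], config: SyntheticConfig) -> str:
    payload = {
        "config": dataclasses.asdict(config),
        "true_knockdown_min": {t.subject_id: t.t_true_min for t in truths},
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def truths_from_json(text: str) -> tuple[list[TrueKnockdown], dict]:
    payload = json.loads(text)
    truths = [
        TrueKnockdown(sid, t) for sid, t in sorted(payload["true_knockdown_min"].items())
    ]
    return truths, payload["config"]
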