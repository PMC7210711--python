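"""Thermal death time curves: log10 knock-down time vs exposure temperature.

The TDTC model is the semi-logarithmic relationship

    log10 t = (CTmax − T) / z

where t is knock-down time in minutes, T the exposure temperature (°C),
z the temperature sensitivity coefficient and CTmax the upper thermal limit
— the temperature at which log10 t = 0, i.e. knock-down within one minute.
Fitting is ordinary least squares of log10(t) on T; then z = −1/slope and
CTmax = −intercept/slope (the regression's x-intercept).  A high z means
*low* sensitivity: tolerance declines more slowly with temperature.

Time is in minutes throughout; CTmax is unit-dependent (it is the
temperature where t equals one time unit), so minutes are part of the
model's definition here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TDTCFit",
    "PooledTDTCFit",
    "fit_tdtc",
    "predict_time",
    "fit_tdtc_by_group",
]


@dataclass(frozen=True)
class TDTCFit:
    """OLS fit of log10(knock-down minutes) on temperature.

    ``z_C`` (= −1/slope) and ``ctmax_C`` (= −intercept/slope) are NaN and
    ``valid`` is False when the slope is non-negative, in which case the
    thermal-death interpretation does not apply.  ``extrapolated`` records
    whether CTmax lies outside the observed temperature range (it usually
    does: CTmax is obtained by extrapolating the regression to log t = 0).
    """

    slope: float
    intercept: float
    z_C: float
    ctmax_C: float
    n_points: int
    group_label: str = ""
    valid: bool = True
    extrapolated: bool = True

    @property
    def elevation(self) -> float:
        """Intercept of the fit: overall magnitude of heat tolerance."""
        return self.intercept


def fit_tdtc(
    temperature_C: np.ndarray | list,
    timm_min: np.ndarray | list,
    group_label: str = "",
) -> TDTCFit:
    """Fit a TDTC by OLS of log10(timm_min) on temperature.

    Requires at least two distinct temperatures and strictly positive times.
    A non-negative slope yields a fit with ``valid=False`` (z and CTmax NaN)
    and a warning; CTmax outside the observed range warns about
    extrapolation.
    """
    T = np.asarray(temperature_C, dtype=float)
    t = np.asarray(timm_min, dtype=float)
    if T.shape != t.shape or T.ndim != 1:
        raise ValueError("temperature and time arrays must be 1-D and equal length")
    if len(T) < 2 or len(np.unique(T)) < 2:
        raise ValueError("need >= 2 points at >= 2 distinct temperatures")
    if not (t > 0).all():
        raise ValueError("all knock-down times must be > 0")

    res = stats.linregress(T, np.log10(t))
    slope, intercept = float(res.slope), float(res.intercept)

    if slope >= 0:
        warnings.warn(
            f"non-negative TDTC slope ({slope:.4g}) for group {group_label!r}; "
            "z and CTmax are undefined",
            stacklevel=2,
        )
        return TDTCFit(slope, intercept, float("nan"), float("nan"),
                       len(T), group_label, valid=False)

    z = -1.0 / slope
    ctmax = -intercept / slope
    extrapolated = not (T.min() <= ctmax <= T.max())
    if extrapolated:
        warnings.warn(
            f"CTmax = {ctmax:.2f} °C lies outside the observed range "
            f"[{T.min():g}, {T.max():g}] °C (extrapolation)",
            stacklevel=2,
        )
    return TDTCFit(slope, intercept, z, ctmax, len(T), group_label,
                   valid=True, extrapolated=extrapolated)


def predict_time(fit: TDTCFit, temperature_C: float | np.ndarray) -> float | np.ndarray:
    """Predicted knock-down time (minutes) at a temperature.

    Evaluates t = 10**((CTmax − T)/z), identically 10**(intercept + slope·T).
    At T = CTmax the prediction is exactly one minute.
    """
    if not fit.valid:
        raise ValueError("cannot predict from an invalid fit (non-negative slope)")
    T = np.asarray(temperature_C, dtype=float)
    out = 10.0 ** ((fit.ctmax_C - T) / fit.z_C)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PooledTDTCFit:
    """Common-slope fit across groups: per-group elevations, shared z."""

    slope: float
    z_C: float
    elevations: dict[str, float]
    n_points: int

    def elevation_difference(self, a: str, b: str) -> float:
        """Elevation of group ``a`` minus group ``b`` (log10 minutes)."""
        return self.elevations[a] - self.elevations[b]


def fit_tdtc_by_group(
    estimates: pd.DataFrame,
    subjects: pd.DataFrame,
    runs: pd.DataFrame,
    grouping: str = "size_group",
) -> tuple[dict[str, TDTCFit], PooledTDTCFit]:
    """Fit one TDTC per group plus a pooled common-slope fit.

    ``estimates`` must carry subject_id, timm_min and (optionally) flag;
    rows whose flag is not usable, or with missing timm_min, are dropped.
    Groups observed at fewer than two distinct temperatures are skipped with
    a warning.  The pooled fit regresses log10 t on temperature with a
    separate intercept per group and one shared slope, giving the elevation
    difference between groups at equal temperature sensitivity.
    """
    df = estimates.merge(subjects, on="subject_id").merge(
        runs[["run_id", "temperature_C"]], on="run_id"
    )
    if "flag" in df.columns:
        from .knockdown import USABLE_FLAGS

        df = df[df["flag"].isin(USABLE_FLAGS)]
    df = df.dropna(subset=["timm_min"])
    if df.empty:
        raise ValueError("no usable estimates to fit")

    fits: dict[str, TDTCFit] = {}
    for label, grp in df.groupby(grouping, sort=True):
        if grp["temperature_C"].nunique() < 2:
            warnings.warn(
                f"group {label!r} observed at < 2 temperatures; skipped",
                stacklevel=2,
            )
            continue
        fits[str(label)] = fit_tdtc(
            grp["temperature_C"].to_numpy(), grp["timm_min"].to_numpy(), str(label)
        )

    # pooled: log10 t ~ C(group) + T  (common slope, per-group intercept)
    y = np.log10(df["timm_min"].to_numpy(dtype=float))
    T = df["temperature_C"].to_numpy(dtype=float)
    labels = sorted(df[grouping].astype(str).unique())
    X = np.column_stack(
        [(df[grouping].astype(str) == g).to_numpy(float) for g in labels] + [T]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(coef[-1])
    z = -1.0 / slope if slope < 0 else float("nan")
    pooled = PooledTDTCFit(
        slope=slope,
        z_C=z,
        elevations={g: float(c) for g, c in zip(labels, coef[:-1])},
        n_points=int(len(df)),
    )
    return fits, pooled
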