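"""Candidate mixed models for knock-down time and their AICc comparison.

Three linear mixed models for log10(T_imm minutes) are fitted by maximum
likelihood and compared with AICc weights:

1. temperature × size  — body size may change the TDTC slope (and hence z)
2. temperature + size  — size shifts only the elevation, z is shared
3. temperature         — no size effect at all

All three share crossed Gaussian random intercepts for source beaker and
measuring run, so each subject's expected response is

    X·beta + u_beaker + u_run,    u_b ~ N(0, s2_beaker), u_r ~ N(0, s2_run)

Body size enters as a continuous covariate (mm).  Temperature is centered
at its sample mean for optimizer stability and coefficients are reported
back on the natural scale.  The parameter count k is the number of fixed
coefficients plus two variance components plus the residual variance.

Fitting is delegated to statsmodels' MixedLM (variance-components
formulation, ML); its solution is then polished by an exact
profiled-likelihood optimizer over the two variance ratios, which also
takes over entirely if MixedLM fails to converge.  The reported
log-likelihood is the exact marginal Gaussian log-likelihood at the
optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LMMSpec",
    "LMMFit",
    "ModelComparisonTable",
    "ConvergenceError",
    "CANDIDATE_SPECS",
    "build_model_frame",
    "fit_lmm",
    "count_parameters",
    "aicc",
    "delta_aicc",
    "akaike_weights",
    "compare_models",
    "r_squared",
]

N_VARIANCE_COMPONENTS = 2  # beaker + run
_BOUNDARY_REL = 1e-8


class ConvergenceError(RuntimeError):
    """ML optimization failed; carries the optimizer diagnostics."""


@dataclass(frozen=True)
class LMMSpec:
    """One candidate model: a fixed-effect structure over the shared
    random-intercept skeleton (beaker + run, crossed) and log10 response."""

    label: str          # e.g. "temperature × size"
    fixed_terms: tuple[str, ...]   # subset of ("temperature", "size", "temperature:size")

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.fixed_terms)  # + intercept


SPEC_INTERACTION = LMMSpec(
    "temperature × size", ("temperature", "size", "temperature:size")
)
SPEC_ADDITIVE = LMMSpec("temperature + size", ("temperature", "size"))
SPEC_TEMPERATURE = LMMSpec("temperature", ("temperature",))

#: the three candidate models, full first
CANDIDATE_SPECS = (SPEC_INTERACTION, SPEC_ADDITIVE, SPEC_TEMPERATURE)


def count_parameters(spec: LMMSpec) -> int:
    """k = fixed coefficients + 2 variance components + residual variance."""
    return spec.n_fixed + N_VARIANCE_COMPONENTS + 1


def build_model_frame(
    estimates: pd.DataFrame, subjects: pd.DataFrame, runs: pd.DataFrame
) -> pd.DataFrame:
    """Merge detection output with metadata into the modelling table.

    Keeps only usable estimates (drops never-moved and right-censored
    subjects) and adds the log10-minutes response.
    """
    from .knockdown import USABLE_FLAGS

    df = estimates.merge(subjects, on="subject_id").merge(
        runs[["run_id", "temperature_C"]], on="run_id"
    )
    if "flag" in df.columns:
        df = df[df["flag"].isin(USABLE_FLAGS)]
    df = df.dropna(subset=["timm_min"]).copy()
    if not (df["timm_min"] > 0).all():
        raise ValueError("timm_min must be positive to take log10")
    df["log10_timm"] = np.log10(df["timm_min"].astype(float))
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class LMMFit:
    """An ML-fitted candidate model.

    ``beta`` holds natural-scale fixed effects keyed "intercept",
    "temperature", "size", "temperature:size" (as present); ``beta_se`` their
    standard errors from the GLS covariance at the ML variance estimates.
    ``vc`` holds the beaker and run intercept variances, ``sigma2_resid`` the
    residual variance, all on the log10-minutes scale.  ``boundary`` is True
    when a variance component sits at (numerically) zero.
    """

    spec: LMMSpec
    beta: dict[str, float]
    beta_se: dict[str, float]
    vc: dict[str, float]
    sigma2_resid: float
    loglik: float
    k: int
    n: int
    converged: bool
    boundary: bool
    method: str
    _y: np.ndarray = field(repr=False)
    _yhat_cond: np.ndarray = field(repr=False)
    _yhat_marg: np.ndarray = field(repr=False)


def _design(data: pd.DataFrame, spec: LMMSpec) -> tuple[np.ndarray, list[str], float]:
    """Fixed-effect design with centered temperature; returns (X, names, Tmean)."""
    T = data["temperature_C"].to_numpy(dtype=float)
    Tm = float(T.mean())
    Tc = T - Tm
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term == "temperature":
            cols.append(Tc)
        elif term == "size":
            cols.append(data["body_length_mm"].to_numpy(dtype=float))
        elif term == "temperature:size":
            cols.append(Tc * data["body_length_mm"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown fixed term {term!r}")
        names.append(term)
    return np.column_stack(cols), names, Tm


def _indicator(codes: pd.Series) -> np.ndarray:
    levels = sorted(codes.unique())
    lut = {lev: i for i, lev in enumerate(levels)}
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes.map(lut).to_numpy()] = 1.0
    return Z


class _ProfiledML:
    """Exact profiled ML objective for the crossed-intercept model.

    Works on the two variance *ratios* gamma = (s2_beaker, s2_run)/s2_resid;
    the residual variance and the fixed effects are profiled out in closed
    form.  The marginal covariance is handled through its low-rank structure
    (Woodbury identity on the q = n_beakers + n_runs random-effect columns),
    so one objective evaluation costs O(q^3) after an O(n q^2) setup.
    """

    def __init__(self, y, X, Zb, Zr):
        U = np.hstack([Zb, Zr])
        self.nb = Zb.shape[1]
        self.n = len(y)
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.q = U.shape[1]

    def nll(self, log_gamma):
        return self.solve(log_gamma)[0]

    def solve(self, log_gamma):
        gb, gr = np.exp(np.clip(log_gamma, -700, 50))
        d = np.sqrt(np.concatenate([np.full(self.nb, gb),
                                    np.full(self.q - self.nb, gr)]))
        C = np.eye(self.q) + (d[:, None] * self.UtU) * d[None, :]
        Lc = np.linalg.cholesky(C)
        # W = D C^{-1} D, applied through triangular solves
        from scipy.linalg import solve_triangular

        rhs = d[:, None] * np.column_stack([self.UtX, self.Uty])
        half = solve_triangular(Lc, rhs, lower=True, check_finite=False)
        hX, hy = half[:, :-1], half[:, -1]
        XtViX = self.XtX - hX.T @ hX
        XtViy = self.Xty - hX.T @ hy
        ytViy = self.yty - float(hy @ hy)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(beta @ XtViy)
        rss = max(rss, 1e-300)
        sigma2 = rss / self.n
        logdet = 2.0 * float(np.log(np.diag(Lc)).sum())
        nll = 0.5 * (self.n * math.log(2.0 * math.pi * sigma2) + self.n + logdet)
        return nll, sigma2, beta

    def optimize(self, starts):
        # a boundary optimum (gamma -> 0) walks log-gamma downward without
        # ever shrinking the simplex, so iterations are capped; far below
        # gamma ~ e^-14 the likelihood is flat to well under 1e-8
        best = None
        for start in starts:
            res = optimize.minimize(
                self.nll, np.asarray(start, dtype=float), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        nll, sigma2, beta = self.solve(best.x)
        gb, gr = np.exp(np.clip(best.x, -700, 50))
        return beta, gb * sigma2, gr * sigma2, sigma2, -nll


_DEFAULT_STARTS = ([-2.0, -2.0], [0.0, 0.0], [-7.0, -7.0], [-14.0, -14.0])


def _loglik_at(
    y: np.ndarray, X: np.ndarray, Zb: np.ndarray, Zr: np.ndarray,
    s2b: float, s2r: float, s2e: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Marginal Gaussian log-likelihood with GLS beta at fixed variances.

    Returns (loglik, beta_gls, cov_beta)."""
    n = len(y)
    V = s2e * np.eye(n) + s2b * (Zb @ Zb.T) + s2r * (Zr @ Zr.T)
    L = np.linalg.cholesky(V)
    from scipy.linalg import solve_triangular

    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + float(resid @ resid))
    return ll, beta, np.linalg.inv(XtX)


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMFit:
    """ML fit of one candidate model.

    ``data`` needs columns log10_timm, temperature_C, body_length_mm,
    beaker_id, run_id with no missing values (see ``build_model_frame``).
    Both random factors must have at least two levels.  Deterministic for a
    given data frame.
    """
    for col in ("log10_timm", "temperature_C", "body_length_mm",
                "beaker_id", "run_id"):
        if col not in data.columns:
            raise ValueError(f"model frame is missing column {col!r}")
        if data[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
    for factor in ("beaker_id", "run_id"):
        if data[factor].nunique() < 2:
            raise ValueError(f"random factor {factor!r} needs >= 2 levels")

    y = data["log10_timm"].to_numpy(dtype=float)
    X, names, Tmean = _design(data, spec)
    Zb = _indicator(data["beaker_id"])
    Zr = _indicator(data["run_id"])
    n = len(y)

    # statsmodels MixedLM provides the fit; an exact profiled-likelihood
    # polish from its solution (plus fixed fallback starts) pins the optimum
    # to full precision and rescues the rare non-converged case
    prof = _ProfiledML(y, X, Zb, Zr)
    sm = _fit_statsmodels(data, spec, y, X, names)
    if sm is not None:
        _, s2b0, s2r0, s2e0, _, method = sm
        floor = 1e-12 * s2e0
        starts = [[math.log(max(s2b0, floor) / s2e0),
                   math.log(max(s2r0, floor) / s2e0)],
                  [-14.0, -14.0]]
        method += "+polish"
    else:
        starts = list(_DEFAULT_STARTS)
        method = "profiled-ml"
    beta_c, s2b, s2r, s2e, ll = prof.optimize(starts)
    if not np.isfinite(ll):
        raise ConvergenceError(
            f"ML optimization diverged for {spec.label!r} "
            f"(loglik={ll}, vc=({s2b}, {s2r}), resid={s2e})"
        )
    converged = True

    # GLS covariance of the fixed effects at the ML variance estimates
    ll_check, beta_gls, cov_beta = _loglik_at(y, X, Zb, Zr, s2b, s2r, s2e)
    se_c = np.sqrt(np.diag(cov_beta))

    beta_nat, se_nat = _uncenter(dict(zip(names, beta_c)),
                                 dict(zip(names, se_c)), cov_beta, names, Tmean)

    # conditional predictions: fixed part + BLUPs of the random intercepts
    Vinv_r = _v_solve(y - X @ np.asarray(beta_c), Zb, Zr, s2b, s2r, s2e)
    yhat_marg = X @ np.asarray(beta_c)
    yhat_cond = yhat_marg + s2b * (Zb @ (Zb.T @ Vinv_r)) + s2r * (Zr @ (Zr.T @ Vinv_r))

    var_y = float(np.var(y))
    boundary = min(s2b, s2r) <= _BOUNDARY_REL * max(var_y, 1e-12)
    return LMMFit(
        spec=spec,
        beta=beta_nat,
        beta_se=se_nat,
        vc={"beaker": float(s2b), "run": float(s2r)},
        sigma2_resid=float(s2e),
        loglik=float(ll),
        k=count_parameters(spec),
        n=n,
        converged=converged,
        boundary=bool(boundary),
        method=method,
        _y=y,
        _yhat_cond=yhat_cond,
        _yhat_marg=yhat_marg,
    )


def _v_solve(r, Zb, Zr, s2b, s2r, s2e):
    V = s2e * np.eye(len(r)) + s2b * (Zb @ Zb.T) + s2r * (Zr @ Zr.T)
    return np.linalg.solve(V, r)


def _uncenter(beta_c, se_c, cov_beta, names, Tmean):
    """Map coefficients on the centered-temperature scale to natural scale."""
    beta = dict(beta_c)
    se = dict(se_c)
    idx = {nm: i for i, nm in enumerate(names)}
    if "temperature" in beta:
        beta["intercept"] = beta_c["intercept"] - beta_c["temperature"] * Tmean
        i, j = idx["intercept"], idx["temperature"]
        se["intercept"] = float(
            np.sqrt(cov_beta[i, i] + Tmean**2 * cov_beta[j, j]
                    - 2 * Tmean * cov_beta[i, j])
        )
    if "temperature:size" in beta:
        beta["size"] = beta_c["size"] - beta_c["temperature:size"] * Tmean
        i, j = idx["size"], idx["temperature:size"]
        se["size"] = float(
            np.sqrt(cov_beta[i, i] + Tmean**2 * cov_beta[j, j]
                    - 2 * Tmean * cov_beta[i, j])
        )
    return ({k: float(v) for k, v in beta.items()},
            {k: float(v) for k, v in se.items()})


def _fit_statsmodels(data, spec, y, X, names):
    """Primary fitter: statsmodels MixedLM (variance components, ML)."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = data.copy()
    exog = pd.DataFrame(X, columns=names, index=df.index)
    vc_formula = {"beaker": "0 + C(beaker_id)", "run": "0 + C(run_id)"}
    groups = np.ones(len(df))
    model = MixedLM.from_formula(
        "log10_timm ~ 0 + intercept"
        + "".join(f" + Q('{nm}')" for nm in names[1:]),
        data=pd.concat([df[["log10_timm", "beaker_id", "run_id"]], exog], axis=1),
        groups=groups,
        vc_formula=vc_formula,
    )
    last_exc = None
    for meth in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, method=meth, maxiter=500)
        except Exception as exc:  # singular steps etc.
            last_exc = exc
            continue
        if res.converged:
            vc_names = list(model.exog_vc.names)
            vcomp = dict(zip(vc_names, np.asarray(res.vcomp, dtype=float)))
            beta = np.asarray(res.fe_params, dtype=float)
            return (beta, float(vcomp["beaker"]), float(vcomp["run"]),
                    float(res.scale), float(res.llf), f"mixedlm-{meth}")
    return None


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = −2·loglik + 2k + 2k(k+1)/(n − k − 1); undefined for n ≤ k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_aicc(values: Sequence[float]) -> np.ndarray:
    """AICc differences to the best (smallest) model."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise ValueError("need >= 1 finite AICc value")
    return v - v.min()


def akaike_weights(values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2).

    Shifting by the minimum before exponentiating keeps the largest term at
    exp(0), so the normalization cannot overflow.
    """
    d = delta_aicc(values)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def r_squared(fit: LMMFit, method: str = "conditional") -> float:
    """Squared Pearson correlation between predictions and observations.

    ``conditional`` (default) predicts with fixed effects plus the predicted
    (BLUP) random intercepts; ``marginal`` uses the fixed effects alone.
    """
    yhat = {"conditional": fit._yhat_cond, "marginal": fit._yhat_marg}[method]
    y = fit._y
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ModelComparisonTable:
    """AICc ranking of the candidate models.

    ``table`` columns: model (rank), fixed_effects, k, AICc, dAICc, w,
    acc_w, R2 — sorted by AICc ascending, exact ties broken by smaller k.
    ``note`` flags a near-tie (ΔAICc < 2 between the top two models).
    """

    table: pd.DataFrame
    note: str | None = None


def compare_models(fits: Sequence[LMMFit]) -> ModelComparisonTable:
    """Rank ML fits of the candidate models by AICc.

    All fits must be on the same data (equal n, identical response).
    Reordering the input fits does not change the output table.
    """
    if not fits:
        raise ValueError("need at least one fit")
    n = fits[0].n
    for f in fits[1:]:
        if f.n != n:
            raise ValueError(f"fits on different n: {f.n} vs {n}")
        if not np.allclose(np.sort(f._y), np.sort(fits[0]._y)):
            raise ValueError("fits appear to use different responses")

    rows = []
    for f in fits:
        rows.append({
            "fixed_effects": f.spec.label,
            "k": f.k,
            "AICc": aicc(f.loglik, f.k, f.n),
            "R2": r_squared(f),
        })
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "k", "fixed_effects"], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "model", np.arange(1, len(df) + 1))
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["w"] = akaike_weights(df["AICc"].to_numpy())
    df["acc_w"] = df["w"].cumsum()
    df = df[["model", "fixed_effects", "k", "AICc", "dAICc", "w", "acc_w", "R2"]]

    note = None
    if len(df) >= 2 and df["dAICc"].iloc[1] < 2.0:
        note = (
            "near-tie: AICc difference between the top two models is "
            f"{df['dAICc'].iloc[1]:.2f} (< 2.0); the simpler model has "
            "comparable support"
        )
    return ModelComparisonTable(table=df, note=note)
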