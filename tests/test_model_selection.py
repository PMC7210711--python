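"""Mixed-model fitting and AICc comparison: oracles, identities, properties."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from thermotol.model_selection import (CANDIDATE_SPECS, SPEC_ADDITIVE,
                                       SPEC_INTERACTION, SPEC_TEMPERATURE,
                                       aicc, akaike_weights, build_model_frame,
                                       compare_models, count_parameters,
                                       delta_aicc, fit_lmm, r_squared)
from thermotol.pipeline import estimates_from_truth
from thermotol.synthetic import generate_experiment

from conftest import tiny_config


def model_frame(**overrides):
    cfg = tiny_config(**overrides)
    runs, subjects, _, truths = generate_experiment(cfg, with_traces=False)
    est = estimates_from_truth(subjects, truths)
    return cfg, build_model_frame(est, subjects, runs)


# ---------------------------------------------------------------------------
# parameter counts and AICc arithmetic
# ---------------------------------------------------------------------------

class TestCounts:
    @pytest.mark.parametrize("spec,k", [
        (SPEC_INTERACTION, 7),   # 4 fixed + 2 vc + residual
        (SPEC_ADDITIVE, 6),      # 3 fixed + 2 vc + residual
        (SPEC_TEMPERATURE, 5),   # 2 fixed + 2 vc + residual
    ])
    def test_candidate_model_parameter_counts(self, spec, k):
        assert count_parameters(spec) == k


class TestAicc:
    def test_large_n_limit_approaches_aic(self):
        val = aicc(-100.0, 3, 10**6)
        assert val == pytest.approx(206.0, abs=1e-4)
        assert val > 206.0  # the correction is strictly positive

    def test_direct_arithmetic(self):
        assert aicc(-184.0, 7, 277) == pytest.approx(368 + 14 + 112 / 269,
                                                     rel=1e-12)

    def test_undefined_when_correction_blows_up(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(-500, -1), st.floats(-500, -1),
           st.integers(3, 10), st.integers(50, 500))
    def test_equal_k_differences_reduce_to_loglik(self, ll1, ll2, k, n):
        # the small-sample correction cancels between equal-k models
        assert aicc(ll1, k, n) - aicc(ll2, k, n) == pytest.approx(
            -2.0 * (ll1 - ll2), rel=1e-9, abs=1e-9)


class TestAkaikeWeights:
    def test_weights_from_published_deltas(self):
        # deltas 0.00 / 1.46 / 81.74 split the support 2:1 between the top
        # two models and give the third none
        w = akaike_weights([0.0, 1.46, 81.74])
        assert np.round(w, 2).tolist() == [0.67, 0.33, 0.00]

    def test_equal_aicc_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([12.0] * 4), 0.25)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8),
           st.floats(-1e6, 1e6))
    def test_weights_normalize_and_are_shift_invariant(self, values, shift):
        w = akaike_weights(values)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()
        np.testing.assert_allclose(akaike_weights(np.asarray(values) + shift),
                                   w, atol=1e-9)

    def test_overflow_safety_with_huge_values(self):
        w = akaike_weights([1e8, 1e8 + 2.0])
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ML fitting against independent oracles
# ---------------------------------------------------------------------------

def dense_ml_oracle(y, X, Zb, Zr):
    """Brute-force ML: build the full marginal covariance and maximize the
    exact Gaussian log-density over the three variances (beta by GLS)."""
    n = len(y)

    def neg_loglik(log_s2):
        s2b, s2r, s2e = np.exp(log_s2)
        V = s2e * np.eye(n) + s2b * (Zb @ Zb.T) + s2r * (Zr @ Zr.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r)

    best = None
    for start in ([-3, -3, -3], [-5, -5, -2], [-8, -8, -4], [-1, -1, -1]):
        res = optimize.minimize(neg_loglik, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def design_matrices(frame, spec):
    T = frame["temperature_C"].to_numpy()
    Tc = T - T.mean()
    S = frame["body_length_mm"].to_numpy()
    cols = {"temperature": Tc, "size": S, "temperature:size": Tc * S}
    X = np.column_stack([np.ones(len(frame))]
                        + [cols[t] for t in spec.fixed_terms])
    Zb = pd.get_dummies(frame["beaker_id"]).to_numpy(float)
    Zr = pd.get_dummies(frame["run_id"]).to_numpy(float)
    return X, Zb, Zr


class TestFitLmm:
    def test_matches_dense_covariance_oracle(self):
        # small balanced design: 4 beakers x 2 runs per temperature
        cfg, frame = model_frame(subjects_per_run=8, n_beakers=4, seed=21)
        for spec in CANDIDATE_SPECS:
            fit = fit_lmm(frame, spec)
            X, Zb, Zr = design_matrices(frame, spec)
            oracle_ll = dense_ml_oracle(frame["log10_timm"].to_numpy(), X, Zb, Zr)
            assert fit.loglik == pytest.approx(oracle_ll, abs=1e-5), spec.label

    def test_zero_variance_components_reduce_to_ols(self):
        # On data generated without beaker/run effects the ML optimum sits
        # at the variance boundary and the GLS solution collapses to OLS.
        # (On finite null data ML can also land on a small spurious positive
        # variance; this dataset is one where the boundary is the optimum.)
        from thermotol.synthetic import SyntheticConfig, generate_experiment

        cfg = SyntheticConfig(sigma_beaker=0.0, sigma_run=0.0, seed=23)
        runs, subjects, _, truths = generate_experiment(cfg, with_traces=False)
        frame = build_model_frame(estimates_from_truth(subjects, truths),
                                  subjects, runs)
        fit = fit_lmm(frame, SPEC_ADDITIVE)
        assert fit.vc["beaker"] <= 1e-4 and fit.vc["run"] <= 1e-4
        assert fit.boundary
        T = frame["temperature_C"].to_numpy()
        X = np.column_stack([np.ones(len(frame)), T,
                             frame["body_length_mm"].to_numpy()])
        beta_ols, *_ = np.linalg.lstsq(X, frame["log10_timm"].to_numpy(),
                                       rcond=None)
        assert fit.beta["intercept"] == pytest.approx(beta_ols[0], abs=1e-6)
        assert fit.beta["temperature"] == pytest.approx(beta_ols[1], abs=1e-6)
        assert fit.beta["size"] == pytest.approx(beta_ols[2], abs=1e-6)

    def test_nested_models_never_lose_loglik(self):
        for seed in (30, 31, 32):
            _, frame = model_frame(seed=seed)
            lls = {s.label: fit_lmm(frame, s).loglik for s in CANDIDATE_SPECS}
            assert lls["temperature × size"] >= lls["temperature + size"] - 1e-6
            assert lls["temperature + size"] >= lls["temperature"] - 1e-6

    def test_recovers_generating_fixed_effects(self):
        cfg, frame = model_frame(seed=33)
        fit = fit_lmm(frame, SPEC_ADDITIVE)
        assert fit.beta["temperature"] == pytest.approx(cfg.beta_T, abs=0.05)
        assert fit.beta["size"] == pytest.approx(cfg.beta_S, abs=0.15)
        assert fit.n == len(frame)
        assert fit.converged

    def test_duplicated_data_keeps_coefficient_signs_and_order(self):
        _, frame = model_frame(seed=34)
        doubled = pd.concat([frame, frame], ignore_index=True)
        a = fit_lmm(frame, SPEC_ADDITIVE)
        b = fit_lmm(doubled, SPEC_ADDITIVE)
        assert b.loglik != pytest.approx(a.loglik, abs=1e-3)
        for key in ("temperature", "size"):
            assert np.sign(a.beta[key]) == np.sign(b.beta[key])
        assert (a.beta["temperature"] < a.beta["size"]) == (
            b.beta["temperature"] < b.beta["size"])

    def test_missing_columns_and_degenerate_factors_rejected(self):
        _, frame = model_frame(seed=35)
        with pytest.raises(ValueError, match="body_length_mm"):
            fit_lmm(frame.drop(columns=["body_length_mm"]), SPEC_ADDITIVE)
        single_run = frame[frame["run_id"] == frame["run_id"].iloc[0]]
        with pytest.raises(ValueError, match="run_id"):
            fit_lmm(single_run, SPEC_ADDITIVE)


# ---------------------------------------------------------------------------
# R^2 and the comparison table
# ---------------------------------------------------------------------------

class TestRSquared:
    def test_noise_free_saturated_model_reaches_one(self):
        _, frame = model_frame(sigma_beaker=0.0, sigma_run=0.0,
                               sigma_resid=0.0, seed=40)
        fit = fit_lmm(frame, SPEC_INTERACTION)
        assert r_squared(fit) == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_response_has_no_explanatory_power(self):
        cfg = tiny_config(subjects_per_run=20, n_beakers=10,
                          temperatures=(35., 36., 37., 38., 39., 40.),
                          runs_per_temperature=(3, 2, 2, 2, 2, 3), seed=41)
        runs, subjects, _, truths = generate_experiment(cfg, with_traces=False)
        est = estimates_from_truth(subjects, truths)
        frame = build_model_frame(est, subjects, runs)
        rng = np.random.default_rng(0)
        frame["log10_timm"] = rng.permutation(frame["log10_timm"].to_numpy())
        fit = fit_lmm(frame, SPEC_TEMPERATURE)
        assert r_squared(fit, method="marginal") < 0.05

    def test_richer_fixed_structure_never_fits_worse(self):
        _, frame = model_frame(seed=42)
        r2 = {s.label: r_squared(fit_lmm(frame, s)) for s in CANDIDATE_SPECS}
        assert r2["temperature × size"] >= r2["temperature"] - 1e-6


@pytest.fixture(scope="module")
def fits():
    _, frame = model_frame(seed=50)
    return [fit_lmm(frame, s) for s in CANDIDATE_SPECS]


class TestCompareModels:

    def test_table_structure_and_invariants(self, fits):
        res = compare_models(fits)
        t = res.table
        assert list(t.columns) == ["model", "fixed_effects", "k", "AICc",
                                   "dAICc", "w", "acc_w", "R2"]
        assert t["AICc"].is_monotonic_increasing
        assert t["dAICc"].iloc[0] == 0.0
        assert t["w"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t["acc_w"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert t["acc_w"].is_monotonic_increasing

    def test_input_order_irrelevant(self, fits):
        a = compare_models(fits).table
        b = compare_models(fits[::-1]).table
        pd.testing.assert_frame_equal(a, b)

    def test_single_model_gets_full_weight(self, fits):
        t = compare_models(fits[:1]).table
        assert t["dAICc"].iloc[0] == 0.0
        assert t["w"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_n_rejected(self, fits):
        _, other = model_frame(subjects_per_run=10, seed=51)
        bad = fit_lmm(other, SPEC_TEMPERATURE)
        with pytest.raises(ValueError, match="different"):
            compare_models([fits[0], bad])

    def test_published_aicc_ordering(self):
        # arithmetic on a printed comparison: AICc 382.22 / 383.67 / 463.96
        d = delta_aicc([463.96, 382.22, 383.67])
        assert d.min() == 0.0
        assert np.round(d[0], 2) == 81.74
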