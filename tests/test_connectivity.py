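"""VAR fitting, conditional Granger causality and network block means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from freqec import (
    conditional_gc,
    fit_var,
    network_mean_ec,
    select_order,
    subject_significance,
)
from freqec.connectivity import ECMatrix


def _simulate_var(coefs: list[np.ndarray], T: int, seed: int, burn: int = 50) -> np.ndarray:
    n = coefs[0].shape[0]
    p = len(coefs)
    rng = np.random.default_rng(seed)
    x = np.zeros((n, T + burn))
    for t in range(p, T + burn):
        for m, A in enumerate(coefs, start=1):
            x[:, t] += A @ x[:, t - m]
        x[:, t] += rng.standard_normal(n)
    return x[:, burn:]


class TestFitVar:
    def test_noiseless_recursion_recovered_exactly(self):
        A = np.array([[0.8, 0.2, 0.0], [0.0, 0.7, 0.2], [0.1, 0.0, 0.6]])
        x = np.zeros((3, 40))
        x[:, 0] = [1.0, -2.0, 0.5]
        for t in range(1, 40):
            x[:, t] = A @ x[:, t - 1]
        model = fit_var(x, 1)
        np.testing.assert_allclose(model.coefficients[:, :, 0], A, atol=1e-6)

    def test_consistency_at_large_T(self):
        A = np.array([[0.5, 0.3], [-0.2, 0.4]])
        x = _simulate_var([A], T=5000, seed=0)
        model = fit_var(x, 1)
        rmse = np.sqrt(np.mean((model.coefficients[:, :, 0] - A) ** 2))
        assert rmse < 0.05

    def test_residuals_orthogonal_to_predictors(self):
        x = _simulate_var([np.array([[0.5, 0.2], [0.0, 0.4]])], T=300, seed=1)
        model = fit_var(x, 2)
        pred = np.zeros((2, x.shape[1]))
        for t in range(2, x.shape[1]):
            for m in range(2):
                pred[:, t] += model.coefficients[:, :, m] @ x[:, t - m - 1]
            pred[:, t] += model.intercept
        resid = (x - pred)[:, 2:]
        for m in range(1, 3):
            lagged = x[:, 2 - m : -m]
            dots = np.abs(resid @ lagged.T)
            norms = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(lagged, axis=1)[None, :]
            assert np.max(dots / norms) < 1e-6

    def test_constant_component_rejected(self):
        x = np.vstack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(ValueError):
            conditional_gc(x, 1)


class TestSelectOrder:
    def test_strong_var2_selects_two(self):
        A1 = np.array([[0.5, 0.1], [0.0, 0.4]])
        A2 = np.array([[-0.3, 0.0], [0.25, -0.2]])
        hits = sum(select_order(_simulate_var([A1, A2], 500, seed=s), 5) == 2 for s in range(20))
        assert hits >= 16

    def test_white_noise_selects_smallest(self):
        hits = 0
        for s in range(20):
            x = np.random.default_rng(s).standard_normal((3, 400))
            hits += select_order(x, 5) == 1
        assert hits >= 16

    def test_single_candidate(self):
        x = np.random.default_rng(0).standard_normal((2, 100))
        assert select_order(x, 1) == 1


class TestConditionalGC:
    def test_closed_form_bivariate(self):
        rng = np.random.default_rng(1)
        T = 20000
        x = rng.standard_normal(T)
        e = rng.standard_normal(T)
        y = np.empty(T)
        y[0] = e[0]
        y[1:] = 0.5 * x[:-1] + e[1:]
        ec = conditional_gc(np.vstack([x, y]), p=1)
        assert ec.values[0, 1] == pytest.approx(np.log(1.25), abs=0.02)
        assert ec.values[1, 0] < 0.005

    def test_null_gc_small_and_calibrated(self):
        vals = []
        T_eff = 1999
        for s in range(60):
            S = np.random.default_rng(s).standard_normal((3, 2000))
            v = conditional_gc(S, 1).values
            vals.extend(v[~np.eye(3, dtype=bool)])
        vals = np.asarray(vals)
        assert vals.mean() <= 2.0 / T_eff
        exceed = np.mean(T_eff * vals > sstats.chi2.ppf(0.95, 1))
        assert 0.01 <= exceed <= 0.10

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        S = _simulate_var([np.array([[0.4, 0.3], [0.1, 0.5]])], 400, seed=3)
        a = conditional_gc(S, 1).values
        S2 = S * np.array([[5.0], [0.01]]) + np.array([[3.0], [-7.0]])
        b = conditional_gc(S2, 1).values
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestSubjectSignificance:
    def test_null_calibration(self):
        frac = []
        for s in range(60):
            S = np.random.default_rng(100 + s).standard_normal((4, 500))
            ec = conditional_gc(S, 1)
            model = fit_var((S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True), 1)
            out = subject_significance(ec, model, alpha=0.05)
            frac.append(out.significance_mask.sum() / 12)
        assert np.mean(frac) <= 0.05 + 0.02

    def test_strong_coupling_significant(self):
        rng = np.random.default_rng(4)
        T = 20000
        x = rng.standard_normal(T)
        y = np.r_[0.0, 0.5 * x[:-1]] + rng.standard_normal(T)
        S = np.vstack([x, y])
        ec = conditional_gc(S, 1)
        model = fit_var((S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True), 1)
        out = subject_significance(ec, model, alpha=0.05)
        assert out.significance_mask[0, 1]

    def test_alpha_zero_empty_mask(self):
        S = np.random.default_rng(5).standard_normal((3, 300))
        ec = conditional_gc(S, 1)
        model = fit_var((S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True), 1)
        out = subject_significance(ec, model, alpha=0.0)
        assert not out.significance_mask.any()


class TestNetworkMeanEC:
    LABELS = {0: "DMN", 1: "DMN", 2: "SN", 3: "CEN", 4: "CEN"}

    def test_constant_matrix_gives_constant_blocks(self):
        labels = {0: "DMN", 1: "DMN", 2: "SN", 3: "SN", 4: "CEN", 5: "CEN"}
        v = np.full((6, 6), 0.4)
        np.fill_diagonal(v, 0.0)
        blocks = network_mean_ec(v, labels)
        np.testing.assert_allclose(blocks.to_numpy(), 0.4)

    def test_two_entry_average(self):
        v = np.zeros((4, 4))
        labels = {0: "DMN", 1: "DMN", 2: "SN", 3: "CEN"}
        v[0, 2] = 0.2
        v[1, 2] = 0.4
        blocks = network_mean_ec(v, labels)
        assert blocks.loc["DMN", "SN"] == pytest.approx(0.3)

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(6)
        v = np.abs(rng.standard_normal((5, 5)))
        np.fill_diagonal(v, 0.0)
        blocks = network_mean_ec(v, self.LABELS)
        nets = {"DMN": [0, 1], "SN": [2], "CEN": [3, 4]}
        for a, ia in nets.items():
            for b, ib in nets.items():
                acc = [v[j, k] for j in ia for k in ib if not (a == b and j == k)]
                if acc:
                    assert blocks.loc[a, b] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_var_model_cross_check_against_statsmodels(self):
        """Independent oracle: statsmodels VAR OLS coefficients."""
        from statsmodels.tsa.api import VAR as SMVAR

        S = _simulate_var([np.array([[0.5, 0.2], [-0.1, 0.4]])], 400, seed=7)
        ours = fit_var(S, 2)
        sm = SMVAR(S.T).fit(maxlags=2, trend="c")
        np.testing.assert_allclose(
            ours.coefficients[:, :, 0], sm.coefs[0], atol=1e-8
        )
        np.testing.assert_allclose(
            ours.coefficients[:, :, 1], sm.coefs[1], atol=1e-8
        )
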