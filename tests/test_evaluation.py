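"""MSPE decomposition, concordance analysis, equation evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ch4meta.equations import get_equation
from ch4meta.errors import EvaluationError
from ch4meta.evaluation import (
    ccc_analysis,
    correlation_screen,
    decompose_mspe,
    evaluate_equations,
    evaluate_metrics,
    mspe,
    residual_diagnostics,
    rmspe_pct,
)

series = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=3, max_size=40
)


def _nondegenerate(o, p):
    return np.std(o) > 1e-6 and np.std(p) > 1e-6


class TestMSPE:
    def test_examples(self):
        assert mspe([1, 2, 3], [1, 2, 3]) == 0.0
        assert mspe([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)
        with pytest.raises(EvaluationError):
            mspe([1, 2], [1, 2, 3])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 30)
            o, p = rng.normal(size=n), rng.normal(size=n)
            loop = sum((a - b) ** 2 for a, b in zip(o, p)) / n
            assert mspe(o, p) == pytest.approx(loop, rel=1e-12)


class TestDecomposition:
    def test_pure_mean_bias(self):
        o = np.array([1.0, 2, 3, 4])
        parts = decompose_mspe(o, o + 1)
        assert parts == pytest.approx((1.0, 0.0, 0.0))

    def test_pure_slope_bias(self):
        o = np.array([1.0, 2, 3, 4])
        p = 2 * o - o.mean()  # equal means, doubled spread, r = 1
        ect, er, ed = decompose_mspe(o, p)
        assert ect == pytest.approx(0.0, abs=1e-12)
        assert ed == pytest.approx(0.0, abs=1e-12)
        assert er == pytest.approx((2 * o.std() - o.std()) ** 2)

    @given(series, series)
    @settings(max_examples=200, deadline=None)
    def test_identity_sums_to_mspe(self, o, p):
        n = min(len(o), len(p))
        o, p = np.asarray(o[:n]), np.asarray(p[:n])
        if not _nondegenerate(o, p):
            return
        parts = decompose_mspe(o, p)
        total = mspe(o, p)
        assert sum(parts) == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(EvaluationError):
            decompose_mspe([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRMSPE:
    def test_examples(self):
        assert rmspe_pct([10.0, 10.0], [9.0, 11.0]) == pytest.approx(10.0)
        assert rmspe_pct([5.0, 6.0], [5.0, 6.0]) == 0.0
        with pytest.raises(EvaluationError):
            rmspe_pct([-1.0, 1.0], [0.0, 0.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        o = rng.uniform(5, 20, 30)
        p = o + rng.normal(0, 2, 30)
        assert rmspe_pct(3 * o, 3 * p) == pytest.approx(rmspe_pct(o, p), rel=1e-12)


class TestCCC:
    def test_perfect_agreement(self):
        o = np.array([1.0, 2, 3, 5])
        r = ccc_analysis(o, o)
        assert r == pytest.approx((1.0, 1.0, 1.0, 1.0, 0.0))

    def test_shifted_example(self):
        out = ccc_analysis([1.0, 2, 3], [2.0, 3, 4])
        assert out.r == pytest.approx(1.0)
        assert out.v == pytest.approx(1.0)
        assert out.mu == pytest.approx(-1.224744871, rel=1e-8)
        assert out.cb == pytest.approx(4 / 7)
        assert out.ccc == pytest.approx(4 / 7)

    @given(series, series)
    @settings(max_examples=200, deadline=None)
    def test_component_equals_direct_form(self, o, p):
        n = min(len(o), len(p))
        o, p = np.asarray(o[:n]), np.asarray(p[:n])
        if not _nondegenerate(o, p):
            return
        out = ccc_analysis(o, p)
        s_o, s_p = np.std(o), np.std(p)
        direct = 2 * out.r * s_o * s_p / (s_o**2 + s_p**2 + (o.mean() - p.mean()) ** 2)
        assert out.ccc == pytest.approx(direct, rel=1e-12, abs=1e-12)
        assert out.ccc == pytest.approx(out.r * out.cb, rel=1e-12, abs=1e-15)
        assert abs(out.ccc) <= abs(out.r) + 1e-12
        assert 0 < out.cb <= 1.0

    def test_mu_sign_means_overprediction(self):
        rng = np.random.default_rng(2)
        o = rng.uniform(5, 15, 50)
        over = ccc_analysis(o, o + 2 + rng.normal(0, 0.1, 50))
        under = ccc_analysis(o, o - 2 + rng.normal(0, 0.1, 50))
        assert over.mu < 0 < under.mu

    def test_scale_invariance_of_ccc_but_not_ect(self):
        rng = np.random.default_rng(3)
        o = rng.uniform(5, 15, 40)
        p = o + 1 + rng.normal(0, 1, 40)
        c1, c2 = ccc_analysis(o, p), ccc_analysis(5 * o, 5 * p)
        assert c1.ccc == pytest.approx(c2.ccc, rel=1e-12)
        e1, e2 = decompose_mspe(o, p), decompose_mspe(5 * o, 5 * p)
        assert e2.ect == pytest.approx(25 * e1.ect, rel=1e-9)


class TestEvaluateEquations:
    def test_true_equation_is_perfect_on_noiseless_data(self, noiseless_db):
        table = evaluate_equations(noiseless_db, [get_equation("eq1c")])
        row = table.iloc[0]
        assert row.rmspe_pct == pytest.approx(0.0, abs=1e-9)
        assert row.ccc == pytest.approx(1.0, abs=1e-9)

    def test_true_equation_beats_misspecified(self, noiseless_db):
        eqs = [get_equation(e) for e in ("eq1c", "ipcc2006", "mills_linear", "yan2009")]
        table = evaluate_equations(noiseless_db, eqs).set_index("equation")
        assert table.rmspe_pct.idxmin() == "eq1c"

    def test_rows_dropped_per_equation(self, small_db):
        df = small_db.copy()
        df.loc[df.index[:20], "gei_mj_d"] = np.nan  # IPCC needs GEI
        table = evaluate_equations(df, [get_equation("ipcc2006"), get_equation("eq1c")])
        n_ipcc = table.loc[table.equation == "ipcc2006", "n"].iloc[0]
        n_1c = table.loc[table.equation == "eq1c", "n"].iloc[0]
        assert n_ipcc == len(df) - 20 and n_1c == len(df)

    def test_unusable_equation_warns(self, small_db):
        df = small_db.drop(columns=["bw_kg"])
        with pytest.warns(UserWarning, match="eq1d"):
            table = evaluate_equations(df, [get_equation("eq1d")])
        assert table.iloc[0].n == 0

    def test_constant_prediction_decomposition(self):
        o = np.array([1.0, 2, 3, 4, 6])
        m = evaluate_metrics(o, np.full(5, o.mean()) + 0.0 * o + 1e-9 * np.arange(5))
        # constant equal to the observed mean: essentially no mean bias
        assert m.ect_pct == pytest.approx(0.0, abs=1e-3)


class TestCorrelationScreen:
    def test_self_correlation(self, small_db):
        out = correlation_screen(small_db, ["ch4_mj_d"]).iloc[0]
        assert out.r == pytest.approx(1.0)
        assert out.p_value < 1e-10

    def test_null_variable_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"ch4_mj_d": rng.normal(10, 2, 1000), "noise": rng.normal(size=1000)}
        )
        out = correlation_screen(df, ["noise"]).iloc[0]
        assert abs(out.r) < 0.1

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"ch4_mj_d": rng.normal(10, 2, 40), "x": rng.normal(size=40)}
        )
        df["x"] += 0.3 * df["ch4_mj_d"]
        out = correlation_screen(df, ["x"]).iloc[0]
        o, x = df.ch4_mj_d.to_numpy(), df.x.to_numpy()
        r = np.sum((o - o.mean()) * (x - x.mean())) / np.sqrt(
            np.sum((o - o.mean()) ** 2) * np.sum((x - x.mean()) ** 2)
        )
        t = r * np.sqrt(38 / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=38)
        assert out.r == pytest.approx(r, rel=1e-12)
        assert out.p_value == pytest.approx(p, rel=1e-9)
        assert out.r2 == pytest.approx(r * r, rel=1e-12)

    def test_insufficient_pairs_noted(self):
        df = pd.DataFrame({"ch4_mj_d": [1.0, 2.0], "x": [1.0, 2.0]})
        out = correlation_screen(df, ["x", "absent"])
        assert "fewer than 3" in out.iloc[0].note
        assert out.iloc[1].note == "column absent"


class TestResidualDiagnostics:
    def test_exact_cases(self):
        o = np.array([1.0, 2, 3, 4])
        perfect = residual_diagnostics(o, o)
        assert (perfect.slope, perfect.intercept) == (0.0, 0.0)
        shifted = residual_diagnostics(o, o + 1)
        assert shifted.slope == pytest.approx(0.0, abs=1e-12)
        assert shifted.intercept == pytest.approx(-1.0)

    @given(series, series)
    @settings(max_examples=100, deadline=None)
    def test_intercept_is_mean_bias(self, o, p):
        n = min(len(o), len(p))
        o, p = np.asarray(o[:n]), np.asarray(p[:n])
        if not _nondegenerate(o, p):
            return
        d = residual_diagnostics(o, p)
        assert d.intercept == pytest.approx(
            float(o.mean() - p.mean()), rel=1e-9, abs=1e-9
        )
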