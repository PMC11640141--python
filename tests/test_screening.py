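"""Cook's D screen, VIF, backward elimination, BIC selection."""

import numpy as np
import pandas as pd
import pytest

from ch4meta.errors import RankError, SelectionError
from ch4meta.screening import (
    backward_eliminate,
    compute_vif,
    detect_outliers,
    screen_random_and_quadratic,
    select_best,
)


def _frame(x, y, w=None):
    return pd.DataFrame(
        {"dmi_kg_d": x, "ch4_mj_d": y,
         "n_animals": w if w is not None else np.ones(len(x)),
         "study_id": ["s"] * len(x)}
    )


class TestCooksD:
    def test_gross_outlier_flagged(self):
        x = np.linspace(1, 20, 30)
        y = 2.0 + 0.5 * x
        y[17] += 25.0  # gross outlier on an otherwise exact line
        flagged = detect_outliers(_frame(x, y), predictors=["dmi_kg_d"])
        assert flagged == [17]

    def test_null_flag_fraction_small(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 20, 100)
        y = 2 + 0.5 * x + rng.normal(0, 1, 100)
        flagged = detect_outliers(_frame(x, y), predictors=["dmi_kg_d"])
        assert len(flagged) / 100 < 0.10

    def test_rank_error(self):
        df = pd.DataFrame(
            {"ch4_mj_d": [1.0, 2.0], "dmi_kg_d": [1.0, 2.0], "bw_kg": [1.0, 3.0],
             "study_id": ["a", "b"], "n_animals": [1, 1]}
        )
        with pytest.raises(RankError):
            detect_outliers(df, predictors=["dmi_kg_d", "bw_kg"])

    def test_matches_leave_one_out_oracle(self):
        """Cook's D equals the brute-force leave-one-out formula
        D_i = sum_j (yhat_j - yhat_j^(-i))^2 / (p * s^2) on weighted data."""
        rng = np.random.default_rng(3)
        n = 25
        x = rng.uniform(1, 20, n)
        w = rng.integers(1, 10, n).astype(float)
        y = 1 + 0.8 * x + rng.normal(0, 1, n) / np.sqrt(w)
        df = _frame(x, y, w)
        sw = np.sqrt(w)
        X = np.column_stack([np.ones(n), x]) * sw[:, None]
        Y = y * sw
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        fit_all = X @ beta
        p = 2
        s2 = np.sum((Y - fit_all) ** 2) / (n - p)
        oracle = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            bi = np.linalg.lstsq(X[keep], Y[keep], rcond=None)[0]
            oracle[i] = np.sum((fit_all - X @ bi) ** 2) / (p * s2)
        cut = np.sort(oracle)[-4]  # threshold picking the top 3
        flagged = detect_outliers(df, predictors=["dmi_kg_d"], cutoff=float(cut))
        assert set(flagged) == set(np.flatnonzero(oracle > cut))


class TestVIF:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        vif = compute_vif(df, ["a", "b"])
        assert np.allclose(vif, 1.0)

    def test_exact_collinearity_is_inf(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.isinf(compute_vif(df, ["a", "b"])).all()

    def test_r09_closed_form(self):
        # construct an exact sample correlation of 0.9
        n = 400
        rng = np.random.default_rng(1)
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalize
        z2 /= z2.std()
        b = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        vif = compute_vif(pd.DataFrame({"a": z1, "b": b}), ["a", "b"])
        assert np.allclose(vif, 1 / (1 - 0.81), rtol=1e-9)

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        df["d"] = df["a"] * 0.7 + df["b"] * 0.2 + rng.normal(0, 0.5, 40)
        vif = compute_vif(df, list("abcd"))
        for k in "abcd":
            others = [c for c in "abcd" if c != k]
            X = np.column_stack([np.ones(40)] + [df[c] for c in others])
            beta = np.linalg.lstsq(X, df[k], rcond=None)[0]
            resid = df[k] - X @ beta
            r2 = 1 - np.sum(resid**2) / np.sum((df[k] - df[k].mean()) ** 2)
            assert vif[k] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestBackwardElimination:
    def test_collinear_candidate_rejected_before_fitting(self, small_db):
        df = small_db.assign(dmi2=small_db.dmi_kg_d * 2)
        res, trace = backward_eliminate(df, ["dmi_kg_d", "dmi2"])
        assert trace[0].action == "vif_reject"
        assert list(res.params.index) == ["Intercept", "dmi_kg_d"]

    def test_single_strong_candidate_survives(self, small_db):
        res, trace = backward_eliminate(small_db, ["dmi_kg_d"])
        fits = [s for s in trace if s.action == "fit"]
        assert len(fits) == 1
        assert res.pvalues["dmi_kg_d"] < 1e-6

    def test_noise_predictors_removed(self, small_db):
        res, trace = backward_eliminate(
            small_db, ["dmi_kg_d", "bw_kg", "roughage_g_kg"]
        )
        assert [c for c in res.params.index if c != "Intercept"] == ["dmi_kg_d"]
        actions = [s.action for s in trace]
        assert actions.count("remove") == 2 and actions[-1] == "keep"

    def test_trace_deterministic(self, small_db):
        _, t1 = backward_eliminate(small_db, ["dmi_kg_d", "bw_kg"])
        _, t2 = backward_eliminate(small_db, ["dmi_kg_d", "bw_kg"])
        assert [(s.action, s.detail) for s in t1] == [(s.action, s.detail) for s in t2]


def test_random_and_quadratic_screen(small_db):
    out = screen_random_and_quadratic(small_db, "dmi_kg_d")
    assert 0 <= out["quadratic_p"] <= 1
    assert 0 <= out["random_slope_p"] <= 1
    kept = out["result"]
    assert "dmi_kg_d" in kept.params.index


class TestSelectBest:
    class _Fit:
        def __init__(self, bic, k, converged=True):
            self.bic, self.n_parameters, self.converged = bic, k, converged

    def test_single_and_ordering(self):
        a, b = self._Fit(100, 3), self._Fit(105, 2)
        assert select_best([a]) is a
        assert select_best([a, b]) is a

    def test_tie_prefers_fewer_parameters(self):
        a, b = self._Fit(100, 3), self._Fit(100, 2)
        assert select_best([a, b]) is b

    def test_no_converged_fit(self):
        with pytest.raises(SelectionError):
            select_best([self._Fit(1, 1, converged=False)])
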