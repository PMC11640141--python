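"""Weighted linear mixed models with a study random intercept and slope.

The meta-analytic development model for a response ``Y`` (methane, MJ/day)
observed at level ``j`` of a predictor ``X`` in study ``i`` is

    Y_ij = B0 + B1 X_ij + B2 X_ij^2 + s_i + b_i X_ij + e_ij

with fixed coefficients ``B``, study random intercept ``s_i`` and study
random slope ``b_i`` (jointly Gaussian; unstructured ``UN`` or independent
``VC`` covariance), and residual ``e_ij ~ N(0, sigma^2 / w_ij)`` where the
precision weight ``w_ij`` is the number of animals behind the treatment mean
(standard meta-analytic weighting; estimates are invariant to rescaling all
weights).

Estimation is restricted maximum likelihood with the residual variance
profiled out, optimized over the relative variance components by L-BFGS-B
from a small deterministic grid of starts.  Under ``cov_struct="auto"`` the
UN structure is attempted first and the model falls back to VC when the UN
fit does not converge or its intercept-slope covariance is not significant
(REML likelihood-ratio test at alpha = 0.10).

The API follows the statsmodels idiom: build a :class:`MethaneMixedLM` from a
DataFrame, call :meth:`~MethaneMixedLM.fit`, inspect the returned
:class:`MixedLMResult` (``params``, ``bse``, ``pvalues``, ``varcomps``,
``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, RankError

__all__ = ["MethaneMixedLM", "MixedLMResult"]

_SIGMA2_FLOOR = 1e-10
_LOGSD_BOUNDS = (-8.0, 4.0)


@dataclass
class _Profile:
    """Profiled quantities at one value of the relative variance components."""

    beta: np.ndarray
    sigma2: float
    neg2_reml: float
    xtvix_inv: np.ndarray


class MethaneMixedLM:
    """Weighted mixed linear model for treatment-mean methane records.

    Parameters
    ----------
    data
        Flat record table (one row per treatment mean).
    response, predictors
        Response column and fixed-effect predictor columns.
    squared
        Subset of ``predictors`` whose squared terms enter as fixed effects.
    group
        Study identifier column (the random-effect grouping factor).
    weights
        Column of per-record precision weights (animal counts), or ``None``
        for unit weights.
    random_slope
        Predictor column carrying the study random slope; defaults to the
        first predictor.  ``False`` requests a random intercept only.
    cov_struct
        ``"auto"`` (UN with VC fallback), ``"UN"``, ``"VC"`` or
        ``"intercept"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "ch4_mj_d",
        predictors: Sequence[str] = ("dmi_kg_d",),
        squared: Sequence[str] = (),
        group: str = "study_id",
        weights: Optional[str] = "n_animals",
        random_slope=None,
        cov_struct: str = "auto",
    ) -> None:
        self.data = data
        self.response = response
        self.predictors = list(predictors)
        self.squared = list(squared)
        self.group = group
        self.weights_col = weights if (weights and weights in data.columns) else None
        if random_slope is None:
            random_slope = self.predictors[0] if self.predictors else False
        self.random_slope = random_slope
        if cov_struct not in ("auto", "UN", "VC", "intercept"):
            raise ValueError(f"unknown cov_struct {cov_struct!r}")
        self.cov_struct = cov_struct

        cols = [response] + self.predictors + [group]
        if self.weights_col:
            cols.append(self.weights_col)
        d = data.dropna(subset=[c for c in cols if c in data.columns])
        self._frame = d
        self.endog = d[response].to_numpy(float)
        self.exog_names = ["Intercept"] + self.predictors + [
            f"{p}^2" for p in self.squared
        ]
        X = [np.ones(len(d))] + [d[p].to_numpy(float) for p in self.predictors]
        X += [d[p].to_numpy(float) ** 2 for p in self.squared]
        self.exog = np.column_stack(X)
        w = d[self.weights_col].to_numpy(float) if self.weights_col else np.ones(len(d))
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        self.weights = w
        self.groups = d[group].to_numpy()
        self.nobs = len(d)
        if self.nobs <= self.exog.shape[1]:
            raise RankError(
                f"{self.nobs} usable records for {self.exog.shape[1]} fixed "
                "coefficients"
            )
        self._split()

    def _split(self) -> None:
        order = np.argsort(self.groups, kind="stable")
        self._order = order
        g = self.groups[order]
        self._bounds = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
        self._y = self.endog[order]
        self._X = self.exog[order]
        self._w = self.weights[order]
        if self.random_slope:
            zi = self._frame[self.random_slope].to_numpy(float)[order]
            self._Z = np.column_stack([np.ones(self.nobs), zi])
        else:
            self._Z = np.ones((self.nobs, 1))
        self.n_groups = len(self._bounds) - 1

    # -- REML machinery -------------------------------------------------------

    def _lambda(self, theta: np.ndarray, struct: str) -> np.ndarray:
        """Relative random-effect covariance G / sigma^2 from free parameters."""
        q = self._Z.shape[1]
        if q == 1:
            sd = math.exp(theta[0])
            return np.array([[sd * sd]])
        sd1, sd2 = math.exp(theta[0]), math.exp(theta[1])
        rho = math.tanh(theta[2]) if struct == "UN" else 0.0
        return np.array(
            [[sd1 * sd1, rho * sd1 * sd2], [rho * sd1 * sd2, sd2 * sd2]]
        )

    def _profile(self, theta: np.ndarray, struct: str) -> _Profile:
        lam = self._lambda(theta, struct)
        p = self._X.shape[1]
        sizes = np.diff(self._bounds)
        if np.all(sizes == sizes[0]):
            # uniform group sizes: batched linear algebra over all studies
            G, ni = self.n_groups, int(sizes[0])
            Z = self._Z.reshape(G, ni, -1)
            X = self._X.reshape(G, ni, p)
            y = self._y.reshape(G, ni)
            w = self._w.reshape(G, ni)
            V = Z @ lam @ np.swapaxes(Z, 1, 2)
            V[:, np.arange(ni), np.arange(ni)] += 1.0 / w
            sign, logdets = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                raise FloatingPointError("non-PD marginal covariance")
            logdet_v = float(logdets.sum())
            rhs = np.concatenate([X, y[:, :, None]], axis=2)
            sol = np.linalg.solve(V, rhs)
            Vinv_X, Vinv_y = sol[:, :, :p], sol[:, :, p]
            xtvx = np.einsum("gij,gik->jk", X, Vinv_X)
            xtvy = np.einsum("gij,gi->j", X, Vinv_y)
            beta = np.linalg.solve(xtvx, xtvy)
            r = y - X @ beta
            quad = float(np.einsum("gi,gi->", r, np.linalg.solve(V, r[:, :, None])[:, :, 0]))
        else:
            xtvx = np.zeros((p, p))
            xtvy = np.zeros(p)
            logdet_v = 0.0
            chunks: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
            for k in range(self.n_groups):
                s, e = self._bounds[k], self._bounds[k + 1]
                Zk, Xk, yk, wk = self._Z[s:e], self._X[s:e], self._y[s:e], self._w[s:e]
                V = Zk @ lam @ Zk.T + np.diag(1.0 / wk)
                try:
                    c = np.linalg.cholesky(V)
                except np.linalg.LinAlgError:
                    raise FloatingPointError("non-PD marginal covariance")
                logdet_v += 2.0 * np.log(np.diag(c)).sum()
                xtvx += Xk.T @ np.linalg.solve(V, Xk)
                xtvy += Xk.T @ np.linalg.solve(V, yk)
                chunks.append((Xk, yk, V))
            beta = np.linalg.solve(xtvx, xtvy)
            quad = 0.0
            for Xk, yk, V in chunks:
                r = yk - Xk @ beta
                quad += r @ np.linalg.solve(V, r)
        dof = self.nobs - p
        sigma2 = max(quad / dof, _SIGMA2_FLOOR)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise FloatingPointError("singular fixed-effect information")
        neg2 = (
            dof * math.log(sigma2)
            + logdet_v
            + logdet_xtvx
            + dof * (1.0 + math.log(2.0 * math.pi))
        )
        return _Profile(beta, sigma2, neg2, np.linalg.inv(xtvx))

    def _objective(self, theta: np.ndarray, struct: str) -> float:
        try:
            return self._profile(theta, struct).neg2_reml
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    def _n_theta(self, struct: str) -> int:
        q = self._Z.shape[1]
        if q == 1:
            return 1
        return 3 if struct == "UN" else 2

    def _fit_struct(self, struct: str) -> Tuple[np.ndarray, bool]:
        k = self._n_theta(struct)
        # deterministic multi-start over relative random-effect scales
        starts = [np.full(k, s) for s in (-2.0, 0.0)]
        if k == 3:
            for s in starts:
                s[2] = 0.0
        best, best_val, ok = None, np.inf, False
        bounds = [_LOGSD_BOUNDS] * min(k, 2) + [(-5.0, 5.0)] * (k - min(k, 2))
        for x0 in starts:
            res = optimize.minimize(
                self._objective,
                x0,
                args=(struct,),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200},
            )
            if np.isfinite(res.fun) and res.fun < best_val - 1e-10:
                best, best_val = res.x, res.fun
                ok = bool(res.success) or res.fun < 1e11
        if best is None:
            return np.zeros(k), False
        return best, ok and best_val < 1e11

    def fit(self) -> "MixedLMResult":
        """Fit by REML, applying the UN -> VC fallback when requested.

        Raises
        ------
        ConvergenceError
            If no requested covariance structure yields a converged fit.
        """
        attempts: List[Tuple[str, np.ndarray, bool]] = []
        single_re = self._Z.shape[1] == 1
        if single_re:
            order = ["intercept"]
        elif self.cov_struct == "auto":
            order = ["UN", "VC"]
        else:
            order = [self.cov_struct]
        fits: Dict[str, Tuple[np.ndarray, bool]] = {}
        for struct in order:
            fits[struct] = self._fit_struct(struct)
        chosen = order[0]
        fallback_reason = None
        if self.cov_struct == "auto" and not single_re:
            th_un, ok_un = fits["UN"]
            th_vc, ok_vc = fits["VC"]
            if not ok_un:
                chosen, fallback_reason = "VC", "UN did not converge"
            else:
                # LRT for the intercept-slope covariance (1 df, alpha = 0.10)
                lr = self._objective(th_vc, "VC") - self._objective(th_un, "UN")
                p_cov = 1.0 - stats.chi2.cdf(max(lr, 0.0), df=1)
                if p_cov > 0.10:
                    chosen, fallback_reason = "VC", f"covariance LRT p={p_cov:.3f}"
        theta, ok = fits[chosen]
        if not ok:
            diag = {s: bool(f[1]) for s, f in fits.items()}
            raise ConvergenceError(f"mixed-model fit failed; attempts: {diag}")
        prof = self._profile(theta, chosen)
        return MixedLMResult(self, chosen, theta, prof, fallback_reason)


class MixedLMResult:
    """Results of a :class:`MethaneMixedLM` fit (statsmodels-style)."""

    def __init__(
        self,
        model: MethaneMixedLM,
        cov_struct: str,
        theta: np.ndarray,
        prof: _Profile,
        fallback_reason: Optional[str],
    ) -> None:
        self.model = model
        self.cov_struct_used = cov_struct
        self.fallback_reason = fallback_reason
        self.converged = True
        self._theta = theta
        sigma2 = prof.sigma2
        self.params = pd.Series(prof.beta, index=model.exog_names)
        cov = prof.xtvix_inv * sigma2
        self.cov_params = pd.DataFrame(cov, index=model.exog_names, columns=model.exog_names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=model.exog_names)
        z = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(z)), index=model.exog_names
        )
        lam = model._lambda(theta, cov_struct)
        self.scale = sigma2  # residual variance at unit weight
        vc: Dict[str, float] = {"residual_var": sigma2}
        vc["study_intercept_var"] = float(lam[0, 0] * sigma2)
        if lam.shape[0] == 2:
            vc["study_slope_var"] = float(lam[1, 1] * sigma2)
            vc["study_cov"] = float(lam[0, 1] * sigma2)
        self.varcomps = vc
        self.neg2_reml = prof.neg2_reml
        self.llf = -0.5 * prof.neg2_reml
        k = len(self.params) + model._n_theta(cov_struct) + 1
        self.n_parameters = k
        self.bic = prof.neg2_reml + k * math.log(model.nobs)
        self.nobs = model.nobs
        self.fittedvalues = pd.Series(
            model.exog @ prof.beta, index=model._frame.index
        )
        resid = model.endog - model.exog @ prof.beta
        self.resid = pd.Series(resid, index=model._frame.index)
        self.rmse = math.sqrt(sigma2)
        # R^2: squared correlation between observed response and the
        # fixed-effects predictions (mixed-model R^2 conventions differ;
        # this one is documented prominently)
        if np.std(model.endog) > 0 and np.std(self.fittedvalues.to_numpy()) > 0:
            self.r2 = float(
                np.corrcoef(model.endog, self.fittedvalues.to_numpy())[0, 1] ** 2
            )
        else:
            self.r2 = float("nan")

    @property
    def n_used(self) -> int:
        return self.nobs

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Fixed-effects (population-level) predictions for new records."""
        m = self.model
        X = [np.ones(len(data))] + [data[p].to_numpy(float) for p in m.predictors]
        X += [data[p].to_numpy(float) ** 2 for p in m.squared]
        return pd.Series(np.column_stack(X) @ self.params.to_numpy(), index=data.index)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Weighted mixed linear model (REML)",
            "=" * 64,
            f"Response: {m.response}    Groups: {m.group} ({m.n_groups})",
            f"N records: {self.nobs}    Covariance structure: {self.cov_struct_used}"
            + (f" (fallback: {self.fallback_reason})" if self.fallback_reason else ""),
            "",
            pd.DataFrame(
                {
                    "coef": self.params,
                    "std err": self.bse,
                    "z": self.params / self.bse,
                    "P>|z|": self.pvalues,
                }
            ).to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Variance components:",
        ]
        for k, v in self.varcomps.items():
            lines.append(f"  {k:<22s} {v: .5f}")
        lines.append("")
        lines.append(
            f"RMSE = {self.rmse:.4f}   R2(fixed) = {self.r2:.4f}   "
            f"BIC = {self.bic:.2f}"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MixedLMResult {self.model.response} ~ "
            f"{' + '.join(self.model.exog_names[1:]) or '1'}, "
            f"{self.cov_struct_used}, n={self.nobs}>"
        )
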