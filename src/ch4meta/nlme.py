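"""Nonlinear mixed models for methane versus intake.

Five diminishing-returns / sigmoidal / growth forms relate methane output
``Y`` (MJ/day) to a single intake variable ``x`` (DM intake kg/day or ME
intake MJ/day):

    monomolecular   Y = a - (a + b) exp(-c x)
    mitscherlich    Y = a (1 - exp(-c x))          (monomolecular with b = 0)
    gompertz        Y = b exp{[1 - exp(-c x)] ln[(a + 2b)/b]} - 2b
    exponential     Y = b exp(c x)
    power           Y = b x^c

``a`` is the upper asymptote, ``b`` sets the Y-intercept and ``c`` the shape
of the response curve.  Parameters carry study-level random effects
(independent Gaussian deviations added to each random parameter); the
marginal likelihood is approximated by the Laplace method with a
Gauss-Newton Hessian, per-study inner optimization of the random deviations,
and a derivative-free outer optimizer.  When the all-parameters-random
structure fails to converge the model falls back to a random ``b`` only and
finally to a fixed-effects-only nonlinear least-squares fit.  Initial values
come from a deterministic coarse grid over data-driven bounds (log-spaced;
no randomness).

Fits report BIC for across-form selection
(:func:`ch4meta.screening.select_best`).
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError

__all__ = ["NonlinearMixedModel", "NonlinearResult", "FORMS"]

_EPS = 1e-8


def _mono(th, x):
    a, b, c = th
    return a - (a + b) * np.exp(-np.maximum(c, _EPS) * x)


def _mitscherlich(th, x):
    a, c = th
    return a * (1.0 - np.exp(-np.maximum(c, _EPS) * x))


def _gompertz(th, x):
    a, b, c = th
    a = max(a, _EPS)
    b = max(b, _EPS)
    inner = (1.0 - np.exp(-np.maximum(c, _EPS) * x)) * math.log((a + 2 * b) / b)
    return b * np.exp(inner) - 2 * b


def _exponential(th, x):
    b, c = th
    return np.abs(b) * np.exp(c * x)


def _power(th, x):
    b, c = th
    return b * np.power(np.maximum(x, _EPS), c)


# form -> (parameter names, vectorized mean function)
FORMS: Dict[str, Tuple[Tuple[str, ...], callable]] = {
    "monomolecular": (("a", "b", "c"), _mono),
    "mitscherlich": (("a", "c"), _mitscherlich),
    "gompertz": (("a", "b", "c"), _gompertz),
    "exponential": (("b", "c"), _exponential),
    "power": (("b", "c"), _power),
}


def _grid_init(form: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic coarse-grid / regression-based starting values."""
    names, f = FORMS[form]
    ymax, xbar = float(np.max(y)), float(np.mean(x))
    pos = (y > 0) & (x > 0)
    if form in ("exponential", "power"):
        # log-linear / log-log regression gives closed-form starts
        ly = np.log(y[pos])
        reg = np.log(x[pos]) if form == "power" else x[pos]
        A = np.column_stack([np.ones(pos.sum()), reg])
        coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
        return np.array([math.exp(coef[0]), coef[1]])
    a_grid = np.geomspace(max(ymax, _EPS), 5.0 * max(ymax, 1.0), 10)
    c_grid = np.geomspace(0.05 / max(xbar, _EPS), 5.0 / max(xbar, _EPS), 10)
    if form == "mitscherlich":
        combos = [(a, c) for a in a_grid for c in c_grid]
    else:
        b_grid = np.geomspace(1e-3, max(ymax, 1.0), 10)
        combos = [(a, b, c) for a in a_grid for b in b_grid for c in c_grid]
    best, best_ssr = None, np.inf
    for th in combos:
        r = y - f(np.asarray(th, float), x)
        ssr = float(r @ r)
        if ssr < best_ssr:
            best, best_ssr = np.asarray(th, float), ssr
    return best


def _bounds(form: str) -> Tuple[np.ndarray, np.ndarray]:
    names, _ = FORMS[form]
    lo = np.array([_EPS if n in ("a", "c") else (_EPS if form == "gompertz" else 0.0)
                   for n in names])
    if form in ("exponential", "power"):
        lo = np.array([_EPS, -5.0])
    return lo, np.full(len(names), np.inf)


class NonlinearResult:
    """Results of a :class:`NonlinearMixedModel` fit."""

    def __init__(
        self,
        model: "NonlinearMixedModel",
        params: Dict[str, float],
        bse: Dict[str, float],
        sd_random: Dict[str, float],
        sigma: float,
        neg2ll: float,
        converged: bool,
        structure: Tuple[str, ...],
    ) -> None:
        self.model = model
        self.form = model.form
        self.params = params
        self.bse = bse
        self.sd_random = sd_random
        self.sigma = sigma
        self.rmse = sigma
        self.neg2ll = neg2ll
        self.llf = -0.5 * neg2ll
        self.converged = converged
        self.structure = structure
        self.n_parameters = len(params) + len(sd_random) + 1
        self.nobs = model.nobs
        self.bic = neg2ll + self.n_parameters * math.log(model.nobs)
        fitted = self.predict(model.x)
        if np.std(model.y) > 0 and np.std(fitted) > 0:
            self.r2 = float(np.corrcoef(model.y, fitted)[0, 1] ** 2)
        else:
            self.r2 = float("nan")

    def predict(self, x) -> np.ndarray:
        names, f = FORMS[self.form]
        th = np.array([self.params[n] for n in names])
        return f(th, np.asarray(x, float))

    def summary(self) -> str:
        lines = [
            f"Nonlinear mixed model: {self.form}",
            "=" * 48,
            f"N records: {self.nobs}    random parameters: "
            + (", ".join(self.structure) if self.structure else "none"),
        ]
        for n, v in self.params.items():
            se = self.bse.get(n)
            se_s = f" (se {se:.4f})" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {n} = {v:.4f}{se_s}")
        for n, s in self.sd_random.items():
            lines.append(f"  sd(u_{n}) = {s:.4f}")
        lines.append(
            f"sigma = {self.sigma:.4f}   R2(fixed) = {self.r2:.4f}   BIC = {self.bic:.2f}"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<NonlinearResult {self.form} n={self.nobs} bic={self.bic:.1f}>"


class NonlinearMixedModel:
    """Nonlinear model with study-level random effects on the parameters.

    Parameters
    ----------
    data
        Record table.
    form
        One of ``monomolecular``, ``mitscherlich``, ``gompertz``,
        ``exponential``, ``power``.
    predictor, response, group
        Column names (DM or ME intake; methane MJ/day; study id).
    random
        ``"auto"`` (all parameters random, falling back to ``b`` only, then
        fixed-only), ``"none"``, or an explicit tuple of parameter names.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        form: str,
        predictor: str = "dmi_kg_d",
        response: str = "ch4_mj_d",
        group: str = "study_id",
        random: object = "auto",
    ) -> None:
        if form not in FORMS:
            raise ValueError(f"unknown nonlinear form {form!r}")
        self.form = form
        self.predictor = predictor
        self.response = response
        d = data.dropna(subset=[predictor, response, group])
        self.x = d[predictor].to_numpy(float)
        self.y = d[response].to_numpy(float)
        self.groups = d[group].to_numpy()
        self.nobs = len(d)
        self.random = random
        names, _ = FORMS[form]
        self.param_names = names
        labels, inv = np.unique(self.groups, return_inverse=True)
        self._group_rows = [np.flatnonzero(inv == k) for k in range(len(labels))]

    # -- fixed-effects-only NLS ----------------------------------------------

    def _fit_fixed(self) -> NonlinearResult:
        names, f = FORMS[self.form]
        x0 = _grid_init(self.form, self.x, self.y)
        lo, hi = _bounds(self.form)
        x0 = np.clip(x0, lo + 1e-9, None)
        sol = optimize.least_squares(
            lambda th: self.y - f(th, self.x), x0, bounds=(lo, hi), xtol=1e-12,
            ftol=1e-12, max_nfev=2000,
        )
        th = sol.x
        ssr = float(sol.fun @ sol.fun)
        sigma2 = max(ssr / self.nobs, 1e-12)
        neg2ll = self.nobs * (math.log(2 * math.pi * sigma2) + 1.0)
        # asymptotic SEs from the Gauss-Newton information
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * ssr / max(self.nobs - len(th), 1)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(len(th), np.nan)
        return NonlinearResult(
            self,
            dict(zip(names, th)),
            dict(zip(names, se)),
            {},
            math.sqrt(sigma2),
            neg2ll,
            bool(sol.success),
            (),
        )

    # -- Laplace-approximate mixed fit ----------------------------------------

    def _fit_random(self, rand_names: Tuple[str, ...]) -> NonlinearResult:
        names, f = FORMS[self.form]
        ridx = [names.index(n) for n in rand_names]
        q = len(ridx)
        fixed0 = self._fit_fixed()
        th0 = np.array([fixed0.params[n] for n in names])
        sd0 = np.maximum(0.1 * np.abs(th0[ridx]), 1e-2)
        sigma0 = max(fixed0.sigma, 1e-3)
        v0 = np.concatenate([th0, np.log(sd0), [math.log(sigma0)]])
        m = len(names)
        warm: Dict[int, np.ndarray] = {}

        def group_neg2ll(k: int, th, d, sigma2) -> float:
            rows = self._group_rows[k]
            xg, yg = self.x[rows], self.y[rows]
            h = 1e-6

            def theta_with(u):
                t = th.copy()
                t[ridx] = t[ridx] + u
                return t

            def jac_resid(u):
                base = f(theta_with(u), xg)
                J = np.empty((len(rows), q))
                for j in range(q):
                    du = np.zeros(q)
                    du[j] = h
                    J[:, j] = (f(theta_with(u + du), xg) - base) / h
                return yg - base, J

            # inner mode by damped Gauss-Newton (penalized nonlinear ridge)
            u = warm.get(k, np.zeros(q)).copy()
            r, J = jac_resid(u)
            obj = float(r @ r) / sigma2 + float(np.sum(u * u / d))
            for _ in range(30):
                H = (J.T @ J) / sigma2 + np.diag(1.0 / d)
                g = -(J.T @ r) / sigma2 + u / d
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    return 1e10
                lam_damp = 1.0
                for _ in range(8):
                    u_new = u - lam_damp * step
                    r_new, J_new = jac_resid(u_new)
                    obj_new = float(r_new @ r_new) / sigma2 + float(np.sum(u_new**2 / d))
                    if obj_new <= obj + 1e-12:
                        break
                    lam_damp *= 0.5
                moved = np.max(np.abs(u_new - u))
                u, r, J, obj = u_new, r_new, J_new, obj_new
                if moved < 1e-9:
                    break
            warm[k] = u
            H = (J.T @ J) / sigma2 + np.diag(1.0 / d)
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            return (
                float(r @ r) / sigma2
                + len(rows) * math.log(2 * math.pi * sigma2)
                + float(np.sum(u * u / d))
                + float(np.sum(np.log(d)))
                + logdetH
            )

        def objective(v):
            th = v[:m]
            d = np.exp(2.0 * v[m:m + q])
            sigma2 = math.exp(2.0 * v[-1])
            if not np.all(np.isfinite(th)):
                return 1e12
            try:
                total = sum(group_neg2ll(k, th, d, sigma2)
                            for k in range(len(self._group_rows)))
            except (FloatingPointError, ValueError):
                return 1e12
            return total if np.isfinite(total) else 1e12

        sol = optimize.minimize(
            objective, v0, method="Nelder-Mead",
            options={"maxiter": 250 * len(v0), "xatol": 1e-5, "fatol": 1e-6},
        )
        th = sol.x[:m]
        sd_u = np.exp(sol.x[m:m + q])
        sigma = math.exp(sol.x[-1])
        ok = bool(sol.success) and np.isfinite(sol.fun) and sol.fun < 1e9
        return NonlinearResult(
            self,
            dict(zip(names, th)),
            {n: float("nan") for n in names},
            dict(zip(rand_names, sd_u)),
            sigma,
            float(sol.fun),
            ok,
            tuple(rand_names),
        )

    def fit(self) -> NonlinearResult:
        """Fit, walking the fallback chain of random structures.

        Raises
        ------
        ConvergenceError
            If every attempted structure fails.
        """
        names = self.param_names
        if self.random == "none" or self.random == ():
            chain: List[Tuple[str, ...]] = [()]
        elif isinstance(self.random, (tuple, list)):
            chain = [tuple(self.random), ()]
        else:  # auto: all random -> b only (or first param) -> fixed only
            b_only = ("b",) if "b" in names else (names[0],)
            chain = [tuple(names), b_only, ()]
        errors = []
        for structure in chain:
            try:
                res = self._fit_random(structure) if structure else self._fit_fixed()
            except Exception as exc:  # noqa: BLE001 - diagnostic chain
                errors.append(f"{structure}: {exc}")
                continue
            if res.converged:
                return res
            errors.append(f"{structure}: did not converge")
        raise ConvergenceError(
            f"nonlinear mixed fit failed at every level: {'; '.join(errors)}"
        )
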