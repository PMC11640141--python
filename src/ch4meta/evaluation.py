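"""Model-comparison calculus: MSPE decomposition and concordance analysis.

For observed ``O_i`` and predicted ``P_i`` methane (MJ/day):

* ``MSPE = sum (O_i - P_i)^2 / n`` and ``RMSPE% = 100 sqrt(MSPE) / mean(O)``;
* the MSPE decomposes exactly (population, divide-by-n SDs throughout) into
  mean bias ``ECT = (Pbar - Obar)^2``, regression (slope) bias
  ``ER = (S_p - r S_o)^2`` and random error ``ED = (1 - r^2) S_o^2``;
* Lin's concordance correlation coefficient ``CCC = r x Cb`` with bias
  correction factor ``Cb = 2 / (v + 1/v + mu^2)``, scale shift
  ``v = S_o / S_p`` and location shift ``mu = (Obar - Pbar) / sqrt(S_o S_p)``
  (negative ``mu`` = systematic overprediction).

Population SDs make ECT + ER + ED = MSPE an algebraic identity; the
component form of the CCC is cross-checked against the direct form
``2 r S_o S_p / (S_o^2 + S_p^2 + (Obar - Pbar)^2)`` in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equations import EquationSpec, predict, predictors_from_record, required_inputs
from .errors import EvaluationError, PredictionError

__all__ = [
    "mspe",
    "decompose_mspe",
    "rmspe_pct",
    "ccc_analysis",
    "EvalMetrics",
    "evaluate_metrics",
    "evaluate_equations",
    "correlation_screen",
    "residual_diagnostics",
    "ResidualDiagnostics",
]


def _check(obs, pred) -> tuple:
    o = np.asarray(obs, float)
    p = np.asarray(pred, float)
    if o.shape != p.shape:
        raise EvaluationError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 2:
        raise EvaluationError("need at least two observations")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise EvaluationError("non-finite values in input")
    return o, p


def mspe(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Mean squared prediction error, (MJ/day)^2."""
    o, p = _check(obs, pred)
    return float(np.mean((o - p) ** 2))


class MSPEComponents(NamedTuple):
    ect: float  # error of central tendency (mean bias)
    er: float  # error due to regression (slope bias)
    ed: float  # error due to disturbance (random)


def decompose_mspe(obs: Sequence[float], pred: Sequence[float]) -> MSPEComponents:
    """Decompose the MSPE into (ECT, ER, ED); the parts sum to the MSPE exactly."""
    o, p = _check(obs, pred)
    s_o, s_p = float(np.std(o)), float(np.std(p))
    if s_o == 0.0 or s_p == 0.0:
        raise EvaluationError("zero variance in observed or predicted series")
    r = float(np.corrcoef(o, p)[0, 1])
    ect = (p.mean() - o.mean()) ** 2
    er = (s_p - r * s_o) ** 2
    ed = (1.0 - r * r) * s_o * s_o
    return MSPEComponents(float(ect), float(er), float(ed))


def rmspe_pct(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Root MSPE as a percentage of the observed mean."""
    o, p = _check(obs, pred)
    if o.mean() <= 0:
        raise EvaluationError("observed mean must be positive for RMSPE%")
    return float(100.0 * np.sqrt(mspe(o, p)) / o.mean())


class CCCAnalysis(NamedTuple):
    r: float  # Pearson correlation (precision)
    ccc: float  # concordance correlation coefficient
    cb: float  # bias correction factor (accuracy)
    v: float  # scale shift S_o / S_p
    mu: float  # location shift; negative = overprediction


def ccc_analysis(obs: Sequence[float], pred: Sequence[float]) -> CCCAnalysis:
    """Lin's concordance analysis with population SDs."""
    o, p = _check(obs, pred)
    s_o, s_p = float(np.std(o)), float(np.std(p))
    if s_o == 0.0 or s_p == 0.0:
        raise EvaluationError("zero variance in observed or predicted series")
    r = float(np.corrcoef(o, p)[0, 1])
    v = s_o / s_p
    mu = (o.mean() - p.mean()) / np.sqrt(s_o * s_p)
    cb = 2.0 / (v + 1.0 / v + mu * mu)
    return CCCAnalysis(r, float(r * cb), float(cb), float(v), float(mu))


@dataclass(frozen=True)
class EvalMetrics:
    """Full evaluation of one equation on one dataset."""

    equation: str
    n: int
    mean_obs: float
    mean_pred: float
    mspe: float
    rmspe: float
    rmspe_pct: float
    ect: float
    er: float
    ed: float
    ect_pct: float
    er_pct: float
    ed_pct: float
    r: float
    ccc: float
    cb: float
    v: float
    mu: float


def evaluate_metrics(obs, pred, label: str = "") -> EvalMetrics:
    """Compute every evaluation statistic for one observed/predicted pair."""
    o, p = _check(obs, pred)
    m = mspe(o, p)
    parts = decompose_mspe(o, p)
    conc = ccc_analysis(o, p)
    shares = (
        tuple(100.0 * c / m for c in parts) if m > 0 else (0.0, 0.0, 0.0)
    )
    return EvalMetrics(
        equation=label,
        n=int(o.size),
        mean_obs=float(o.mean()),
        mean_pred=float(p.mean()),
        mspe=m,
        rmspe=float(np.sqrt(m)),
        rmspe_pct=rmspe_pct(o, p),
        ect=parts.ect,
        er=parts.er,
        ed=parts.ed,
        ect_pct=shares[0],
        er_pct=shares[1],
        ed_pct=shares[2],
        r=conc.r,
        ccc=conc.ccc,
        cb=conc.cb,
        v=conc.v,
        mu=conc.mu,
    )


def evaluate_equations(
    records: pd.DataFrame,
    equations: Sequence[EquationSpec],
    response: str = "ch4_mj_d",
    literal_sign: bool = False,
) -> pd.DataFrame:
    """Evaluate each equation against observed methane on a record table.

    Records missing a predictor an equation needs are dropped *for that
    equation* (no evaluation-time imputation); ``n`` reports the records
    actually used.  Equations with no usable records yield a warning row of
    NaNs.  Row order matches the input equation order.
    """
    rows: List[Dict] = []
    for eq in equations:
        obs, preds = [], []
        for _, rec in records.iterrows():
            y = rec.get(response)
            if pd.isna(y):
                continue
            x = predictors_from_record(rec)
            if not required_inputs(eq) <= set(x):
                continue
            obs.append(float(y))
            preds.append(predict(eq, x, literal_sign=literal_sign))
        if len(obs) < 2:
            warnings.warn(
                f"equation {eq.id!r}: no usable records; skipped", stacklevel=2
            )
            rows.append({"equation": eq.id, "n": len(obs)})
            continue
        rows.append(asdict(evaluate_metrics(obs, preds, label=eq.id)))
    return pd.DataFrame(rows)


def correlation_screen(
    records: pd.DataFrame,
    variables: Sequence[str],
    response: str = "ch4_mj_d",
) -> pd.DataFrame:
    """Pearson correlation of methane with each candidate variable.

    Returns one row per variable (name, n, r, two-sided p, R2 = r^2);
    variables with fewer than 3 complete pairs are reported with a note and
    NaN statistics.
    """
    rows = []
    for var in variables:
        if var not in records.columns:
            rows.append({"variable": var, "n": 0, "note": "column absent"})
            continue
        d = pd.DataFrame(
            {"y": records[response], "x": records[var]}
        ).dropna()
        if len(d) < 3:
            rows.append(
                {"variable": var, "n": len(d), "note": "fewer than 3 complete pairs"}
            )
            continue
        r, p = stats.pearsonr(d["x"].to_numpy(), d["y"].to_numpy())
        rows.append(
            {
                "variable": var,
                "n": len(d),
                "r": float(r),
                "p_value": float(p),
                "r2": float(r * r),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Mean-centered residual regression (observed - predicted on centered predicted)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float


def residual_diagnostics(obs, pred) -> ResidualDiagnostics:
    """Regress residuals on mean-centered predictions.

    Centering the predictions makes the intercept equal the mean bias
    ``Obar - Pbar`` exactly, and the slope measures how the bias changes
    across the prediction range.
    """
    o, p = _check(obs, pred)
    if np.std(p) == 0.0:
        raise EvaluationError("degenerate predictions (zero variance)")
    resid = o - p
    xc = p - p.mean()
    X = np.column_stack([np.ones_like(xc), xc])
    coef, res_ss, *_ = np.linalg.lstsq(X, resid, rcond=None)
    fitted = X @ coef
    dof = max(len(o) - 2, 1)
    s2 = float(np.sum((resid - fitted) ** 2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return ResidualDiagnostics(
        slope=float(coef[1]),
        intercept=float(coef[0]),
        slope_se=float(np.sqrt(cov[1, 1])),
        intercept_se=float(np.sqrt(cov[0, 0])),
    )
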