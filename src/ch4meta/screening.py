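"""Outlier screening, collinearity checks, backward elimination, BIC selection.

The equation-development workflow around :class:`~ch4meta.mixedlm.MethaneMixedLM`:

1. screen records by Cook's distance on the fixed-effects regression
   (an explicit ``D > 4/n`` rule replaces visual inspection of the Cook's D
   distribution; the cutoff is configurable);
2. reject candidate predictor sets with variance inflation factors >= 10
   before any mixed fit;
3. backward-eliminate fixed terms (worst p first; a term stays when its
   Wald p <= ``alpha_stay``, default 0.05);
4. retain the quadratic term and the study random slope of the primary
   predictor only when significant at the 0.10 level (likelihood-ratio test
   for the random component);
5. select among converged fits by minimum BIC, ties broken toward fewer
   parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankError, SelectionError
from .mixedlm import MethaneMixedLM, MixedLMResult

__all__ = [
    "detect_outliers",
    "compute_vif",
    "backward_eliminate",
    "screen_random_and_quadratic",
    "select_best",
    "EliminationStep",
]


def detect_outliers(
    data: pd.DataFrame,
    response: str = "ch4_mj_d",
    predictors: Sequence[str] = ("dmi_kg_d",),
    weights: Optional[str] = "n_animals",
    cutoff: Optional[float] = None,
) -> List:
    """Flag influential records by Cook's distance on the fixed-effects fit.

    Returns the index labels of records with ``D > cutoff`` (default ``4/n``).
    Flagged records are reported, never silently dropped.

    Raises
    ------
    RankError
        If there are fewer usable records than regression coefficients or
        fewer than 10 records overall.
    """
    cols = [response] + list(predictors)
    if weights and weights in data.columns:
        cols.append(weights)
    d = data.dropna(subset=[c for c in cols if c in data.columns])
    n, p = len(d), len(predictors) + 1
    if n < 10 or n <= p:
        raise RankError(f"{n} records is too few for {p} regression coefficients")
    y = d[response].to_numpy(float)
    X = sm.add_constant(d[list(predictors)].to_numpy(float))
    w = (
        d[weights].to_numpy(float)
        if weights and weights in d.columns
        else np.ones(n)
    )
    # WLS is OLS on sqrt(w)-scaled data; influence measures carry over
    sw = np.sqrt(w)
    res = sm.OLS(y * sw, X * sw[:, None]).fit()
    cooks = res.get_influence().cooks_distance[0]
    cut = 4.0 / n if cutoff is None else cutoff
    return list(d.index[cooks > cut])


def compute_vif(data: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors, ``VIF_k = 1 / (1 - R2_k)``.

    ``R2_k`` comes from regressing predictor ``k`` on the other predictors
    (with intercept).  Exact collinearity is reported as ``inf``, not raised.

    Raises
    ------
    RankError
        With fewer than two predictors (VIF is then undefined).
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise RankError("VIF needs at least two predictors")
    d = data.dropna(subset=predictors)
    out = {}
    for k in predictors:
        others = [p for p in predictors if p != k]
        X = sm.add_constant(d[others].to_numpy(float))
        r2 = sm.OLS(d[k].to_numpy(float), X).fit().rsquared
        out[k] = float("inf") if (1.0 - r2) < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class EliminationStep:
    """One decision in the backward-elimination trace."""

    action: str  # "vif_reject" | "fit" | "remove" | "keep"
    detail: str
    predictors: Tuple[str, ...]
    pvalues: Dict[str, float] = field(default_factory=dict)


def backward_eliminate(
    data: pd.DataFrame,
    candidates: Sequence[str],
    response: str = "ch4_mj_d",
    group: str = "study_id",
    weights: Optional[str] = "n_animals",
    alpha_stay: float = 0.05,
    vif_threshold: float = 10.0,
    cov_struct: str = "auto",
) -> Tuple[MixedLMResult, List[EliminationStep]]:
    """Backward elimination over candidate predictors of the mixed model.

    Candidate sets with any VIF >= ``vif_threshold`` are trimmed (worst VIF
    first) before any fit.  Then, repeatedly, the fixed term with the largest
    Wald p > ``alpha_stay`` is dropped and the model refitted; the study
    random slope rides on the first surviving candidate.  The trace records
    every fit and decision; the procedure is fully deterministic given the
    data.

    Returns the final fit and the trace.
    """
    current = list(candidates)
    if not current:
        raise SelectionError("backward_eliminate: empty candidate set")
    trace: List[EliminationStep] = []
    while len(current) >= 2:
        vif = compute_vif(data, current)
        if vif.max() < vif_threshold:
            break
        # ties (e.g. exact collinearity) drop the later-listed candidate
        top = [k for k in current if vif[k] == vif.max()]
        worst = top[-1]
        trace.append(
            EliminationStep(
                "vif_reject",
                f"{worst} removed before fitting (VIF={vif[worst]:.3g} >= {vif_threshold:g})",
                tuple(current),
                {k: float(v) for k, v in vif.items()},
            )
        )
        current.remove(worst)

    while True:
        model = MethaneMixedLM(
            data,
            response=response,
            predictors=current,
            group=group,
            weights=weights,
            random_slope=current[0],
            cov_struct=cov_struct,
        )
        result = model.fit()
        pvals = {k: float(result.pvalues[k]) for k in current}
        trace.append(
            EliminationStep("fit", f"fitted with {current}", tuple(current), pvals)
        )
        removable = {k: p for k, p in pvals.items() if p > alpha_stay}
        if not removable or len(current) == 1:
            trace.append(
                EliminationStep(
                    "keep",
                    "all remaining terms significant"
                    if not removable
                    else "single candidate retained",
                    tuple(current),
                    pvals,
                )
            )
            return result, trace
        worst = max(removable, key=removable.get)
        trace.append(
            EliminationStep(
                "remove",
                f"{worst} dropped (p={removable[worst]:.4f} > {alpha_stay:g})",
                tuple(current),
                pvals,
            )
        )
        current.remove(worst)


def screen_random_and_quadratic(
    data: pd.DataFrame,
    predictor: str,
    response: str = "ch4_mj_d",
    group: str = "study_id",
    weights: Optional[str] = "n_animals",
    alpha: float = 0.10,
) -> Dict[str, object]:
    """Single-predictor development screen at the 0.10 level.

    Tests (a) the quadratic fixed term (Wald) and (b) the study random slope
    (REML likelihood-ratio against the intercept-only random structure,
    p-value from chi-square with 1 df) and returns the retained model.
    """
    quad = MethaneMixedLM(
        data, response=response, predictors=[predictor], squared=[predictor],
        group=group, weights=weights, random_slope=predictor,
    ).fit()
    keep_quad = float(quad.pvalues[f"{predictor}^2"]) <= alpha

    full = MethaneMixedLM(
        data, response=response, predictors=[predictor], group=group,
        weights=weights, random_slope=predictor,
    ).fit()
    null = MethaneMixedLM(
        data, response=response, predictors=[predictor], group=group,
        weights=weights, random_slope=False,
    ).fit()
    lr = max(null.neg2_reml - full.neg2_reml, 0.0)
    p_slope = 1.0 - stats.chi2.cdf(lr, df=1)
    keep_slope = p_slope <= alpha

    chosen = MethaneMixedLM(
        data,
        response=response,
        predictors=[predictor],
        squared=[predictor] if keep_quad else [],
        group=group,
        weights=weights,
        random_slope=predictor if keep_slope else False,
    ).fit()
    return {
        "result": chosen,
        "quadratic_retained": keep_quad,
        "quadratic_p": float(quad.pvalues[f"{predictor}^2"]),
        "random_slope_retained": keep_slope,
        "random_slope_p": float(p_slope),
    }


def select_best(fits: Sequence) -> object:
    """Minimum-BIC selection among converged fits; ties favor fewer parameters."""
    converged = [f for f in fits if getattr(f, "converged", False)]
    if not converged:
        raise SelectionError("no converged fit to select from")
    return min(converged, key=lambda f: (f.bic, f.n_parameters))
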