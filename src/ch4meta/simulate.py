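"""Seeded synthetic treatment-mean databases.

The literature database behind the published equations is not deposited, so
this module generates surrogate databases with the structure the analysis
assumes:

* marginals of animal and diet variables are truncated normals whose
  *truncated* mean and SD are moment-matched to the packaged calibration
  summaries (solving for the underlying location/scale numerically — using
  the printed mean/SD as untruncated parameters would bias every skewed
  variable, e.g. combined DMI from 10.28 to ~11.2 kg/day);
* non-fibrous carbohydrate closes the composition (NFC = OM - CP - EE - NDF);
* OM digestibility is negatively linked to diet NDF (fibrous diets digest
  worse), and GE/DM digestibility follow the harmonization regressions plus
  their reported residual scatter;
* methane is generated from a *true equation* (by default the database's own
  DMI-only linear equation) plus a study random intercept, a study random
  slope on DMI, and residual noise, then floored at 0.1 MJ/day;
* every methane unit variant and the full energy chain (GEI from chemistry,
  DEI from GE digestibility, UE as 4% of GEI, MEI by balance, q, FL, OMDm)
  are derived with the harmonization constants, so generated tables are
  internally consistent.

A config plus seed fully determines the output table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import schema
from .calibration import CalibrationTable, calibration_table
from .equations import EquationSpec, get_equation, predict, predictors_from_record, required_inputs
from .errors import ConfigurationError, GenerationError
from .harmonize import CONSTANTS, feeding_level, ge_concentration, omd_at_maintenance

__all__ = [
    "SyntheticConfig",
    "sample_diet_and_animal",
    "assign_true_methane",
    "generate_database",
    "matched_truncnorm_params",
]

# default data-generating equation per database: the DMI-only linear equation
# developed on that database (DM intake is the single best methane predictor)
_DEFAULT_TRUE_EQUATION = {"beef": "eq1b", "dairy": "eq2d", "combined": "eq1c"}

# assumed correlation between diet NDF and OM digestibility (structural link;
# more fibrous diets are less digestible)
_NDF_OMD_CORR = -0.5
# urinary energy as a fraction of gross energy intake
_UE_FRACTION = 0.04
# residual SDs of the digestibility imputation regressions (g/kg), used as
# scatter when deriving GE and DM digestibility from OM digestibility
_GED_RESID_SD = 7.9
_DMD_RESID_SD = 32.8

CH4_FLOOR_MJ_D = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic database draw.

    ``treatments_per_study`` may be an int or an inclusive ``(lo, hi)`` range.
    ``true_equation`` is an equation id or :class:`EquationSpec`; it defines
    the data-generating conditional mean of CH4 (MJ/day) given the diet.
    Random-effect SDs are chosen so that methane stays positive over the DMI
    range and the 0.1 MJ/day floor is essentially never active.
    """

    database: str = "combined"
    n_studies: int = 30
    treatments_per_study: Union[int, Tuple[int, int]] = 5
    true_equation: Union[str, EquationSpec, None] = None
    study_intercept_sd: float = 0.6  # MJ/day
    study_slope_sd: float = 0.08  # (MJ/day)/(kg/day)
    residual_sd: float = 0.8  # MJ/day
    animals_per_treatment: Tuple[int, int] = (4, 16)
    variable_sd_scale: float = 1.0  # scales all diet/animal marginal SDs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.database not in ("beef", "dairy", "combined"):
            raise ConfigurationError(f"unknown database {self.database!r}")
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be a positive integer")
        tps = self.treatments_per_study
        if isinstance(tps, int):
            ok = tps >= 1
        else:
            ok = len(tps) == 2 and 1 <= tps[0] <= tps[1]
        if not ok:
            raise ConfigurationError(f"invalid treatments_per_study {tps!r}")
        for name in ("study_intercept_sd", "study_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.variable_sd_scale < 0:
            raise ConfigurationError("variable_sd_scale must be >= 0")
        lo, hi = self.animals_per_treatment
        if not (1 <= lo <= hi):
            raise ConfigurationError("animals_per_treatment must be a valid range")

    @property
    def equation(self) -> EquationSpec:
        eq = self.true_equation
        if eq is None:
            eq = _DEFAULT_TRUE_EQUATION[self.database]
        if isinstance(eq, str):
            eq = get_equation(eq)
        return eq

    @property
    def calibration(self) -> CalibrationTable:
        return calibration_table(self.database)


_MATCH_CACHE: Dict[Tuple[float, float, float, float], Tuple[float, float]] = {}


def matched_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> Tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal has the target moments.

    Solved numerically; falls back to the raw (mean, sd) with a warning if no
    parameter pair reproduces the target mean/SD on the interval (the match
    residual is then reported).
    """
    key = (mean, sd, lo, hi)
    if key in _MATCH_CACHE:
        return _MATCH_CACHE[key]

    def residuals(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [(m - mean) / sd, (np.sqrt(v) - sd) / sd]

    sol = optimize.least_squares(
        residuals, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    res = np.abs(sol.fun).max()
    if res > 1e-6:
        warnings.warn(
            f"truncated-normal moment match imperfect for target "
            f"(mean={mean}, sd={sd}, range=[{lo}, {hi}]): residual {res:.2e}; "
            "using best fit"
        )
    out = (float(sol.x[0]), float(np.exp(sol.x[1])))
    _MATCH_CACHE[key] = out
    return out


def _draw(
    cfg: SyntheticConfig, var: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n values of a calibrated variable (moment-matched truncated normal)."""
    s = cfg.calibration[var]
    sd = s.sd * cfg.variable_sd_scale
    if sd == 0:
        return np.full(n, s.mean)
    mu, sigma = matched_truncnorm_params(s.mean, sd, s.min, s.max)
    a, b = (s.min - mu) / sigma, (s.max - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _clip_to_range(cfg: SyntheticConfig, var: str, x: np.ndarray) -> np.ndarray:
    s = cfg.calibration[var]
    return np.clip(x, s.min, s.max)


def _sample_records(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n diet/animal/digestibility records (no study effects, no methane)."""
    cal = cfg.calibration
    d: Dict[str, np.ndarray] = {}
    d["bw_kg"] = _draw(cfg, "bw", n, rng)
    d["dmi_kg_d"] = _draw(cfg, "dmi", n, rng)
    d["cp_g_kg"] = _draw(cfg, "cp", n, rng)
    d["ee_g_kg"] = _draw(cfg, "ee", n, rng)
    d["ndf_g_kg"] = _draw(cfg, "ndf", n, rng)
    adf = _draw(cfg, "adf", n, rng)
    d["adf_g_kg"] = np.minimum(adf, d["ndf_g_kg"])  # ADF is a subset of NDF
    d["roughage_g_kg"] = _draw(cfg, "roughage", n, rng)
    d["om_g_kg"] = _draw(cfg, "om", n, rng)
    # NFC closes the composition; when the closure residual falls below the
    # calibration minimum, scale CP/EE/NDF down so CP+EE+NDF+NFC <= OM holds
    nfc_raw = d["om_g_kg"] - d["cp_g_kg"] - d["ee_g_kg"] - d["ndf_g_kg"]
    nfc_min, nfc_max = cal["nfc"].min, cal["nfc"].max
    low = nfc_raw < nfc_min
    if np.any(low):
        # shrink CP/EE/NDF towards their calibration minima (keeping each in
        # range) until the closure residual reaches the NFC minimum
        mins = {c: cal[v].min for c, v in
                (("cp_g_kg", "cp"), ("ee_g_kg", "ee"), ("ndf_g_kg", "ndf"))}
        excess = sum(d[c][low] - mins[c] for c in mins)
        target = d["om_g_kg"][low] - nfc_min - sum(mins.values())
        shrink = np.clip(target / np.maximum(excess, 1e-12), 0.0, 1.0)
        for comp in mins:
            d[comp][low] = mins[comp] + shrink * (d[comp][low] - mins[comp])
        d["adf_g_kg"][low] = np.minimum(d["adf_g_kg"][low], d["ndf_g_kg"][low])
        nfc_raw[low] = nfc_min
    d["nfc_g_kg"] = np.minimum(nfc_raw, nfc_max)

    # OM digestibility linked (negatively) to diet NDF
    s_omd, s_ndf = cal["dig_om"], cal["ndf"]
    beta = _NDF_OMD_CORR * s_omd.sd / s_ndf.sd
    eps_sd = s_omd.sd * np.sqrt(1 - _NDF_OMD_CORR**2) * cfg.variable_sd_scale
    omd = (
        s_omd.mean
        + beta * (d["ndf_g_kg"] - s_ndf.mean)
        + rng.normal(0.0, eps_sd, n)
    )
    d["dig_om_g_kg"] = _clip_to_range(cfg, "dig_om", omd)
    ged = (
        CONSTANTS.ged_from_omd_intercept
        + CONSTANTS.ged_from_omd_slope * d["dig_om_g_kg"]
        + rng.normal(0.0, _GED_RESID_SD * cfg.variable_sd_scale, n)
    )
    d["dig_ge_g_kg"] = _clip_to_range(cfg, "dig_ge", ged)
    dmd = (d["dig_ge_g_kg"] - CONSTANTS.ged_from_dmd_intercept) / CONSTANTS.ged_from_dmd_slope
    dmd = dmd + rng.normal(0.0, _DMD_RESID_SD * cfg.variable_sd_scale, n)
    d["dig_dm_g_kg"] = _clip_to_range(cfg, "dig_dm", dmd)
    for var, col in (
        ("dig_cp", "dig_cp_g_kg"),
        ("dig_ndf", "dig_ndf_g_kg"),
        ("dig_adf", "dig_adf_g_kg"),
        ("dig_ee", "dig_ee_g_kg"),
    ):
        d[col] = _draw(cfg, var, n, rng)

    # energy chain up to (but excluding) methane
    ge_conc = (
        CONSTANTS.ge_cp * d["cp_g_kg"]
        + CONSTANTS.ge_ee * d["ee_g_kg"]
        + CONSTANTS.ge_nfc * d["nfc_g_kg"]
        + CONSTANTS.ge_ndf * d["ndf_g_kg"]
    ) / 1000.0
    d["gei_mj_d"] = d["dmi_kg_d"] * ge_conc
    d["dei_mj_d"] = d["gei_mj_d"] * d["dig_ge_g_kg"] / 1000.0
    d["fe_mj_d"] = d["gei_mj_d"] - d["dei_mj_d"]
    d["ue_mj_d"] = _UE_FRACTION * d["gei_mj_d"]

    lo, hi = cfg.animals_per_treatment
    d["n_animals"] = rng.integers(lo, hi + 1, size=n)
    df = pd.DataFrame(d)
    df["cattle_class"] = (
        cfg.database
        if cfg.database != "combined"
        else np.where(rng.random(n) < 0.5, "beef", "dairy")
    )
    return df


def sample_diet_and_animal(
    config: SyntheticConfig, study_index: int, rng: Optional[np.random.Generator] = None
) -> pd.Series:
    """Draw one draft treatment record (diet, animal, digestibility, energies).

    Deterministic given ``(config.seed, study_index)`` when no generator is
    supplied.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, study_index])
    rec = _sample_records(config, 1, rng).iloc[0].copy()
    rec["study_id"] = f"S{study_index:04d}"
    return rec


def _true_methane(
    cfg: SyntheticConfig,
    df: pd.DataFrame,
    intercept_eff: np.ndarray,
    slope_eff: np.ndarray,
    residual: np.ndarray,
) -> np.ndarray:
    """Conditional-mean methane plus study effects and noise, floored.

    When the true equation itself uses MEI, methane and MEI are mutually
    defined (MEI = DEI - CH4 - UE); the fixed point is solved by iteration.
    """
    eq = cfg.equation
    needs_mei = "MEI" in required_inputs(eq)
    rows = df.to_dict("records")
    mei = df["dei_mj_d"].to_numpy() - df["ue_mj_d"].to_numpy()  # provisional, CH4=0
    ch4 = np.zeros(len(df))
    for _ in range(60 if needs_mei else 1):
        prev = ch4.copy()
        for i, row in enumerate(rows):
            x = predictors_from_record(row)
            if needs_mei:
                x["MEI"] = mei[i]
            missing = required_inputs(eq) - set(x)
            if missing:
                raise GenerationError(
                    f"true equation {eq.id!r} requires missing field(s): {sorted(missing)}"
                )
            ch4[i] = predict(eq, x)
        ch4 = ch4 + intercept_eff + slope_eff * df["dmi_kg_d"].to_numpy() + residual
        ch4 = np.maximum(ch4, CH4_FLOOR_MJ_D)
        if needs_mei:
            mei = df["dei_mj_d"].to_numpy() - df["ue_mj_d"].to_numpy() - ch4
            if np.max(np.abs(ch4 - prev)) < 1e-12:
                break
    return ch4


def assign_true_methane(
    record: Union[pd.Series, Dict],
    config: SyntheticConfig,
    study_effects: Tuple[float, float] = (0.0, 0.0),
    residual: float = 0.0,
) -> pd.Series:
    """Complete one draft record with methane (all units) and the energy chain."""
    df = pd.DataFrame([dict(record)])
    df = _finalize(config, df, np.array([study_effects[0]]), np.array([study_effects[1]]),
                   np.array([residual]))
    return df.iloc[0]


def _finalize(
    cfg: SyntheticConfig,
    df: pd.DataFrame,
    intercept_eff: np.ndarray,
    slope_eff: np.ndarray,
    residual: np.ndarray,
) -> pd.DataFrame:
    c = CONSTANTS
    df = df.copy()
    ch4 = _true_methane(cfg, df, intercept_eff, slope_eff, residual)
    df["ch4_mj_d"] = ch4
    df["mei_mj_d"] = df["dei_mj_d"] - df["ch4_mj_d"] - df["ue_mj_d"]
    df["q_ratio"] = df["mei_mj_d"] / df["gei_mj_d"]
    df["fl_multiple"] = [
        feeding_level(m, b, q)
        for m, b, q in zip(df["mei_mj_d"], df["bw_kg"], df["q_ratio"])
    ]
    df["dig_omdm_g_kg"] = [
        omd_at_maintenance(o, dm, b)
        for o, dm, b in zip(df["dig_om_g_kg"], df["dmi_kg_d"], df["bw_kg"])
    ]
    # methane unit variants (exact harmonization conversions)
    df["ch4_g_d"] = df["ch4_mj_d"] * 1000.0 / c.kj_per_g
    df["ch4_l_d"] = df["ch4_mj_d"] * 1000.0 / c.kj_per_l
    df["ch4_g_kg_dm"] = df["ch4_g_d"] / df["dmi_kg_d"]
    df["ch4_g_kg_om"] = df["ch4_g_d"] / (df["dmi_kg_d"] * df["om_g_kg"] / 1000.0)
    df["ch4_mj_kg_dm"] = df["ch4_mj_d"] / df["dmi_kg_d"]
    df["ch4_pct_ge"] = 100.0 * df["ch4_mj_d"] / df["gei_mj_d"]
    df["ch4_pct_de"] = 100.0 * df["ch4_mj_d"] / df["dei_mj_d"]
    return df


def generate_database(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a full synthetic treatment-mean database.

    Records within a study share the study's random intercept and slope.
    Output is a flat table in the :mod:`ch4meta.schema` column layout,
    byte-identical across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    tps = config.treatments_per_study
    if isinstance(tps, int):
        n_per_study = np.full(config.n_studies, tps)
    else:
        n_per_study = rng.integers(tps[0], tps[1] + 1, size=config.n_studies)
    n_total = int(n_per_study.sum())

    study_ids = np.repeat(
        [f"S{i:04d}" for i in range(1, config.n_studies + 1)], n_per_study
    )
    df = _sample_records(config, n_total, rng)
    df.insert(0, "study_id", study_ids)

    s_int = rng.normal(0.0, config.study_intercept_sd, config.n_studies)
    s_slope = rng.normal(0.0, config.study_slope_sd, config.n_studies)
    residual = rng.normal(0.0, config.residual_sd, n_total)
    df = _finalize(
        config, df, np.repeat(s_int, n_per_study), np.repeat(s_slope, n_per_study), residual
    )
    # stable column order per the pipeline schema
    cols = [c for c in schema.ALL_COLUMNS if c in df.columns]
    return df[cols].reset_index(drop=True)
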