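"""Record harmonization: energy balance, digestibility imputation, unit conversion.

Literature treatment-mean records are heterogeneous: different studies report
methane in different units and omit different energy or digestibility fields.
This module completes every field that is *derivable* from what a record does
report, using a fixed calculus:

* gross energy (GE) concentration from diet chemistry
  (23.6 CP + 39.8 EE + 17.3 NFC + 18.9 NDF, MJ/kg DM with chemistry in g/kg);
* the energy-balance identities ``DEI = GEI - FE`` and
  ``MEI = DEI - CH4 - UE`` (all MJ/day);
* feeding level ``FL = MEI / ME_m`` with the maintenance requirement
  ``ME_m = 0.53 (BW/1.08)^0.67 / (0.35 q + 0.503)``;
* between-digestibility regressions (OM from GE, GE from OM, GE from DM);
* the maintenance-level digestibility adjustment
  ``OMDm = OMD + 1.83 (DMI/BW - DMI/BW at maintenance)`` with DMI/BW in g/kg;
* exact methane unit conversions (0.714 g/L, 39.54 kJ/L, 55.65 kJ/g,
  4.184 kJ/kcal).

Note the printed conversion constants are mutually inconsistent
(0.714 x 55.65 = 39.73 != 39.54); litre<->energy conversions therefore always
use 39.54 kJ/L directly and are never chained through grams.

Fields that cannot be derived stay missing.  Every filled cell is flagged in a
provenance sidecar (``observed`` / ``derived`` / ``imputed``); observed values
are never overwritten, which makes :func:`harmonize` idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import schema
from .errors import ConsistencyError, ConversionError, HarmonizationError, ImputationError

__all__ = [
    "CONSTANTS",
    "RegressionConstants",
    "ge_concentration",
    "ge_intake",
    "complete_energy_balance",
    "feeding_level",
    "impute_digestibility",
    "dmi_bw_at_maintenance",
    "omd_at_maintenance",
    "convert_methane",
    "harmonize",
    "CH4_UNITS",
]


@dataclass(frozen=True)
class RegressionConstants:
    """Fixed coefficients of the harmonization calculus (immutable)."""

    # GE concentration coefficients, kJ/g of each chemical fraction
    ge_cp: float = 23.6
    ge_ee: float = 39.8
    ge_nfc: float = 17.3
    ge_ndf: float = 18.9
    # digestibility imputation regressions, g/kg
    omd_from_ged_intercept: float = 40.4
    omd_from_ged_slope: float = 0.966
    ged_from_omd_intercept: float = 9.6
    ged_from_omd_slope: float = 0.84
    ged_from_dmd_intercept: float = 16.2
    ged_from_dmd_slope: float = 0.765
    # DMI/BW (g/kg) as a function of feeding level
    dmi_bw_intercept: float = 13.8
    dmi_bw_slope: float = 2.195
    # digestibility depression per g/kg DMI/BW above maintenance
    omdm_slope: float = 1.83
    # maintenance ME requirement scale, MJ per (kg metabolic weight unit)/day
    maintenance_scale: float = 0.53
    # unit conversions
    g_per_l: float = 0.714
    kj_per_l: float = 39.54
    kj_per_g: float = 55.65
    kj_per_kcal: float = 4.184
    # relative tolerance for energy-identity consistency checks
    energy_rel_tol: float = 0.005


CONSTANTS = RegressionConstants()

_COMP_FIELDS = ("cp", "ee", "nfc", "ndf")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


def ge_concentration(comp: Mapping[str, float]) -> float:
    """Gross-energy concentration of a diet, MJ/kg DM.

    Parameters
    ----------
    comp
        Mapping with keys ``cp``, ``ee``, ``nfc``, ``ndf`` in g/kg DM
        (``cp_g_kg``-style schema names are also accepted).
    """
    vals = {}
    for f in _COMP_FIELDS:
        v = comp.get(f, comp.get(f + "_g_kg"))
        if _missing(v):
            raise HarmonizationError(f"ge_concentration: missing diet component {f!r}")
        vals[f] = float(v)
    c = CONSTANTS
    return (
        c.ge_cp * vals["cp"]
        + c.ge_ee * vals["ee"]
        + c.ge_nfc * vals["nfc"]
        + c.ge_ndf * vals["ndf"]
    ) / 1000.0


def ge_intake(dmi: float, comp: Mapping[str, float]) -> float:
    """Gross-energy intake, MJ/day, from DM intake (kg/day) and diet chemistry."""
    if _missing(dmi) or dmi <= 0:
        raise HarmonizationError("ge_intake: DM intake must be positive")
    return float(dmi) * ge_concentration(comp)


def feeding_level(mei: float, bw: float, q: float) -> float:
    """Feeding level as a multiple of the maintenance ME requirement.

    ``FL = MEI / ME_m`` with ``ME_m = 0.53 (BW/1.08)^0.67 / (0.35 q + 0.503)``,
    where ``q`` is the metabolizability ME:GE.  The 0.53 MJ/(kg/d) factor acts
    as the maintenance requirement scale, so FL is dimensionless.
    """
    if _missing(mei) or mei <= 0 or _missing(bw) or bw <= 0:
        raise HarmonizationError("feeding_level: MEI and BW must be positive")
    if _missing(q) or not (0 < q < 1):
        raise HarmonizationError(f"feeding_level: q must lie in (0, 1), got {q!r}")
    me_m = CONSTANTS.maintenance_scale * (bw / 1.08) ** 0.67 / (0.35 * q + 0.503)
    return float(mei) / me_m


def dmi_bw_at_maintenance(fl: float) -> float:
    """DM intake per unit body weight (g/kg) implied by a feeding level."""
    return CONSTANTS.dmi_bw_intercept + CONSTANTS.dmi_bw_slope * float(fl)


def omd_at_maintenance(omd: float, dmi: float, bw: float) -> float:
    """Adjust OM digestibility (g/kg) to the maintenance feeding level.

    ``OMDm = OMD + 1.83 x (actual DMI/BW in g/kg - DMI/BW at FL = 1)``.
    Digestibility declines as intake rises, so records fed above maintenance
    are adjusted upward.
    """
    for name, v in (("omd", omd), ("dmi", dmi), ("bw", bw)):
        if _missing(v) or v <= 0:
            raise HarmonizationError(f"omd_at_maintenance: {name} must be positive")
    actual = 1000.0 * dmi / bw
    return omd + CONSTANTS.omdm_slope * (actual - dmi_bw_at_maintenance(1.0))


# -- digestibility imputation -------------------------------------------------

# (target, source, intercept, slope), applied in precedence order until no
# equation can fill anything new
_IMPUTATION_CHAIN = (
    ("om", "ge", CONSTANTS.omd_from_ged_intercept, CONSTANTS.omd_from_ged_slope),
    ("ge", "om", CONSTANTS.ged_from_omd_intercept, CONSTANTS.ged_from_omd_slope),
    ("ge", "dm", CONSTANTS.ged_from_dmd_intercept, CONSTANTS.ged_from_dmd_slope),
)


def impute_digestibility(dig: Mapping[str, float]) -> Tuple[Dict[str, float], Dict[str, str]]:
    """Complete the OM/GE digestibility set from whichever members are present.

    Applies, in precedence order, OM = 40.4 + 0.966 GE; GE = 9.6 + 0.84 OM;
    GE = 16.2 + 0.765 DM, cascading until a fixed point.  Observed values are
    never overwritten.

    Returns
    -------
    (completed, flags)
        ``completed`` maps ``dm``/``om``/``ge`` (g/kg) to values;
        ``flags`` marks each filled key ``imputed``.
    """
    out = {k: dig.get(k) for k in ("dm", "om", "ge")}
    if all(_missing(out[k]) for k in out):
        raise ImputationError(
            "impute_digestibility: need at least one of DM, OM, GE digestibility"
        )
    flags: Dict[str, str] = {}
    changed = True
    while changed:
        changed = False
        for target, source, a, b in _IMPUTATION_CHAIN:
            if _missing(out[target]) and not _missing(out[source]):
                out[target] = a + b * float(out[source])
                flags[target] = schema.PROVENANCE_IMPUTED
                changed = True
                break
    return out, flags


# -- methane unit conversion --------------------------------------------------

# unit -> (family, context fields needed to express the value per day)
# families: "mass" (g), "energy" (MJ), "volume" (L)
CH4_UNITS: Dict[str, Tuple[str, Tuple[str, ...]]] = {
    "g_d": ("mass", ()),
    "g_kg_dm": ("mass", ("dmi",)),
    "g_kg_om": ("mass", ("dmi", "om")),
    "l_d": ("volume", ()),
    "mj_d": ("energy", ()),
    "kcal_d": ("energy", ()),
    "mj_kg_dm": ("energy", ("dmi",)),
    "pct_ge": ("energy", ("gei",)),
    "pct_de": ("energy", ("dei",)),
}


def _require_context(unit: str, context: Mapping[str, float]) -> Dict[str, float]:
    _, needed = CH4_UNITS[unit]
    got = {}
    for f in needed:
        v = context.get(f)
        if _missing(v):
            raise ConversionError(
                f"convert_methane: unit {unit!r} needs context field {f!r}"
            )
        got[f] = float(v)
    return got


def _to_daily(value: float, unit: str, context: Mapping[str, float]) -> float:
    """Express ``value`` on a per-day basis within its own family."""
    ctx = _require_context(unit, context)
    if unit in ("g_d", "l_d", "mj_d"):
        return value
    if unit == "kcal_d":
        return value * CONSTANTS.kj_per_kcal / 1000.0  # -> MJ/d
    if unit == "g_kg_dm":
        return value * ctx["dmi"]
    if unit == "g_kg_om":
        return value * ctx["dmi"] * ctx["om"] / 1000.0
    if unit == "mj_kg_dm":
        return value * ctx["dmi"]
    if unit == "pct_ge":
        return value / 100.0 * ctx["gei"]
    if unit == "pct_de":
        return value / 100.0 * ctx["dei"]
    raise ConversionError(f"convert_methane: unknown unit {unit!r}")


def _from_daily(value: float, unit: str, context: Mapping[str, float]) -> float:
    ctx = _require_context(unit, context)
    if unit in ("g_d", "l_d", "mj_d"):
        return value
    if unit == "kcal_d":
        return value * 1000.0 / CONSTANTS.kj_per_kcal
    if unit == "g_kg_dm":
        return value / ctx["dmi"]
    if unit == "g_kg_om":
        return value / (ctx["dmi"] * ctx["om"] / 1000.0)
    if unit == "mj_kg_dm":
        return value / ctx["dmi"]
    if unit == "pct_ge":
        return value * 100.0 / ctx["gei"]
    if unit == "pct_de":
        return value * 100.0 / ctx["dei"]
    raise ConversionError(f"convert_methane: unknown unit {unit!r}")


def _cross_family(value: float, src: str, dst: str) -> float:
    """Convert a per-day quantity between mass (g), energy (MJ), volume (L)."""
    if src == dst:
        return value
    c = CONSTANTS
    factor = {
        ("mass", "energy"): c.kj_per_g / 1000.0,
        ("energy", "mass"): 1000.0 / c.kj_per_g,
        ("volume", "mass"): c.g_per_l,
        ("mass", "volume"): 1.0 / c.g_per_l,
        # litre<->energy uses 39.54 kJ/L directly, never chained through grams
        ("volume", "energy"): c.kj_per_l / 1000.0,
        ("energy", "volume"): 1000.0 / c.kj_per_l,
    }[(src, dst)]
    return value * factor


def convert_methane(
    value: float, from_unit: str, to_unit: str, **context: float
) -> float:
    """Convert a methane quantity between any two supported units.

    Intensity and percentage units require context keywords (``dmi`` kg/day,
    ``om`` g/kg DM, ``gei``/``dei`` MJ/day); a missing one raises
    :class:`~ch4meta.errors.ConversionError` naming the field.  Every
    to/from round trip is exact to machine precision.
    """
    for u in (from_unit, to_unit):
        if u not in CH4_UNITS:
            raise ConversionError(f"convert_methane: unknown unit {u!r}")
    daily = _to_daily(float(value), from_unit, context)
    daily = _cross_family(daily, CH4_UNITS[from_unit][0], CH4_UNITS[to_unit][0])
    return _from_daily(daily, to_unit, context)


# -- record-level completion --------------------------------------------------


def _rel_err(lhs: float, rhs: float) -> float:
    scale = max(abs(lhs), abs(rhs), 1e-12)
    return abs(lhs - rhs) / scale


def _set(rec: dict, flags: dict, field: str, value: float, how: str) -> bool:
    """Fill a missing field; never overwrite.  Returns True if it changed."""
    if _missing(rec.get(field)):
        rec[field] = value
        flags[field] = how
        return True
    return False


def complete_energy_balance(rec: dict, flags: Optional[dict] = None) -> dict:
    """Fill every derivable member of the energy identity chain in place.

    ``DEI = GEI - FE`` and ``MEI = DEI - CH4(MJ/d) - UE``; ``q = MEI/GEI``
    when both ends are known.  Observed members that violate an identity by
    more than 0.5% relative raise :class:`ConsistencyError`.
    """
    if flags is None:
        flags = {}
    g = lambda f: rec.get(f)
    changed = True
    while changed:
        changed = False
        gei, dei, mei = g("gei_mj_d"), g("dei_mj_d"), g("mei_mj_d")
        fe, ue, ch4 = g("fe_mj_d"), g("ue_mj_d"), g("ch4_mj_d")
        d = schema.PROVENANCE_DERIVED
        # DEI = GEI - FE
        if not _missing(gei) and not _missing(fe):
            if not _missing(dei):
                if _rel_err(dei, gei - fe) > CONSTANTS.energy_rel_tol:
                    raise ConsistencyError(
                        f"DEI={dei} inconsistent with GEI-FE={gei - fe}"
                    )
            else:
                changed |= _set(rec, flags, "dei_mj_d", gei - fe, d)
        elif not _missing(gei) and not _missing(dei):
            changed |= _set(rec, flags, "fe_mj_d", gei - dei, d)
        elif not _missing(dei) and not _missing(fe):
            changed |= _set(rec, flags, "gei_mj_d", dei + fe, d)
        # MEI = DEI - CH4 - UE
        dei = g("dei_mj_d")
        present = [x for x in (dei, mei, ch4, ue) if not _missing(x)]
        if len(present) == 4:
            if _rel_err(mei, dei - ch4 - ue) > CONSTANTS.energy_rel_tol:
                raise ConsistencyError(
                    f"MEI={mei} inconsistent with DEI-CH4-UE={dei - ch4 - ue}"
                )
        elif len(present) == 3:
            if _missing(mei):
                changed |= _set(rec, flags, "mei_mj_d", dei - ch4 - ue, d)
            elif _missing(ue):
                changed |= _set(rec, flags, "ue_mj_d", dei - ch4 - mei, d)
            elif _missing(ch4):
                changed |= _set(rec, flags, "ch4_mj_d", dei - ue - mei, d)
            else:
                changed |= _set(rec, flags, "dei_mj_d", mei + ch4 + ue, d)
        # q = MEI / GEI
        gei, mei = g("gei_mj_d"), g("mei_mj_d")
        if not _missing(gei) and not _missing(mei) and gei > 0:
            changed |= _set(rec, flags, "q_ratio", mei / gei, d)
    return rec


def _closure_check(rec: dict, flags: dict) -> None:
    comp = {f: rec.get(f + "_g_kg") for f in ("om", "cp", "ee", "ndf", "nfc")}
    if all(not _missing(v) for v in comp.values()):
        total = comp["cp"] + comp["ee"] + comp["ndf"] + comp["nfc"]
        if total > comp["om"] * (1 + CONSTANTS.energy_rel_tol) + 5.0:
            raise ConsistencyError(
                f"composition closure violated: CP+EE+NDF+NFC={total:.1f} "
                f"> OM={comp['om']:.1f} g/kg"
            )
    elif _missing(comp["nfc"]) and all(
        not _missing(comp[f]) for f in ("om", "cp", "ee", "ndf")
    ):
        nfc = comp["om"] - comp["cp"] - comp["ee"] - comp["ndf"]
        if nfc > 0:
            _set(rec, flags, "nfc_g_kg", nfc, schema.PROVENANCE_DERIVED)


def _complete_ch4_units(rec: dict, flags: dict) -> None:
    ctx = {
        "dmi": rec.get("dmi_kg_d"),
        "om": rec.get("om_g_kg"),
        "gei": rec.get("gei_mj_d"),
        "dei": rec.get("dei_mj_d"),
    }
    # canonicalize: prefer an observed g/day or MJ/day anchor, else any unit
    anchor = None
    for unit in ("mj_d", "g_d", "l_d", "g_kg_dm", "mj_kg_dm", "g_kg_om", "pct_ge", "pct_de"):
        col = "ch4_" + unit
        if not _missing(rec.get(col)):
            anchor = unit
            break
    if anchor is None:
        return
    for unit in CH4_UNITS:
        if unit == "kcal_d":
            continue
        col = "ch4_" + unit
        if _missing(rec.get(col)):
            try:
                v = convert_methane(rec["ch4_" + anchor], anchor, unit, **ctx)
            except ConversionError:
                continue
            _set(rec, flags, col, v, schema.PROVENANCE_DERIVED)


def _harmonize_record(rec: dict) -> Tuple[dict, dict]:
    flags: Dict[str, str] = {}
    _closure_check(rec, flags)
    # GE intake from chemistry
    if _missing(rec.get("gei_mj_d")):
        try:
            gei = ge_intake(rec.get("dmi_kg_d"), {f: rec.get(f + "_g_kg") for f in _COMP_FIELDS})
            _set(rec, flags, "gei_mj_d", gei, schema.PROVENANCE_DERIVED)
        except HarmonizationError:
            pass
    # canonical CH4 MJ/day before the balance (g<->MJ needs no context)
    _complete_ch4_units(rec, flags)
    complete_energy_balance(rec, flags)
    # digestibility cascade
    dig = {k: rec.get(f"dig_{k}_g_kg") for k in ("dm", "om", "ge")}
    if any(not _missing(v) for v in dig.values()):
        completed, dig_flags = impute_digestibility(dig)
        for k, how in dig_flags.items():
            _set(rec, flags, f"dig_{k}_g_kg", completed[k], how)
    # feeding level
    if _missing(rec.get("fl_multiple")):
        try:
            fl = feeding_level(rec.get("mei_mj_d"), rec.get("bw_kg"), rec.get("q_ratio"))
            _set(rec, flags, "fl_multiple", fl, schema.PROVENANCE_DERIVED)
        except HarmonizationError:
            pass
    # OM digestibility at maintenance
    if _missing(rec.get("dig_omdm_g_kg")):
        try:
            omdm = omd_at_maintenance(
                rec.get("dig_om_g_kg"), rec.get("dmi_kg_d"), rec.get("bw_kg")
            )
            _set(rec, flags, "dig_omdm_g_kg", omdm, schema.PROVENANCE_DERIVED)
        except HarmonizationError:
            pass
    # remaining CH4 units (context may have been completed above)
    _complete_ch4_units(rec, flags)
    return rec, flags


def harmonize(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a treatment-record table.

    Parameters
    ----------
    records
        Flat table in the :mod:`ch4meta.schema` layout; missing columns are
        treated as all-missing fields.

    Returns
    -------
    (harmonized, provenance)
        ``harmonized`` is a copy with every derivable field filled;
        ``provenance`` is a same-indexed table of ``observed`` / ``derived`` /
        ``imputed`` flags (empty string where the field is still missing).

    The operation is idempotent and never overwrites observed values.
    """
    df = records.copy()
    for col in schema.ALL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    prov = pd.DataFrame("", index=df.index, columns=schema.ALL_COLUMNS)
    for col in schema.ALL_COLUMNS:
        prov.loc[df[col].notna(), col] = schema.PROVENANCE_OBSERVED
    for idx in df.index:
        rec = df.loc[idx].to_dict()
        rec, flags = _harmonize_record(rec)
        for field, how in flags.items():
            df.at[idx, field] = rec[field]
            prov.at[idx, field] = how
        for field in rec:
            if field in df.columns and not _missing(rec[field]):
                df.at[idx, field] = rec[field]
    return df, prov
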