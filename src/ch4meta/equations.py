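"""Registry of extant and developed methane prediction equations.

Each equation predicts daily enteric methane energy output (MJ/day) from one
or more of: DM intake (``DMI``, kg/day), metabolizable or gross energy intake
(``MEI``/``GEI``, MJ/day), NDF/ADF intake (``NDFI``/``ADFI``, kg/day), body
weight (``BW``, kg) and roughage proportion (``roughage``, g/kg DM).

Functional forms
----------------
linear / quadratic
    ``intercept + sum(coef * x)`` (quadratic terms written ``DMI^2``).
monomolecular
    ``a - (a + b) exp(-c x)`` — diminishing returns towards asymptote ``a``.
mitscherlich
    ``a (1 - exp(-c x))``, the monomolecular with ``b = 0``.
gompertz
    ``b exp{[1 - exp(-c x)] ln[(a + 2b)/b]} - 2b`` — sigmoidal, value ``-b``
    at ``x = 0`` and asymptote ``a``.
exponential
    ``|b| exp(c x)``.  The published coefficient tables print a negative
    ``b`` for every exponential row, which would force negative methane; the
    registry stores the printed value, flags the anomaly
    (:attr:`EquationSpec.sign_anomaly`), and evaluates ``|b|`` unless the
    caller asks for the literal printed sign.
power
    ``b x^c``.

Predictions are not clipped; callers decide how to treat extrapolations
outside the calibration range.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .errors import NumericError, PredictionError

__all__ = [
    "EquationSpec",
    "registry",
    "get_equation",
    "predict",
    "required_inputs",
    "predictors_from_record",
    "dump_registry",
    "load_registry",
    "REGISTRY_VERSION",
]

REGISTRY_VERSION = "1"

LINEAR_FORMS = ("linear", "quadratic")
NONLINEAR_FORMS = ("monomolecular", "mitscherlich", "gompertz", "exponential", "power")
PREDICTOR_NAMES = ("DMI", "MEI", "GEI", "NDFI", "ADFI", "BW", "roughage")


@dataclass(frozen=True)
class EquationSpec:
    """One prediction equation, with its printed coefficients and fit statistics."""

    id: str
    source: str  # "developed" | "extant"
    database: str  # "beef" | "dairy" | "combined" | "external"
    form: str
    intercept: Optional[float] = None
    terms: Dict[str, float] = field(default_factory=dict)
    params: Dict[str, float] = field(default_factory=dict)  # a, b, c
    predictor: Optional[str] = None  # nonlinear forms: the single x variable
    reported_rmse: Optional[float] = None
    reported_r2: Optional[float] = None
    reference: str = ""
    aliases: Tuple[str, ...] = ()

    @property
    def sign_anomaly(self) -> bool:
        """True for exponential rows whose printed scale coefficient is negative."""
        return self.form == "exponential" and self.params.get("b", 0.0) < 0

    @property
    def n_parameters(self) -> int:
        if self.form in LINEAR_FORMS:
            return 1 + len(self.terms)
        return len(self.params)


def _lin(eq_id, db, intercept, terms, rmse, r2, source="developed", ref="", aliases=()):
    form = "quadratic" if any("^2" in t for t in terms) else "linear"
    return EquationSpec(
        id=eq_id, source=source, database=db, form=form, intercept=intercept,
        terms=dict(terms), reported_rmse=rmse, reported_r2=r2, reference=ref,
        aliases=tuple(aliases),
    )


def _nl(eq_id, db, form, params, predictor, rmse, r2, source="developed", ref="", aliases=()):
    return EquationSpec(
        id=eq_id, source=source, database=db, form=form, params=dict(params),
        predictor=predictor, reported_rmse=rmse, reported_r2=r2, reference=ref,
        aliases=tuple(aliases),
    )


def _build_registry() -> List[EquationSpec]:
    ext = "extant"
    specs = [
        # ---- extant equations ------------------------------------------------
        _lin("mills_linear", "external", 5.93, {"DMI": 0.92}, None, None,
             source=ext, ref="Mills et al. (2003), eq. 1"),
        _nl("mills_monomolecular", "external", "monomolecular",
            {"a": 56.27, "b": 0.0, "c": 0.028}, "DMI", None, None,
            source=ext, ref="Mills et al. (2003), eq. 3"),
        _lin("ipcc2006", "external", 0.0, {"GEI": 0.065}, None, None,
             source=ext, ref="IPCC (2006) Tier 2, Ym = 6.5% of GEI"),
        _lin("ellis2007", "external", 3.272, {"DMI": 0.736}, None, None,
             source=ext, ref="Ellis et al. (2007)"),
        _lin("yan2009", "external", 0.582, {"DMI": 1.40}, None, None,
             source=ext, ref="Yan et al. (2009)"),
        _lin("ramin_huhtanen2013", "external", 0.797,
             {"DMI": 1.427, "DMI^2": -0.020}, None, None,
             source=ext, ref="Ramin & Huhtanen (2013)"),
        _nl("patra", "external", "monomolecular",
            {"a": 35.21, "b": 0.25, "c": 0.0354}, "DMI", None, None,
            source=ext, ref="Patra (2015/2017)", aliases=("patra2015", "patra2017")),
        # ---- developed: beef -------------------------------------------------
        _lin("eq1b", "beef", 0.9188, {"DMI": 0.8196}, 2.13, 0.83),
        _lin("eq2b", "beef", 2.4904, {"MEI": 0.0657}, 2.24, 0.76),
        _lin("eq3b", "beef", 2.5492, {"NDFI": 1.8401}, 1.96, 0.73),
        _lin("eq4b", "beef", 0.9462, {"DMI": 0.4368, "NDFI": 1.1567}, 1.57, 0.83),
        _lin("eq5b", "beef", 0.019, {"DMI": 0.8058, "ADFI": 0.649}, 2.11, 0.70),
        _lin("eq6b", "beef", -0.8848, {"MEI": 0.0669, "ADFI": 2.1255}, 1.98, 0.73),
        _lin("eq7b", "beef", 1.6836, {"MEI": 0.0342, "NDFI": 1.2202}, 1.57, 0.83),
        _lin("eq8b", "beef", 1.6063,
             {"DMI": 0.4256, "NDFI": 1.2213, "ADFI": -0.475}, 1.55, 0.83),
        _nl("beef_exp1", "beef", "exponential", {"b": -1.264, "c": 0.3094},
            "DMI", 1.21, 0.73),
        _nl("beef_exp2", "beef", "exponential", {"b": -3.002, "c": 0.0172},
            "MEI", 2.33, 0.70),
        _nl("beef_power", "beef", "power", {"b": 1.039, "c": 0.9474},
            "DMI", 2.28, 0.67),
        # ---- developed: dairy ------------------------------------------------
        _lin("eq1d", "dairy", -6.9931, {"BW": 0.0448}, 4.58, 0.55),
        _lin("eq2d", "dairy", 0.7567, {"DMI": 1.0917}, 2.73, 0.84),
        _lin("eq3d", "dairy", 5.5616, {"MEI": 0.0789}, 4.43, 0.79),
        _lin("eq4d", "dairy", 1.6799, {"NDFI": 2.7698}, 3.45, 0.74),
        _lin("eq5d", "dairy", 0.3989, {"DMI": 0.8685, "NDFI": 0.6675}, 2.66, 0.85),
        _lin("eq6d", "dairy", 0.8642, {"DMI": 1.1024, "ADFI": -0.1051}, 2.73, 0.84),
        _lin("eq7d", "dairy", 2.9962, {"MEI": 0.0646, "ADFI": 1.8279}, 4.24, 0.62),
        _lin("eq8d", "dairy", 1.7105, {"MEI": 0.0084, "NDFI": 2.5447}, 3.43, 0.75),
        _lin("eq9d", "dairy", 0.5246,
             {"DMI": 0.8805, "NDFI": 0.6691, "ADFI": -0.1237}, 2.65, 0.88),
        _lin("eq10d", "dairy", -3.0617,
             {"MEI": 0.0147, "NDFI": 2.4028, "roughage": 0.007}, 3.18, 0.78),
        _nl("dairy_gompertz", "dairy", "gompertz",
            {"a": 39.31, "b": 1.396, "c": 0.1002}, "DMI", 3.34, 0.80),
        _nl("dairy_exp1", "dairy", "exponential", {"b": -4.076, "c": 0.0765},
            "DMI", 1.27, 0.86),
        _nl("dairy_exp2", "dairy", "exponential", {"b": -4.84, "c": 0.0055},
            "MEI", 1.50, 0.69),
        _nl("dairy_power", "dairy", "power", {"b": 0.887, "c": 1.085},
            "DMI", 2.62, 0.88),
        # ---- developed: combined ---------------------------------------------
        _lin("eq1c", "combined", 0.0529, {"DMI": 1.0469}, 3.04, 0.83),
        _lin("eq2c", "combined", 3.88, {"MEI": 0.071}, 1.36, 0.81),
        _lin("eq3c", "combined", 0.9454, {"NDFI": 2.6638}, 1.43, 0.78),
        _lin("eq4c", "combined", -0.3821, {"DMI": 0.5932, "NDFI": 1.3849}, 0.54, 0.85),
        _lin("eq5c", "combined", -0.6042, {"DMI": 1.0088, "ADFI": 0.5422}, 1.45, 0.79),
        _lin("eq6c", "combined", -0.2924, {"MEI": 0.0702, "ADFI": 2.3215}, 1.52, 0.61),
        _lin("eq7c", "combined", 0.7085, {"MEI": 0.0167, "NDFI": 2.3096}, 1.56, 0.79),
        _lin("eq8c", "combined", -0.3496,
             {"DMI": 0.5941, "NDFI": 1.388, "ADFI": -0.0276}, 1.47, 0.85),
        _nl("comb_gompertz", "combined", "gompertz",
            {"a": 36.23, "b": 0.956, "c": 0.1058}, "DMI", 3.34, 0.74),
        _nl("comb_exp", "combined", "exponential", {"b": -3.667, "c": 0.0855},
            "DMI", 1.62, 0.81),
        _nl("comb_power1", "combined", "power", {"b": 0.782, "c": 1.1087},
            "DMI", 2.63, 0.84),
        _nl("comb_power2", "combined", "power", {"b": 0.205, "c": 0.8528},
            "MEI", 3.58, 0.70),
    ]
    return specs


_REGISTRY: List[EquationSpec] = _build_registry()
_BY_ID: Dict[str, EquationSpec] = {}
for _s in _REGISTRY:
    _BY_ID[_s.id] = _s
    for _a in _s.aliases:
        _BY_ID[_a] = _s


def registry(
    source: Optional[str] = None, database: Optional[str] = None
) -> List[EquationSpec]:
    """Return all registered equations, optionally filtered by source/database."""
    specs = list(_REGISTRY)
    if source is not None:
        specs = [s for s in specs if s.source == source]
    if database is not None:
        specs = [s for s in specs if s.database == database]
    return specs


def get_equation(eq_id: str) -> EquationSpec:
    try:
        return _BY_ID[eq_id]
    except KeyError:
        raise PredictionError(f"unknown equation id {eq_id!r}") from None


def required_inputs(eq: EquationSpec) -> Set[str]:
    """Minimal predictor set for ``eq``; :func:`predict` succeeds iff all present."""
    if eq.form in LINEAR_FORMS:
        return {t.split("^")[0] for t in eq.terms}
    return {eq.predictor}


def _get_predictor(x: Mapping[str, float], name: str, eq_id: str) -> float:
    v = x.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        raise PredictionError(f"equation {eq_id!r}: missing predictor {name!r}")
    return float(v)


def predict(eq: EquationSpec, x: Mapping[str, float], literal_sign: bool = False) -> float:
    """Evaluate ``eq`` at predictor vector ``x`` -> methane, MJ/day.

    ``x`` maps predictor names (``DMI``, ``MEI``, ``GEI``, ``NDFI``, ``ADFI``,
    ``BW``, ``roughage``) to values.  ``literal_sign=True`` restores the
    printed (negative) scale coefficient of the exponential rows for audit.
    """
    try:
        y = _evaluate(eq, x, literal_sign)
    except OverflowError:
        raise NumericError(
            f"equation {eq.id!r} overflowed at {dict(x)!r}"
        ) from None
    if not math.isfinite(y):
        raise NumericError(f"equation {eq.id!r} produced non-finite prediction {y!r}")
    return y


def _evaluate(eq: EquationSpec, x: Mapping[str, float], literal_sign: bool) -> float:
    if eq.form in LINEAR_FORMS:
        y = float(eq.intercept or 0.0)
        for term, coef in eq.terms.items():
            base, _, power = term.partition("^")
            v = _get_predictor(x, base, eq.id)
            y += coef * (v ** int(power) if power else v)
    else:
        v = _get_predictor(x, eq.predictor, eq.id)
        a, b, c = (eq.params.get(k) for k in ("a", "b", "c"))
        if eq.form == "monomolecular":
            y = a - (a + b) * math.exp(-c * v)
        elif eq.form == "mitscherlich":
            y = a * (1.0 - math.exp(-c * v))
        elif eq.form == "gompertz":
            y = b * math.exp((1.0 - math.exp(-c * v)) * math.log((a + 2 * b) / b)) - 2 * b
        elif eq.form == "exponential":
            scale = b if literal_sign else abs(b)
            y = scale * math.exp(c * v)
        elif eq.form == "power":
            y = b * v ** c
        else:
            raise PredictionError(f"unknown functional form {eq.form!r}")
    return y


def predictors_from_record(rec: Mapping[str, float]) -> Dict[str, float]:
    """Build a predictor vector from a schema-layout record (row dict/Series).

    NDF and ADF intakes are computed as ``DMI x concentration / 1000`` when
    not directly supplied.
    """
    def get(col):
        v = rec.get(col) if hasattr(rec, "get") else rec[col]
        return None if v is None or pd.isna(v) else float(v)

    dmi = get("dmi_kg_d")
    x: Dict[str, Optional[float]] = {
        "DMI": dmi,
        "MEI": get("mei_mj_d"),
        "GEI": get("gei_mj_d"),
        "BW": get("bw_kg"),
        "roughage": get("roughage_g_kg"),
        "NDFI": get("ndfi_kg_d") if "ndfi_kg_d" in rec else None,
        "ADFI": get("adfi_kg_d") if "adfi_kg_d" in rec else None,
    }
    if x["NDFI"] is None and dmi is not None and get("ndf_g_kg") is not None:
        x["NDFI"] = dmi * get("ndf_g_kg") / 1000.0
    if x["ADFI"] is None and dmi is not None and get("adf_g_kg") is not None:
        x["ADFI"] = dmi * get("adf_g_kg") / 1000.0
    return {k: v for k, v in x.items() if v is not None}


# -- plain-text serialization -------------------------------------------------

_COLUMNS = [
    "id", "source", "database", "form", "predictor", "intercept", "terms",
    "params", "reported_rmse", "reported_r2", "reference", "aliases",
]


def _fmt_float(v: Optional[float]) -> str:
    return "" if v is None else repr(v)


def _fmt_map(m: Mapping[str, float]) -> str:
    return ";".join(f"{k}={v!r}" for k, v in m.items())


def _parse_map(s: str) -> Dict[str, float]:
    if not s:
        return {}
    return {k: float(v) for k, v in (item.split("=") for item in s.split(";"))}


def dump_registry(specs: Optional[Sequence[EquationSpec]] = None) -> str:
    """Serialize the registry as a versioned tab-separated table (bit-exact)."""
    specs = list(_REGISTRY) if specs is None else list(specs)
    out = io.StringIO()
    out.write(f"# ch4meta equation registry v{REGISTRY_VERSION}\n")
    out.write("\t".join(_COLUMNS) + "\n")
    for s in specs:
        row = [
            s.id, s.source, s.database, s.form, s.predictor or "",
            _fmt_float(s.intercept), _fmt_map(s.terms), _fmt_map(s.params),
            _fmt_float(s.reported_rmse), _fmt_float(s.reported_r2),
            s.reference, ";".join(s.aliases),
        ]
        out.write("\t".join(row) + "\n")
    return out.getvalue()


def load_registry(text: str) -> List[EquationSpec]:
    """Parse a table produced by :func:`dump_registry`."""
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    specs = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        specs.append(
            EquationSpec(
                id=row["id"],
                source=row["source"],
                database=row["database"],
                form=row["form"],
                predictor=row["predictor"] or None,
                intercept=float(row["intercept"]) if row["intercept"] else None,
                terms=_parse_map(row["terms"]),
                params=_parse_map(row["params"]),
                reported_rmse=float(row["reported_rmse"]) if row["reported_rmse"] else None,
                reported_r2=float(row["reported_r2"]) if row["reported_r2"] else None,
                reference=row["reference"],
                aliases=tuple(a for a in row["aliases"].split(";") if a),
            )
        )
    return specs
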