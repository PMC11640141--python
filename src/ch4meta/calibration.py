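"""Summary-statistic calibration tables for the beef, dairy and combined databases.

The meta-analytic database behind the published prediction equations is not
publicly deposited; what is available are per-database summary statistics
(mean, minimum, maximum, SD) for every animal, diet, energy, digestibility
and methane variable.  This module packages those summaries as
:class:`CalibrationTable` objects.  The synthetic-data generator
(:mod:`ch4meta.simulate`) uses them as distributional targets.

Variables and units
-------------------
``bw``            body weight, kg
``dmi``           dry matter intake, kg/day
``gei``/``dei``/``mei``  gross / digestible / metabolizable energy intake, MJ/day
``fl``            feeding level, multiple of maintenance ME requirement
``om`` .. ``roughage``   diet chemistry, g/kg DM
``dig_*``         apparent digestibilities, g/kg (``dig_omdm`` = OM digestibility
                  adjusted to the maintenance feeding level)
``ch4_*``         methane output in each reported unit
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from .errors import ConfigurationError

DATABASES = ("beef", "dairy", "combined")


@dataclass(frozen=True)
class VariableSummary:
    """Mean / min / max / SD target for a single variable."""

    mean: float
    min: float
    max: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ConfigurationError(
                f"summary violates min <= mean <= max: {self}"
            )
        if self.sd <= 0:
            raise ConfigurationError(f"summary requires sd > 0: {self}")


@dataclass(frozen=True)
class CalibrationTable:
    """Per-variable summary targets for one database (beef, dairy or combined)."""

    database: str
    variables: Dict[str, VariableSummary] = field(default_factory=dict)

    def __getitem__(self, name: str) -> VariableSummary:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def items(self) -> Iterator[Tuple[str, VariableSummary]]:
        return iter(self.variables.items())


def _table(database: str, rows: Dict[str, Tuple[float, float, float, float]]) -> CalibrationTable:
    return CalibrationTable(
        database=database,
        variables={k: VariableSummary(*v) for k, v in rows.items()},
    )


# (mean, min, max, sd) per variable, transcribed from the published database
# summaries.  These are the *targets* the generator matches; they are not
# re-derived anywhere.
_BEEF = {
    "bw": (404.58, 163, 616, 120.2),
    "dmi": (7.45, 2.29, 23.7, 4.07),
    "gei": (134.29, 41.5, 426, 75.77),
    "dei": (93.91, 30.4, 328, 55.36),
    "mei": (70.75, 22.2, 285, 49.73),
    "fl": (2.78, 0.47, 10.47, 1.94),
    "om": (922, 831, 963, 23.02),
    "cp": (153.78, 42, 276, 52.07),
    "ee": (55.18, 8, 318, 43.99),
    "ndf": (352.65, 93, 776, 169.13),
    "adf": (273.43, 73, 491, 106.36),
    "nfc": (361, 93.4, 644, 140.04),
    "roughage": (682.51, 100, 1000, 250),
    "dig_dm": (673.32, 493, 837, 81.57),
    "dig_om": (698.16, 503, 837, 76.52),
    "dig_ge": (692.41, 496, 866, 74.86),
    "dig_omdm": (713.52, 500, 861, 78.4),
    "dig_cp": (650.06, 401, 841, 95.41),
    "dig_ndf": (539.31, 236, 740, 116.66),
    "dig_adf": (433.92, 244, 658, 101.51),
    "dig_ee": (758.24, 82, 942, 219.14),
    "ch4_g_d": (127.83, 50.3, 418, 70.79),
    "ch4_mj_d": (7.07, 2.64, 23.3, 3.97),
    "ch4_g_kg_dm": (18.6, 6.61, 34.1, 5.87),
    "ch4_g_kg_om": (19.99, 6.8, 39.9, 6.56),
    "ch4_mj_kg_dm": (1.03, 0.37, 1.9, 0.32),
    "ch4_pct_ge": (5.81, 2.2, 11.5, 1.99),
    "ch4_pct_de": (8.36, 2.89, 16.9, 3.12),
    "ch4_g_kg_ddm": (27.68, 9.58, 54.89, 9.36),
    "ch4_g_kg_dom": (28.23, 9.58, 59, 10.34),
}

_DAIRY = {
    "bw": (515.9, 263, 734, 118.37),
    "dmi": (13.92, 4.8, 26.2, 5.79),
    "gei": (259.31, 87.4, 491.6, 114.59),
    "dei": (176.55, 63.8, 341.3, 84.00),
    "mei": (133.91, 25.1, 262.9, 73.93),
    "fl": (4.90, 0.49, 12, 3.34),
    "om": (918.66, 815, 965, 40.87),
    "cp": (165.29, 96.3, 210, 24.76),
    "ee": (36.42, 21, 62.6, 11.15),
    "ndf": (386.43, 271, 599, 70.16),
    "adf": (219.85, 131, 347, 53.60),
    "nfc": (328.95, 150, 464, 77.22),
    "roughage": (624.68, 50, 1000, 242.59),
    "dig_dm": (713.26, 543, 819, 58.78),
    "dig_om": (721.91, 595, 826, 62.37),
    "dig_ge": (708.38, 566, 804, 62.19),
    "dig_omdm": (772.18, 603, 859, 56.41),
    "dig_cp": (686.59, 407, 839, 82.99),
    "dig_ndf": (581.02, 403, 718, 96.44),
    "dig_adf": (533.12, 293, 707, 105.20),
    "dig_ee": (760.57, 553, 897, 102.39),
    "ch4_g_d": (286.00, 95.9, 540, 125.54),
    "ch4_mj_d": (15.79, 5.6, 30.1, 7.01),
    "ch4_g_kg_dm": (20.25, 12.2, 28.9, 4.07),
    "ch4_g_kg_om": (22.80, 12.5, 42.3, 5.11),
    "ch4_mj_kg_dm": (1.12, 0.68, 1.58, 0.22),
    "ch4_pct_ge": (6.42, 2.86, 10.86, 1.35),
    "ch4_pct_de": (9.06, 3.49, 17.9, 2.62),
    "ch4_g_kg_ddm": (29.31, 15.04, 57.06, 7.23),
    "ch4_g_kg_dom": (29.48, 14.62, 55.41, 7.59),
}

_COMBINED = {
    "bw": (453.15, 163, 734, 131.55),
    "dmi": (10.28, 2.29, 26.2, 5.86),
    "gei": (188.83, 41.5, 491.6, 113.17),
    "dei": (128.55, 30.4, 341.3, 80.00),
    "mei": (93.72, 22.2, 285, 66.97),
    "fl": (3.56, 0.47, 12, 2.74),
    "om": (920.90, 815, 965, 32.11),
    "cp": (158.80, 42, 276, 42.76),
    "ee": (47.00, 8, 318, 35.10),
    "ndf": (367.39, 93, 776, 136.22),
    "adf": (250.47, 73, 491, 91.65),
    "nfc": (347.02, 93.4, 644, 117.94),
    "roughage": (657.28, 50, 1000, 248.46),
    "dig_dm": (690.74, 493, 837, 75.17),
    "dig_om": (708.81, 503, 837, 71.51),
    "dig_ge": (698.32, 496, 866, 70.86),
    "dig_omdm": (734.34, 500, 861, 76.70),
    "dig_cp": (670.05, 401, 841, 90.67),
    "dig_ndf": (556.35, 236, 740, 110.77),
    "dig_adf": (479.39, 244, 707, 114.45),
    "dig_ee": (759.38, 82, 942, 172.48),
    "ch4_g_d": (196.83, 50.3, 540, 125.91),
    "ch4_mj_d": (10.87, 2.64, 30.1, 7.00),
    "ch4_g_kg_dm": (19.32, 6.61, 34.1, 5.23),
    "ch4_g_kg_om": (21.22, 6.8, 42.3, 6.13),
    "ch4_mj_kg_dm": (1.07, 0.37, 1.9, 0.29),
    "ch4_pct_ge": (6.08, 2.2, 11.5, 1.77),
    "ch4_pct_de": (8.65, 2.89, 17.9, 2.94),
    "ch4_g_kg_ddm": (28.39, 9.58, 57.06, 8.54),
    "ch4_g_kg_dom": (28.80, 9.58, 59, 9.23),
}

_TABLES = {
    "beef": _table("beef", _BEEF),
    "dairy": _table("dairy", _DAIRY),
    "combined": _table("combined", _COMBINED),
}


def calibration_table(database: str) -> CalibrationTable:
    """Return the packaged :class:`CalibrationTable` for ``database``.

    Raises
    ------
    ConfigurationError
        If ``database`` is not one of ``beef``, ``dairy``, ``combined``.
    """
    try:
        return _TABLES[database]
    except KeyError:
        raise ConfigurationError(
            f"unknown database {database!r}; expected one of {DATABASES}"
        ) from None
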