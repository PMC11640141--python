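"""Canonical flat-table schema for treatment-mean records.

One row = one treatment mean (the experimental unit of the meta-analysis:
the average of one dietary treatment within one source study).  Column names
encode units.  Missing values are empty cells / NaN.
"""

from __future__ import annotations

# identity / weighting columns
ID_COLUMNS = ["study_id", "n_animals", "cattle_class"]

# animal & intake
ANIMAL_COLUMNS = ["bw_kg", "dmi_kg_d"]

# diet chemistry, g/kg DM
COMPOSITION_COLUMNS = [
    "om_g_kg",
    "cp_g_kg",
    "ee_g_kg",
    "ndf_g_kg",
    "adf_g_kg",
    "nfc_g_kg",
    "roughage_g_kg",
]

# energy balance, MJ/day (q is the dimensionless ME:GE ratio; fl the
# feeding level as a multiple of maintenance)
ENERGY_COLUMNS = [
    "gei_mj_d",
    "dei_mj_d",
    "mei_mj_d",
    "fe_mj_d",
    "ue_mj_d",
    "q_ratio",
    "fl_multiple",
]

# apparent digestibilities, g/kg
DIGESTIBILITY_COLUMNS = [
    "dig_dm_g_kg",
    "dig_om_g_kg",
    "dig_ge_g_kg",
    "dig_omdm_g_kg",
    "dig_cp_g_kg",
    "dig_ndf_g_kg",
    "dig_adf_g_kg",
    "dig_ee_g_kg",
]

# methane output, one column per reported unit
CH4_COLUMNS = [
    "ch4_g_d",
    "ch4_mj_d",
    "ch4_l_d",
    "ch4_g_kg_dm",
    "ch4_g_kg_om",
    "ch4_mj_kg_dm",
    "ch4_pct_ge",
    "ch4_pct_de",
]

ALL_COLUMNS = (
    ID_COLUMNS
    + ANIMAL_COLUMNS
    + COMPOSITION_COLUMNS
    + ENERGY_COLUMNS
    + DIGESTIBILITY_COLUMNS
    + CH4_COLUMNS
)

NUMERIC_COLUMNS = [c for c in ALL_COLUMNS if c not in ("study_id", "cattle_class")]

# columns that must be present in any input table
MANDATORY_COLUMNS = ["study_id", "dmi_kg_d"]

# provenance flags (sidecar table, same shape as the record table)
PROVENANCE_OBSERVED = "observed"
PROVENANCE_IMPUTED = "imputed"
PROVENANCE_DERIVED = "derived"
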