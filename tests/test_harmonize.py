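"""Harmonization calculus: energy balance, digestibility, unit conversions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ch4meta.errors import (
    ConsistencyError,
    ConversionError,
    HarmonizationError,
    ImputationError,
)
from ch4meta.harmonize import (
    CH4_UNITS,
    CONSTANTS,
    complete_energy_balance,
    convert_methane,
    dmi_bw_at_maintenance,
    feeding_level,
    ge_concentration,
    ge_intake,
    harmonize,
    impute_digestibility,
    omd_at_maintenance,
)

COMP = {"cp": 160.0, "ee": 40.0, "nfc": 400.0, "ndf": 360.0}


class TestGrossEnergy:
    def test_worked_example(self):
        assert ge_concentration(COMP) == pytest.approx(19.092, abs=1e-9)
        assert ge_intake(10.0, COMP) == pytest.approx(190.92, abs=1e-9)

    def test_degenerate_compositions(self):
        assert ge_concentration({k: 0.0 for k in COMP}) == 0.0
        assert ge_concentration({"cp": 1000.0, "ee": 0, "nfc": 0, "ndf": 0}) == 23.6

    def test_missing_component_and_bad_dmi(self):
        with pytest.raises(HarmonizationError, match="nfc"):
            ge_concentration({"cp": 160, "ee": 40, "ndf": 360})
        with pytest.raises(HarmonizationError):
            ge_intake(0.0, COMP)

    @given(st.floats(0.1, 40), st.floats(0.1, 40))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_dmi(self, d1, d2):
        total = ge_intake(d1 + d2, COMP)
        assert total == pytest.approx(ge_intake(d1, COMP) + ge_intake(d2, COMP), rel=1e-12)


class TestEnergyBalance:
    def test_mei_from_identity(self):
        rec = {"dei_mj_d": 128.55, "ch4_mj_d": 10.87, "ue_mj_d": 5.0}
        complete_energy_balance(rec)
        assert rec["mei_mj_d"] == pytest.approx(112.68)

    def test_dei_from_gei_minus_fe(self):
        rec = {"gei_mj_d": 200.0, "fe_mj_d": 60.0}
        complete_energy_balance(rec)
        assert rec["dei_mj_d"] == pytest.approx(140.0)

    def test_consistent_record_is_fixed_point(self):
        rec = {
            "gei_mj_d": 200.0, "fe_mj_d": 60.0, "dei_mj_d": 140.0,
            "ch4_mj_d": 12.0, "ue_mj_d": 8.0, "mei_mj_d": 120.0,
        }
        flags = {}
        complete_energy_balance(dict(rec), flags)
        assert flags == {"q_ratio": "derived"}

    def test_inconsistent_record_raises(self):
        with pytest.raises(ConsistencyError):
            complete_energy_balance(
                {"gei_mj_d": 200.0, "fe_mj_d": 60.0, "dei_mj_d": 150.0}
            )


class TestFeedingLevel:
    def test_worked_example(self):
        assert feeding_level(100.0, 500.0, 0.55) == pytest.approx(2.148, abs=2e-3)

    def test_maintenance_is_unity(self):
        me_m = CONSTANTS.maintenance_scale * (500 / 1.08) ** 0.67 / (0.35 * 0.55 + 0.503)
        assert feeding_level(me_m, 500.0, 0.55) == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_mei_and_q_domain(self):
        fls = [feeding_level(m, 500.0, 0.55) for m in (50, 100, 150)]
        assert fls == sorted(fls) and fls[0] < fls[-1]
        with pytest.raises(HarmonizationError):
            feeding_level(100.0, 500.0, 1.2)


class TestDigestibility:
    def test_imputation_worked_examples(self):
        out, flags = impute_digestibility({"ge": 700.0})
        assert out["om"] == pytest.approx(40.4 + 0.966 * 700)
        assert flags == {"om": "imputed"}
        out, _ = impute_digestibility({"om": 700.0})
        assert out["ge"] == pytest.approx(9.6 + 0.84 * 700)

    def test_never_overwrites_observed(self):
        out, flags = impute_digestibility({"om": 700.0, "ge": 650.0})
        assert out["om"] == 700.0 and out["ge"] == 650.0 and flags == {}

    def test_requires_an_anchor(self):
        with pytest.raises(ImputationError):
            impute_digestibility({})

    def test_cascade_matches_precedence_oracle(self):
        """Brute-force oracle: apply equations one at a time, always the first
        applicable in precedence order, until a fixed point; all other
        orderings either stall or agree after re-ordering."""
        eqs = [
            ("om", "ge", 40.4, 0.966),
            ("ge", "om", 9.6, 0.84),
            ("ge", "dm", 16.2, 0.765),
        ]

        def oracle(start):
            state = dict(start)
            while True:
                for tgt, src, a, b in eqs:
                    if state.get(tgt) is None and state.get(src) is not None:
                        state[tgt] = a + b * state[src]
                        break
                else:
                    return state

        for present in itertools.chain.from_iterable(
            itertools.combinations(("dm", "om", "ge"), k) for k in (1, 2, 3)
        ):
            start = {k: (700.0 + 10 * i if k in present else None)
                     for i, k in enumerate(("dm", "om", "ge"))}
            got, _ = impute_digestibility(start)
            expected = oracle(start)
            for k in ("dm", "om", "ge"):
                assert got[k] == pytest.approx(expected[k], rel=1e-12), (present, k)

    def test_maintenance_adjustment(self):
        assert dmi_bw_at_maintenance(1.0) == pytest.approx(15.995)
        assert dmi_bw_at_maintenance(0.0) == pytest.approx(13.8)
        assert omd_at_maintenance(700.0, 10.0, 500.0) == pytest.approx(707.329, abs=1e-3)
        # actual intake at the maintenance level -> zero adjustment
        bw = 500.0
        dmi = dmi_bw_at_maintenance(1.0) * bw / 1000.0
        assert omd_at_maintenance(700.0, dmi, bw) == pytest.approx(700.0)
        # slope of 1.83 per g/kg DMI/BW
        d1 = omd_at_maintenance(700.0, 10.0, 500.0)
        d2 = omd_at_maintenance(700.0, 10.5, 500.0)  # +1 g/kg DMI/BW
        assert d2 - d1 == pytest.approx(1.83)


CTX = {"dmi": 10.0, "om": 930.0, "gei": 190.0, "dei": 130.0}


class TestConversions:
    def test_printed_constants(self):
        assert convert_methane(1.0, "g_d", "mj_d") * 1000 == pytest.approx(55.65)
        assert convert_methane(1.0, "l_d", "g_d") == pytest.approx(0.714)
        assert convert_methane(1.0, "l_d", "mj_d") * 1000 == pytest.approx(39.54)
        assert convert_methane(1000.0, "kcal_d", "mj_d") == pytest.approx(4.184)
        assert convert_methane(100.0, "g_d", "mj_d") == pytest.approx(5.565)

    @pytest.mark.parametrize(
        "u1,u2", list(itertools.permutations(CH4_UNITS, 2))
    )
    def test_round_trip_identity(self, u1, u2):
        v = 12.34
        back = convert_methane(convert_methane(v, u1, u2, **CTX), u2, u1, **CTX)
        assert back == pytest.approx(v, rel=1e-12)

    def test_missing_context_named(self):
        with pytest.raises(ConversionError, match="gei"):
            convert_methane(5.0, "mj_d", "pct_ge")
        with pytest.raises(ConversionError):
            convert_methane(5.0, "mj_d", "furlongs")


class TestHarmonizeTable:
    def base_record(self):
        return {
            "study_id": "S1", "n_animals": 8, "bw_kg": 500.0, "dmi_kg_d": 10.0,
            "om_g_kg": 960.0, "cp_g_kg": 160.0, "ee_g_kg": 40.0,
            "ndf_g_kg": 360.0, "nfc_g_kg": 400.0, "ch4_g_d": 200.0,
        }

    def test_gains_derivable_fields(self):
        df = pd.DataFrame([self.base_record()])
        out, prov = harmonize(df)
        assert out.loc[0, "gei_mj_d"] == pytest.approx(190.92)
        assert out.loc[0, "ch4_mj_d"] == pytest.approx(200 * 55.65 / 1000)
        assert out.loc[0, "ch4_pct_ge"] == pytest.approx(100 * 11.13 / 190.92)
        assert prov.loc[0, "gei_mj_d"] == "derived"
        assert prov.loc[0, "ch4_g_d"] == "observed"

    def test_idempotent(self):
        df = pd.DataFrame([self.base_record()])
        once, _ = harmonize(df)
        twice, _ = harmonize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_energy_monotonicity_on_synthetic(self, small_db):
        out, _ = harmonize(small_db)
        ok = out.dropna(subset=["gei_mj_d", "dei_mj_d", "mei_mj_d"])
        assert (ok["gei_mj_d"] >= ok["dei_mj_d"]).all()
        assert (ok["dei_mj_d"] >= ok["mei_mj_d"]).all()

    def test_observed_never_overwritten(self):
        rec = self.base_record()
        rec["gei_mj_d"] = 189.5  # observed, slightly off the chemistry value
        out, prov = harmonize(pd.DataFrame([rec]))
        assert out.loc[0, "gei_mj_d"] == 189.5
        assert prov.loc[0, "gei_mj_d"] == "observed"

    def test_violated_identity_raises(self):
        rec = self.base_record()
        rec.update({"gei_mj_d": 200.0, "fe_mj_d": 60.0, "dei_mj_d": 170.0})
        with pytest.raises(ConsistencyError):
            harmonize(pd.DataFrame([rec]))
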