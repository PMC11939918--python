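"""Rates, classification, osmotic conditions, and experiment summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcmdslb import (
    BUFFERS,
    BufferSpec,
    InconsistentFeaturesError,
    InvalidParameterError,
    OsmoticLabel,
    Outcome,
    UnknownSpeciesError,
    adsorption_rate,
    classify_outcome,
    conditions_for,
    load_conditions_table,
    load_summary_table,
    osmotic_condition,
    rupture_rate,
    summarize_experiment,
)

#: outcome of each experimental run per the study's narrative
NARRATIVE_OUTCOMES = {
    "2A": Outcome.SLB, "11A": Outcome.SLB, "11C": Outcome.SLB, "11D": Outcome.SLB,
    "12Aa": Outcome.SLB, "12Ab": Outcome.SLB, "12Ac": Outcome.SLB,
    "12Ad": Outcome.SLB, "12Ae": Outcome.SLB, "12Af": Outcome.SLB,
    "6A": Outcome.SLV, "7A": Outcome.SLV, "7C": Outcome.SLV,
    "8A": Outcome.SLV, "8C": Outcome.SLV,
    "9A": Outcome.PARTIAL_SLB_SLV, "10A": Outcome.PARTIAL_SLB_SLV,
}


class TestRates:
    @pytest.mark.parametrize(
        "df_min,t_ads,expected",
        [(-56.5, 2.1, 26.9), (0.0, 3.0, 0.0), (-60.0, 2.0, 30.0)],
    )
    def test_adsorption_rate(self, df_min, t_ads, expected):
        assert adsorption_rate(df_min, t_ads) == pytest.approx(expected, abs=0.05)

    def test_adsorption_rate_rejects_bad_time(self):
        with pytest.raises(InvalidParameterError):
            adsorption_rate(-10.0, 0.0)

    @pytest.mark.parametrize(
        "df_min,df_asymp,t_rup,expected",
        [
            (-56.5, -25.1, 1.4, 22.4),
            (-56.6, -56.6, math.inf, 0.0),
            (-45.1, -31.0, 1.95, 7.2),
        ],
    )
    def test_rupture_rate(self, df_min, df_asymp, t_rup, expected):
        assert rupture_rate(df_min, df_asymp, t_rup) == pytest.approx(expected, abs=0.05)

    def test_infinite_t_rup_gives_exact_zero(self):
        assert rupture_rate(-80.0, -50.0, math.inf) == 0.0

    def test_inconsistent_features_rejected(self):
        with pytest.raises(InconsistentFeaturesError):
            rupture_rate(-30.0, -40.0, 1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "df,dd,expected",
        [
            (-25.1, 0.1, Outcome.SLB),
            (-94.4, 17.2, Outcome.SLV),
            (-42.8, 2.4, Outcome.PARTIAL_SLB_SLV),
        ],
    )
    def test_band_examples(self, df, dd, expected):
        assert classify_outcome(df, dd) is expected

    def test_all_seventeen_rows_match_narrative(self):
        table = load_summary_table()
        for _, row in table.iterrows():
            got = classify_outcome(row["dF_asymp_hz"], row["dD_asymp_1e6"])
            assert got is NARRATIVE_OUTCOMES[row["figure"]], row["figure"]

    def test_rates_nonnegative_and_zero_iff_unruptured(self):
        table = load_summary_table()
        for _, row in table.iterrows():
            assert row["R_ads_hz_min"] >= 0
            assert row["R_rup_hz_min"] >= 0
            if math.isinf(row["t_rup_min"]):
                assert row["R_rup_hz_min"] == 0.0

    def test_rate_recomputation_on_consistent_rows(self):
        # rows whose printed (rounded) features reproduce the printed rates
        table = load_summary_table().set_index("figure")
        r2a = table.loc["2A"]
        assert adsorption_rate(r2a["dF_min_hz"], r2a["t_ads_min"]) == pytest.approx(26.9, abs=0.05)
        assert rupture_rate(
            r2a["dF_min_hz"], r2a["dF_asymp_hz"], r2a["t_rup_min"]
        ) == pytest.approx(22.4, abs=0.05)
        r6a = table.loc["6A"]
        assert rupture_rate(r6a["dF_min_hz"], r6a["dF_asymp_hz"], r6a["t_rup_min"]) == 0.0
        r11a = table.loc["11A"]
        assert rupture_rate(
            r11a["dF_min_hz"], r11a["dF_asymp_hz"], r11a["t_rup_min"]
        ) == pytest.approx(7.2, abs=0.05)

    def test_finite_inputs_required(self):
        with pytest.raises(InvalidParameterError):
            classify_outcome(math.nan, 0.1)


class TestOsmotic:
    def test_hyperosmotic_dilution_b2_to_b5(self):
        res = osmotic_condition(BUFFERS["B2"], BUFFERS["B5"])
        assert res.label is OsmoticLabel.HYPEROSMOTIC
        # the study quotes this difference as 150 mM NaCl (2.5 mM MgCl2 extra
        # in B5 adds a little under the ideal van't Hoff count)
        assert res.nacl_equivalent_mm == pytest.approx(150.0, abs=5.0)

    def test_hyperosmotic_dilution_b6_to_b2(self):
        res = osmotic_condition(BUFFERS["B6"], BUFFERS["B2"])
        assert res.label is OsmoticLabel.HYPEROSMOTIC
        assert res.nacl_equivalent_mm == pytest.approx(100.0, abs=1e-9)

    def test_identical_buffers_isosmotic(self):
        res = osmotic_condition(BUFFERS["B1"], BUFFERS["B1"])
        assert res.label is OsmoticLabel.ISOSMOTIC
        assert res.delta_mosm == 0.0

    def test_small_divalent_difference_stays_isosmotic(self):
        # B2 -> B4 adds only 2.5 mM MgCl2 (7.5 mOsm): the isosmotic protocol
        res = osmotic_condition(BUFFERS["B2"], BUFFERS["B4"])
        assert res.label is OsmoticLabel.ISOSMOTIC

    @given(
        a=st.sampled_from(sorted(BUFFERS)),
        b=st.sampled_from(sorted(BUFFERS)),
    )
    @settings(max_examples=36, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        fwd = osmotic_condition(BUFFERS[a], BUFFERS[b])
        rev = osmotic_condition(BUFFERS[b], BUFFERS[a])
        assert fwd.delta_mosm == -rev.delta_mosm
        flip = {
            OsmoticLabel.HYPEROSMOTIC: OsmoticLabel.HYPOOSMOTIC,
            OsmoticLabel.HYPOOSMOTIC: OsmoticLabel.HYPEROSMOTIC,
            OsmoticLabel.ISOSMOTIC: OsmoticLabel.ISOSMOTIC,
        }
        assert rev.label is flip[fwd.label]

    def test_unknown_species_rejected(self):
        odd = BufferSpec("X", (("sucrose", 100.0),))
        with pytest.raises(UnknownSpeciesError):
            osmotic_condition(odd, BUFFERS["B1"])


class TestSummaries:
    def test_slb_preset_summary(self, simulated):
        trace, _ = simulated["dopc_fig2"]
        rec = summarize_experiment(trace, conditions=conditions_for("2A"))
        assert rec["outcome"] == "SLB"
        assert rec["R_ads_hz_min"] == pytest.approx(26.9, rel=0.15)
        assert rec["h_nm"] == pytest.approx(20.0, rel=0.10)
        assert rec["bilayer_thickness_nm"] is not None
        assert rec["osmotic_adsorption"] == "isosmotic"

    def test_slv_preset_summary(self, simulated):
        trace, _ = simulated["slv"]
        rec = summarize_experiment(trace, conditions=conditions_for("6A"))
        assert rec["outcome"] == "SLV"
        assert rec["R_rup_hz_min"] == 0.0
        assert rec["bilayer_thickness_nm"] is None

    def test_partial_preset_summary(self, simulated):
        trace, _ = simulated["partial"]
        rec = summarize_experiment(trace)
        assert rec["outcome"] == "PARTIAL_SLB_SLV"
        assert rec["R_rup_hz_min"] > 0.0

    def test_osmotic_labels_for_osmotic_stress_protocol(self, simulated):
        # hyperosmotic dilution during adsorption: the SLB-forming protocol
        trace, _ = simulated["slb"]
        rec = summarize_experiment(trace, conditions=conditions_for("11A"))
        assert rec["osmotic_adsorption"] == "hyperosmotic"
        assert rec["osmotic_rinse"] == "isosmotic"


class TestConditionsTable:
    def test_all_rows_build_conditions(self):
        for code in load_conditions_table()["figure"]:
            cond = conditions_for(code)
            assert cond.vesicle_diameter_nm > 0
            assert cond.temperature_c in (23.0, 35.0)

    def test_unknown_code(self):
        with pytest.raises(KeyError):
            conditions_for("99Z")
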