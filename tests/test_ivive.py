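import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import POTENCY_ORDER, PUBLISHED_TABLE
from cypscreen.ivive import (
    RISK_EXCLUDED,
    RISK_POTENTIAL,
    assess_compound,
    ddi_ratio_and_flag,
    ki_u_cheng_prusoff,
    ki_u_regulatory,
    rank_by_potency,
    unbound_cmax,
    unbound_ic50,
)
from cypscreen.plate import CompoundProfile


class TestUnboundIC50:
    @pytest.mark.parametrize("name", list(PUBLISHED_TABLE))
    def test_published_columns_reproduced_exactly(self, name):
        row = PUBLISHED_TABLE[name]
        assert unbound_ic50(row["ic50"], 0.02) == pytest.approx(row["ic50_u"], abs=0.05)

    def test_fully_unbound_is_identity(self):
        assert unbound_ic50(3.7, 1.0) == 3.7

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            unbound_ic50(1.0, 0.0)
        with pytest.raises(ValueError):
            unbound_ic50(1.0, 1.5)


class TestKiConventions:
    def test_no_substrate_competition_is_identity(self):
        assert ki_u_cheng_prusoff(50.0, 0.0, 10.0) == 50.0

    def test_substrate_at_km_halves(self):
        assert ki_u_cheng_prusoff(331.0, 7.0, 7.0) == pytest.approx(165.5)

    @pytest.mark.parametrize("name", list(PUBLISHED_TABLE))
    def test_regulatory_half_reproduces_published_ki(self, name):
        row = PUBLISHED_TABLE[name]
        assert ki_u_regulatory(row["ic50_u"]) == pytest.approx(row["ki_u"], abs=0.005)

    @given(ic50_u=st.floats(1e-3, 1e4), km=st.floats(1e-3, 1e3))
    @settings(max_examples=100, derandomize=True)
    def test_half_convention_equals_cheng_prusoff_at_s_equals_km(self, ic50_u, km):
        assert ki_u_regulatory(ic50_u) == pytest.approx(
            ki_u_cheng_prusoff(ic50_u, km, km), rel=1e-12
        )

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            ki_u_cheng_prusoff(1.0, 1.0, 0.0)


class TestUnboundCmax:
    @pytest.mark.parametrize("name", list(PUBLISHED_TABLE))
    def test_published_cmax_u_both_units(self, name, profiles):
        row = PUBLISHED_TABLE[name]
        ug, um = unbound_cmax(profiles[name])
        assert ug == pytest.approx(row["cmax_u_ug"], abs=5e-4)
        assert um == pytest.approx(row["cmax_u_um"], abs=5e-4)

    def test_fully_unbound_equals_total(self):
        p = CompoundProfile(name="X", molecular_weight=300.0,
                            cmax_total_ug_per_ml=1.5, fu_plasma=1.0)
        ug, _ = unbound_cmax(p)
        assert ug == 1.5


class TestRatioAndFlag:
    def test_inclusive_threshold_boundary(self):
        ratio, flag = ddi_ratio_and_flag(0.02, 1.0)
        assert ratio == 0.02 and flag == RISK_POTENTIAL

    def test_zero_exposure_excluded(self):
        ratio, flag = ddi_ratio_and_flag(0.0, 5.0)
        assert ratio == 0.0 and flag == RISK_EXCLUDED

    def test_published_inputs_give_sub_threshold_computed_ratio(self):
        # computed from the published Cmax,u and Ki,u the omeprazole ratio
        # is ~9.2e-4, far below the printed 0.0288 — the ratio is computed
        # from the formula, never copied
        ratio, flag = ddi_ratio_and_flag(0.0324, 35.25)
        assert ratio == pytest.approx(9.19e-4, rel=1e-3)
        assert flag == RISK_EXCLUDED

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            ddi_ratio_and_flag(1.0, 0.0)

    @given(
        cmax=st.floats(1e-6, 1e3), ki=st.floats(1e-6, 1e3),
        d_cmax=st.floats(0.0, 10.0), d_ki=st.floats(0.0, 10.0),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity_and_scale_invariance(self, cmax, ki, d_cmax, d_ki, scale):
        ratio, flag = ddi_ratio_and_flag(cmax, ki)
        up, _ = ddi_ratio_and_flag(cmax + d_cmax, ki)
        down, _ = ddi_ratio_and_flag(cmax, ki + d_ki)
        assert up >= ratio >= down
        _, scaled_flag = ddi_ratio_and_flag(cmax * scale, ki * scale)
        assert scaled_flag == flag


class TestFullChain:
    @pytest.mark.parametrize("name", list(PUBLISHED_TABLE))
    def test_assessment_reproduces_all_published_columns(self, name, profiles):
        row = PUBLISHED_TABLE[name]
        a = assess_compound(row["ic50"], profiles[name])
        assert a.ic50_u_uM == pytest.approx(row["ic50_u"], abs=0.05)
        assert a.ki_u_uM == pytest.approx(row["ki_u"], abs=0.05)
        assert a.cmax_u_uM == pytest.approx(row["cmax_u_um"], abs=5e-4)
        assert a.ki_u_uM <= a.ic50_u_uM

    def test_cheng_prusoff_convention_requires_kinetics(self, profiles):
        with pytest.raises(ValueError):
            assess_compound(1.0, profiles["Omeprazole"], ki_convention="cheng_prusoff")


class TestPotencyRanking:
    def test_published_ic50s_reproduce_reported_order(self, profiles):
        assessments = [assess_compound(PUBLISHED_TABLE[n]["ic50"], profiles[n])
                       for n in sorted(PUBLISHED_TABLE)]
        ordered, ties = rank_by_potency(assessments)
        assert [a.compound for a in ordered] == POTENCY_ORDER
        assert not ties

    def test_ties_break_alphabetically_and_are_flagged(self, profiles):
        a = assess_compound(2.0, profiles["Omeprazole"])
        b = assess_compound(2.0, profiles["Ilaprazole"])
        ordered, ties = rank_by_potency([a, b])
        assert [x.compound for x in ordered] == ["Ilaprazole", "Omeprazole"]
        assert ties

    def test_single_compound(self, profiles):
        a = assess_compound(2.0, profiles["Omeprazole"])
        ordered, ties = rank_by_potency([a])
        assert ordered == [a] and not ties
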