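import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypscreen.plate import (
    CompoundProfile,
    DegenerateControlsError,
    MissingControlError,
    WellMeasurement,
    aggregate_controls,
    build_dilution_series,
    clip_inhibition,
    frame_to_wells,
    mass_conc_to_molar,
    molar_to_mass_conc,
    parse_well,
    percent_inhibition,
    read_plate_csv,
    wells_to_frame,
    write_plate_csv,
)


def well(role="test", compound="X", conc=1.0, rfu=500.0, w="A3", unit="uM"):
    return WellMeasurement(plate_id="P", well=w, role=role, compound=compound,
                           conc_value=conc, conc_unit=unit, rfu=rfu)


class TestWellParsing:
    @pytest.mark.parametrize("raw,canon", [("a1", "A1"), ("H12", "H12"), ("b07", "B7")])
    def test_case_insensitive_canonicalisation(self, raw, canon):
        assert parse_well(raw) == canon

    @pytest.mark.parametrize("bad", ["I1", "A13", "A0", "11", "AA1", ""])
    def test_out_of_plate_coordinates_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_well(bad)


class TestWellMeasurementInvariants:
    def test_blank_must_have_zero_concentration(self):
        with pytest.raises(ValueError):
            well(role="blank", compound="", conc=1.0)

    def test_test_well_needs_compound_and_positive_concentration(self):
        with pytest.raises(ValueError):
            well(compound="")
        with pytest.raises(ValueError):
            well(conc=0.0)

    def test_rfu_must_be_finite_nonnegative(self):
        with pytest.raises(ValueError):
            well(rfu=-1.0)
        with pytest.raises(ValueError):
            well(rfu=float("nan"))


class TestPercentInhibition:
    def test_control_boundaries_and_midpoint(self):
        # test equal to solvent control: no inhibition; equal to positive
        # control: full inhibition; halfway: 50% (the statistic is affine)
        assert percent_inhibition(1000.0, 1000.0, 100.0) == 0.0
        assert percent_inhibition(100.0, 1000.0, 100.0) == 100.0
        assert percent_inhibition(550.0, 1000.0, 100.0) == 50.0

    def test_values_outside_0_100_are_preserved(self):
        assert percent_inhibition(1100.0, 1000.0, 100.0) < 0.0
        assert percent_inhibition(50.0, 1000.0, 100.0) > 100.0
        assert list(clip_inhibition([-5.0, 50.0, 120.0])) == [0.0, 50.0, 100.0]

    def test_degenerate_controls_raise(self):
        with pytest.raises(DegenerateControlsError):
            percent_inhibition(500.0, 300.0, 300.0)

    @given(
        a=st.floats(-1e5, 1e5), b=st.floats(-1e5, 1e5),
        x1=st.floats(-1e5, 1e5), x2=st.floats(-1e5, 1e5),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_in_test_signal_and_exact_at_controls(self, a, b, x1, x2, alpha):
        if abs(a - b) < 1e-3:
            return
        assert percent_inhibition(a, a, b) == pytest.approx(0.0, abs=1e-9)
        assert percent_inhibition(b, a, b) == pytest.approx(100.0, abs=1e-9)
        mix = alpha * x1 + (1 - alpha) * x2
        lhs = percent_inhibition(mix, a, b)
        rhs = (alpha * percent_inhibition(x1, a, b)
               + (1 - alpha) * percent_inhibition(x2, a, b))
        assert lhs == pytest.approx(rhs, abs=1e-6 * max(1.0, abs(rhs)))


class TestUnitConversion:
    @pytest.mark.parametrize("ug_ml,mw,um", [
        (0.0112, 345.42, 0.0324),  # omeprazole unbound Cmax
        (0.0045, 366.44, 0.0123),  # ilaprazole unbound Cmax
        (0.0, 123.4, 0.0),
    ])
    def test_mass_to_molar_reference_values(self, ug_ml, mw, um):
        assert mass_conc_to_molar(ug_ml, mw) == pytest.approx(um, abs=5e-5)

    @given(conc=st.floats(1e-6, 1e4), mw=st.floats(50.0, 2000.0))
    @settings(max_examples=100, derandomize=True)
    def test_roundtrip_is_identity(self, conc, mw):
        back = molar_to_mass_conc(mass_conc_to_molar(conc, mw), mw)
        assert back == pytest.approx(conc, rel=1e-12)

    def test_nonpositive_molecular_weight_rejected(self):
        with pytest.raises(ValueError):
            mass_conc_to_molar(1.0, 0.0)


class TestDilutionSeries:
    def test_standard_series_500nm_twofold(self):
        s = build_dilution_series(500.0, 2.0, 7, unit="nM")
        assert s.concentrations == [500, 250, 125, 62.5, 31.25, 15.625, 7.8125]

    def test_published_test_range_series(self):
        s = build_dilution_series(6.4, 2.0, 4, unit="ug/mL")
        assert s.concentrations == pytest.approx([6.4, 3.2, 1.6, 0.8])

    def test_two_point_series(self):
        assert build_dilution_series(9.0, 3.0, 2).concentrations == [9.0, 3.0]

    @given(top=st.floats(1e-3, 1e3), fold=st.floats(1.1, 10.0),
           n=st.integers(2, 12))
    @settings(max_examples=50, derandomize=True)
    def test_consecutive_ratio_equals_fold(self, top, fold, n):
        c = build_dilution_series(top, fold, n).concentrations
        assert len(c) == n
        ratios = [c[i] / c[i + 1] for i in range(n - 1)]
        assert np.allclose(ratios, fold, rtol=1e-12)
        assert all(c[i] > c[i + 1] for i in range(n - 1))

    @pytest.mark.parametrize("top,fold,n", [(1.0, 1.0, 4), (1.0, 0.5, 4), (1.0, 2.0, 1)])
    def test_invalid_parameters_rejected(self, top, fold, n):
        with pytest.raises(ValueError):
            build_dilution_series(top, fold, n)


class TestControlAggregation:
    def test_replicates_averaged_at_rfu_level(self):
        wells = [
            well(role="solvent_control", compound="", conc=0, rfu=1000, w="A2"),
            well(role="solvent_control", compound="", conc=0, rfu=1010, w="B2"),
            well(role="positive_control", compound="", conc=0, rfu=100, w="E2"),
            well(role="positive_control", compound="", conc=0, rfu=110, w="F2"),
        ]
        s = aggregate_controls(wells)
        assert (s.a_rfu, s.b_rfu) == (1005.0, 105.0)
        assert s.a_sd == pytest.approx(np.std([1000, 1010], ddof=1))

    def test_single_replicate_flags_undefined_sd(self):
        wells = [
            well(role="solvent_control", compound="", conc=0, rfu=900, w="A2"),
            well(role="positive_control", compound="", conc=0, rfu=90, w="E2"),
        ]
        s = aggregate_controls(wells)
        assert s.a_rfu == 900 and s.b_rfu == 90
        assert math.isnan(s.a_sd) and math.isnan(s.b_sd)

    def test_missing_positive_control_raises(self):
        with pytest.raises(MissingControlError):
            aggregate_controls(
                [well(role="solvent_control", compound="", conc=0, rfu=900, w="A2")]
            )


class TestCsvRoundTrip:
    def test_plate_csv_roundtrip_lossless(self, tmp_path, noisy_plate):
        path = tmp_path / "plate.csv"
        write_plate_csv(list(noisy_plate.wells), path)
        back = read_plate_csv(path)
        assert back == list(noisy_plate.wells)

    def test_frame_conversion_inverse(self, noiseless_plate):
        wells = list(noiseless_plate.wells)
        assert frame_to_wells(wells_to_frame(wells)) == wells


def test_compound_profile_validates_fractions():
    with pytest.raises(ValueError):
        CompoundProfile(name="X", molecular_weight=100.0, fu_plasma=0.0)
    with pytest.raises(ValueError):
        CompoundProfile(name="X", molecular_weight=100.0, fu_incubation=1.5)
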