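"""Densitometry chain: loading normalization, calibration, interpolation,
per-cell amounts, cellular concentration, and sequence constants."""

import numpy as np
import pandas as pd
import pytest

from synquant import abs_quant, syngen
from synquant.abs_quant import ASYN_HUMAN
from synquant.errors import CalibrationError, SequenceError
from synquant.syngen import GenConfig
from synquant.types import DensitometryTable, ProteinSequence


def blot_table(rows):
    return DensitometryTable(pd.DataFrame(rows))


class TestNormalizeLoading:
    def test_equal_loading_unchanged(self):
        table, _ = syngen.gen_blot(loading_cv=0.0)
        normalized, factors = abs_quant.normalize_loading(table)
        assert np.allclose(normalized.data["band_density"],
                           table.data["band_density"])
        assert np.allclose(list(factors.values()), 1.0)

    def test_overloaded_lane_divided_down(self):
        rows = []
        for lane, load in (("a", 1.0), ("b", 1.0), ("c", 1.1)):
            rows.append({"lane": lane, "role": "standard",
                         "band_density": 100.0 * load,
                         "loading_1": 500 * load, "loading_2": 800 * load,
                         "loading_3": 1100 * load, "known_conc": 5.0})
        normalized, factors = abs_quant.normalize_loading(blot_table(rows))
        # equal true signal: after correction all lanes agree
        assert np.allclose(normalized.data["band_density"],
                           normalized.data["band_density"].iloc[0])
        assert factors["c"] / factors["a"] == pytest.approx(1.1)

    def test_zero_loading_density_rejected(self):
        rows = [{"lane": "a", "role": "standard", "band_density": 10.0,
                 "loading_1": 0.0, "loading_2": 1.0, "loading_3": 1.0,
                 "known_conc": 2.0}]
        with pytest.raises(CalibrationError):
            abs_quant.normalize_loading(blot_table(rows))

    def test_large_correction_flagged(self):
        rows = []
        for lane, load in (("a", 1.0), ("b", 2.0)):
            rows.append({"lane": lane, "role": "standard",
                         "band_density": 10.0,
                         "loading_1": 500 * load, "loading_2": 800 * load,
                         "loading_3": 1100 * load, "known_conc": 2.0})
        with pytest.warns(UserWarning, match="deviates"):
            abs_quant.normalize_loading(blot_table(rows))


class TestCalibration:
    def test_exact_linear_standards(self):
        concs = np.array([2.0, 3.5, 5.0, 6.5, 8.0])
        dens = 120.0 * concs + 30.0
        standards = pd.DataFrame({"known_conc": concs, "band_density": dens})
        fit = abs_quant.fit_calibration(standards)
        assert fit.slope == pytest.approx(120.0)
        assert fit.intercept == pytest.approx(30.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_generator_slope_recovered(self):
        table, gt = syngen.gen_blot(slope=85.0, cfg=GenConfig(seed=1))
        fit = abs_quant.fit_calibration(table.standards)
        assert fit.slope == pytest.approx(85.0, rel=1e-9)

    def test_degenerate_concentrations_rejected(self):
        standards = pd.DataFrame({"known_conc": [5.0, 5.0, 5.0],
                                  "band_density": [1.0, 2.0, 3.0]})
        with pytest.raises(CalibrationError):
            abs_quant.fit_calibration(standards)

    def test_through_origin_mode(self):
        concs = np.array([2.0, 4.0, 8.0])
        standards = pd.DataFrame({"known_conc": concs, "band_density": 50.0 * concs})
        fit = abs_quant.fit_calibration(standards, through_origin=True)
        assert fit.intercept == 0.0 and fit.slope == pytest.approx(50.0)


class TestInterpolation:
    @pytest.fixture
    def fit(self):
        concs = np.array([2.0, 3.5, 5.0, 6.5, 8.0])
        standards = pd.DataFrame({"known_conc": concs,
                                  "band_density": 100.0 * concs + 20.0})
        return abs_quant.fit_calibration(standards)

    def test_standard_density_maps_back(self, fit):
        assert abs_quant.interpolate_concentration(fit, 520.0) == pytest.approx(5.0)

    def test_midpoint(self, fit):
        assert abs_quant.interpolate_concentration(fit, 100.0 * 4.25 + 20.0) == \
            pytest.approx(4.25)

    def test_density_at_intercept_is_zero_with_flag(self, fit):
        with pytest.warns(UserWarning):
            assert abs_quant.interpolate_concentration(fit, 20.0) == 0.0

    def test_extrapolation_flagged(self, fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            abs_quant.interpolate_concentration(fit, 100.0 * 12.0 + 20.0)


class TestPerCellAndCellular:
    def test_hand_value(self):
        # 4 ug/ml in 25 ul over 1.875e5 cell equivalents -> 0.533 pg/cell
        amount = abs_quant.per_cell_amount(4.0, 0.025, 1.875e5)
        assert amount == pytest.approx(0.5333, abs=1e-3)

    def test_doubling_cells_halves_amount(self):
        a = abs_quant.per_cell_amount(4.0, 0.025, 1.0e5)
        b = abs_quant.per_cell_amount(4.0, 0.025, 2.0e5)
        assert a == pytest.approx(2 * b)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            abs_quant.per_cell_amount(4.0, 0.025, 0)

    def test_mass_concentration_conversion(self):
        # choose the per-cell amount that puts 130 ug/ml in the mean cell volume
        amount = 130e-6 * abs_quant.DEFAULT_CELL_VOLUME_UM3
        cc = abs_quant.cellular_concentration(amount)
        assert cc.mass_ug_per_ml == pytest.approx(130.0)
        assert cc.molar_uM_rounded == 9

    def test_doubling_volume_halves_both(self):
        cc1 = abs_quant.cellular_concentration(0.4, cell_volume=2000.0)
        cc2 = abs_quant.cellular_concentration(0.4, cell_volume=4000.0)
        assert cc1.mass_ug_per_ml == pytest.approx(2 * cc2.mass_ug_per_ml)
        assert cc1.molar_uM == pytest.approx(2 * cc2.molar_uM)

    def test_unit_round_trip(self):
        cc = abs_quant.cellular_concentration(0.3415)
        back = cc.molar_uM * cc.molecular_weight_da / 1e3
        assert back == pytest.approx(cc.mass_ug_per_ml, rel=1e-12)


class TestSequenceConstants:
    def test_single_glycine(self):
        assert abs_quant.molecular_weight(ProteinSequence("G")) == \
            pytest.approx(75.07, abs=0.01)

    def test_diglycine_loses_one_water(self):
        assert abs_quant.molecular_weight(ProteinSequence("GG")) == \
            pytest.approx(132.12, abs=0.01)

    def test_asyn_mass_against_independent_oracle(self):
        from Bio.SeqUtils import molecular_weight as bio_mw
        ours = abs_quant.molecular_weight(ASYN_HUMAN)
        theirs = bio_mw(ASYN_HUMAN.sequence, seq_type="protein")
        assert ours == pytest.approx(theirs, abs=1.0)
        assert ours == pytest.approx(14460.0, abs=1.0)

    def test_asyn_composition(self):
        assert len(ASYN_HUMAN) == 140
        assert ASYN_HUMAN.count("W") == 0
        assert ASYN_HUMAN.count("Y") == 4
        assert ASYN_HUMAN.count("C") == 0

    def test_extinction_asyn(self):
        assert abs_quant.extinction_coefficient(ASYN_HUMAN) == 5960.0

    def test_extinction_tryptophan_only(self):
        assert abs_quant.extinction_coefficient(ProteinSequence("WWG")) == 11000.0

    def test_no_chromophore_warns(self):
        with pytest.warns(UserWarning):
            assert abs_quant.extinction_coefficient(ProteinSequence("GAGA")) == 0.0

    def test_noncanonical_sequence_rejected(self):
        with pytest.raises(SequenceError):
            ProteinSequence("GAXB")


class TestEndToEndChain:
    def run_chain(self, table):
        normalized, _ = abs_quant.normalize_loading(table)
        fit = abs_quant.fit_calibration(normalized.standards)
        out = {}
        for _, row in normalized.unknowns.iterrows():
            out[row["lane"]] = abs_quant.interpolate_concentration(
                fit, row["band_density"])
        return out

    def test_zero_noise_exact_recovery(self):
        table, gt = syngen.gen_blot(unknown_concs=(3.0, 6.0),
                                    cfg=GenConfig(seed=3))
        recovered = self.run_chain(table)
        for lane, true in gt.true_lane_concentrations.items():
            assert recovered[lane] == pytest.approx(true, rel=1e-9)

    def test_loading_variation_within_ten_percent(self):
        for seed in range(10):
            table, gt = syngen.gen_blot(unknown_concs=(3.0, 6.0),
                                        loading_cv=0.05,
                                        cfg=GenConfig(seed=seed, noise_sd=10.0))
            recovered = self.run_chain(table)
            for lane, true in gt.true_lane_concentrations.items():
                assert abs(recovered[lane] - true) / true < 0.10
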