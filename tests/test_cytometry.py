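"""MFI computation, saturation detection, QC rules and binding-curve fits."""

import numpy as np
import pandas as pd
import pytest

from glycoshield import cytometry, synthetic
from glycoshield.cytometry import (
    FitError,
    QCConfig,
    compute_mfi,
    demultiplex,
    detect_saturating,
    fit_binding_curve,
    qc_equal_expression,
    qc_positivity,
)
from glycoshield.synthetic import BindingModel, Genotype

from conftest import curve_from_dict, noiseless_curve


class TestComputeMfi:
    @pytest.mark.parametrize("method", ["mean", "geomean", "median"])
    def test_constant_population(self, method):
        assert compute_mfi([100, 100, 100], method) == pytest.approx(100)

    def test_mean_and_geomean(self):
        assert compute_mfi([10, 20, 30, 40]) == 25
        assert compute_mfi([10, 1000], "geomean") == pytest.approx(100.0)

    def test_rejects_empty_and_nonpositive_geomean(self):
        with pytest.raises(ValueError):
            compute_mfi([])
        with pytest.raises(ValueError):
            compute_mfi([0.0, 10.0], "geomean")


class TestDemultiplex:
    def test_pure_wt_well(self):
        """A table of only dye1-high events demultiplexes to 100% WT."""
        rng = np.random.default_rng(0)
        n = 2000
        # half the events high on dye1, none on dye2: WT vs B3GNT5KO split
        dye1 = np.where(rng.random(n) < 0.5, 10_000.0, 100.0) * rng.lognormal(0, 0.05, n)
        events = pd.DataFrame(
            {
                "genotype": "WT",
                "dye1": dye1,
                "dye2": 100.0 * rng.lognormal(0, 0.05, n),
                "viability": 100.0,
                "stain": 500.0,
            }
        )
        with pytest.warns(UserWarning, match="unimodal"):
            split = demultiplex(events)
        assert len(split[Genotype.SPPL3KO]) == 0
        assert len(split[Genotype.DKO]) == 0
        assert len(split[Genotype.WT]) + len(split[Genotype.B3GNT5KO]) == n

    def test_empty_table(self):
        events = pd.DataFrame(columns=["dye1", "dye2", "viability", "stain"])
        split = demultiplex(events)
        assert all(len(v) == 0 for v in split.values())

    def test_partition_is_exact(self, small_panel_run):
        _, events, _, _ = small_panel_run
        well = events[
            (events["antibody"] == events["antibody"].iloc[0])
            & (events["concentration_ugml"] == 1.0)
        ]
        viable = cytometry.viability_gate(well)
        split = demultiplex(well)
        assert sum(len(v) for v in split.values()) == len(viable)


class TestDetectSaturating:
    def test_example_curve(self):
        curve = curve_from_dict(
            "ab", {("WT", 20.0): 1000.0, ("WT", 1.0): 990.0, ("WT", 0.05): 400.0}
        )
        res = detect_saturating(curve, tolerance=0.10)
        assert res.saturating == [1.0, 20.0]
        assert res.analysis_concentration == 0.05
        assert res.status == "ok"

    def test_linear_curve_only_top_saturating(self):
        curve = curve_from_dict(
            "ab", {("WT", c): 10.0 * c for c in (0.1, 1.0, 10.0)}
        )
        res = detect_saturating(curve, tolerance=0.10)
        assert res.saturating == [10.0]
        assert res.analysis_concentration == 1.0

    def test_flat_curve_all_saturating(self):
        curve = curve_from_dict("ab", {("WT", c): 500.0 for c in (0.1, 1.0, 10.0)})
        res = detect_saturating(curve, tolerance=0.10)
        assert res.status == "all_saturating"
        assert res.analysis_concentration is None

    def test_single_concentration_undetermined(self):
        curve = curve_from_dict("ab", {("WT", 1.0): 500.0})
        with pytest.warns(UserWarning, match="undetermined"):
            res = detect_saturating(curve, tolerance=0.10)
        assert res.status == "undetermined"


class TestQcPositivity:
    @pytest.mark.parametrize(
        "top_mfi,expected", [(1000.0, True), (150.0, False), (200.0, True)]
    )
    def test_threshold_inclusive(self, top_mfi, expected):
        curve = curve_from_dict("ab", {("WT", 20.0): top_mfi, ("WT", 1.0): top_mfi / 2})
        assert qc_positivity(curve, control_mfi=100.0).passed is expected

    def test_missing_wt_fails_with_reason(self):
        curve = curve_from_dict("ab", {("SPPL3KO", 20.0): 1000.0})
        res = qc_positivity(curve, control_mfi=100.0)
        assert not res.passed and res.reason == "no_wt_curve"


class TestQcEqualExpression:
    def _curve(self, sat_ratios):
        mfis = {("WT", 20.0): 1000.0, ("WT", 1.0): 990.0, ("WT", 0.05): 300.0}
        for g, r in sat_ratios.items():
            mfis[(g, 20.0)] = 1000.0 * r
            mfis[(g, 1.0)] = 990.0 * r
            mfis[(g, 0.05)] = 300.0 * r
        return curve_from_dict("ab", mfis)

    def test_similar_saturating_ratios_pass(self):
        curve = self._curve({"SPPL3KO": 0.95, "B3GNT5KO": 1.05, "DKO": 1.0})
        assert qc_equal_expression(curve).passed

    def test_differential_expression_fails(self):
        curve = self._curve({"SPPL3KO": 0.5, "B3GNT5KO": 1.0, "DKO": 1.0})
        res = qc_equal_expression(curve)
        assert not res.passed
        assert res.reason == "differential_expression_at_saturation"

    def test_shielded_generator_output_passes(self, shielded_model):
        """Multiplicative-Kd shielding keeps saturating stains genotype-equal."""
        curve = noiseless_curve(shielded_model, synthetic.DEFAULT_CONCENTRATIONS)
        assert qc_equal_expression(curve).passed

    def test_no_saturating_concentration_undetermined(self):
        # a single-concentration curve has no established saturating point
        single = curve_from_dict("ab", {("WT", 1.0): 500.0, ("SPPL3KO", 1.0): 400.0})
        with pytest.warns(UserWarning):
            res = qc_equal_expression(single)
        assert not res.passed
        assert res.reason == "undetermined_no_saturating_concentration"


class TestFitBindingCurve:
    CONCS_NM = (0.1, 0.5, 2.0, 10.0, 40.0, 100.0)

    def _noiseless(self, model):
        ugml = [c * model.mw_kda / 1000.0 for c in self.CONCS_NM]
        return noiseless_curve(model, ugml)

    def test_parameter_recovery_within_one_percent(self):
        model = BindingModel(bmax=1000.0, kd_nm=5.0, background=50.0)
        fit = fit_binding_curve(self._noiseless(model), Genotype.WT)
        assert fit.bmax == pytest.approx(1000.0, rel=0.01)
        assert fit.kd_eff_nm == pytest.approx(5.0, rel=0.01)
        assert fit.background == pytest.approx(50.0, rel=0.01)

    def test_shielded_genotype_kd_doubles(self):
        """beta=1 inflates the fitted effective Kd to 2x the WT fit."""
        model = BindingModel(
            bmax=1000.0, kd_nm=5.0, background=50.0,
            shield_beta={Genotype.SPPL3KO: 1.0},
        )
        curve = self._noiseless(model)
        wt = fit_binding_curve(curve, Genotype.WT)
        ko = fit_binding_curve(curve, Genotype.SPPL3KO)
        assert ko.kd_eff_nm / wt.kd_eff_nm == pytest.approx(2.0, rel=0.05)

    def test_flat_curve_unidentifiable(self):
        curve = curve_from_dict("ab", {("WT", c): 500.0 for c in (0.1, 1.0, 10.0)})
        with pytest.raises(FitError, match="flat"):
            fit_binding_curve(curve, Genotype.WT)

    def test_requires_three_concentrations(self):
        curve = curve_from_dict("ab", {("WT", 1.0): 100.0, ("WT", 10.0): 500.0})
        with pytest.raises(FitError):
            fit_binding_curve(curve, Genotype.WT)


def test_mfi_monotone_in_concentration(shielded_model):
    """Noiseless generator MFIs never decrease with concentration."""
    curve = noiseless_curve(shielded_model, (0.05, 0.2, 1.0, 5.0, 20.0))
    for g in Genotype:
        series = curve.genotype_series(g)
        assert series.is_monotonic_increasing
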