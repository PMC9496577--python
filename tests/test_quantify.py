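"""Standard-curve fitting, prediction, replicate and dilution statistics."""
from __future__ import annotations

import math

import numpy as np
import pytest

import platequant as pq
from platequant.errors import FitError


def _exact_curve(x=2.0, z=1.0, ods=(-1.0, -0.5, -0.2)):
    pairs = [(math.exp(x * od + z), od) for od in ods]
    return pq.fit_standard_curve(pairs)


class TestFitStandardCurve:
    def test_exact_log_linear_data_recovers_coefficients(self):
        curve = _exact_curve()
        assert curve.x == pytest.approx(2.0, rel=1e-12)
        assert curve.z == pytest.approx(1.0, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_standard_excluded_but_widens_range(self):
        pairs = [(0.0, 0.001)] + [
            (math.exp(2 * od + 1), od) for od in (-1.0, -0.5, -0.2)
        ]
        curve = pq.fit_standard_curve(pairs)
        assert curve.n_points == 3
        assert curve.conc_range[0] == 0.0
        assert curve.x == pytest.approx(2.0, rel=1e-9)

    def test_degenerate_standards_rejected(self):
        with pytest.raises(FitError, match="degenerate"):
            pq.fit_standard_curve([(1.0, -0.3), (2.0, -0.3), (3.0, -0.3)])

    def test_too_few_nonzero_standards_rejected(self):
        with pytest.raises(FitError, match="at least 3"):
            pq.fit_standard_curve([(0.0, 0.0), (1.0, -0.3), (2.0, -0.6)])

    def test_noiseless_synthetic_plate_fits_tightly(self, corner_bundle, creatinine):
        """The generator's log-linear response makes the standard curve fit
        with R^2 > 0.999 and recover the generating coefficients."""
        b = corner_bundle
        res = pq.run_pipeline(b.image, b.white, b.layout, creatinine)
        assert res.curve.r_squared > 0.999
        assert res.curve.x == pytest.approx(creatinine.dye.slope, rel=0.02)
        assert res.curve.z == pytest.approx(creatinine.dye.intercept, rel=0.02)


class TestPredictConcentration:
    def test_direct_evaluation(self):
        curve = _exact_curve(x=2.0, z=1.0)
        res = pq.predict_concentration(0.0, curve, df=10.0, well_id="B3")
        assert res.cd == pytest.approx(math.e, rel=1e-12)
        assert res.c == pytest.approx(10 * math.e, rel=1e-12)

    def test_unit_dilution_is_identity(self):
        curve = _exact_curve()
        res = pq.predict_concentration(-0.4, curve)
        assert res.c == res.cd

    def test_c_equals_cd_times_df_bitwise(self):
        curve = _exact_curve()
        for od, df in [(-0.8, 7.0), (-0.3, 50.0), (-0.1, 1.0)]:
            res = pq.predict_concentration(od, curve, df=df)
            assert res.c == res.cd * df  # exact, not approx

    def test_fit_predict_round_trip_is_identity_on_standards(self):
        ods = (-0.9, -0.6, -0.45, -0.3, -0.15)
        pairs = [(math.exp(-2.5 * od - 2.0), od) for od in ods]
        curve = pq.fit_standard_curve(pairs)
        for conc, od in pairs:
            assert pq.predict_concentration(od, curve).cd == pytest.approx(
                conc, rel=1e-9
            )

    def test_above_range_flag_recommends_further_dilution(self, creatinine):
        # build a curve from exact data, then ask for a Cd above the range top
        curve = pq.fit_standard_curve(
            [(c, (math.log(c) + 2.0) / -2.5) for c in (0.25, 0.5, 1.0, 1.77)],
            assay=creatinine,
        )
        od_high = curve.od_of(2.5)  # Cd = 2.5 > 1.77
        res = pq.predict_concentration(od_high, curve, df=10.0)
        assert "above-range" in res.flags

    def test_below_range_and_extrapolated_flags(self):
        curve = pq.fit_standard_curve(
            [(c, (math.log(c) + 2.0) / -2.5) for c in (0.25, 0.5, 1.0, 1.77)]
        )
        od_low = curve.od_of(0.01)  # far below the 0.25 bottom standard
        res = pq.predict_concentration(od_low, curve)
        assert "below-range" in res.flags
        assert "extrapolated" in res.flags

    def test_dilution_below_one_rejected(self):
        with pytest.raises(FitError, match=">= 1"):
            pq.predict_concentration(-0.3, _exact_curve(), df=0.5)


class TestReplicateStats:
    @pytest.mark.parametrize(
        "pair, mean, sd",
        [
            ((2.83, 5.31), 4.07, 1.75),
            ((6.00, 6.30), 6.15, 0.21),
            ((7.14, 7.41), 7.28, 0.19),
            ((7.28, 7.64), 7.46, 0.25),
        ],
    )
    def test_duplicate_mean_and_sample_sd(self, pair, mean, sd):
        m, s = pq.replicate_stats(list(pair))
        assert round(m, 2) == mean
        assert round(s, 2) == sd

    def test_n_minus_one_denominator_for_two_replicates(self):
        _, s = pq.replicate_stats([1.0, 3.0])
        assert s == pytest.approx(2.0 / math.sqrt(2.0))

    def test_identical_replicates_have_zero_sd(self):
        assert pq.replicate_stats([4.2, 4.2]) == (4.2, 0.0)

    def test_single_replicate_has_undefined_sd(self):
        mean, sd = pq.replicate_stats([3.3])
        assert mean == 3.3 and sd is None


def _result(well, cd, df, flags=()):
    return pq.AssayResult(
        well_id=well, od=0.0, cd=cd, df=df, c=cd * df, flags=list(flags)
    )


class TestDilutionSeriesReport:
    def test_strong_dilution_minimises_spread(self):
        """Replicate pairs across dilution 10-150: the 100-fold level has
        the smallest SD and is recommended; 10-fold is noisiest."""
        results = []
        for df, pair in [
            (10.0, (2.83, 5.31)),
            (50.0, (6.00, 6.30)),
            (100.0, (7.14, 7.41)),
            (150.0, (7.28, 7.64)),
        ]:
            results += [_result(f"B{i+1}", c / df, df) for i, c in enumerate(pair)]
        table = pq.dilution_series_report(results).set_index("df")
        assert table.loc[100.0, "recommended"]
        assert table["recommended"].sum() == 1
        assert table.loc[10.0, "sd"] == table["sd"].max()

    def test_ties_break_toward_lowest_dilution(self):
        # identical final-concentration pairs at both levels: equal SDs
        results = []
        for df in (10.0, 50.0):
            results += [
                _result(f"C{df:.0f}a", 5.0 / df, df),
                _result(f"C{df:.0f}b", 5.2 / df, df),
            ]
        table = pq.dilution_series_report(results).set_index("df")
        assert table.loc[10.0, "recommended"]
        assert not table.loc[50.0, "recommended"]

    def test_out_of_range_levels_excluded_from_recommendation(self):
        results = [
            _result("D1", 0.30, 10.0),
            _result("D2", 0.34, 10.0),
            # over-diluted: below the detection limit, tiny SD but excluded
            _result("D3", 0.01, 200.0, flags=["below-range"]),
            _result("D4", 0.0101, 200.0, flags=["below-range"]),
        ]
        table = pq.dilution_series_report(results).set_index("df")
        assert table.loc[10.0, "recommended"]
        assert not table.loc[200.0, "recommended"]
        assert not table.loc[200.0, "in_range"]


class TestCurvatureSensitivity:
    def test_sensitivity_increases_with_concentration(self, creatinine):
        """A fixed intensity perturbation moves the computed concentration
        more at the high end of the curve than mid-range."""
        curve = pq.fit_standard_curve(
            [(c, (math.log(c) - creatinine.dye.intercept) / creatinine.dye.slope)
             for c in creatinine.standards[1:]],
            assay=creatinine,
        )
        concs = np.linspace(0.3, 1.7, 10)
        sens = [
            pq.concentration_sensitivity(curve, c, incident=250.0) for c in concs
        ]
        assert np.all(np.diff(sens) > 0)

    def test_finite_difference_agrees(self, creatinine):
        curve = pq.fit_standard_curve(
            [(c, (math.log(c) - creatinine.dye.intercept) / creatinine.dye.slope)
             for c in creatinine.standards[1:]]
        )
        incident = 250.0
        c0 = 1.0
        od0 = curve.od_of(c0)
        y0 = incident * 10.0**od0
        dy = 1e-6
        od1 = pq.optical_density(y0 + dy, incident)
        c1 = curve.predict_cd(od1)
        fd = abs(c1 - c0) / dy
        assert pq.concentration_sensitivity(curve, c0, incident) == pytest.approx(
            fd, rel=1e-4
        )
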