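"""OD600-to-DCW conversion, standard curves and titre arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from operon_doe import errors
from operon_doe.quantify import (
    SampleMeasurement,
    fit_standard_curve,
    od_to_dcw,
    peak_area_to_titre,
    quantify_table,
    screen_summary,
)


class TestOdToDcw:
    def test_ratio_is_0p36_g_per_litre(self):
        assert od_to_dcw(1.0, 1000.0) == pytest.approx(0.36)

    def test_zero_od_zero_mass(self):
        assert od_to_dcw(0.0, 1.0) == 0.0

    def test_linear_in_od(self):
        assert od_to_dcw(2.5, 1.0) == pytest.approx(2.5 * od_to_dcw(1.0, 1.0))

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            od_to_dcw(-0.1, 1.0)

    @given(st.floats(min_value=0, max_value=50, allow_nan=False),
           st.floats(min_value=0.1, max_value=10))
    def test_homogeneous(self, od, a):
        assert od_to_dcw(a * od, 1.0) == pytest.approx(a * od_to_dcw(od, 1.0))


class TestStandardCurve:
    def test_exact_line_recovered(self):
        curve = fit_standard_curve([0.0, 1.0, 2.0], [0.0, 10.0, 20.0])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.min_nonzero_conc == 1.0

    def test_residuals_orthogonal_to_fit(self):
        rng = np.random.default_rng(7)
        conc = np.linspace(0, 5, 12)
        area = 3.0 + 8.0 * conc + rng.normal(0, 0.5, 12)
        curve = fit_standard_curve(conc, area)
        fitted = curve.slope * conc + curve.intercept
        resid = area - fitted
        assert float(resid @ fitted) == pytest.approx(0.0, abs=1e-8)

    def test_single_point_underdetermined(self):
        with pytest.raises(errors.UnderdeterminedError):
            fit_standard_curve([1.0], [10.0])
        with pytest.raises(errors.UnderdeterminedError):
            fit_standard_curve([1.0, 1.0], [10.0, 11.0])

    def test_through_origin_variant(self):
        curve = fit_standard_curve([1.0, 2.0], [11.0, 19.0],
                                   through_origin=True)
        assert curve.intercept == 0.0
        assert curve.slope == pytest.approx((11 + 38) / 5)


class TestTitre:
    def _curve(self):
        return fit_standard_curve([0.0, 1.0, 5.0], [0.0, 10.0, 50.0])

    def test_unit_arithmetic(self):
        # area 50 / slope 10 -> 5 mg/mL; x 1 mL extract -> 5 mg;
        # OD 1.0, 1 mL culture -> 0.36 mg DCW = 3.6e-4 g; titre = 5/3.6e-4
        m = SampleMeasurement("S001", 1, od600=1.0, peak_area_471=50.0)
        rec = peak_area_to_titre(m, self._curve())
        assert rec.dcw_g == pytest.approx(3.6e-4)
        assert rec.titre_mg_per_gdcw == pytest.approx(5.0 / 3.6e-4)
        assert rec.detected

    def test_area_at_intercept_not_detected(self):
        curve = fit_standard_curve([0.0, 1.0], [4.0, 14.0])
        m = SampleMeasurement("S001", 1, od600=1.0, peak_area_471=4.0)
        rec = peak_area_to_titre(m, curve)
        assert rec.titre_mg_per_gdcw == 0.0
        assert not rec.detected

    def test_area_below_intercept_clamped_with_warning(self, caplog):
        import logging
        curve = fit_standard_curve([0.0, 1.0], [4.0, 14.0])
        m = SampleMeasurement("S001", 1, od600=1.0, peak_area_471=2.0)
        with caplog.at_level(logging.WARNING):
            rec = peak_area_to_titre(m, curve)
        assert rec.titre_mg_per_gdcw == 0.0 and not rec.detected
        assert any("clamping" in r.message for r in caplog.records)

    def test_zero_dcw_with_signal_is_undefined(self):
        m = SampleMeasurement("S001", 1, od600=0.0, peak_area_471=50.0)
        with pytest.raises(errors.UndefinedTitreError):
            peak_area_to_titre(m, self._curve())

    def test_channel_450_selectable(self):
        m = SampleMeasurement("S001", 1, od600=1.0,
                              peak_area_450=50.0, peak_area_471=0.0)
        rec = peak_area_to_titre(m, self._curve(), channel=450)
        assert rec.detected

    @given(st.floats(min_value=0.5, max_value=20))
    def test_titre_invariant_to_area_rescaling(self, scale):
        # scaling all standard areas and the sample area together cancels
        base = fit_standard_curve([0.0, 1.0, 5.0], [2.0, 12.0, 52.0])
        scaled = fit_standard_curve([0.0, 1.0, 5.0],
                                    [2.0 * scale, 12.0 * scale, 52.0 * scale])
        m1 = SampleMeasurement("S", 1, od600=1.0, peak_area_471=30.0)
        m2 = SampleMeasurement("S", 1, od600=1.0, peak_area_471=30.0 * scale)
        r1 = peak_area_to_titre(m1, base)
        r2 = peak_area_to_titre(m2, scaled)
        assert r2.titre_mg_per_gdcw == pytest.approx(r1.titre_mg_per_gdcw)


class TestScreenSummary:
    def test_worked_example_counts(self):
        # 45 constructs never grew, 2 grew without product, 41 produced
        rows = []
        for i in range(45):
            rows.append({"stitch_id": f"N{i}", "dcw_g": 0.0, "detected": False})
        for i in range(2):
            rows.append({"stitch_id": f"G{i}", "dcw_g": 7e-4, "detected": False})
        for i in range(41):
            rows.append({"stitch_id": f"P{i}", "dcw_g": 7e-4, "detected": True})
        summary = screen_summary(pd.DataFrame(rows))
        assert summary.n_constructs == 88
        assert summary.producers == 41
        assert summary.no_growth == 45
        assert summary.no_product == 2
        assert summary.failure_rate_pct == 53

    def test_replicates_collapse_to_constructs(self):
        df = pd.DataFrame({
            "stitch_id": ["A", "A", "B", "B"],
            "dcw_g": [7e-4, 7e-4, 0.0, 0.0],
            "detected": [True, False, False, False],
        })
        summary = screen_summary(df)
        assert summary.n_constructs == 2
        assert summary.producers == 1 and summary.no_growth == 1


def test_quantify_table_round_trip():
    curve = fit_standard_curve([0.0, 0.001, 0.002], [0.0, 10.0, 20.0])
    meas = pd.DataFrame({
        "stitch_id": ["S1", "S2"],
        "replicate": [1, 1],
        "od600": [2.0, 0.0],
        "peak_area_450": [8.0, 0.0],
        "peak_area_471": [10.0, 0.0],
    })
    out = quantify_table(meas, curve)
    assert list(out.columns) == ["stitch_id", "replicate", "dcw_g",
                                 "titre_mg_per_gdcw", "detected"]
    # S1: conc 0.001 mg/mL, mass 0.001 mg, dcw 0.36*2*0.001 g
    assert out.loc[0, "titre_mg_per_gdcw"] == pytest.approx(0.001 / 7.2e-4)
    assert not out.loc[1, "detected"]
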