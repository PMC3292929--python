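"""The three-parameter logistic decay: transform, binning, fitting,
prediction and the probability surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from careseek.decay import (
    BinnedAttendance,
    DecayResults,
    DistanceDecayModel,
    bin_attendance,
    fit_logistic3,
    logistic3,
    predict_probability,
    probability_surface,
    transform_time,
)
from careseek.grids import GridSpec, Raster
from careseek.traveltime import TravelTimeSurface

FIG2 = dict(C=0.766, A=3.736, B=-0.609)


def fig2_results() -> DecayResults:
    return DecayResults.from_params(**FIG2, transform="log10")


class TestTransformTime:
    def test_log10_of_one_minute_is_zero(self):
        assert transform_time(1.0, "log10") == 0.0

    def test_zero_floored_to_one_minute(self):
        assert transform_time(0.0, "log10") == transform_time(1.0, "log10")

    def test_three_hours_log10(self):
        assert transform_time(180.0, "log10") == pytest.approx(2.2553, abs=1e-4)

    def test_natural_log_and_identity(self):
        assert transform_time(np.e, "ln") == pytest.approx(1.0)
        assert transform_time(42.0, "identity") == 42.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transform_time(-1.0)


class TestBinAttendance:
    def test_single_bin_recovers_overall_proportion(self):
        t = np.array([1.0, 10.0, 100.0, 30.0])
        a = np.array([1, 0, 0, 1])
        b = bin_attendance((t, a), n_bins=1)
        assert b.n_bins == 1
        assert b.p_hat[0] == 0.5
        assert b.n[0] == 4

    def test_quantile_bins_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1.0, 400.0, 401)
        a = rng.integers(0, 2, 401)
        b = bin_attendance((t, a), n_bins=15, scheme="quantile")
        assert b.n.sum() == 401
        assert b.n.max() - b.n.min() <= 1

    def test_counts_partition_records(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.0, 500.0, 257)
        a = rng.integers(0, 2, 257)
        for scheme in ("quantile", "equal-width"):
            b = bin_attendance((t, a), n_bins=12, scheme=scheme)
            assert b.n.sum() == 257
            assert np.all((b.p_hat >= 0) & (b.p_hat <= 1))
            assert np.all(np.diff(b.x_mean) > 0)

    def test_non_binary_attendance_rejected(self):
        with pytest.raises(ValueError):
            bin_attendance((np.array([1.0, 2.0]), np.array([0.5, 1.0])))


class TestFit:
    def test_exact_recovery_on_noise_free_curve(self):
        x = np.linspace(0.5, 3.5, 10)
        p = logistic3(x, 0.5, 2.0, -0.5)
        binned = BinnedAttendance(
            edges=np.linspace(0.4, 3.6, 11), x_mean=x, p_hat=p,
            n=np.full(10, 100), transform="log10",
        )
        res = fit_logistic3(binned)
        assert res.params == pytest.approx([0.5, 2.0, -0.5], abs=1e-6)
        assert res.ssr == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        x = np.array([0.5, 1.5, 2.5])
        binned = BinnedAttendance(
            edges=np.array([0.0, 1.0, 2.0, 3.0]), x_mean=x,
            p_hat=logistic3(x, 0.5, 2.0, -0.5), n=np.full(3, 10),
        )
        with pytest.raises(ValueError, match="at least 4"):
            fit_logistic3(binned)

    def test_ssr_equals_sum_of_squared_bin_residuals(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.2, 3.0, 15)
        p = np.clip(logistic3(x, 0.7, 2.0, -0.6) + rng.normal(0, 0.02, 15), 0, 1)
        binned = BinnedAttendance(
            edges=np.linspace(0.1, 3.1, 16), x_mean=x, p_hat=p, n=np.full(15, 50),
        )
        res = fit_logistic3(binned)
        resid = logistic3(x, *res.params) - p
        assert res.ssr == pytest.approx(float(np.sum(resid**2)), rel=1e-9)
        assert res.rse == pytest.approx(np.sqrt(res.ssr / 12), rel=1e-9)

    def test_c_fixed_at_one_matches_two_parameter_logistic(self):
        # with C pinned to 1 the model is the standard logistic; an
        # independent curve_fit on the same bins must agree
        rng = np.random.default_rng(8)
        x = np.linspace(0.0, 4.0, 12)
        p = np.clip(
            1.0 / (1.0 + np.exp((2.0 - x) / -0.7)) + rng.normal(0, 0.01, 12), 0, 1
        )
        binned = BinnedAttendance(
            edges=np.linspace(-0.1, 4.1, 13), x_mean=x, p_hat=p, n=np.full(12, 80),
        )
        params = fit_logistic3(binned, fix_C=1.0).params
        ref, _ = curve_fit(
            lambda xx, A, B: 1.0 / (1.0 + np.exp((A - xx) / B)),
            x, p, p0=[2.0, -0.5], maxfev=10_000,
        )
        assert params[1] == pytest.approx(ref[0], abs=1e-5)
        assert params[2] == pytest.approx(ref[1], abs=1e-5)

    def test_monotone_increasing_pattern_is_flagged(self):
        x = np.linspace(0.0, 3.0, 8)
        p = np.linspace(0.1, 0.9, 8)  # attendance rising with travel time
        binned = BinnedAttendance(
            edges=np.linspace(-0.1, 3.1, 9), x_mean=x, p_hat=p, n=np.full(8, 30),
        )
        with pytest.warns(UserWarning, match="increase"):
            res = fit_logistic3(binned)
        assert res.diag["monotone_increasing"]

    def test_survey_recovery_at_large_n(self):
        # one large synthetic survey: C is tightly identified even though
        # the design only covers the curve's upper shoulder
        rng = np.random.default_rng(123)
        x = rng.uniform(0.0, 2.6, 50_000)
        t = 10.0**x
        a = (rng.uniform(size=x.size) < logistic3(x, **FIG2)).astype(int)
        res = DistanceDecayModel(t, a).fit()
        assert abs(res.C - FIG2["C"]) <= 0.02
        assert np.isfinite(res.bse).all()

    def test_from_dataframe_keeps_fever_cases_only(self):
        df = pd.DataFrame(
            {
                "travel_time_min": [5.0, 10.0, 20.0, 40.0],
                "fever": [1, 1, 0, 1],
                "attended_public": [1.0, 0.0, np.nan, 1.0],
            }
        )
        m = DistanceDecayModel.from_dataframe(df)
        assert m.nobs == 3


class TestPredict:
    def test_inflection_point_is_half_C(self):
        res = fig2_results()
        t_inflect = 10.0 ** FIG2["A"]
        assert predict_probability(res, t_inflect) == pytest.approx(FIG2["C"] / 2)

    def test_approaches_C_from_below_at_floor(self):
        res = fig2_results()
        p0 = predict_probability(res, 0.0)
        assert p0 < FIG2["C"]
        assert p0 == pytest.approx(FIG2["C"], abs=0.002)

    def test_three_hours_probability(self):
        # attendance stays high out to 180 minutes under this model
        assert predict_probability(fig2_results(), 180.0) == pytest.approx(
            0.704, abs=5e-4
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        t1=st.floats(min_value=0.0, max_value=1e4),
        t2=st.floats(min_value=0.0, max_value=1e4),
    )
    def test_monotone_non_increasing_and_bounded(self, t1, t2):
        res = fig2_results()
        lo, hi = sorted((t1, t2))
        p_lo = predict_probability(res, lo)
        p_hi = predict_probability(res, hi)
        assert 0.0 <= p_hi <= p_lo <= FIG2["C"]

    def test_infinite_time_limit_is_zero(self):
        assert predict_probability(fig2_results(), np.inf) == 0.0


class TestProbabilitySurface:
    def test_constant_time_gives_constant_surface(self):
        grid = GridSpec(4, 4)
        tt = TravelTimeSurface(Raster(np.full((4, 4), 60.0), grid))
        p = probability_surface(fig2_results(), tt)
        assert np.all(p.values == p.values[0, 0])

    def test_unreached_cells_get_zero(self):
        grid = GridSpec(4, 4)
        m = np.full((4, 4), 30.0)
        m[3, 3] = np.inf
        p = probability_surface(fig2_results(), TravelTimeSurface(Raster(m, grid)))
        assert p.values[3, 3] == 0.0
        assert p.values[0, 0] > 0.7

    def test_facility_cell_evaluates_at_floor(self):
        grid = GridSpec(4, 4)
        m = np.zeros((4, 4))
        p = probability_surface(fig2_results(), TravelTimeSurface(Raster(m, grid)))
        assert p.values[0, 0] == pytest.approx(
            predict_probability(fig2_results(), 1.0)
        )


class TestSummaryAndSerialization:
    def test_summary_names_all_coefficients(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.0, 2.6, 5000)
        a = (rng.uniform(size=x.size) < logistic3(x, **FIG2)).astype(int)
        res = DistanceDecayModel(10.0**x, a).fit()
        text = res.summary()
        for name in ("C", "A", "B", "SSR", "RSE"):
            assert name in text

    def test_json_roundtrip(self, tmp_path):
        res = fig2_results()
        res.to_json(tmp_path / "m.json")
        back = DecayResults.from_json(tmp_path / "m.json")
        assert (back.C, back.A, back.B) == (res.C, res.A, res.B)
        assert back.transform == "log10"
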