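"""Limiting-dilution estimators: analytic recovery, oracle agreement, bias."""

import numpy as np
import pytest

from igscreen.lda import (
    BoundaryEstimateWarning,
    DilutionSeries,
    LimitingDilutionEstimator,
    NoCrossingError,
    UndefinedFrequencyError,
    aggregate_frequency,
    estimate_frequency_crossing37,
    estimate_frequency_mle,
    expected_nonreactive_percent,
    nonreactive_fractions,
    single_hit_gof,
)
from igscreen.synth import gen_dilution_series

from conftest import noise_free_series


class TestSeriesAndFractions:
    def test_fraction_arithmetic(self):
        s = DilutionSeries.from_arrays([500], [20], [10])
        assert nonreactive_fractions(s)[0] == 0.5

    @pytest.mark.parametrize("k,expected", [(20, 1.0), (0, 0.0)])
    def test_fraction_extremes(self, k, expected):
        s = DilutionSeries.from_arrays([500], [20], [k])
        assert nonreactive_fractions(s)[0] == expected

    def test_row_order_and_duplicate_doses_are_immaterial(self):
        a = DilutionSeries.from_arrays([500, 125, 250], [24, 24, 24], [20, 23, 22])
        b = DilutionSeries.from_arrays([125, 250, 250, 500], [24, 12, 12, 24],
                                       [23, 11, 11, 20])
        fa = estimate_frequency_mle(a).frequency
        fb = estimate_frequency_mle(b).frequency
        assert fa == pytest.approx(fb, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            DilutionSeries.from_arrays([0], [10], [5])
        with pytest.raises(ValueError):
            DilutionSeries.from_arrays([100], [10], [11])
        with pytest.raises(ValueError):
            DilutionSeries.from_arrays([100], [0], [0])


class TestCrossing37:
    def test_single_dose_exactly_at_criterion(self):
        s = DilutionSeries.from_arrays([1000], [10**6],
                                       [round(np.exp(-1) * 10**6)])
        est = estimate_frequency_crossing37(s)
        assert 1 / est.frequency == pytest.approx(1000, rel=1e-4)

    def test_recovers_patient_design_frequency_on_noise_free_curve(self):
        # doses 125-2,500 from f = 1/1,790: the crossing criterion inverts
        # the curve to within 1 %
        est = estimate_frequency_crossing37(noise_free_series(1 / 1790))
        assert 1 / est.frequency == pytest.approx(1790, rel=0.01)
        assert est.one_in == 1790

    def test_no_crossing_raises_and_points_to_mle(self):
        s = DilutionSeries.from_arrays([125, 250], [24, 24], [23, 22])
        with pytest.raises(NoCrossingError, match="mle"):
            estimate_frequency_crossing37(s)

    def test_agrees_with_mle_on_noise_free_lattice(self):
        # the crossing criterion needs the 37 % dose (1/f cells) inside the
        # plating range, so the grid extends for the rarest frequency
        for f in (1 / 500, 1 / 1790, 1 / 2430, 1 / 5000):
            doses = (125, 250, 500, 1000, 2500) if 1 / f <= 2500 else \
                (500, 1000, 2500, 5000, 10000)
            s = noise_free_series(f, doses=doses)
            fc = estimate_frequency_crossing37(s).frequency
            fm = estimate_frequency_mle(s).frequency
            assert fc == pytest.approx(fm, rel=0.01)
            assert fc == pytest.approx(f, rel=0.01)


class TestMLE:
    def test_single_dose_closed_form(self):
        s = DilutionSeries.from_arrays([500], [20], [15])
        est = estimate_frequency_mle(s)
        assert est.frequency == pytest.approx(-np.log(0.75) / 500, rel=1e-8)
        assert 1 / est.frequency == pytest.approx(1738, abs=1)

    def test_matches_dense_grid_search_oracle(self):
        rng = np.random.default_rng(123)
        grid = np.logspace(-6, -1, 30_000)
        for _ in range(10):
            f_true = rng.uniform(1 / 5000, 1 / 400)
            series, _ = gen_dilution_series(f_true, seed=int(rng.integers(2**31)))
            est = estimate_frequency_mle(series)
            # brute-force oracle: maximize the same likelihood over a dense grid
            n, m, k = series.dose, series.tested, series.nonreactive
            ll = (-np.outer(grid, (k * n).sum() * np.ones(1)).ravel()
                  + np.sum((m - k) * np.log1p(-np.exp(-np.outer(grid, n))), axis=1))
            f_oracle = grid[np.argmax(ll)]
            assert est.frequency == pytest.approx(f_oracle, rel=0.005)

    def test_profile_ci_brackets_estimate(self):
        series, _ = gen_dilution_series(1 / 1790, seed=8)
        est = estimate_frequency_mle(series)
        assert est.ci_low <= est.frequency <= est.ci_high

    def test_all_nonreactive_is_zero_boundary_with_upper_ci(self):
        s = DilutionSeries.from_arrays([125, 250], [24, 24], [24, 24])
        with pytest.warns(BoundaryEstimateWarning):
            est = estimate_frequency_mle(s)
        assert est.frequency == 0.0
        assert est.ci_low == 0.0 and est.ci_high > 0

    def test_all_reactive_is_upper_boundary(self):
        s = DilutionSeries.from_arrays([1000, 2500], [24, 24], [0, 0])
        with pytest.warns(BoundaryEstimateWarning):
            est = estimate_frequency_mle(s)
        assert est.ci_high == 1.0 and est.ci_low > 0

    def test_bootstrap_ci_available_and_seeded(self):
        series, _ = gen_dilution_series(1 / 1790, seed=8)
        a = estimate_frequency_mle(series, ci_method="bootstrap", n_boot=100, seed=1)
        b = estimate_frequency_mle(series, ci_method="bootstrap", n_boot=100, seed=1)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < a.frequency < a.ci_high


class TestEstimatorClass:
    def test_sklearn_interface(self):
        est = LimitingDilutionEstimator(method="crossing37")
        assert est.get_params()["method"] == "crossing37"
        est.set_params(method="mle")
        fitted = est.fit(noise_free_series(1 / 1790).to_dataframe())
        assert fitted.frequency_ == pytest.approx(1 / 1790, rel=0.01)
        assert fitted.predict([1790])[0] == pytest.approx(np.exp(-1), rel=0.01)


class TestAggregateFrequency:
    def test_healthy_cohort_arithmetic(self):
        est = aggregate_frequency(12, 600, 500)
        assert 1 / est.frequency == pytest.approx(25_000)

    def test_saturation_bound(self):
        est = aggregate_frequency(600, 600, 500)
        assert 1 / est.frequency == pytest.approx(500)

    def test_patient_cohort_arithmetic(self):
        est = aggregate_frequency(504, 1800, 500)
        assert 1 / est.frequency == pytest.approx(1785.7, abs=0.1)
        assert est.one_in == 1790  # nearest-10 reporting

    def test_zero_positives_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            aggregate_frequency(0, 600, 500)

    def test_underestimates_when_multiclone_wells_collapse(self):
        # simulate wells at high f*cells: multi-clone wells count once, so the
        # aggregate estimate falls below the generating frequency
        rng = np.random.default_rng(4)
        f_true, cells, n_wells = 1 / 400, 500, 4000
        clones = rng.binomial(cells, f_true, size=n_wells)
        n_pos = int((clones > 0).sum())
        est = aggregate_frequency(n_pos, n_wells, cells)
        assert est.frequency < f_true


class TestGoodnessOfFit:
    def test_single_dose_not_applicable(self):
        s = DilutionSeries.from_arrays([500], [24], [12])
        est = estimate_frequency_mle(s)
        assert not single_hit_gof(s, est).applicable

    def test_model_data_fit_is_not_rejected(self):
        series = noise_free_series(1 / 1790, wells=10_000)
        est = estimate_frequency_mle(series)
        gof = single_hit_gof(series, est)
        assert gof.applicable and gof.p_value > 0.2

    def test_saturating_multihit_pattern_is_detected(self):
        # wells need three reactive cells: strong curvature vs exp(-f*n)
        rng = np.random.default_rng(2)
        doses = np.array([125, 250, 500, 1000, 2500])
        f = 1 / 300
        p0 = np.exp(-f * doses) * (1 + f * doses + (f * doses) ** 2 / 2)
        hits = 0
        for _ in range(50):
            k = rng.binomial(96, p0)
            s = DilutionSeries.from_arrays(doses, [96] * 5, k)
            gof = single_hit_gof(s, estimate_frequency_mle(s))
            hits += gof.p_value < 0.05
        assert hits / 50 > 0.8


class TestExpectedNonreactive:
    def test_reciprocal_dose_gives_37_percent(self):
        pct = expected_nonreactive_percent(1 / 1790, 1790)
        assert round(pct) == 37

    def test_monotone_in_dose(self):
        f = 1 / 1000
        doses = [100, 500, 1000, 5000]
        vals = [expected_nonreactive_percent(f, d) for d in doses]
        assert vals == sorted(vals, reverse=True)
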