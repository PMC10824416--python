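"""Critical point, penetration ratio, mean error and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micpsim import (DomainError, Profile, UndefinedMetricError,
                     column_average_conductivity, critical_point, mean_error,
                     mean_error_series, metrics_table, penetration_ratio,
                     profile_summaries, theoretical_ammonium)


class TestCriticalPoint:
    def test_all_zero_profile(self):
        p = Profile(positions=[0.1, 0.3, 0.5], values=[0.0, 0.0, 0.0], length=0.5)
        assert critical_point(p, 1.0) == (0.0, 0.0)

    def test_profile_above_threshold_everywhere_penetrates_fully(self):
        p = Profile(positions=np.linspace(0.05, 0.95, 10),
                    values=np.full(10, 5.0), length=1.0)
        assert critical_point(p, 1.0) == (1.0, 100.0)

    def test_interpolated_crossing(self):
        # linear segment from 1.38 at x=0.6 to 0.38 at x=0.7 crosses
        # epsilon=1 at x = 0.638 -> 63.8% of a 1 m column
        p = Profile(positions=[0.2, 0.6, 0.7], values=[2.0, 1.38, 0.38],
                    length=1.0)
        loc, ratio = critical_point(p, 1.0)
        assert loc == pytest.approx(0.638, rel=1e-12)
        assert ratio == pytest.approx(63.8, rel=1e-12)

    @given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_under_pointwise_decrease(self, values):
        x = np.linspace(0.1, 1.0, len(values))
        p_hi = Profile(positions=x, values=values, length=1.0)
        lowered = [v * 0.5 for v in values]
        p_lo = Profile(positions=x, values=lowered, length=1.0)
        eps = 1.0
        assert critical_point(p_lo, eps)[1] <= critical_point(p_hi, eps)[1]

    def test_epsilon_and_profile_validation(self):
        p = Profile(positions=[0.1, 0.2], values=[1.0, 1.0])
        with pytest.raises(DomainError):
            critical_point(p, 0.0)
        with pytest.raises(DomainError):
            Profile(positions=[], values=[])
        with pytest.raises(DomainError):
            Profile(positions=[0.2, 0.1], values=[1.0, 1.0])


class TestMeanError:
    def test_equal_means_give_zero(self):
        assert mean_error(3.0, 3.0) == 0.0

    def test_twenty_percent_increase(self):
        assert mean_error(1.2, 1.0) == pytest.approx(20.0)

    def test_sign_flip_on_argument_swap(self):
        d1 = mean_error(1.2, 1.0)
        d2 = mean_error(1.0, 1.2)
        assert d1 > 0.0 > d2
        # antisymmetric up to the change of denominator
        assert d2 == pytest.approx(-100.0 * (1.2 - 1.0) / 1.2)

    def test_zero_reference_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mean_error(1.0, 0.0)

    def test_series_masks_zero_reference(self):
        out = mean_error_series([1.0, 2.4], [0.0, 2.0])
        assert np.isnan(out[0])
        assert out[1] == pytest.approx(20.0)


class TestTheoreticalAmmonium:
    def test_stoichiometric_factor_of_two(self):
        assert theoretical_ammonium(0.0) == 0.0
        assert theoretical_ammonium(1.0) == 2.0
        with pytest.raises(DomainError):
            theoretical_ammonium(-1.0)


class TestProfileSummaries:
    def test_constant_profile(self):
        p = Profile(positions=np.linspace(0.05, 0.95, 10),
                    values=np.full(10, 7.0), length=1.0)
        mean, vmax, _ = profile_summaries(p)
        assert mean == pytest.approx(7.0)
        assert vmax == 7.0

    def test_linear_ramp_has_half_mean(self):
        n = 200
        x = (np.arange(n) + 0.5) / n
        p = Profile(positions=x, values=10.0 * x, length=1.0)
        mean, vmax, argmax = profile_summaries(p)
        assert mean == pytest.approx(5.0, rel=1e-3)
        assert vmax == pytest.approx(10.0 * x[-1])
        assert argmax == pytest.approx(x[-1])


class TestColumnAverageConductivity:
    def test_harmonic_mean_dominated_by_clogged_stretch(self):
        assert column_average_conductivity([1.0, 1.0]) == pytest.approx(1.0)
        k = column_average_conductivity([1e-6, 1.0])
        assert k == pytest.approx(2e-6, rel=1e-4)
        with pytest.raises(DomainError):
            column_average_conductivity([0.0, 1.0])


class TestResultMetrics:
    def test_penetration_and_table_from_simulation(self, mini_result):
        ratio = penetration_ratio(mini_result, "bacl", "B_end")
        assert 0.0 < ratio <= 100.0
        table = metrics_table(mini_result)
        assert set(table.columns) == {"scenario", "species", "phase",
                                      "metric", "value"}
        rows = table[(table.species == "bacl")
                     & (table.phase == "B_end")
                     & (table.metric == "penetration_ratio_pct")]
        assert len(rows) == 1
        assert rows.value.iloc[0] == pytest.approx(ratio)
        # carbonate appears once cementation has run
        assert (table.species == "caco3").any()

    def test_threshold_sensitivity_is_monotone(self, mini_result):
        ratios = [penetration_ratio(mini_result, "bacl", "B_end", epsilon_rel=e)
                  for e in (1e-2, 1e-3, 1e-4)]
        assert ratios[0] <= ratios[1] <= ratios[2]
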