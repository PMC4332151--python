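import numpy as np
import pytest

import photoclock as pc
from photoclock.observables import (NoPeakError, Timeseries, auc, cost,
                                    count_local_maxima, denormalise,
                                    fold_change, normalise_to_peak, peak_time,
                                    phase_advance)


def ts(zt, value, label="x"):
    return Timeseries(np.asarray(zt, float), np.asarray(value, float), label)


@pytest.fixture
def sine():
    zt = np.arange(0, 24.0001, 0.05)
    return ts(zt, 1.0 + np.sin(2 * np.pi * zt / 24.0))


class TestNormalise:
    def test_self_normalised_peaks_at_one(self, sine):
        assert normalise_to_peak(sine).value.max() == pytest.approx(1.0)

    def test_idempotent(self, sine):
        once = normalise_to_peak(sine)
        twice = normalise_to_peak(once)
        assert np.allclose(once.value, twice.value)

    def test_reference_normalisation_preserves_ratios(self, sine):
        mutant = ts(sine.zt, 0.3 * sine.value)
        n_mut = normalise_to_peak(mutant, ref=sine)
        n_wt = normalise_to_peak(sine)
        mask = n_wt.value > 1e-6
        assert np.allclose(n_mut.value[mask] / n_wt.value[mask], 0.3)

    def test_round_trip_exact(self, sine):
        back = denormalise(normalise_to_peak(sine))
        assert np.allclose(back.value, sine.value, rtol=1e-12, atol=0)

    def test_zero_reference_rejected(self):
        z = ts([0, 1, 2], [0, 0, 0])
        with pytest.raises(ValueError):
            normalise_to_peak(z)


class TestAUC:
    def test_constant_one_gives_window_length(self):
        s = ts(np.linspace(0, 24, 49), np.ones(49))
        assert auc(s) == pytest.approx(24.0)

    def test_one_plus_sine_over_period(self, sine):
        assert auc(sine) == pytest.approx(24.0, abs=1e-3)

    def test_linearity_in_scale(self, sine):
        assert auc(ts(sine.zt, 3.5 * sine.value)) == pytest.approx(
            3.5 * auc(sine), rel=1e-12)

    def test_subwindow(self, sine):
        full = auc(sine)
        assert auc(sine, (0, 12)) + auc(sine, (12, 24)) == pytest.approx(full)

    def test_degenerate_window_rejected(self, sine):
        with pytest.raises(ValueError):
            auc(sine, (5, 5))
        with pytest.raises(ValueError):
            auc(sine, (-1, 25))


class TestPeakTime:
    def test_exact_sample_maximum(self):
        # symmetric neighbours: the quadratic refinement keeps the sample ZT
        s = ts([0, 1, 2, 3], [0, 1, 0, -0.5])
        assert peak_time(s) == pytest.approx(1.0, abs=1e-9)

    def test_parabola_vertex_recovered(self):
        zt = np.linspace(0, 24, 97)
        vertex = 9.37
        s = ts(zt, -(zt - vertex) ** 2)
        assert peak_time(s) == pytest.approx(vertex, abs=1e-6)

    def test_tie_breaks_to_earliest(self):
        s = ts([0, 1, 2, 3, 4], [0, 1, 0, 1, 0])
        assert peak_time(s) <= 1.0

    def test_constant_series_has_no_peak(self):
        with pytest.raises(NoPeakError):
            peak_time(ts([0, 1, 2], [1, 1, 1]))


class TestPhaseAdvance:
    def test_identical_series_zero(self, sine):
        assert phase_advance(sine, sine) == 0.0

    def test_constructed_shift_recovered(self, sine):
        shifted = ts(sine.zt, 1.0 + np.sin(2 * np.pi * (sine.zt + 3.0) / 24.0))
        assert phase_advance(shifted, sine) == pytest.approx(3.0, abs=0.1)

    def test_antisymmetric(self, sine):
        shifted = ts(sine.zt, 1.0 + np.sin(2 * np.pi * (sine.zt + 5.0) / 24.0))
        assert phase_advance(sine, shifted) == pytest.approx(
            -phase_advance(shifted, sine), abs=1e-9)

    def test_wraps_into_half_open_interval(self, sine):
        shifted = ts(sine.zt, 1.0 + np.sin(2 * np.pi * (sine.zt - 20.0) / 24.0))
        adv = phase_advance(shifted, sine)
        assert -12.0 < adv <= 12.0
        assert adv == pytest.approx(4.0, abs=0.1)


class TestCountLocalMaxima:
    def test_constant_has_none(self):
        assert count_local_maxima(ts(np.linspace(0, 24, 50), np.ones(50))) == 0

    def test_single_sine_period_has_one(self, sine):
        assert count_local_maxima(sine) == 1

    def test_two_bumps_counted_circularly(self):
        zt = np.linspace(0, 24, 481)
        y = np.exp(-((zt - 0.5) % 24 - 0) ** 2) + 0.5 * np.exp(-(zt - 14) ** 2)
        assert count_local_maxima(ts(zt, y), 0.1) == 2

    def test_prominence_threshold_filters_ripple(self):
        zt = np.linspace(0, 24, 481)
        y = np.sin(2 * np.pi * zt / 24) + 0.01 * np.sin(2 * np.pi * zt)
        assert count_local_maxima(ts(zt, y), 0.1) == 1

    def test_invalid_prominence_rejected(self, sine):
        with pytest.raises(ValueError):
            count_local_maxima(sine, 0.0)


class TestFoldChange:
    def test_equal_series_is_one(self, sine):
        for mode in ("auc", "peak"):
            assert fold_change(sine, sine, mode) == pytest.approx(1.0)
        assert fold_change(sine, sine, "at_zt", zt=6.0) == pytest.approx(1.0)

    def test_doubling_is_two_under_every_mode(self, sine):
        a = ts(sine.zt, 2 * sine.value)
        for mode in ("auc", "peak"):
            assert fold_change(a, sine, mode) == pytest.approx(2.0)
        assert fold_change(a, sine, "at_zt", zt=0.0) == pytest.approx(2.0)

    def test_zero_denominator_rejected(self, sine):
        zero = ts(sine.zt, np.zeros_like(sine.value))
        with pytest.raises(ZeroDivisionError):
            fold_change(sine, zero, "peak")


class TestCost:
    def test_identical_sets_cost_zero(self, sine):
        total, per = cost({"a": sine}, {"a": sine})
        assert total == 0.0 and per == {"a": 0.0}

    def test_scale_invariance_under_self_normalisation(self, sine):
        scaled = ts(sine.zt, 7.3 * sine.value)
        total, _ = cost({"a": scaled}, {"a": sine})
        assert total == pytest.approx(0.0, abs=1e-20)

    def test_matches_hand_computed_sse(self):
        m = ts([0, 1, 2], [1.0, 0.5, 0.25])
        d = ts([0, 1, 2], [1.0, 0.4, 0.30])
        total, per = cost({"x": m}, {"x": d}, normalise=False)
        assert total == pytest.approx(0.1 ** 2 + 0.05 ** 2, abs=1e-12)

    def test_weights_scale_per_dataset(self):
        m = ts([0, 1], [1.0, 0.0]); d = ts([0, 1], [1.0, 1.0])
        t1, _ = cost({"x": m}, {"x": d}, normalise=False)
        t2, _ = cost({"x": m}, {"x": d}, weights={"x": 2.5}, normalise=False)
        assert t2 == pytest.approx(2.5 * t1)

    def test_label_mismatch_rejected(self, sine):
        with pytest.raises(KeyError):
            cost({"a": sine}, {"b": sine})


class TestModelAnchors:
    def test_ld_ft_peaks_near_zt16(self, sims):
        ft = sims.series("FT_m", hours=16)
        assert 15.0 <= peak_time(ft) <= 17.0

    def test_fkf1_and_gi_peak_mid_to_late_day(self, sims):
        for sp in ("FKF1_m", "GI_m"):
            peak = peak_time(sims.series(sp, hours=10))
            assert 8.0 <= peak <= 11.5, sp

    def test_ft_area_larger_in_long_days(self, sims):
        assert auc(sims.series("FT_m", hours=16)) > auc(
            sims.series("FT_m", hours=8))
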