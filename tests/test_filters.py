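"""Moving-average filter stages: direct, recursive, and window selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triqrs.filters import (
    ECGSignal,
    RecursiveMovingMean,
    StreamingHighPass,
    StreamingLowPass,
    centered_mean,
    highpass,
    highpass_frequency_response,
    lowpass,
    select_highpass_halfwindow,
    select_lowpass_halfwindow,
)
from triqrs.filters import highpass_unrectified


class TestHighPass:
    def test_constant_input_rejected_exactly(self):
        for c in (0.1, -3.7, 2.5):
            y = highpass(np.full(500, c), 25)
            assert np.all(y == 0.0)

    def test_rectification_makes_output_polarity_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        assert np.array_equal(highpass(x, 10), highpass(-x, 10))

    def test_unit_impulse_center_value(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = highpass(x, 25)
        assert y[50] == 50.0 / 51.0

    def test_output_nonnegative_and_same_length(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=333)
        y = highpass(x, 7)
        assert y.size == x.size
        assert np.all(y >= 0)

    def test_accepts_ecgsignal(self):
        sig = ECGSignal(np.sin(np.arange(300) / 10), 360.0)
        assert highpass(sig, 5).size == 300

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="too short"):
            highpass(np.zeros(51), 25)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(-100, 100, allow_nan=False).filter(lambda v: v != 0),
        seed=st.integers(0, 2**16),
    )
    def test_linearity_before_rectification(self, a, seed):
        x = np.random.default_rng(seed).normal(size=200)
        lhs = highpass_unrectified(a * x, 10)
        rhs = a * highpass_unrectified(x, 10)
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-10 * abs(a))


class TestLowPass:
    def test_constant_input_passes_exactly(self):
        for c in (0.3, -8.25):
            assert np.all(lowpass(np.full(200, c), 5) == c)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        l = lowpass(x, 5)
        assert np.allclose(l[45:56], 1.0 / 11.0, rtol=1e-12)
        assert np.allclose(l[:40], 0.0) and np.allclose(l[61:], 0.0)

    def test_mass_preserved_over_interior(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=1000)
        l = lowpass(x, 5)
        # away from the padded edges, the mean filter conserves window mass
        assert np.sum(l[5:-5]) == pytest.approx(
            np.sum(centered_mean(x, 5)[5:-5]), rel=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(11), 5)


class TestRecursiveForms:
    def test_highpass_recursive_matches_direct_on_random_signal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10_000)
        n = 25
        direct = np.abs(x - centered_mean(x, n))
        hp = StreamingHighPass(n)
        emitted = [v for v in (hp.push(s) for s in x) if v is not None]
        # streaming covers centers n .. len-1-n (no reflect padding)
        emitted = np.asarray(emitted)
        scale = np.max(np.abs(x))
        assert np.max(np.abs(emitted - direct[n : n + emitted.size])) <= 1e-9 * scale

    def test_lowpass_recursive_matches_direct(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, size=10_000)
        lp = StreamingLowPass(5)
        emitted = np.asarray([v for v in (lp.push(s) for s in x) if v is not None])
        direct = centered_mean(x, 5)
        assert np.max(np.abs(emitted - direct[5 : 5 + emitted.size])) <= 1e-9 * 5

    def test_constant_stream_emits_zero(self):
        hp = StreamingHighPass(25)
        outs = [hp.push(3.0) for _ in range(200)]
        vals = [v for v in outs if v is not None]
        assert vals and all(v == 0.0 for v in vals)

    def test_zero_history_zero_sample_gives_zero(self):
        mean = RecursiveMovingMean(25)
        mean.initialize(np.zeros(51))
        assert mean.step(0.0) == 0.0

    def test_step_before_initialize_raises(self):
        with pytest.raises(RuntimeError):
            RecursiveMovingMean(5).step(1.0)

    def test_bad_initialize_length_raises(self):
        with pytest.raises(ValueError):
            RecursiveMovingMean(5).initialize(np.zeros(10))


class TestWindowSelection:
    @pytest.mark.parametrize(
        "fs,fc,expected",
        [(360, 5, 25), (720, 5, 51), (360, 90, 1)],
    )
    def test_highpass_halfwindow(self, fs, fc, expected):
        assert select_highpass_halfwindow(fs, fc) == expected

    @pytest.mark.parametrize(
        "fs,fc,expected",
        [(360, 35, 5), (360, 40, 4), (360, 179, 1)],
    )
    def test_lowpass_halfwindow(self, fs, fc, expected):
        assert select_lowpass_halfwindow(fs, fc) == expected

    def test_monotone_in_cutoff_and_rate(self):
        ns = [select_highpass_halfwindow(360, fc) for fc in (2, 5, 10, 40)]
        assert ns == sorted(ns, reverse=True)
        ns = [select_highpass_halfwindow(fs, 5) for fs in (250, 360, 500, 1000)]
        assert ns == sorted(ns)

    @pytest.mark.parametrize("fc", [0, -1, 180, 200])
    def test_invalid_cutoff_raises(self, fc):
        with pytest.raises(ValueError):
            select_highpass_halfwindow(360, fc)
        with pytest.raises(ValueError):
            select_lowpass_halfwindow(360, fc)


class TestFrequencyResponse:
    def test_dc_fully_rejected(self):
        assert highpass_frequency_response(25, 360, 0.0) == 0.0

    def test_unity_at_first_null_of_the_mean(self):
        gain = highpass_frequency_response(25, 360, 360 / 51)
        assert gain == pytest.approx(1.0, abs=1e-12)

    def test_gain_at_5hz_anchor(self):
        # 1 - sin(pi*5*51/360) / (51*sin(pi*5/360)), evaluated independently
        assert highpass_frequency_response(25, 360, 5.0) == pytest.approx(
            0.6433707855968206, rel=1e-9
        )

    def test_out_of_band_frequency_raises(self):
        with pytest.raises(ValueError):
            highpass_frequency_response(25, 360, 180.0)


class TestECGSignal:
    def test_rejects_nonfinite_and_empty(self):
        with pytest.raises(ValueError):
            ECGSignal(np.array([1.0, np.nan]), 360)
        with pytest.raises(ValueError):
            ECGSignal(np.array([]), 360)
        with pytest.raises(ValueError):
            ECGSignal(np.ones(10), 0)

    def test_duration(self):
        assert ECGSignal(np.ones(720), 360).duration_s == 2.0
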