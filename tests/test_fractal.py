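"""Unit and property tests for detrended cross-correlation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dccabci.fractal import (
    DccaStream,
    DegenerateSignalError,
    ScaleSpec,
    dcca_matrix,
    dcca_pair,
    dccc,
    detrended_cov_window,
    dfa_exponent,
    integrate_profile,
    stream_init,
    stream_update,
)


@pytest.mark.parametrize(
    "x,expected",
    [([1, 1, 1], [1, 2, 3]), ([0, 0, 0], [0, 0, 0]), ([1, -1, 2], [1, 0, 2])],
)
def test_integrate_profile_is_cumulative_sum(x, expected):
    assert np.array_equal(integrate_profile(x), expected)


def test_integrate_profile_rejects_empty():
    with pytest.raises(ValueError):
        integrate_profile(np.array([]))


class TestDetrendedCovWindow:
    def test_exact_line_fully_removed(self):
        assert detrended_cov_window([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_window_hand_ols(self):
        # OLS on [1,-1,1,-1]: slope -0.4, intercept 1.0,
        # residuals (0.4, -1.2, 1.2, -0.4), sum r^2 / 3 = 16/15
        x = [1, -1, 1, -1]
        assert detrended_cov_window(x, x) == pytest.approx(16 / 15)

    def test_sign_flip(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert detrended_cov_window(x, -x) == pytest.approx(-16 / 15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detrended_cov_window([1, 2, 3], [1, 2, 3])  # s < 4
        with pytest.raises(ValueError):
            detrended_cov_window([1, 2, 3, 4], [1, 2, 3, 4, 5])


class TestDccaPair:
    def test_self_pair_equals_dfa_fluctuation_path(self, rng):
        x = rng.standard_normal(300)
        for mode in ("sliding", "nonoverlap"):
            spec = ScaleSpec(s=32, mode=mode, integrate=True)
            f2 = dcca_pair(x, x, spec)
            _, fluct, _ = dfa_exponent(x, [16, 32, 64], mode=mode, integrate=True)
            assert f2 == pytest.approx(fluct.values[1] ** 2, rel=1e-12)

    def test_lines_give_zero(self):
        t = np.arange(64.0)
        spec = ScaleSpec(s=8)
        assert dcca_pair(3 * t + 1, -2 * t + 5, spec) == pytest.approx(0.0, abs=1e-10)

    def test_independent_white_noise_mean_near_zero(self):
        spec = ScaleSpec(s=128)
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(dcca_pair(r.standard_normal(4096), r.standard_normal(4096), spec))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            dcca_pair(rng.standard_normal(10), rng.standard_normal(10), ScaleSpec(s=16))

    def test_nonoverlap_needs_two_windows(self, rng):
        x = rng.standard_normal(7)
        with pytest.raises(ValueError):
            dcca_pair(x, x, ScaleSpec(s=4, mode="nonoverlap"))


class TestDccaMatrix:
    def test_duplicated_channel_repaired_to_spd(self, rng):
        x = rng.standard_normal(256)
        epoch = np.stack([x, x])
        spec = ScaleSpec(s=32)
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            m, info = dcca_matrix(epoch, spec, return_info=True)
        assert info["repaired"]
        assert np.linalg.eigvalsh(m)[0] > 0
        # off-diagonal equals the (pre-repair) diagonal for a perfect copy
        assert m[0, 1] == pytest.approx(m[0, 0] - info["ridge_added"], rel=1e-10)

    def test_white_noise_off_diagonals_small(self):
        spec = ScaleSpec(s=128)
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = dcca_matrix(r.standard_normal((22, 512)), spec)
            assert np.abs(m - np.diag(np.diag(m))).max() / np.diag(m).min() < 0.5

    def test_symmetry_and_positive_definiteness_contract(self, rng):
        m = dcca_matrix(rng.standard_normal((5, 400)), ScaleSpec(s=64))
        assert np.abs(m - m.T).max() < 1e-10
        assert np.linalg.eigvalsh(m)[0] > 0

    def test_constant_channel_degenerate(self, rng):
        epoch = np.vstack([np.ones(128), rng.standard_normal(128)])
        with pytest.raises(DegenerateSignalError):
            dcca_matrix(epoch, ScaleSpec(s=16))

    def test_scale_factor_cancels_under_trace_normalization(self, rng):
        m = dcca_matrix(rng.standard_normal((4, 300)), ScaleSpec(s=32))
        for c in (0.5, 3.0, 1e6):
            scaled = c * m
            assert np.allclose(scaled / np.trace(scaled), m / np.trace(m))


class TestStreaming:
    def test_packetwise_equals_batch_example(self, rng):
        x = rng.standard_normal((4, 512))
        spec = ScaleSpec(s=128)
        st_state = stream_init(4, spec)
        out = None
        for i in range(16):
            st_state, out = stream_update(st_state, x[:, i * 32 : (i + 1) * 32])
        batch = dcca_matrix(x, spec)
        rel = np.linalg.norm(out - batch) / np.linalg.norm(batch)
        assert rel < 1e-8

    def test_no_output_before_scale_samples(self, rng):
        stream = DccaStream(3, ScaleSpec(s=32))
        assert stream.update(rng.standard_normal((3, 31))) is None

    def test_constant_channels_flagged(self):
        stream = DccaStream(2, ScaleSpec(s=8))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = stream.update(np.ones((2, 16)))
        assert out is None

    def test_channel_mismatch_rejected(self, rng):
        stream = DccaStream(3, ScaleSpec(s=8))
        with pytest.raises(ValueError):
            stream.update(rng.standard_normal((2, 8)))

    def test_nonoverlap_mode_unsupported(self):
        with pytest.raises(ValueError):
            DccaStream(2, ScaleSpec(s=8, mode="nonoverlap"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_ch=st.integers(2, 6),
        n=st.integers(40, 200),
        s=st.integers(4, 32),
    )
    def test_streaming_equals_batch_property(self, seed, n_ch, n, s):
        """After any packet sequence the stream equals the batch sliding DCCA."""
        if n < s:
            n = s + 5
        r = np.random.default_rng(seed)
        x = r.standard_normal((n_ch, n))
        stream = DccaStream(n_ch, ScaleSpec(s=s))
        out = None
        i = 0
        while i < n:
            step = int(r.integers(1, 20))
            out = stream.update(x[:, i : i + step])
            i += step
        batch = dcca_matrix(x, ScaleSpec(s=s))
        assert np.linalg.norm(out - batch) / np.linalg.norm(batch) < 1e-8


class TestDfaExponent:
    def test_white_noise_near_half(self):
        vals = [
            dfa_exponent(
                np.random.default_rng(seed).standard_normal(4096),
                [16, 32, 64, 128, 256],
            )[0]
            for seed in range(30)
        ]
        assert 0.43 < np.mean(vals) < 0.57

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            dfa_exponent(np.ones(1024), [16, 32, 64])

    def test_needs_three_scales(self, rng):
        with pytest.raises(ValueError):
            dfa_exponent(rng.standard_normal(512), [16, 32])


class TestDccc:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(400)
        spec = ScaleSpec(s=32)
        assert dccc(x, x, spec) == pytest.approx(1.0)
        assert dccc(x, -x, spec) == pytest.approx(-1.0)

    def test_independent_noise_bounded_and_centered(self):
        spec = ScaleSpec(s=128)
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(dccc(r.standard_normal(4096), r.standard_normal(4096), spec))
        vals = np.asarray(vals)
        assert np.all(np.abs(vals) <= 1.0)
        assert abs(vals.mean()) < 0.05

    def test_degenerate_self_fluctuation(self, rng):
        with pytest.raises(DegenerateSignalError):
            dccc(np.ones(128), rng.standard_normal(128), ScaleSpec(s=16))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, seed, a, b):
        """DCCC is unchanged by positive affine rescaling of either series."""
        r = np.random.default_rng(seed)
        x = r.standard_normal(256)
        y = r.standard_normal(256) + 0.5 * x
        spec = ScaleSpec(s=16)
        assert dccc(x, a * y + b, spec) == pytest.approx(dccc(x, y, spec), abs=1e-10)
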