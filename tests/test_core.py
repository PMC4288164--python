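"""Core model evaluation, convolution, and fit-statistic tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcspcfit import (
    ChannelGrid,
    DecayTrace,
    InvalidParameterError,
    MultiExpParams,
    convolve_irf,
    evaluate_multiexp,
    fit_statistics,
    mean_lifetime,
    runs_test_p,
)
from tcspcfit.simulate import SimulationSpec, make_irf


def _grid_with_unit_times(n=64):
    # t(k) = k ns exactly, so analytic values can be read off channels
    return ChannelGrid(n_channels=n, dwell=1.0, t0_channel=0)


class TestEvaluateMultiexp:
    @pytest.mark.parametrize(
        "alphas, taus, channel, expected",
        [
            ([1.0], [11.3], 0, 1.0),  # exponential at the origin
            ([0.5, 0.5], [1.0, 2.0], 2, 0.5 * np.exp(-2.0) + 0.5 * np.exp(-1.0)),
        ],
    )
    def test_values_on_unit_grid(self, alphas, taus, channel, expected):
        grid = _grid_with_unit_times()
        out = evaluate_multiexp(MultiExpParams(alphas=alphas, taus=taus), grid)
        assert out[channel] == pytest.approx(expected, rel=1e-12)

    def test_single_lifetime_reaches_1_over_e(self):
        # t = tau exactly: value e^-1
        grid = ChannelGrid(n_channels=128, dwell=0.113, t0_channel=0)
        out = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[11.3]), grid)
        assert out[int(round(11.3 / 0.113))] == pytest.approx(np.exp(-1), rel=1e-12)

    def test_zero_before_time_zero_and_background_everywhere(self):
        grid = ChannelGrid(n_channels=32, dwell=0.5, t0_channel=10)
        p = MultiExpParams(alphas=[1.0], taus=[2.0], background=3.0)
        out = evaluate_multiexp(p, grid)
        assert np.all(out[:10] == 3.0)
        assert out[10] == pytest.approx(4.0)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(InvalidParameterError):
            MultiExpParams(alphas=[1.0], taus=[-1.0])
        with pytest.raises(InvalidParameterError):
            MultiExpParams(alphas=[1.0, 1.0], taus=[1.0, 0.0])

    def test_component_count_bounds(self):
        with pytest.raises(InvalidParameterError):
            MultiExpParams(alphas=[0.2] * 5, taus=[1, 2, 3, 4, 5])

    @given(
        taus=st.lists(st.floats(0.05, 20.0), min_size=1, max_size=4),
        raw_alphas=st.lists(st.floats(0.1, 5.0), min_size=4, max_size=4),
    )
    def test_monotone_decreasing_after_time_zero(self, taus, raw_alphas):
        grid = ChannelGrid(n_channels=256, dwell=0.05, t0_channel=16)
        p = MultiExpParams(alphas=raw_alphas[: len(taus)], taus=taus).normalized()
        out = evaluate_multiexp(p, grid)
        after = out[grid.t0_channel :]
        assert np.all(np.diff(after) <= 1e-15)


class TestMeanLifetime:
    @pytest.mark.parametrize(
        "alphas, taus, expected",
        [
            ([1.0], [11.3], 11.3),
            ([0.5, 0.5], [1.0, 2.0], 1.5),
            ([0.9, 0.1], [0.05, 10.0], 1.045),
        ],
    )
    def test_values(self, alphas, taus, expected):
        assert mean_lifetime(MultiExpParams(alphas=alphas, taus=taus)) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        taus=st.lists(
            st.floats(0.05, 20.0), min_size=2, max_size=4, unique=True
        ),
        scale=st.floats(0.1, 10.0),
        data=st.data(),
    )
    def test_permutation_and_rescaling_invariance(self, taus, scale, data):
        n = len(taus)
        alphas = data.draw(
            st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n)
        )
        perm = data.draw(st.permutations(range(n)))
        base = MultiExpParams(alphas=alphas, taus=taus)
        shuffled = MultiExpParams(
            alphas=[alphas[i] * scale for i in perm], taus=[taus[i] for i in perm]
        )
        assert mean_lifetime(shuffled) == pytest.approx(
            mean_lifetime(base), rel=1e-9
        )

    def test_unnormalized_amplitudes_warn_and_normalize(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="tcspcfit.core"):
            tm = mean_lifetime(MultiExpParams(alphas=[2.0, 2.0], taus=[1.0, 3.0]))
        assert tm == pytest.approx(2.0)
        assert any("normalizing" in r.message for r in caplog.records)


class TestConvolveIrf:
    def test_delta_irf_is_identity(self, grid, delta_irf):
        model = evaluate_multiexp(
            MultiExpParams(alphas=[1.0], taus=[2.0]), grid
        )
        out = convolve_irf(model, delta_irf)
        np.testing.assert_allclose(out, model, rtol=0, atol=1e-12)

    def test_linearity(self, grid):
        spec = SimulationSpec(
            intensity=MultiExpParams(alphas=[1.0], taus=[1.0]), grid=grid
        )
        irf = make_irf(spec, unit_area=True)
        m1 = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[0.5]), grid)
        m2 = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[5.0]), grid)
        a, b = 2.5, -0.7
        lhs = convolve_irf(a * m1 + b * m2, irf)
        rhs = a * convolve_irf(m1, irf) + b * convolve_irf(m2, irf)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_conserves_integrated_intensity(self, grid):
        # short lifetime: negligible mass lost past the window edge
        spec = SimulationSpec(
            intensity=MultiExpParams(alphas=[1.0], taus=[1.0]), grid=grid
        )
        irf = make_irf(spec, unit_area=True)
        model = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[1.0]), grid)
        out = convolve_irf(model, irf)
        assert out.sum() == pytest.approx(model.sum(), rel=1e-9)

    def test_narrow_irf_tail_matches_unconvolved_exponential(self, grid):
        # a 40 ps kernel barely reshapes an 11.3 ns decay beyond 1 ns
        spec = SimulationSpec(
            intensity=MultiExpParams(alphas=[1.0], taus=[11.3]), grid=grid
        )
        irf = make_irf(spec, unit_area=True)
        model = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[11.3]), grid)
        out = convolve_irf(model, irf)
        # exclude the last few ns: the acausal kernel half runs off the grid
        # edge there and the discrete convolution is truncated
        tail = (grid.times > 1.0) & (grid.times < grid.times[-1] - 3.0)
        np.testing.assert_allclose(out[tail], model[tail], rtol=1e-3)

    def test_fractional_shift_moves_centroid(self, grid, delta_irf):
        model = evaluate_multiexp(MultiExpParams(alphas=[1.0], taus=[2.0]), grid)
        shifted = convolve_irf(model, delta_irf, shift=1.0)
        np.testing.assert_allclose(shifted[1:], model[:-1], atol=1e-12)

    def test_grid_mismatch_rejected(self, grid, delta_irf):
        with pytest.raises(InvalidParameterError):
            convolve_irf(np.ones(grid.n_channels + 1), delta_irf)

    def test_zero_irf_rejected(self, grid):
        zero = DecayTrace(grid=grid, counts=np.zeros(grid.n_channels), kind="irf")
        with pytest.raises(InvalidParameterError):
            convolve_irf(np.ones(grid.n_channels), zero)


class TestFitStatistics:
    def test_perfect_fit_gives_zero_chi2(self, grid):
        counts = np.full(grid.n_channels, 50.0)
        trace = DecayTrace(grid=grid, counts=counts)
        chi2, _ = fit_statistics(trace, counts, n_free_params=2)
        assert chi2 == 0.0

    def test_chi2_calibrated_on_poisson_replicates(self):
        # Poisson data against its own generating model: E[chi2_r] ~ 1
        rng = np.random.default_rng(42)
        expected = 5000.0 * np.exp(-np.arange(400) * 0.04 / 2.0) + 10.0
        chis = []
        for _ in range(100):
            obs = rng.poisson(expected).astype(float)
            chi2, _ = fit_statistics(obs, expected, n_free_params=0)
            chis.append(chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_alternating_residuals_fail_runs_test(self):
        signs = np.tile([1.0, -1.0], 50)
        assert runs_test_p(signs) < 0.05

    def test_one_signed_residuals_fail_runs_test(self):
        assert runs_test_p(np.ones(100)) == 0.0

    def test_random_residuals_pass_runs_test(self):
        rng = np.random.default_rng(7)
        assert runs_test_p(rng.standard_normal(500)) > 0.05

    def test_dof_error(self, grid):
        trace = DecayTrace(grid=grid, counts=np.ones(grid.n_channels))
        with pytest.raises(ValueError, match="channels"):
            fit_statistics(trace, np.ones(grid.n_channels), grid.n_channels)


class TestGridAndTrace:
    def test_grid_invariants(self):
        with pytest.raises(InvalidParameterError):
            ChannelGrid(n_channels=10, dwell=-1.0)
        with pytest.raises(InvalidParameterError):
            ChannelGrid(n_channels=10, dwell=0.04, t0_channel=10)

    def test_times_zero_at_t0(self, grid):
        assert grid.times[grid.t0_channel] == 0.0
        assert grid.times[grid.t0_channel + 1] == pytest.approx(grid.dwell)

    def test_negative_counts_rejected(self, grid):
        counts = np.zeros(grid.n_channels)
        counts[5] = -1
        with pytest.raises(InvalidParameterError):
            DecayTrace(grid=grid, counts=counts)

    def test_normalized_canonical_order(self):
        p = MultiExpParams(alphas=[1.0, 3.0], taus=[5.0, 0.5], scale=2.0)
        q = p.normalized()
        np.testing.assert_allclose(q.taus, [0.5, 5.0])
        np.testing.assert_allclose(q.alphas, [0.75, 0.25])
        assert q.scale == pytest.approx(8.0)
        assert q.is_normalized
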