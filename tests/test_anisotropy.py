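"""Anisotropy analysis tests: G-factor estimation, anisotropy construction,
constrained pair fitting, mean correlation time, viscosity check."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcspcfit import (
    AnisotropyParams,
    DecayTrace,
    GFactor,
    InvalidParameterError,
    MultiExpParams,
    anisotropy_decay,
    construct_anisotropy,
    estimate_g_factor,
    fit_anisotropy,
    mean_rotational_correlation,
    stokes_einstein_check,
)
from tcspcfit.anisotropy import polarized_pair_model
from tcspcfit.simulate import SimulationSpec, make_irf, simulate_polarized_pair

MONO2NS = MultiExpParams(alphas=[1.0], taus=[2.0])


def _pair_spec(grid, aniso, **kw):
    defaults = dict(
        intensity=MONO2NS, anisotropy=aniso, grid=grid, peak_counts=10_000.0
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestAnisotropyParams:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            AnisotropyParams(r0=0.5, betas=[1.0], phis=[1.0])  # r0 > 0.4
        with pytest.raises(InvalidParameterError):
            AnisotropyParams(r0=0.31, betas=[0.6, 0.5], phis=[1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            AnisotropyParams(r0=0.31, betas=[0.5, 0.5], phis=[3.0, 1.0])

    @given(
        r0=st.floats(0.05, 0.4),
        b1=st.floats(0.0, 1.0),
        phi1=st.floats(0.05, 2.0),
        ratio=st.floats(1.0, 100.0),
    )
    def test_r_of_t_monotone_and_bounded(self, r0, b1, phi1, ratio):
        params = AnisotropyParams(
            r0=r0, betas=[b1, 1.0 - b1], phis=[phi1, phi1 * ratio]
        )
        t = np.linspace(0.0, 40.0, 500)
        r = anisotropy_decay(params, t)
        assert r[0] == pytest.approx(r0, rel=1e-12)
        assert np.all(np.diff(r) <= 1e-15)
        # positive until floating-point underflow of the exponential tail
        assert np.all(r >= 0)
        assert np.all(r[t < 30.0 * phi1 * ratio] > 0)
        assert np.all(r <= r0 + 1e-15)


class TestMeanRotationalCorrelation:
    @pytest.mark.parametrize(
        "betas, phis, capped, expected",
        [
            ([1.0], [0.5], False, 0.5),
            ([0.5, 0.5], [1.0, 3.0], False, 2.0),
            ([0.4, 0.6], [0.5, 200.0], True, 0.4 * 0.5 + 0.6 * 50.0),  # 30.2
        ],
    )
    def test_values(self, betas, phis, capped, expected):
        p = AnisotropyParams(r0=0.31, betas=betas, phis=phis, phi2_capped=capped)
        assert mean_rotational_correlation(p) == pytest.approx(expected, rel=1e-12)

    def test_equals_phi1_when_beta2_zero(self):
        p = AnisotropyParams(r0=0.31, betas=[1.0, 0.0], phis=[0.7, 9.0])
        assert mean_rotational_correlation(p) == pytest.approx(0.7)


class TestGFactor:
    def test_recovers_simulated_detection_imbalance(self, grid):
        std_aniso = AnisotropyParams(r0=0.31, betas=[1.0], phis=[0.1])
        spec = _pair_spec(
            grid,
            std_aniso,
            intensity=MultiExpParams(alphas=[1.0], taus=[11.3]),
            g_factor=1.15,
            peak_counts=20_000.0,
            seed=3,
        )
        pair = simulate_polarized_pair(spec)
        g = estimate_g_factor(pair, known_lifetime=11.3)
        assert g.value == pytest.approx(1.15, abs=0.02)

    def test_symmetric_detection_gives_unity(self, grid):
        std_aniso = AnisotropyParams(r0=0.31, betas=[1.0], phis=[0.1])
        spec = _pair_spec(
            grid,
            std_aniso,
            intensity=MultiExpParams(alphas=[1.0], taus=[11.3]),
            noise=False,
        )
        pair = simulate_polarized_pair(spec)
        g = estimate_g_factor(pair, known_lifetime=11.3)
        assert g.value == pytest.approx(1.0, abs=1e-6)

    def test_estimated_g_zeroes_tail_anisotropy(self, grid):
        std_aniso = AnisotropyParams(r0=0.31, betas=[1.0], phis=[0.1])
        spec = _pair_spec(
            grid,
            std_aniso,
            intensity=MultiExpParams(alphas=[1.0], taus=[11.3]),
            g_factor=1.2,
            peak_counts=50_000.0,
            seed=8,
        )
        pair = simulate_polarized_pair(spec)
        g = estimate_g_factor(pair, known_lifetime=11.3)
        curve = construct_anisotropy(pair, g)
        sel = curve.valid & (curve.times >= 3.0)
        assert abs(np.nanmean(curve.r[sel])) < 0.005

    def test_low_tail_counts_warn(self, grid):
        std_aniso = AnisotropyParams(r0=0.31, betas=[1.0], phis=[0.1])
        spec = _pair_spec(grid, std_aniso, peak_counts=500.0, seed=2)
        pair = simulate_polarized_pair(spec)
        with pytest.warns(UserWarning, match="tail counts"):
            estimate_g_factor(pair, known_lifetime=2.0)


class TestConstructAnisotropy:
    def test_equal_channels_give_zero(self, grid):
        counts = np.full(grid.n_channels, 1000.0)
        par = DecayTrace(grid=grid, counts=counts, kind="parallel")
        perp = DecayTrace(grid=grid, counts=counts.copy(), kind="perpendicular")
        curve = construct_anisotropy((par, perp), GFactor(1.0))
        np.testing.assert_allclose(curve.r[curve.valid], 0.0, atol=1e-12)

    def test_zero_perpendicular_gives_unity(self, grid):
        par = DecayTrace(grid=grid, counts=np.full(grid.n_channels, 1000.0))
        perp = DecayTrace(grid=grid, counts=np.zeros(grid.n_channels))
        curve = construct_anisotropy((par, perp), 1.0)
        np.testing.assert_allclose(curve.r[curve.valid], 1.0, atol=1e-12)

    def test_all_masked_raises(self, grid):
        par = DecayTrace(grid=grid, counts=np.full(grid.n_channels, 1.0))
        perp = DecayTrace(grid=grid, counts=np.full(grid.n_channels, 1.0))
        with pytest.raises(InvalidParameterError):
            construct_anisotropy((par, perp), 1.0, min_denominator=100.0)


class TestFitAnisotropy:
    def test_noiseless_single_phi_exact(self, grid):
        aniso = AnisotropyParams(r0=0.31, betas=[1.0], phis=[1.5])
        spec = _pair_spec(grid, aniso, noise=False)
        pair = simulate_polarized_pair(spec)
        fitted, res = fit_anisotropy(
            pair, make_irf(spec), intensity_params=MONO2NS, r0=0.31, n_rot=1
        )
        assert fitted.phis[0] == pytest.approx(1.5, rel=1e-6)
        assert res.chi2_reduced < 1e-9

    def test_biexponential_recovery_with_noise(self, grid):
        aniso = AnisotropyParams(r0=0.31, betas=[0.6, 0.4], phis=[0.3, 8.0])
        phi1s, phi2s = [], []
        for seed in range(8):
            spec = _pair_spec(grid, aniso, seed=500 + seed)
            pair = simulate_polarized_pair(spec)
            fitted, _ = fit_anisotropy(
                pair, make_irf(spec), intensity_params=MONO2NS, r0=0.31, n_rot=2
            )
            phi1s.append(fitted.phis[0])
            phi2s.append(fitted.phis[1])
        assert np.mean(phi1s) == pytest.approx(0.3, rel=0.10)
        assert np.mean(phi2s) == pytest.approx(8.0, rel=0.10)

    def test_very_long_component_flagged_and_capped(self, grid):
        aniso = AnisotropyParams(r0=0.31, betas=[0.6, 0.4], phis=[0.3, 200.0])
        spec = _pair_spec(grid, aniso, seed=7)
        pair = simulate_polarized_pair(spec)
        fitted, res = fit_anisotropy(
            pair, make_irf(spec), intensity_params=MONO2NS, r0=0.31, n_rot=2
        )
        assert fitted.phi2_capped
        assert "long component >= bound" in res.flags
        # phi_m uses the 50 ns reporting cap, not the unidentifiable value
        phi_m = mean_rotational_correlation(fitted)
        assert phi_m == pytest.approx(
            fitted.betas[0] * fitted.phis[0] + fitted.betas[1] * 50.0
        )

    def test_slow_amplitude_recovered_within_pm_005(self, grid):
        # phi2 beyond the window is unidentifiable; its amplitude is not
        for phi2 in (50.0, 500.0):
            aniso = AnisotropyParams(r0=0.31, betas=[0.6, 0.4], phis=[0.3, phi2])
            errs = []
            for seed in range(3):
                spec = _pair_spec(grid, aniso, seed=1000 + seed)
                pair = simulate_polarized_pair(spec)
                fitted, _ = fit_anisotropy(
                    pair, make_irf(spec), intensity_params=MONO2NS, r0=0.31, n_rot=2
                )
                errs.append(abs(fitted.betas[1] - 0.4))
            assert max(errs) < 0.05

    def test_mismatched_grids_rejected(self, grid, delta_irf):
        from tcspcfit import ChannelGrid

        other = ChannelGrid(n_channels=512, dwell=0.04, t0_channel=64)
        par = DecayTrace(grid=other, counts=np.ones(512), kind="parallel")
        perp = DecayTrace(grid=other, counts=np.ones(512), kind="perpendicular")
        with pytest.raises(InvalidParameterError):
            fit_anisotropy((par, perp), delta_irf, intensity_params=MONO2NS)


class TestStokesEinstein:
    # small-molecule standard: phi vs viscosity, printed +/- sigma
    NATA_PHI = np.array([0.060, 0.121, 0.224, 0.315])
    NATA_SIGMA = np.array([0.027, 0.034, 0.029, 0.029])
    NATA_ETA = np.array([1.0, 2.1, 4.4, 5.4])

    def test_reported_values_consistent_with_proportionality(self):
        fit = stokes_einstein_check(
            self.NATA_PHI, self.NATA_ETA, errors=self.NATA_SIGMA
        )
        assert np.all(np.abs(fit.residuals) <= self.NATA_SIGMA)

    def test_exact_proportional_data(self):
        eta = np.array([1.0, 2.0, 4.0])
        fit = stokes_einstein_check(0.058 * eta, eta)
        assert fit.slope == pytest.approx(0.058, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_positive_molecular_volume(self):
        fit = stokes_einstein_check(self.NATA_PHI, self.NATA_ETA, temperature=298.0)
        assert fit.volume_nm3 > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            stokes_einstein_check([0.06], [1.0])
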