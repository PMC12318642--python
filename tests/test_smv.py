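"""SMV computation, orthogonality, response curves and retardance fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import c

import polspec as ps
from conftest import random_spectrum


def frequency_flat_spectrum(nu_lo, nu_hi, n=4001):
    """Spectrum flat in optical frequency between the given bounds."""
    lam_nm = np.linspace(c / nu_hi * 1e9, c / nu_lo * 1e9, n)
    grid = ps.SpectralGrid(lam_nm)
    return ps.Spectrum(grid, c / (lam_nm * 1e-9) ** 2)


class TestComputeSMV:
    def test_flat_spectrum_over_one_period_has_zero_cosine_mean(self):
        mods = ps.ModulationSet(retardance_nm=3350.0)  # period fits in-band
        nu_c = c / 550e-9
        s = frequency_flat_spectrum(nu_c - mods.period_hz / 2, nu_c + mods.period_hz / 2)
        v = ps.compute_smv(s, mods)
        assert abs(v[0]) < 1e-6
        assert v[1] == pytest.approx(0.5, abs=1e-6)  # mean of sin^2

    def test_gaussian_spectrum_matches_characteristic_function(self):
        # closed form: V1 = cos(L nu0) exp(-L^2 s^2/2),
        #              V2 = (1 - cos(2 L nu0) exp(-2 L^2 s^2)) / 2
        mods = ps.ModulationSet()
        grid = ps.default_grid(450, 650, 0.1)
        for lam_c, sig_lam in [(550.0, 5.0), (500.0, 8.0), (600.0, 3.0)]:
            nu0 = c / (lam_c * 1e-9)
            sig = c * sig_lam * 1e-9 / (lam_c * 1e-9) ** 2
            s = ps.make_frequency_gaussian(nu0, sig, grid)
            v = ps.compute_smv(s, mods)
            L = mods.base_frequency
            assert v[0] == pytest.approx(
                np.cos(L * nu0) * np.exp(-(L * sig) ** 2 / 2), abs=1e-8
            )
            assert v[1] == pytest.approx(
                0.5 * (1 - np.cos(2 * L * nu0) * np.exp(-2 * (L * sig) ** 2)), abs=1e-8
            )

    def test_delta_line_evaluates_modulation_functions(self, mods):
        lam = 4.0 * mods.retardance_nm / 3.0  # in a wide custom grid
        grid = ps.SpectralGrid(np.linspace(lam - 100, lam + 100, 801))
        inten = np.zeros(grid.n)
        inten[np.argmin(np.abs(grid.wavelengths_nm - lam))] = 1.0
        v = ps.compute_smv(ps.Spectrum(grid, inten), mods)
        delta = 2 * np.pi * mods.retardance_nm / lam
        assert v[0] == pytest.approx(np.cos(delta), abs=1e-12)
        assert v[1] == pytest.approx(np.sin(delta) ** 2, abs=1e-12)

    def test_zero_power_spectrum_rejected(self, grid, mods):
        with pytest.raises(ValueError, match="zero-power"):
            ps.compute_smv(ps.Spectrum(grid, np.zeros(grid.n)), mods)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        w_a=st.floats(0.05, 10.0),
        w_b=st.floats(0.05, 10.0),
        seed=st.integers(0, 2**20),
    )
    def test_linearity_mixing_rule(self, w_a, w_b, seed):
        """SMV of a mixture is the power-weighted mean of component SMVs."""
        mods = ps.ModulationSet()
        grid = ps.default_grid(step_nm=2.0)
        rng = np.random.default_rng(seed)
        a = random_spectrum(rng, grid).normalised().scaled(w_a)
        b = random_spectrum(rng, grid).normalised().scaled(w_b)
        mix = ps.Spectrum(grid, a.intensity + b.intensity)
        va, vb = ps.compute_smv(a, mods), ps.compute_smv(b, mods)
        vmix = ps.compute_smv(mix, mods)
        np.testing.assert_allclose(vmix, (w_a * va + w_b * vb) / (w_a + w_b), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_boundedness(self, seed):
        mods = ps.ModulationSet()
        grid = ps.default_grid(step_nm=2.0)
        rng = np.random.default_rng(seed)
        v = ps.compute_smv(random_spectrum(rng, grid, smooth=False), mods)
        assert np.all(np.abs(v) <= 1.0 + 1e-12)


class TestOrthogonality:
    def test_cosine_harmonics_orthogonal_over_period(self):
        mods = ps.ModulationSet(family="cos_harmonics", n=3)
        mat, exact = ps.check_orthogonality(mods)
        assert exact
        off = mat - np.diag(np.diag(mat))
        assert np.abs(off).max() < 1e-10
        assert np.all(np.diag(mat) > 0)

    def test_mosaic_pair_orthogonal_over_period(self, mods):
        # sin^2 = 1/2 - cos(2 delta)/2: both cross terms vanish over a period
        mat, exact = ps.check_orthogonality(mods)
        assert exact
        assert abs(mat[0, 1]) < 1e-10

    def test_non_integer_window_flagged(self, mods):
        nu0 = c / 650e-9
        mat, exact = ps.check_orthogonality(mods, window_hz=(nu0, nu0 + 1.37 * mods.period_hz))
        assert not exact
        assert mat.shape == (2, 2)


class TestSMVFromChannels:
    def test_quadrature_point_channels(self, config):
        ch = ps.ChannelImages(
            channels={"I0": np.array([[0.5]]), "I45": np.array([[1.0]]),
                      "I90": np.array([[0.5]]), "I135": np.array([[0.0]])},
            config=config,
        )
        img = ps.smv_from_polarsens(ch)
        np.testing.assert_allclose(img.v[0, 0], [0.0, 1.0], atol=1e-14)

    def test_full_wave_channels(self, config):
        ch = ps.ChannelImages(
            channels={"I0": np.array([[1.0]]), "I45": np.array([[0.5]]),
                      "I90": np.array([[0.0]]), "I135": np.array([[0.5]])},
            config=config,
        )
        img = ps.smv_from_polarsens(ch)
        np.testing.assert_allclose(img.v[0, 0], [1.0, 0.0], atol=1e-14)

    def test_zero_pixels_masked_not_nan(self, config):
        z = np.zeros((2, 2))
        z[0, 0] = 1.0
        ch = ps.ChannelImages(
            channels={"I0": z * 0.5, "I45": z, "I90": z * 0.5, "I135": z * 0.0},
            config=config,
        )
        img = ps.smv_from_polarsens(ch)
        assert img.valid[0, 0]
        assert not img.valid[1, 1]
        assert np.all(np.isfinite(img.v))

    def test_four_detector_full_wave(self):
        cfg = ps.InstrumentConfig(config_kind="four_detector")
        ch = ps.ChannelImages(
            channels={"I0_0": np.array([[1.0]]), "I0_90": np.array([[0.0]]),
                      "I90_0": np.array([[0.0]]), "I90_90": np.array([[1.0]])},
            config=cfg,
        )
        img = ps.smv_from_four_detector(ch)
        np.testing.assert_allclose(img.v[0, 0], [1.0, 1.0], atol=1e-14)

    def test_four_detector_dead_arm_masked(self):
        cfg = ps.InstrumentConfig(config_kind="four_detector")
        ch = ps.ChannelImages(
            channels={"I0_0": np.array([[1.0]]), "I0_90": np.array([[0.5]]),
                      "I90_0": np.array([[0.0]]), "I90_90": np.array([[0.0]])},
            config=cfg,
        )
        img = ps.smv_from_four_detector(ch)
        assert not img.valid[0, 0]


class TestPipelineEquivalence:
    def test_rendered_smv_equals_direct_projection(self, config, mods):
        scene = ps.make_two_fluorophore_scene(seed=4, n_blobs_per_class=2,
                                              height=24, width=24)
        img = ps.smv_from_polarsens(ps.render_scene(scene, config, "unpolarised"))
        for y, x in [(0, 0), (5, 7), (12, 20), (23, 23)]:
            direct = ps.compute_smv(scene.pixel_spectrum(y, x), mods)
            np.testing.assert_allclose(img.v[y, x], direct, atol=1e-10)


class TestResponseCurves:
    def test_theoretical_parabola_identity(self, mods):
        sweep = np.linspace(450, 650, 201)
        curve = ps.theoretical_irf(mods, sweep)
        assert np.abs(curve.parabola_residuals()).max() < 1e-12

    def test_parabola_endpoints(self, mods):
        # V1 = 0 -> V2 = 1 (at 4*lambda0/3); V1 = +-1 -> V2 = 0
        curve = ps.theoretical_irf(mods, np.array([4 * 335.0 / 3, 335.0, 670.0]))
        np.testing.assert_allclose(curve.smv[0], [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(curve.smv[1], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(curve.smv[2], [-1.0, 0.0], atol=1e-12)

    def test_cos_harmonics_chebyshev_relation(self):
        mods = ps.ModulationSet(family="cos_harmonics", n=2)
        curve = ps.theoretical_irf(mods, np.linspace(450, 650, 101))
        np.testing.assert_allclose(
            curve.smv[:, 1], 2 * curve.smv[:, 0] ** 2 - 1, atol=1e-12
        )

    def test_measured_sweep_parabola_deviation_is_bandwidth_bias(self, grid, config):
        """3 nm-bandwidth sweep: the parabola deviation equals the
        second-order bandwidth bias -(Lambda sigma_nu)^2 sin^2(delta)."""
        sweep = np.arange(455.0, 650.1, 5.0)  # interior (untruncated) lines
        frames = [
            (lam, ps.polarsens_channels(ps.make_narrowband(lam, 3.0, grid), config))
            for lam in sweep
        ]
        curve = ps.measure_irf(frames)
        resid = curve.parabola_residuals()
        sigma_lam = 3.0 / (2 * np.sqrt(2 * np.log(2)))
        x = 2 * np.pi * 335.0 * sigma_lam / sweep**2  # Lambda * sigma_nu
        delta = 2 * np.pi * 335.0 / sweep
        predicted = -(x**2) * np.sin(delta) ** 2
        assert np.abs(resid).max() < 2e-4
        np.testing.assert_allclose(resid, predicted, atol=2e-6)

    def test_repeated_wavelength_gives_identical_points(self, grid, config):
        ch = ps.polarsens_channels(ps.make_narrowband(550, 3, grid), config)
        curve = ps.measure_irf([(550.0, ch)] * 5)
        assert np.allclose(curve.smv, curve.smv[0])

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.measure_irf([])

    def test_csv_roundtrip(self, tmp_path, mods):
        from polspec.io import read_response_curve, write_response_curve

        curve = ps.theoretical_irf(mods, np.linspace(450, 650, 21))
        write_response_curve(tmp_path / "c.csv", curve)
        back = read_response_curve(tmp_path / "c.csv")
        np.testing.assert_allclose(back.smv, curve.smv, atol=1e-12)
        np.testing.assert_allclose(back.wavelengths_nm, curve.wavelengths_nm)


class TestFitRetardance:
    @pytest.mark.parametrize("lam0, tol", [(335.0, 0.1), (670.0, 0.2)])
    def test_ideal_curve_recovery(self, lam0, tol):
        mods = ps.ModulationSet(retardance_nm=lam0)
        curve = ps.theoretical_irf(mods, np.linspace(450, 650, 41))
        fit = ps.fit_retardance(curve)
        assert fit.retardance_nm == pytest.approx(lam0, abs=tol)
        assert fit.residual_norm < 1e-10
        assert "retardance" in fit.summary()

    def test_noisy_sweep_recovery_within_ci(self, config, mods):
        """Poisson noise at 1e4 photons/pixel over 50 sweep points."""
        grid = ps.default_grid()
        sweep = np.linspace(450, 650, 50)
        frames = []
        for i, lam in enumerate(sweep):
            spec = ps.make_narrowband(lam, 3.0, grid).scaled(1e4)
            cube = np.broadcast_to(spec.intensity, (8, 8, grid.n))
            scene = ps.HyperspectralScene(grid=grid, cube=np.array(cube))
            ch = ps.render_scene(scene, config, "polarised_0deg")
            raw = ps.mosaic_and_noise(ch, config, photon_scale=1.0, seed=1000 + i)
            frames.append((lam, raw))
        fit = ps.fit_retardance(ps.measure_irf(frames))
        assert fit.retardance_nm == pytest.approx(335.0, abs=1.0)
        assert fit.stderr_nm < 1.0

    def test_degenerate_sweep_rejected(self, mods):
        curve = ps.ResponseCurve(np.full(6, 550.0), np.zeros((6, 2)))
        with pytest.raises(ValueError, match="distinct"):
            ps.fit_retardance(curve)
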