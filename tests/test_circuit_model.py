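"""Subunit circuit model: mosaic, filtering, coupling, pooling, variants."""

from dataclasses import replace

import numpy as np
import pytest

from parasolsim.circuit_model import (CompiledCell, CouplingParams,
                                      GanglionModelConfig, ResponseTrace,
                                      add_poisson_noise, apply_coupling,
                                      apply_subunit_nonlinearity,
                                      build_subunit_mosaic, filter_stimulus,
                                      pool_subunits, run_model,
                                      sweep_coupling_gain,
                                      approach_recede_indices,
                                      default_subunit_temporal)
from parasolsim.metrics import epoch_response
from parasolsim.rf_estimation import DoGParams, NonlinearityParams
from parasolsim.stimuli import (StimulusMovie, default_annulus_pair,
                                generate_texture_sequence, TextureSpec)


def small_mosaic(**kwargs):
    defaults = dict(spacing=32.0, jitter_sd=2.0, extent=200.0, seed=0)
    defaults.update(kwargs)
    return build_subunit_mosaic(**defaults)


def uniform_movie(value, n_frames=20, n_px=48, pitch=4.0, rate=60.0):
    frames = np.full((n_frames, n_px, n_px), float(value))
    return StimulusMovie(frames, pitch, rate, (0, n_frames))


class TestMosaic:
    def test_zero_jitter_gives_perfect_lattice(self):
        m = small_mosaic(jitter_sd=0.0)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(m.positions).query(m.positions, k=2)
        assert np.allclose(d[:, 1], 32.0, atol=1e-9)

    def test_seed_determinism(self):
        a = small_mosaic(seed=5)
        b = small_mosaic(seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_jitter_sd_matches_specification(self):
        """Empirical jitter SD of 2 µm ± 0.2 at n >= 500 subunits."""
        lattice = build_subunit_mosaic(jitter_sd=0.0, extent=800.0, seed=0)
        jittered = build_subunit_mosaic(jitter_sd=2.0, extent=800.0, seed=1)
        assert lattice.n_subunits >= 500
        disp = jittered.positions - lattice.positions
        assert disp.std() == pytest.approx(2.0, abs=0.2)

    def test_distance_matrix_properties(self):
        m = small_mosaic()
        d = m.distances
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        i, j = 3, 11
        assert d[i, j] == pytest.approx(
            np.hypot(*(m.positions[i] - m.positions[j])))

    def test_extent_too_small_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            build_subunit_mosaic(extent=30.0)


class TestFilterStimulus:
    def test_balanced_dog_cancels_full_field(self):
        dog = DoGParams(1.0, 1.0, 16.0, 40.0)  # equal integrated weights
        m = small_mosaic(dog=dog, jitter_sd=0.0, extent=100.0)
        movie = uniform_movie(0.7, n_px=200, pitch=2.0)
        traces = filter_stimulus(m, movie)
        # central subunits see both Gaussians fully inside the field
        central = m.radial_distances < 30.0
        assert np.all(np.abs(traces[central]) < 0.01)

    def test_impulse_at_subunit_center_reproduces_kernel(self):
        m = small_mosaic(jitter_sd=0.0, extent=100.0)
        movie = uniform_movie(0.0, n_frames=30, n_px=64)
        idx = int(np.argmin(m.radial_distances))
        movie.frames[2] = 0.0
        x, y = movie.pixel_coordinates()
        px = np.argmin(np.abs(x - m.positions[idx, 0]))
        py = np.argmin(np.abs(y - m.positions[idx, 1]))
        movie.frames[2, py, px] = 1.0
        traces = filter_stimulus(m, movie)
        from parasolsim.rf_estimation import temporal_kernel
        kern = temporal_kernel(m.temporal, 1000 / 60.0, 250.0,
                               normalize="step")
        resp = traces[idx, 2:2 + kern.size]
        assert np.corrcoef(resp, kern)[0, 1] > 0.999

    def test_grating_attenuation_matches_dog_mtf(self):
        """Response ratio grating/DC equals the DoG's analytic transform."""
        dog = DoGParams(1.0, 0.3, 16.0, 48.0)
        m = build_subunit_mosaic(jitter_sd=0.0, extent=80.0, dog=dog)
        f = 1.0 / 100.0  # cycles/µm
        n_px, pitch = 200, 2.0
        xx = (np.arange(n_px) - (n_px - 1) / 2) * pitch
        grating = np.cos(2 * np.pi * f * xx)[None, :] * np.ones((n_px, 1))
        mv_g = uniform_movie(0.0, n_frames=40, n_px=n_px, pitch=pitch)
        mv_g.frames[5:] = grating
        mv_dc = uniform_movie(0.0, n_frames=40, n_px=n_px, pitch=pitch)
        mv_dc.frames[5:] = 1.0
        center = int(np.argmin(m.radial_distances))
        rg = filter_stimulus(m, mv_g)[center, -1]
        rdc = filter_stimulus(m, mv_dc)[center, -1]
        def mtf(freq):
            return (dog.w_center * np.exp(-2 * np.pi ** 2 * dog.sigma_center ** 2 * freq ** 2)
                    - dog.w_surround * np.exp(-2 * np.pi ** 2 * dog.sigma_surround ** 2 * freq ** 2))
        assert rg / rdc == pytest.approx(mtf(f) / mtf(0.0), rel=0.02)

    def test_coarse_resolution_rejected(self):
        m = small_mosaic()
        movie = uniform_movie(0.0, pitch=10.0)
        with pytest.raises(ValueError, match="pitch"):
            filter_stimulus(m, movie)

    def test_poisson_noise_magnitude(self, rng):
        traces = rng.normal(0.2, 0.05, size=(50, 4000))
        noisy = add_poisson_noise(traces, 0.1, rng)
        err_sd = (noisy - traces).std()
        assert err_sd == pytest.approx(0.1 * traces.std(), rel=0.15)


class TestCoupling:
    def test_zero_gain_is_identity(self, rng):
        m = small_mosaic()
        r0 = rng.normal(size=(m.n_subunits, 30))
        out = apply_coupling(r0, m, CouplingParams(g=0.0))
        assert out is r0 or np.array_equal(out, r0)

    def test_identical_traces_unchanged(self):
        m = small_mosaic()
        r0 = np.tile(np.sin(np.linspace(0, 3, 40)), (m.n_subunits, 1))
        out = apply_coupling(r0, m, CouplingParams(g=0.25))
        assert np.allclose(out, r0, atol=1e-12)

    @pytest.mark.parametrize("sign", ["as-printed", "diffusive"])
    def test_three_subunit_brute_force_oracle(self, sign, rng):
        positions = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 50.0]])
        m = build_subunit_mosaic(jitter_sd=0.0, extent=200.0)
        m.positions = positions
        from scipy.spatial.distance import pdist, squareform
        m.distances = squareform(pdist(positions))
        r0 = rng.normal(size=(3, 7))
        params = CouplingParams(g=0.13, length_constant=36.4,
                                sign_convention=sign)
        out = apply_coupling(r0, m, params)
        expected = r0.copy()
        for i in range(3):
            for j in range(3):
                diff = r0[i] - r0[j]
                if sign == "diffusive":
                    diff = -diff
                expected[i] = expected[i] + 0.13 * diff * np.exp(
                    -m.distances[i, j] / 36.4)
        assert np.max(np.abs(out - expected)) < 1e-12


class TestSubunitNonlinearity:
    def test_linear_variant_is_identity(self, rng):
        x = rng.normal(size=(5, 20))
        params = NonlinearityParams(1.0, 0.0, 180.0, -9.0)
        assert apply_subunit_nonlinearity(x, params, "linear") is x

    def test_matches_closed_form_cdf(self):
        from scipy.stats import norm
        params = NonlinearityParams(alpha=2.0, epsilon=0.3, beta=4.0,
                                    gamma=-1.0)
        x = np.linspace(-2, 2, 41)
        expected = 0.3 + 2.0 * norm.cdf(4.0 * x - 1.0)
        out = apply_subunit_nonlinearity(x, params, "nonlinear")
        assert np.allclose(out, expected, atol=1e-12)

    def test_large_beta_half_wave_rectifies(self):
        params = NonlinearityParams(alpha=1.0, epsilon=0.0, beta=500.0,
                                    gamma=0.0)
        x = np.array([-0.5, -0.01, 0.01, 0.5])
        out = apply_subunit_nonlinearity(x, params, "coupled")
        assert np.allclose(out[:2], [0.0, 0.0], atol=1e-3)
        assert np.allclose(out[2:], [1.0, 1.0], atol=1e-3)


class TestPooling:
    def test_single_center_subunit(self):
        m = small_mosaic(jitter_sd=0.0, extent=100.0)
        keep = int(np.argmin(m.radial_distances))
        m.positions = m.positions[[keep]]
        m.distances = np.zeros((1, 1))
        outputs = np.sin(np.linspace(0, 2, 25))[None, :]
        cfg = GanglionModelConfig(
            variant="nonlinear",
            ganglion_dog=DoGParams(0.8, 0.0, 60.0, 180.0),
            surround_delay_ms=0.0)
        trace = pool_subunits(outputs, m, cfg, frame_rate=60.0)
        # single subunit at ~0 µm with no surround: z = w_center * N(t)
        assert np.allclose(trace.values, 0.8 * outputs[0], rtol=1e-6)

    def test_surround_delay_lags_surround_peak(self):
        m = small_mosaic(jitter_sd=0.0, extent=600.0)
        outputs = np.zeros((m.n_subunits, 60))
        outputs[:, 10] = 1.0  # synchronous impulse drive in every subunit
        cfg = GanglionModelConfig(variant="nonlinear", surround_delay_ms=50.0)
        trace = pool_subunits(outputs, m, cfg, frame_rate=60.0)
        # center peak at frame 10; delayed surround dip 3 frames later
        assert np.argmax(trace.values) == 10
        assert np.argmin(trace.values) == 13

    def test_five_subunit_hand_computed_oracle(self, rng):
        m = small_mosaic(jitter_sd=0.0, extent=100.0)
        m.positions = np.array([[0, 0], [40, 0], [0, 80], [-60, -10],
                                [25, 25]], dtype=float)
        from scipy.spatial.distance import pdist, squareform
        m.distances = squareform(pdist(m.positions))
        outputs = rng.normal(size=(5, 12))
        g = DoGParams(1.0, 0.75, 60.0, 180.0)
        cfg = GanglionModelConfig(variant="nonlinear", ganglion_dog=g,
                                  surround_delay_ms=0.0)
        trace = pool_subunits(outputs, m, cfg, frame_rate=60.0)
        d = np.hypot(m.positions[:, 0], m.positions[:, 1])
        wc = np.exp(-d ** 2 / (2 * 60.0 ** 2))
        ws = np.exp(-d ** 2 / (2 * 180.0 ** 2))
        expected = (1.0 * (wc @ outputs) / wc.sum()
                    - 0.75 * (ws @ outputs) / ws.sum())
        assert np.max(np.abs(trace.values - expected)) < 1e-12


class TestRunModel:
    def test_linear_variant_time_reversal_sum_equality(self, texture_pair):
        """Epoch-summed linear output is reversal-invariant to machine
        precision with zero surround delay and noise off."""
        ap, re = texture_pair
        cfg = GanglionModelConfig(variant="linear", surround_delay_ms=0.0,
                                  noise_scale=0.0)
        sa = np.sum(run_model(cfg, ap, seed=3).values)
        sr = np.sum(run_model(cfg, re, seed=3).values)
        assert sa == pytest.approx(sr, rel=1e-10)

    def test_coupled_gain_zero_equals_nonlinear_bitwise(self, texture_pair):
        ap, _ = texture_pair
        base = dict(noise_scale=0.1)
        c0 = GanglionModelConfig(variant="coupled",
                                 coupling=CouplingParams(g=0.0), **base)
        nl = GanglionModelConfig(variant="nonlinear", **base)
        va = run_model(c0, ap, seed=9).values
        vb = run_model(nl, ap, seed=9).values
        assert np.array_equal(va, vb)

    def test_enlarged_selectivity_below_coupled(self):
        ap, re = default_annulus_pair()
        coupled = GanglionModelConfig(variant="coupled")
        enlarged = GanglionModelConfig(variant="enlarged")
        ic = approach_recede_indices(coupled, ap, re, n_seeds=5, seed=2)
        ie = approach_recede_indices(enlarged, ap, re, n_seeds=5, seed=2)
        assert ic.mean() > ie.mean() + 0.2

    def test_near_identity_nonlinearity_matches_linear(self, texture_pair):
        """With a nonlinearity tuned to its shallow linear regime, the
        nonlinear variant reproduces the linear variant up to offset."""
        ap, _ = texture_pair
        beta = 0.05
        alpha = np.sqrt(2 * np.pi) / beta  # unit slope at the origin
        nl_params = NonlinearityParams(alpha=alpha, epsilon=-alpha / 2,
                                       beta=beta, gamma=0.0)
        lin = GanglionModelConfig(variant="linear", noise_scale=0.0)
        non = GanglionModelConfig(variant="nonlinear", noise_scale=0.0,
                                  nonlinearity=nl_params)
        vl = run_model(lin, ap, seed=4).values
        vn = run_model(non, ap, seed=4).values
        assert np.allclose(vn, vl, atol=1e-4)

    def test_enlarged_variant_requires_larger_diameter(self):
        with pytest.raises(ValueError, match="enlarged"):
            GanglionModelConfig(variant="enlarged", enlarged_diameter=30.0)

    def test_off_polarity_flips_contrast_sign(self):
        ap, _ = default_annulus_pair(contrast=0.25)
        dark, _ = default_annulus_pair(contrast=-0.25)
        on = GanglionModelConfig(variant="nonlinear", polarity="on",
                                 noise_scale=0.0)
        off = GanglionModelConfig(variant="nonlinear", polarity="off",
                                  noise_scale=0.0)
        von = run_model(on, ap, seed=6).values
        voff = run_model(off, dark, seed=6).values
        assert np.allclose(von, voff, atol=1e-12)


class TestSweepCouplingGain:
    def test_zero_gain_equals_nonlinear_variant(self):
        ap, re = default_annulus_pair()
        cfg = GanglionModelConfig(variant="coupled")
        df = sweep_coupling_gain(cfg, ap, re, gains=[0.0], n_seeds=4, seed=7)
        nl = GanglionModelConfig(variant="nonlinear")
        idx = approach_recede_indices(nl, ap, re, n_seeds=4, seed=7)
        assert df.asi_mean.iloc[0] == pytest.approx(idx.mean(), abs=1e-12)

    def test_reproducible_under_fixed_seed(self):
        ap, re = default_annulus_pair()
        cfg = GanglionModelConfig(variant="coupled")
        a = sweep_coupling_gain(cfg, ap, re, gains=[0.1], n_seeds=3, seed=5)
        b = sweep_coupling_gain(cfg, ap, re, gains=[0.1], n_seeds=3, seed=5)
        assert a.asi_mean.iloc[0] == b.asi_mean.iloc[0]

    def test_negative_gain_rejected(self):
        ap, re = default_annulus_pair()
        cfg = GanglionModelConfig(variant="coupled")
        with pytest.raises(ValueError):
            sweep_coupling_gain(cfg, ap, re, gains=[-0.1], n_seeds=2)


class TestResponseTrace:
    def test_hdf5_round_trip(self, tmp_path):
        tr = ResponseTrace(np.linspace(0, 1, 50), 60.0, (10, 40))
        tr.to_hdf5(tmp_path / "t.h5")
        back = ResponseTrace.from_hdf5(tmp_path / "t.h5")
        assert np.array_equal(back.values, tr.values)
        assert back.rate == 60.0
        assert back.epoch_markers == (10, 40)
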