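"""Generators: determinism, ground-truth arithmetic, warp correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal
from skimage import measure

import pellikit as pk
from pellikit.synthgen import (
    SpeckleSpec, ProfileNodes, ForceTraceSpec, TimelapseSpec,
    generate_speckle, evaluate_profile, apply_displacement,
    generate_force_trace, generate_timelapse,
)


class TestSpeckle:
    def test_no_grains_uniform(self):
        spec = SpeckleSpec(width_px=64, height_px=48, grain_density=0.0,
                           noise_sd=0.0, background_level=100.0)
        img = generate_speckle(spec)
        assert np.all(img.pixels == 100.0)

    def test_deterministic(self):
        spec = SpeckleSpec(width_px=128, height_px=96, seed=11)
        a = generate_speckle(spec)
        b = generate_speckle(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_grain_count_poisson_consistent(self):
        # independent labelling pass counts connected bright/dark blobs
        spec = SpeckleSpec(width_px=256, height_px=256, grain_density=5.0,
                           grain_radius_px=2.0, seed=7, noise_sd=0.0,
                           background_level=128.0)
        img = generate_speckle(spec)
        dev = np.abs(img.pixels - 128.0) > 25.0
        n_blobs = measure.label(dev).max()
        lam = 5.0 * 256 * 256 / 1000.0
        # blob merging only lowers the count; bound by 5 sigma above and a
        # generous merging allowance below
        assert 0.6 * lam < n_blobs < lam + 5 * np.sqrt(lam)

    @pytest.mark.parametrize("bad", [
        dict(width_px=0), dict(height_px=-3), dict(grain_density=-1.0),
        dict(noise_sd=-0.1), dict(contrast=0.0),
    ])
    def test_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            SpeckleSpec(**bad)

    def test_grey_range_clipped(self):
        spec = SpeckleSpec(width_px=64, height_px=64, grain_density=30.0,
                           contrast=1.0, noise_sd=20.0, seed=5)
        img = generate_speckle(spec)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 255.0


class TestProfile:
    def test_canonical_plateau(self):
        assert evaluate_profile(pk.CANONICAL_ROUGH_NODES, 0.80) == pytest.approx(0.60)

    def test_affine_identity(self):
        assert evaluate_profile(pk.AFFINE_NODES, 0.37) == pytest.approx(0.37)

    def test_interpolation_between_nodes(self):
        # hand interpolation between (0.15, 0.33) and (0.70, 0.60)
        expected = 0.33 + 0.27 * (0.50 - 0.15) / 0.55
        assert evaluate_profile(pk.CANONICAL_ROUGH_NODES, 0.50) == \
            pytest.approx(expected)

    def test_exact_at_nodes(self):
        for x, u in pk.CANONICAL_ROUGH_NODES.nodes:
            assert evaluate_profile(pk.CANONICAL_ROUGH_NODES, x) == \
                pytest.approx(u)

    @pytest.mark.parametrize("x", [-0.01, 1.01])
    def test_out_of_range(self, x):
        with pytest.raises(ValueError):
            evaluate_profile(pk.CANONICAL_ROUGH_NODES, x)

    @pytest.mark.parametrize("nodes", [
        ((0.0, 0.0), (0.5, 0.1), (0.4, 0.2), (1.0, 1.0)),  # not increasing
        ((0.1, 0.0), (1.0, 1.0)),                           # no x=0 node
        ((0.0, 0.0), (0.9, 1.0)),                           # no x=1 node
    ])
    def test_invalid_nodes(self, nodes):
        with pytest.raises(ValueError):
            ProfileNodes(nodes)

    @given(x=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_canonical_monotone_and_bounded(self, x):
        u = evaluate_profile(pk.CANONICAL_ROUGH_NODES, x)
        assert 0.0 <= u <= 1.0
        # non-decreasing: compare with a point just to the left
        if x > 1e-6:
            assert evaluate_profile(pk.CANONICAL_ROUGH_NODES, x - 1e-6) <= \
                u + 1e-12


class TestWarp:
    def test_zero_elongation_identity(self, speckle_image):
        out = apply_displacement(speckle_image, pk.CANONICAL_ROUGH_NODES, 0.0)
        assert np.allclose(out.pixels, speckle_image.pixels)

    def test_uniform_translation_crosscorrelation(self, speckle_image):
        # full-frame correlation oracle: 3 px shift peaks at lag 3
        moved = apply_displacement(
            speckle_image, ProfileNodes(((0.0, 1.0), (1.0, 1.0))), 3.0)
        a = speckle_image.pixels - speckle_image.pixels.mean()
        b = moved.pixels - moved.pixels.mean()
        # correlate rows only: sum over y then 1-D correlation
        pa, pb = a.sum(axis=0), b.sum(axis=0)
        cc = signal.correlate(pb, pa, mode="full")
        lag = int(np.argmax(cc)) - (pa.size - 1)
        assert lag == 3

    def test_affine_midcolumn_block_matching(self, speckle_image):
        # independent SSD block matching at the mid-column expects ~3 px
        moved = apply_displacement(speckle_image, pk.AFFINE_NODES, 6.0)
        H, W = speckle_image.shape
        cx, cy = W // 2, H // 2
        block = speckle_image.pixels[cy - 16:cy + 16, cx - 16:cx + 16]
        ssd = [np.sum((moved.pixels[cy - 16:cy + 16,
                                    cx - 16 + d:cx + 16 + d] - block) ** 2)
               for d in range(-8, 9)]
        d_best = int(np.argmin(ssd)) - 8
        assert abs(d_best - 3) <= 1

    def test_negative_elongation_rejected(self, speckle_image):
        with pytest.raises(ValueError):
            apply_displacement(speckle_image, pk.AFFINE_NODES, -1.0)


class TestForceTrace:
    def test_linear_model_arithmetic(self):
        # 0.51 N/m, -1.2 mN at d = 5 mm: -1.2 + 0.51*5 = 1.35 mN
        spec = ForceTraceSpec(stiffness_true=0.51, intercept_true=-1.2,
                              failure_elongation=6.0, noise_sd=0.0,
                              post_failure_level=0.0, central_fraction=1.0)
        tr = generate_force_trace(spec)
        i = int(np.argmin(np.abs(tr.plate_displacement - 5.0)))
        d = tr.plate_displacement[i]   # nearest sampled displacement
        assert d == pytest.approx(5.0, abs=0.01)
        assert tr.raw_signal[i] == pytest.approx(-1.2 + 0.51 * d, abs=1e-9)
        # at exactly 5 mm the model force is -1.2 + 0.51*5 = 1.35 mN
        assert tr.raw_signal[i] == pytest.approx(1.35, abs=0.01)

    def test_zero_stiffness_zero_force(self):
        spec = ForceTraceSpec(stiffness_true=0.0, intercept_true=0.0,
                              noise_sd=0.0, post_failure_level=0.0)
        tr = generate_force_trace(spec)
        assert np.all(tr.raw_signal == 0.0)

    def test_true_strain_generation(self):
        # stiffness applied to the central elongation 0.27 * 3.7 ~ 1 mm
        spec = ForceTraceSpec(stiffness_true=5.1, intercept_true=0.0,
                              central_fraction=0.27, noise_sd=0.0,
                              post_failure_level=0.0, failure_elongation=2.0)
        tr = generate_force_trace(spec)
        i = int(np.argmin(np.abs(tr.plate_displacement - 3.7)))
        d = tr.plate_displacement[i]
        assert tr.raw_signal[i] == pytest.approx(5.1 * 0.27 * d, abs=1e-9)
        assert tr.raw_signal[i] == pytest.approx(5.1, abs=0.03)

    def test_noise_free_linearity(self):
        spec = ForceTraceSpec(noise_sd=0.0)
        tr = generate_force_trace(spec)
        pre = tr.plate_displacement * spec.central_fraction < \
            spec.failure_elongation
        coef = np.polyfit(tr.plate_displacement[pre], tr.raw_signal[pre], 1)
        resid = tr.raw_signal[pre] - np.polyval(coef, tr.plate_displacement[pre])
        assert np.abs(resid).max() < 1e-10

    def test_unit_identity_N_per_m_is_mN_per_mm(self):
        spec = ForceTraceSpec(stiffness_true=2.0, intercept_true=0.0,
                              noise_sd=0.0, post_failure_level=0.0,
                              failure_elongation=11.0)
        tr = generate_force_trace(spec)
        pre = tr.plate_displacement < 11.0
        slope = np.polyfit(tr.plate_displacement[pre], tr.raw_signal[pre],
                           1)[0]
        assert slope == pytest.approx(2.0)  # mN/mm == N/m

    def test_no_failure_flagged(self):
        spec = ForceTraceSpec(failure_elongation=50.0)
        tr = generate_force_trace(spec)
        assert tr.meta["failed"] is False

    def test_deterministic(self):
        spec = ForceTraceSpec(seed=9)
        a, b = generate_force_trace(spec), generate_force_trace(spec)
        assert np.array_equal(a.raw_signal, b.raw_signal)


class TestTimelapse:
    def _small(self, **kw):
        base = dict(duration=2.0, dish_width=20.0, dish_height=6.0,
                    front_start=5.0, noise_sd=0.0, seed=0)
        base.update(kw)
        return TimelapseSpec(**base)

    def test_zero_speed_static_boundary(self):
        st_ = generate_timelapse(self._small(front_speed=0.0))
        edges = [np.flatnonzero(fr[3] > 100.0)[-1] for fr in st_.frames]
        assert len(set(edges)) == 1

    def test_front_advance_arithmetic(self):
        # 0.25 mm/h at 0.05 mm/px and 15-min frames: 1.25 px per frame
        st_ = generate_timelapse(self._small(front_speed=0.25, duration=8.0))
        edges = np.array([np.flatnonzero(fr[3] > 100.0)[-1]
                          for fr in st_.frames], dtype=float)
        per_frame = np.polyfit(np.arange(edges.size), edges, 1)[0]
        assert per_frame == pytest.approx(1.25, abs=0.1)

    def test_wrinkle_period_autocorrelation(self):
        st_ = generate_timelapse(self._small(
            wrinkle_onset=0.0, wrinkle_wavelength=2.0, front_start=18.0))
        row = st_.frames[-1][3, :int(16 / 0.05)]
        x0 = row - row.mean()
        acf = signal.correlate(x0, x0, mode="full")[x0.size - 1:]
        period_px = int(np.argmax(acf[20:60])) + 20
        assert period_px * 0.05 == pytest.approx(2.0, abs=0.1)

    def test_unresolvable_wavelength_rejected(self):
        with pytest.raises(ValueError):
            self._small(wrinkle_wavelength=0.05, pixel_size=0.05)

    def test_deterministic(self):
        spec = self._small(noise_sd=4.0, seed=21)
        a, b = generate_timelapse(spec), generate_timelapse(spec)
        assert np.array_equal(a.frames, b.frames)
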