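"""Synthetic scene generator: bead geometry, 4-layer rendering, PSF, noise."""

import numpy as np
import pytest

from oracles import parratt_reflectance
from sprimage import gold_sensor_stack, penetration_depth, stack_reflectance
from sprimage.analysis import brightfield_radius, fwhm_from_profile
from sprimage.dispersion import WATER
from sprimage.simulate import (
    BeadSpec,
    ImagingConfig,
    PSFModel,
    bead_height_map,
    delta_r_vs_gap,
    instrument_psf,
    make_bead_dataset,
    noise_sigma_for_threshold_at_depth,
    reflectance_vs_gap,
    render_brightfield_bead_image,
    render_point_source,
    render_spr_bead_image,
    resolve_operating_angle,
)

CFG = ImagingConfig(pixel_size_um=0.1, image_shape=(200, 200), seed=3)
CENTER = (10.0, 10.0)


def _lp(stack):
    eps = stack.epsilons()
    return penetration_depth(stack.wavelength_nm, eps[1], eps[-1].real)


class TestBeadHeightMap:
    def test_sphere_geometry(self):
        bead = BeadSpec(5.0, 1.48, CENTER)
        z = bead_height_map(bead, CFG)
        # contact point: the nearest pixel center to CENTER
        iy = ix = int(10.0 / 0.1)  # pixel centers at 9.95 and 10.05
        assert z[iy, ix] < 1.0  # sub-nm at ~70 nm from contact? no: z(0.0707 um)
        # z at in-plane distance rho: exact chord formula
        rho = np.hypot(9.95 - 10.0, 10.05 - 10.0)
        assert z[iy, ix] == pytest.approx((5 - np.sqrt(25 - rho**2)) * 1000, rel=1e-9)
        # beyond the equator: no bead
        assert np.isnan(z[iy, int(15.2 / 0.1)])

    def test_forward_chord_formula(self):
        # rho = sqrt(d(2 r1 - d)) lies at height d: hand-checked chord
        bead = BeadSpec(30.0, 1.48, (16.0, 16.0))
        cfg = ImagingConfig(pixel_size_um=0.1, image_shape=(320, 320))
        z = bead_height_map(bead, cfg)
        d = 0.2  # μm
        rho = np.sqrt(d * (2 * 30.0 - d))  # ≈ 3.458 μm
        assert rho == pytest.approx(3.458, abs=1e-3)
        iy = int(16.0 / 0.1)
        ix = int(round((16.0 + rho) / 0.1 - 0.5))
        x_px = (ix + 0.5) * 0.1
        rho_px = np.hypot(x_px - 16.0, 16.05 - 16.0)
        assert z[iy, ix] == pytest.approx(
            (30 - np.sqrt(900 - rho_px**2)) * 1000, rel=1e-9
        )
        assert z[iy, ix] == pytest.approx(200.0, abs=6.0)  # within a pixel of d


class TestRenderSprBead:
    def test_index_matched_bead_is_invisible(self, gold_stack_620):
        n_water = np.sqrt(WATER.epsilon_at(620.0).real)
        bead = BeadSpec(5.0, float(n_water), CENTER)
        img = render_spr_bead_image(bead, gold_stack_620, CFG)
        angle = resolve_operating_angle(gold_stack_620, CFG)
        bg = stack_reflectance(gold_stack_620, angle)
        np.testing.assert_allclose(img.pixels, bg, atol=1e-9)

    def test_contact_point_matches_independent_four_layer_oracle(self, gold_stack_620):
        bead = BeadSpec(5.0, 1.48, CENTER)
        angle = resolve_operating_angle(gold_stack_620, CFG)
        r0 = reflectance_vs_gap(bead, gold_stack_620, angle, 0.0)[0]
        eps = gold_stack_620.epsilons()
        oracle = parratt_reflectance(
            [eps[0], eps[1], eps[2], complex(1.48**2)],
            [None, 45.0, 0.0, None],
            620.0,
            angle,
            "p",
        )
        assert r0 == pytest.approx(oracle, abs=1e-12)

    def test_noise_free_background_equals_three_layer_model(self, gold_stack_620):
        bead = BeadSpec(2.0, 1.48, CENTER)
        img = render_spr_bead_image(bead, gold_stack_620, CFG)
        angle = resolve_operating_angle(gold_stack_620, CFG)
        bg = stack_reflectance(gold_stack_620, angle)
        corner = img.pixels[-20:, -20:]  # far from the bead
        np.testing.assert_allclose(corner, bg, atol=1e-9)

    def test_footprint_shrinks_at_shorter_wavelength(self):
        sizes = []
        for wl in (670.0, 620.0, 550.0):
            stack = gold_sensor_stack(wl)
            cfg = ImagingConfig(
                wavelength_nm=wl, pixel_size_um=0.1, image_shape=(200, 200),
                psf=instrument_psf(wl, stack),
            )
            bead = BeadSpec(5.0, 1.48, CENTER)
            img = render_spr_bead_image(bead, stack, cfg)
            angle = resolve_operating_angle(stack, cfg)
            bg = stack_reflectance(stack, angle)
            sizes.append(int((img.pixels - bg > 0.05).sum()))
        assert sizes[0] > sizes[1] > sizes[2]

    def test_four_layer_converges_to_background_far_from_surface(self, gold_stack_620):
        bead = BeadSpec(30.0, 1.59, CENTER)
        angle = resolve_operating_angle(gold_stack_620, CFG)
        lp = _lp(gold_stack_620)
        dr = delta_r_vs_gap(bead, gold_stack_620, angle, 20 * lp)
        assert abs(dr[0]) < 1e-6

    def test_weak_contrast_bead_follows_field_intensity_decay(self, gold_stack_620):
        # first-order regime: the reflectance perturbation of a weak-contrast
        # bead follows the evanescent *intensity* |E(z)|², a single
        # exponential of decay length Lp/2 (Lp being the amplitude-formula
        # 1/e depth) — this ties the image model to the field-decay picture
        n_water = np.sqrt(WATER.epsilon_at(620.0).real)
        bead = BeadSpec(10.0, float(n_water) + 0.02, CENTER)
        angle = resolve_operating_angle(gold_stack_620, CFG)
        lp = _lp(gold_stack_620)
        # decay regime beyond the near-contact saturation zone
        z = np.linspace(lp / 4, 2 * lp, 9)
        dr = delta_r_vs_gap(bead, gold_stack_620, angle, z)
        ratio = dr / dr[0]
        slope = np.polyfit(z, np.log(ratio), 1)[0]
        assert -1.0 / slope == pytest.approx(lp / 2, rel=0.10)
        fitted = np.exp(np.polyval(np.polyfit(z, np.log(ratio), 1), z))
        np.testing.assert_allclose(ratio, fitted, rtol=0.10)

    def test_bit_reproducible_under_seed(self, gold_stack_620):
        bead = BeadSpec(3.0, 1.48, CENTER)
        cfg = ImagingConfig(
            pixel_size_um=0.1, image_shape=(128, 128), noise_sigma=0.01, seed=42
        )
        a = render_spr_bead_image(bead, gold_stack_620, cfg)
        b = render_spr_bead_image(bead, gold_stack_620, cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestBrightfield:
    def test_ring_radius_round_trip(self):
        bead = BeadSpec(5.0, 1.48, CENTER)
        img = render_brightfield_bead_image(bead, CFG)
        r = brightfield_radius(img, CENTER, 8.0)
        assert r == pytest.approx(5.0, abs=0.05)

    def test_pixel_size_scaling(self):
        bead = BeadSpec(5.0, 1.48, CENTER)
        coarse = ImagingConfig(pixel_size_um=0.2, image_shape=(100, 100))
        img = render_brightfield_bead_image(bead, coarse)
        ring_px = np.unravel_index(np.argmin(img.pixels), img.shape)
        rho = np.hypot(
            (ring_px[1] + 0.5) * 0.2 - 10.0, (ring_px[0] + 0.5) * 0.2 - 10.0
        )
        assert rho == pytest.approx(5.0, abs=0.2)

    def test_empty_scene_is_uniform(self):
        bead = BeadSpec(5.0, 1.48, (1000.0, 1000.0))  # far outside the FOV
        img = render_brightfield_bead_image(bead, CFG)
        np.testing.assert_allclose(img.pixels, 1.0, atol=1e-12)


class TestPointSource:
    def test_isotropic_limit(self):
        cfg = ImagingConfig(
            pixel_size_um=0.05, image_shape=(128, 128), psf=PSFModel(0.30, 0.0)
        )
        img = render_point_source(cfg)
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.shape)
        fx = fwhm_from_profile(img.pixels[iy, :], 0.05)
        fy = fwhm_from_profile(img.pixels[:, ix], 0.05)
        assert fx == pytest.approx(fy, rel=1e-6)
        assert fx == pytest.approx(0.30, abs=0.01)

    def test_default_anisotropy_matches_instrument(self):
        cfg = ImagingConfig(pixel_size_um=0.02, image_shape=(300, 300))
        img = render_point_source(cfg)
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.shape)
        fx = fwhm_from_profile(img.pixels[iy, :], 0.02)
        fy = fwhm_from_profile(img.pixels[:, ix], 0.02)
        assert fx == pytest.approx(0.30, abs=0.01)
        assert fy == pytest.approx(0.60, abs=0.02)
        assert fy / fx == pytest.approx(2.0, abs=0.1)

    def test_integrated_signal_conserved(self):
        cfg = ImagingConfig(pixel_size_um=0.05, image_shape=(256, 256))
        img = render_point_source(cfg, amplitude=2.5)
        assert img.pixels.sum() == pytest.approx(2.5, rel=1e-3)


class TestBeadDataset:
    def test_minimal_scene_bundle(self, gold_stack_620):
        bead = BeadSpec(3.0, 1.48, CENTER, "PMMA")
        scenes = make_bead_dataset([bead], [620.0], CFG)
        assert len(scenes) == 1
        sc = scenes[0]
        assert sc.p_image.shape == sc.s_image.shape == sc.brightfield.shape
        assert len(sc.truth) == 1
        assert sc.truth["material"][0] == "PMMA"

    def test_truth_r2_sits_at_calibrated_chord(self):
        # with noise calibrated for threshold-at-Lp, expected r2 ≈ Lp chord
        wl = 620.0
        stack = gold_sensor_stack(wl)
        lp = _lp(stack)
        bead = BeadSpec(3.05, 1.48, (10.0, 10.0), "PMMA")
        cfg = ImagingConfig(
            wavelength_nm=wl, pixel_size_um=0.1, image_shape=(200, 200),
            psf=instrument_psf(wl, stack), seed=1,
        )
        sigma = noise_sigma_for_threshold_at_depth(bead, stack, cfg, lp)
        from dataclasses import replace

        scenes = make_bead_dataset([bead], [wl], replace(cfg, noise_sigma=sigma))
        truth = scenes[0].truth
        d_um = lp / 1000
        r2_lp = np.sqrt(d_um * (2 * 3.05 - d_um))
        assert truth["expected_r2_um"][0] == pytest.approx(r2_lp, rel=0.05)
        assert truth["expected_d_nm"][0] == pytest.approx(lp, rel=0.10)

    def test_two_beads_measured_independently(self, gold_stack_620):
        cfg = ImagingConfig(pixel_size_um=0.1, image_shape=(256, 256), seed=5)
        b1 = BeadSpec(2.5, 1.48, (7.0, 7.0), "a")
        b2 = BeadSpec(2.5, 1.59, (18.0, 18.0), "b")
        single = make_bead_dataset([b1], [620.0], cfg)[0]
        pair = make_bead_dataset([b1, b2], [620.0], cfg)[0]
        angle = single.operating_angle_deg
        bg = stack_reflectance(single.stack, angle)
        # noise-free scenes: compare the b1 neighborhood
        region = np.s_[40:100, 40:100]
        np.testing.assert_allclose(
            pair.p_image.pixels[region], single.p_image.pixels[region], rtol=0.01, atol=1e-6
        )

    def test_s_frame_shares_illumination_with_p(self, gold_stack_620):
        bead = BeadSpec(2.0, 1.48, CENTER)
        scenes = make_bead_dataset([bead], [620.0], CFG, illumination_strength=0.08)
        sc = scenes[0]
        rs = stack_reflectance(sc.stack, sc.operating_angle_deg, "s")
        bg = stack_reflectance(sc.stack, sc.operating_angle_deg)
        ratio = sc.p_image.pixels / sc.s_image.pixels * rs
        corner = ratio[-30:, -30:]
        # p/s cancels the polynomial illumination in the background
        np.testing.assert_allclose(corner, bg, rtol=5e-3)
        assert sc.s_image.pixels[-30:, -30:].std() > 1e-4  # illumination present


class TestInstrumentPsf:
    def test_anchored_at_620(self):
        psf = instrument_psf(620.0)
        assert psf.fwhm_x_um == pytest.approx(0.30)
        assert psf.decay_y_um == pytest.approx(0.4543, abs=1e-4)

    def test_tail_collapses_with_lossy_gold(self):
        assert instrument_psf(480.0).decay_y_um < 0.1 * instrument_psf(620.0).decay_y_um

    def test_tail_capped_beyond_reference(self):
        assert instrument_psf(670.0).decay_y_um == pytest.approx(0.4543, abs=1e-4)
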