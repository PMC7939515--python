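"""Simulator: scene generation, hologram forward model, reconstruction oracle."""

import math

import numpy as np
import pytest
from scipy import ndimage

from holocount import sim_dhm
from holocount.sim_dhm import (
    SceneError,
    SimConfig,
    SimOptics,
    generate_dataset,
    generate_phase_map,
    generate_sample,
    generate_scene,
    mask_from_scene,
    phase_from_scene,
    reconstruct_phase,
    synthesize_hologram,
    synthesize_scene_hologram,
)


def _count_components(mask):
    _, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return n


def _on_bin_optics(f_cycles_per_px=0.1875, noise=0.0, defocus=0.0):
    """Optics whose carrier falls exactly on an FFT bin of a 128-px image."""
    wl, pitch = 682e-9, 5.7e-6
    theta = math.asin(f_cycles_per_px * wl / pitch)
    return SimOptics(
        wavelength=wl,
        pixel_pitch=pitch,
        carrier_angle=(theta, theta),
        noise_sigma=noise,
        defocus_distance=defocus,
    )


class TestSceneGeneration:
    CFG = SimConfig(
        image_size=(96, 96),
        n_cells_range=(5, 5),
        cell_radius_range=(5.0, 8.0),
        seed=7,
    )

    def test_component_count_matches_requested(self):
        phase, mask, n = generate_phase_map(self.CFG)
        assert n == 5
        assert _count_components(mask) == 5

    def test_seeded_determinism(self):
        p1, m1, _ = generate_phase_map(self.CFG)
        p2, m2, _ = generate_phase_map(self.CFG)
        assert np.array_equal(p1, p2)
        assert np.array_equal(m1, m2)

    def test_mask_is_phase_above_taper_cutoff(self):
        # non-overlapping scene: mask == {phase >= 5% of that cell's peak}
        scene = generate_scene(self.CFG)
        phase = phase_from_scene(scene, self.CFG.image_size)
        mask = mask_from_scene(scene, self.CFG.image_size)
        expected = np.zeros_like(mask)
        for cell in scene:
            cutoff = sim_dhm.MASK_TAPER_CUTOFF * cell.amplitude
            yy = np.arange(96)[:, None] - cell.row
            xx = np.arange(96)[None, :] - cell.col
            r = np.hypot(yy, xx)
            inside = r <= cell.radius
            expected |= inside & (phase * inside >= cutoff - 1e-12)
        assert np.array_equal(mask, expected)

    def test_20x_mode_quarters_cell_area(self):
        base = SimConfig(
            image_size=(192, 192),
            n_cells_range=(4, 8),
            cell_radius_range=(8.0, 12.0),
        )
        areas = {"40x": [], "20x": []}
        for mode in areas:
            for seed in range(50):
                cfg = SimConfig(
                    image_size=base.image_size,
                    n_cells_range=base.n_cells_range,
                    cell_radius_range=base.cell_radius_range,
                    magnification_mode=mode,
                    seed=seed,
                )
                _, mask, n = generate_phase_map(cfg)
                areas[mode].append(mask.sum() / n)
        ratio = np.mean(areas["20x"]) / np.mean(areas["40x"])
        assert 0.25 * 0.8 < ratio < 0.25 * 1.2

    def test_impossible_placement_raises_with_count(self):
        cfg = SimConfig(
            image_size=(96, 96),
            n_cells_range=(10, 10),
            cell_radius_range=(30.0, 30.0),
            seed=0,
        )
        with pytest.raises(SceneError, match="10"):
            generate_scene(cfg)

    def test_overlap_allowed_skips_rejection(self):
        cfg = SimConfig(
            image_size=(96, 96),
            n_cells_range=(10, 10),
            cell_radius_range=(30.0, 30.0),
            overlap_allowed=True,
            seed=0,
        )
        assert len(generate_scene(cfg)) == 10


class TestHologramSynthesis:
    def test_flat_phase_gives_pure_carrier_sidebands(self):
        optics = _on_bin_optics()
        holo = synthesize_hologram(np.zeros((128, 128)), optics)
        spec = np.abs(np.fft.fft2(holo))
        # expected bins: DC and +-carrier at 0.1875 * 128 = 24 on both axes
        peaks = {(0, 0), (24, 24), (128 - 24, 128 - 24)}
        order = np.dstack(np.unravel_index(np.argsort(spec, axis=None)[::-1], spec.shape))[0]
        top3 = {tuple(map(int, order[i])) for i in range(3)}
        assert top3 == peaks
        # everything else is numerically zero
        mask = np.ones_like(spec, dtype=bool)
        for (i, j) in peaks:
            mask[i, j] = False
        assert spec[mask].max() < 1e-6 * spec[0, 0]

    def test_intensity_nonnegative_with_noise(self):
        optics = _on_bin_optics(noise=0.5)
        phase, _, _ = generate_phase_map(SimConfig(image_size=(96, 96), seed=3,
                                                   cell_radius_range=(5.0, 8.0)))
        holo = synthesize_hologram(phase, optics, rng=5)
        assert holo.min() >= 0.0

    def test_difference_confined_to_cell_support(self):
        cfg = SimConfig(image_size=(128, 128), n_cells_range=(1, 1),
                        cell_radius_range=(10.0, 10.0), seed=11)
        scene = generate_scene(cfg)
        phase = phase_from_scene(scene, cfg.image_size)
        optics = _on_bin_optics()
        holo_cell = synthesize_hologram(phase, optics)
        holo_empty = synthesize_hologram(np.zeros_like(phase), optics)
        diff = np.abs(holo_cell - holo_empty)
        outside = phase == 0.0
        assert diff[outside].max() < 1e-9
        assert diff[~outside].max() > 0.1

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SimOptics(carrier_angle=(0.5, 0.5))

    def test_bead_mode_defocus_changes_hologram(self):
        cfg = SimConfig(image_size=(128, 128), n_cells_range=(3, 3),
                        cell_radius_range=(6.0, 9.0), magnification_mode="bead", seed=2)
        scene = generate_scene(cfg)
        assert any(c.defocus != 0.0 for c in scene)
        optics = _on_bin_optics()
        holo = synthesize_scene_hologram(scene, cfg.image_size, optics)
        focused = [sim_dhm.CellSpec(c.row, c.col, c.radius, c.amplitude, 0.0) for c in scene]
        holo_focused = synthesize_scene_hologram(focused, cfg.image_size, optics)
        assert holo.min() >= 0
        assert not np.allclose(holo, holo_focused)
        # ground truth stays the in-focus support
        assert np.array_equal(mask_from_scene(scene, cfg.image_size),
                              mask_from_scene(focused, cfg.image_size))


def _roundtrip_rms(noise, seed=0):
    cfg = SimConfig(image_size=(128, 128), n_cells_range=(1, 1),
                    cell_radius_range=(30.0, 30.0),
                    phase_amplitude_range=(2.0, 2.0), seed=4)
    phase, _, _ = generate_phase_map(cfg)
    optics = _on_bin_optics(noise=noise)
    holo = synthesize_hologram(phase, optics, rng=seed)
    rec = reconstruct_phase(holo, optics)
    err = rec - phase
    err -= err.mean()  # reconstruction carries an arbitrary constant offset
    return float(np.sqrt((err**2).mean()))


class TestReconstruction:
    def test_roundtrip_recovers_smooth_phase(self):
        assert _roundtrip_rms(0.0) < 0.1

    def test_null_object_reconstructs_flat(self):
        optics = _on_bin_optics()
        holo = synthesize_hologram(np.zeros((128, 128)), optics)
        rec = reconstruct_phase(holo, optics)
        assert rec.std() < 1e-6

    def test_error_grows_with_noise(self):
        errs = [_roundtrip_rms(s) for s in (0.0, 0.05, 0.1)]
        assert errs[0] < errs[1] < errs[2]

    def test_low_carrier_warns(self):
        optics = _on_bin_optics(f_cycles_per_px=0.05)
        holo = synthesize_hologram(np.zeros((64, 64)), optics)
        with pytest.warns(RuntimeWarning, match="sideband"):
            reconstruct_phase(holo, optics, bandpass_radius=0.06)


class TestDatasetGeneration:
    CFG = SimConfig(image_size=(64, 64), n_cells_range=(2, 5),
                    cell_radius_range=(4.0, 6.0), seed=9)

    def test_manifest_and_files(self, tmp_path):
        manifest = generate_dataset(self.CFG, 6, tmp_path)
        assert len(manifest) == 6
        for _, row in manifest.iterrows():
            holo = sim_dhm.read_hologram(tmp_path / row["image_path"])
            mask = sim_dhm.read_mask(tmp_path / row["mask_path"])
            assert holo.shape == mask.shape == (64, 64)
            assert _count_components(mask) == row["n_cells"]

    def test_regeneration_is_byte_identical(self, tmp_path):
        m1 = generate_dataset(self.CFG, 3, tmp_path / "a")
        m2 = generate_dataset(self.CFG, 3, tmp_path / "b")
        assert m1.drop(columns=["image_path", "mask_path"]).equals(
            m2.drop(columns=["image_path", "mask_path"])
        )
        for _, row in m1.iterrows():
            a = (tmp_path / "a" / row["mask_path"]).read_bytes()
            b = (tmp_path / "b" / row["mask_path"]).read_bytes()
            assert a == b

    def test_sample_determinism(self):
        h1, m1, n1 = generate_sample(self.CFG, rng=17)
        h2, m2, n2 = generate_sample(self.CFG, rng=17)
        assert np.array_equal(h1, h2) and np.array_equal(m1, m2) and n1 == n2
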