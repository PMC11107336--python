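"""Scan-sequence geometry, tissue physics, frame formation, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fiberscope as fs
from fiberscope.acquisition import IlluminationPattern, ScanSequence, ScanStep


def audit_rows(seq):
    """Independent per-row audit: coverage count and overlap count per step."""
    cov = np.zeros(seq.n_rows, int)
    overlaps = 0
    for step in seq.steps:
        ds, de = step.detection_band
        cov[ds:de] += 1
        det = set(range(ds, de))
        for s, e in step.pattern.bands:
            overlaps += len(det & set(range(s, e)))
    return cov, overlaps


def mirror_phantom(extent=330.0):
    """Pure-specular scene: zero diffuse reflectance, no stain."""
    return fs.render_phantom([], extent, 1.0, nuclear_optical_depth=0.0,
                             background_optical_depth=0.0,
                             nuclear_fluor_yield=0.0, background_fluor_yield=0.0,
                             diffuse_reflectance=0.0)


class TestScanSequence:
    def test_example_geometry_12_rows(self):
        seq = fs.make_scan_sequence(12, band_height_rows=4, offset_rows=1,
                                    line_width_rows=2)
        assert seq.n_steps == 3
        cov, overlaps = audit_rows(seq)
        assert (cov == 1).all()
        assert overlaps == 0
        # middle step has a full flanking pair, edge steps a single line
        assert len(seq.steps[1].pattern.bands) == 2
        assert len(seq.steps[0].pattern.bands) == 1
        assert len(seq.steps[-1].pattern.bands) == 1

    def test_full_band_leaves_no_room_for_lines(self):
        with pytest.raises(ValueError, match="infeasible"):
            fs.make_scan_sequence(12, band_height_rows=12, offset_rows=1,
                                  line_width_rows=2)

    @pytest.mark.parametrize("n,band,off,width", [
        (100, 10, 2, 5), (97, 16, 4, 8), (790, 16, 4, 8), (64, 7, 1, 1),
    ])
    def test_detection_bands_tile_sensor(self, n, band, off, width):
        seq = fs.make_scan_sequence(n, band, off, width)
        total = sum(s.detection_band[1] - s.detection_band[0] for s in seq.steps)
        assert total == n
        cov, overlaps = audit_rows(seq)
        assert (cov == 1).all() and overlaps == 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(30, 400), st.integers(1, 40), st.integers(1, 10),
           st.integers(1, 12))
    def test_any_feasible_geometry_is_valid(self, n, band, off, width):
        if band + 2 * (off + width) > n:
            with pytest.raises(ValueError):
                fs.make_scan_sequence(n, band, off, width)
            return
        seq = fs.make_scan_sequence(n, band, off, width)
        cov, overlaps = audit_rows(seq)
        assert (cov == 1).all() and overlaps == 0
        seq.validate()

    def test_validator_flags_overlap_and_gaps(self):
        bad = ScanSequence(
            steps=[ScanStep(IlluminationPattern(((0, 6),)), (4, 12))],
            n_rows=12, offset_rows=1)
        with pytest.raises(ValueError):
            bad.validate()

    def test_csv_export(self, tmp_path):
        seq = fs.make_scan_sequence(48, 8, 2, 4)
        seq.to_csv(tmp_path / "seq.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "seq.csv")
        assert len(df) == seq.n_steps
        assert list(df.columns)[:3] == ["step", "det_start", "det_end"]


class TestTissueReturn:
    def test_no_stain_returns_diffuse_reflectance(self, bundle300):
        p = fs.render_phantom([], 330.0, 1.0, nuclear_optical_depth=0.0,
                              background_optical_depth=0.0,
                              diffuse_reflectance=0.45)
        sig = fs.tissue_return(p, bundle300, "widefield_reflectance")
        np.testing.assert_allclose(sig.values, 0.45, rtol=1e-12)

    def test_beer_lambert_double_pass_ratio(self, bundle300):
        tau = 0.5
        nuc = fs.NucleusRecord(0.0, 0.0, 30.0, 30.0, 0.0, 1.0)
        p = fs.render_phantom([nuc], 330.0, 1.0, nuclear_optical_depth=tau,
                              background_optical_depth=0.0,
                              diffuse_reflectance=0.6)
        sig = fs.tissue_return(p, bundle300, "darkfield")
        r = np.hypot(*bundle300.core_centers.T)
        center = sig.values[r < 20].mean()
        outer = sig.values[(r > 60) & (r < 100)].mean()
        assert center / outer == pytest.approx(np.exp(-2 * tau), rel=1e-6)

    def test_single_pass_when_double_pass_off(self, bundle300):
        tau = 0.5
        nuc = fs.NucleusRecord(0.0, 0.0, 30.0, 30.0, 0.0, 1.0)
        p = fs.render_phantom([nuc], 330.0, 1.0, nuclear_optical_depth=tau,
                              background_optical_depth=0.0)
        sig = fs.tissue_return(p, bundle300, "darkfield", double_pass=False)
        r = np.hypot(*bundle300.core_centers.T)
        ratio = sig.values[r < 20].mean() / sig.values[(r > 60) & (r < 100)].mean()
        assert ratio == pytest.approx(np.exp(-tau), rel=1e-6)

    def test_fluorescence_dark_without_stain(self, bundle300, seq300, noise_free):
        p = mirror_phantom()
        cfg = fs.AcquisitionConfig(mode="fluorescence", residual_background=0.0,
                                   **noise_free)
        frame = fs.acquire(p, bundle300, cfg, seq300)
        assert frame.pixels.max() == 0

    def test_unknown_mode_rejected(self, small_phantom, bundle300):
        with pytest.raises(ValueError, match="unknown mode"):
            fs.tissue_return(small_phantom, bundle300, "brightfield")


class TestWidefield:
    def test_zero_illumination_gives_zero_frame(self, small_phantom, bundle300,
                                                noise_free):
        cfg = fs.AcquisitionConfig(mode="widefield_reflectance",
                                   illumination_level=0.0, **noise_free)
        frame = fs.acquire_widefield(small_phantom, bundle300, cfg)
        assert frame.pixels.max() == 0

    def test_specular_term_is_linear_in_r_spec(self, bundle300, noise_free):
        p = mirror_phantom()
        frames = {}
        for r in (2.0, 4.0):
            cfg = fs.AcquisitionConfig(
                mode="widefield_reflectance", specular_reflectance=r,
                residual_background=0.0, polarization_leakage=0.2,
                **noise_free)
            frames[r] = fs.acquire_widefield(p, bundle300, cfg).pixels.astype(int)
        assert np.abs(frames[4.0] - 2 * frames[2.0]).max() <= 1  # quantization

    def test_mode_restriction(self, small_phantom, bundle300):
        cfg = fs.AcquisitionConfig(mode="darkfield")
        with pytest.raises(ValueError):
            fs.acquire_widefield(small_phantom, bundle300, cfg)


class TestDarkfield:
    def test_mirror_phantom_rejected_exactly(self, bundle300, seq300, noise_free):
        p = mirror_phantom()
        cfg = fs.AcquisitionConfig(mode="darkfield", specular_reflectance=50.0,
                                   polarization_leakage=0.0, **noise_free)
        frame = fs.acquire_darkfield(p, bundle300, cfg, seq300)
        assert frame.pixels.max() == 0

    def test_equals_widefield_without_specular(self, small_phantom, bundle300,
                                               seq300, noise_free):
        # cross-mode oracle: R_spec = 0, uniform-spread limit
        base = dict(specular_reflectance=0.0, **noise_free)
        wf = fs.acquire_widefield(
            small_phantom, bundle300,
            fs.AcquisitionConfig(mode="widefield_reflectance", **base))
        df = fs.acquire_darkfield(
            small_phantom, bundle300,
            fs.AcquisitionConfig(mode="darkfield", scatter_sigma_um=np.inf, **base),
            seq300)
        np.testing.assert_array_equal(wf.pixels, df.pixels)

    def test_overlapping_apertures_leak_specular(self, bundle300, noise_free):
        p = mirror_phantom()
        n = 300
        steps = [ScanStep(IlluminationPattern(((ds, min(ds + 30, n)),)),
                          (ds, min(ds + 30, n)))
                 for ds in range(0, n, 30)]
        bad = ScanSequence(steps=steps, n_rows=n, offset_rows=0)
        cfg = fs.AcquisitionConfig(mode="darkfield", specular_reflectance=5.0,
                                   polarization_leakage=0.2, specular_cv=0.0,
                                   residual_background=0.0, **noise_free)
        frame = fs.acquire_darkfield(p, bundle300, cfg, bad, validate=False)
        assert frame.pixels.max() > 0
        # fully overlapped apertures reproduce the widefield specular level
        wf = fs.acquire_widefield(
            p, bundle300, cfg.replace(mode="widefield_reflectance"))
        np.testing.assert_array_equal(frame.pixels, wf.pixels)

    def test_sequence_shape_mismatch(self, small_phantom, bundle300):
        seq = fs.make_scan_sequence(100)
        cfg = fs.AcquisitionConfig(mode="darkfield")
        with pytest.raises(ValueError, match="rows"):
            fs.acquire_darkfield(small_phantom, bundle300, cfg, seq)

    def test_determinism_with_noise(self, small_phantom, bundle300, seq300):
        cfg = fs.AcquisitionConfig(mode="darkfield", rng_seed=42)
        a = fs.acquire_darkfield(small_phantom, bundle300, cfg, seq300)
        b = fs.acquire_darkfield(small_phantom, bundle300, cfg, seq300)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestNoiseAndQuantization:
    def test_noise_off_is_identity(self):
        cfg = fs.AcquisitionConfig(shot_noise=False, read_noise_sd=0.0)
        x = np.linspace(0, 100, 50).reshape(5, 10)
        np.testing.assert_array_equal(fs.add_sensor_noise(x, cfg), x)

    def test_negative_input_rejected(self):
        cfg = fs.AcquisitionConfig()
        with pytest.raises(ValueError):
            fs.add_sensor_noise(np.array([-1.0]), cfg)

    def test_shot_noise_is_poisson(self):
        cfg = fs.AcquisitionConfig(shot_noise=True, read_noise_sd=0.0, rng_seed=0)
        x = np.full((200, 200), 5000.0)
        y = fs.add_sensor_noise(x, cfg, np.random.default_rng(0))
        assert y.var() / y.mean() == pytest.approx(1.0, abs=0.1)

    def test_quantize_rounds_half_up_and_clips(self):
        q = fs.quantize(np.array([-3.0, 0.2, 2.5, 4094.7, 9000.0]), 12)
        np.testing.assert_array_equal(q, [0, 0, 3, 4095, 4095])


class TestBackgroundSubtraction:
    def test_frame_minus_itself_is_zero(self, small_phantom, bundle300, seq300):
        cfg = fs.AcquisitionConfig(mode="darkfield", rng_seed=1)
        f = fs.acquire_darkfield(small_phantom, bundle300, cfg, seq300)
        out = fs.subtract_background(f, f)
        assert out.pixels.max() == 0
        assert out.provenance[-1][0] == "subtract_background"

    def test_residual_stray_removed_exactly(self, bundle300, noise_free):
        # a void scene contains only the stray term; its paired background
        # frame is constructed identically, so subtraction is exact
        cfg = fs.AcquisitionConfig(mode="widefield_reflectance",
                                   specular_reflectance=0.0,
                                   residual_background=0.2,
                                   polarization_leakage=0.5, **noise_free)
        f = fs.acquire_widefield(mirror_phantom(), bundle300, cfg)
        bg = fs.acquire_background(bundle300, cfg)
        assert f.pixels.max() > 0
        assert fs.subtract_background(f, bg).pixels.max() == 0

    def test_clipping_at_zero(self, small_phantom, bundle300, noise_free):
        cfg = fs.AcquisitionConfig(mode="widefield_reflectance", **noise_free)
        f = fs.acquire_widefield(small_phantom, bundle300, cfg)
        brighter = fs.RawFrame(pixels=(f.pixels + 10).astype(np.uint16),
                               mode=f.mode, config=f.config,
                               pixel_pitch_um=f.pixel_pitch_um,
                               fov_diameter_um=f.fov_diameter_um)
        out = fs.subtract_background(f, brighter)
        assert out.pixels.max() == 0

    def test_shape_mismatch_rejected(self, small_phantom, bundle300, noise_free):
        cfg = fs.AcquisitionConfig(mode="widefield_reflectance", **noise_free)
        f = fs.acquire_widefield(small_phantom, bundle300, cfg)
        small = fs.RawFrame(pixels=f.pixels[:10, :10], mode=f.mode,
                            config=f.config, pixel_pitch_um=1.0,
                            fov_diameter_um=f.fov_diameter_um)
        with pytest.raises(ValueError):
            fs.subtract_background(f, small)


def test_raw_frame_save_with_sidecar(tmp_path, small_phantom, bundle300,
                                     seq300):
    cfg = fs.AcquisitionConfig(mode="darkfield", rng_seed=9)
    f = fs.acquire_darkfield(small_phantom, bundle300, cfg, seq300)
    f.save(tmp_path / "frame.tif")
    import json, tifffile
    arr = tifffile.imread(tmp_path / "frame.tif")
    np.testing.assert_array_equal(arr, f.pixels)
    meta = json.loads((tmp_path / "frame.json").read_text())
    assert meta["mode"] == "darkfield"
    assert meta["config"]["rng_seed"] == 9
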