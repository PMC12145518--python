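"""Stain-ellipse detection, cropping, resizing, and CLAHE."""

import numpy as np
import pytest

from papillae import (AnnotatedSample, ImageGrid, PointSet, PreprocessConfig,
                      clahe_normalize, crop_square, detect_ellipse,
                      preprocess_sample, resize_to_standard)
from papillae.preprocess import EllipseRegion
from papillae.errors import DetectionError, StageError, ValidationError


def render_stain(shape, center, a, b, theta):
    """Light background with a filled blue-dominant ellipse."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.sin(theta) + dc * np.cos(theta)
    v = -dr * np.cos(theta) + dc * np.sin(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1
    img = np.empty(shape + (3,), dtype=np.float32)
    img[...] = [0.8, 0.6, 0.55]
    img[inside] = [0.25, 0.3, 0.6]
    return ImageGrid(img)


class TestDetectEllipse:
    def test_recovers_disk_center_and_radius(self):
        img = render_stain((300, 300), (120, 130), 80, 80, 0.0)
        ell = detect_ellipse(img, PreprocessConfig())
        assert abs(ell.center[0] - 120) < 1 and abs(ell.center[1] - 130) < 1
        assert abs(ell.semi_axes[0] - 80) < 2 and abs(ell.semi_axes[1] - 80) < 2

    def test_recovers_rotated_ellipse_parameters(self):
        img = render_stain((300, 300), (150, 150), 90, 60, 0.4)
        ell = detect_ellipse(img, PreprocessConfig())
        assert ell.semi_axes[0] == pytest.approx(90, rel=0.03)
        assert ell.semi_axes[1] == pytest.approx(60, rel=0.03)
        assert ell.orientation == pytest.approx(0.4, abs=0.03)

    def test_all_background_raises_detection_error(self):
        img = ImageGrid(np.full((100, 100, 3), [0.8, 0.6, 0.55], dtype=np.float32))
        with pytest.raises(DetectionError):
            detect_ellipse(img, PreprocessConfig())

    def test_grayscale_rejected(self):
        with pytest.raises(ValidationError):
            detect_ellipse(ImageGrid(np.zeros((50, 50, 1))), PreprocessConfig())


class TestCropSquare:
    def test_centered_crop_arithmetic(self):
        img = ImageGrid(np.random.default_rng(0).random((300, 300, 3)))
        ell = EllipseRegion(center=(100, 100), semi_axes=(50, 50), orientation=0)
        crop, t = crop_square(img, ell, margin=0.0)
        assert crop.shape == (100, 100)
        assert t.crop_offset == (50.0, 50.0)

    def test_margin_widens_side(self):
        img = ImageGrid(np.zeros((300, 300, 3)))
        ell = EllipseRegion(center=(150, 150), semi_axes=(50, 50), orientation=0)
        crop, _ = crop_square(img, ell, margin=0.1)
        assert crop.shape == (110, 110)

    def test_border_ellipse_clamped_but_square(self):
        img = ImageGrid(np.random.default_rng(1).random((200, 200, 3)))
        ell = EllipseRegion(center=(10, 190), semi_axes=(40, 40), orientation=0)
        crop, t = crop_square(img, ell, margin=0.0)
        assert crop.shape[0] == crop.shape[1] == 80
        r0, c0 = t.crop_offset
        assert r0 >= 0 and c0 + 80 <= 200
        # transform consistency: crop pixel (0,0) equals source pixel (r0,c0)
        assert np.array_equal(crop.pixels[0, 0], img.pixels[int(r0), int(c0)])


class TestResize:
    def test_downscale_records_scale(self, rng):
        img = ImageGrid(rng.random((500, 500, 3), dtype=np.float32))
        out, t = resize_to_standard(img, PreprocessConfig(target_side=250))
        assert out.shape == (250, 250) and t.scale == (0.5, 0.5)

    def test_already_standard_is_identity(self, rng):
        img = ImageGrid(rng.random((250, 250, 3), dtype=np.float32))
        out, t = resize_to_standard(img, PreprocessConfig())
        assert out is img and t.scale == (1.0, 1.0)

    def test_constant_input_stays_constant(self):
        img = ImageGrid(np.full((100, 100, 3), 0.4, dtype=np.float32))
        out, _ = resize_to_standard(img, PreprocessConfig(target_side=250))
        assert np.allclose(out.pixels, 0.4, atol=1e-5)

    def test_non_square_rejected(self, rng):
        img = ImageGrid(rng.random((100, 120, 3), dtype=np.float32))
        with pytest.raises(ValidationError):
            resize_to_standard(img, PreprocessConfig())


class TestClahe:
    def test_constant_image_unchanged(self):
        img = ImageGrid(np.full((64, 64, 3), 0.5, dtype=np.float32))
        out = clahe_normalize(img, PreprocessConfig())
        assert np.allclose(out.pixels, 0.5)

    def test_output_stays_in_unit_range(self, rng):
        img = ImageGrid(rng.random((64, 64, 3), dtype=np.float32))
        for lum in (True, False):
            out = clahe_normalize(img, PreprocessConfig(clahe_on_luminance=lum))
            assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_enhances_spot_background_contrast(self):
        # low-contrast spots on a mid-gray background
        rng = np.random.default_rng(3)
        img = np.full((128, 128, 3), 0.45)
        spot_mask = np.zeros((128, 128), dtype=bool)
        for r, c in rng.integers(20, 108, (10, 2)):
            rr, cc = np.mgrid[r - 3:r + 4, c - 3:c + 4]
            spot_mask[rr, cc] = True
            img[rr, cc] += 0.05
        img = ImageGrid(np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1))
        out = clahe_normalize(img, PreprocessConfig())

        def contrast(grid):
            lum = grid.pixels.mean(axis=2)
            return lum[spot_mask].mean() - lum[~spot_mask].mean()

        assert contrast(out) > contrast(img)


class TestFullChain:
    def test_synthetic_scene_preprocesses_to_standard_frame(self):
        from papillae import SceneConfig, generate_scene
        scene = generate_scene(SceneConfig(image_size=(250, 250), n_spots=15,
                                           seed=9, noise_sd=0.01))
        cfg = PreprocessConfig(target_side=250)
        done = preprocess_sample(scene, cfg)
        assert done.image.shape == (250, 250)
        assert len(done.annotations) == 15
        assert len(done.transform_log) == 2

    def test_determinism(self):
        from papillae import SceneConfig, generate_scene
        scene = generate_scene(SceneConfig(n_spots=10, seed=4))
        a = preprocess_sample(scene, PreprocessConfig())
        b = preprocess_sample(scene, PreprocessConfig())
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.annotations.coords, b.annotations.coords)

    def test_annotation_alignment_with_rendered_spots(self):
        # after preprocessing, each mapped annotation must sit within 2 px
        # of a local brightness maximum of its spot
        from papillae import SceneConfig, generate_scene
        scene = generate_scene(SceneConfig(
            image_size=(250, 250), n_spots=8, seed=21, noise_sd=0.0,
            background_speckle_density=0.0, spot_contrast=(0.3, 0.4)))
        done = preprocess_sample(scene, PreprocessConfig())
        lum = done.image.pixels.mean(axis=2)
        for r, c in done.annotations:
            ri, ci = int(round(r)), int(round(c))
            window = lum[max(0, ri - 4):ri + 5, max(0, ci - 4):ci + 5]
            peak = np.unravel_index(np.argmax(window), window.shape)
            dr = peak[0] - min(4, ri)
            dc = peak[1] - min(4, ci)
            assert abs(dr) <= 2 and abs(dc) <= 2

    def test_stage_error_names_stage(self):
        img = ImageGrid(np.full((100, 100, 3), [0.8, 0.6, 0.55], dtype=np.float32))
        sample = AnnotatedSample(image=img, annotations=PointSet.from_list([]),
                                 sample_id="flat")
        with pytest.raises(StageError, match="detect_ellipse"):
            preprocess_sample(sample, PreprocessConfig())
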