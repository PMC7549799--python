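"""Extremum detection, localization, orientation and descriptors."""

import numpy as np
import pytest

from finid import DEFAULT_CONFIG
from finid.features import (
    Descriptor,
    GradientField,
    Keypoint,
    assign_orientations,
    compute_descriptor,
    detect_extrema,
    extract_features,
    gradient_field,
    load_descriptors,
    localize_keypoint,
    save_descriptors,
)
from finid.imaging import GrayImage
from finid.scale_space import DoGStack, ReducedDoG
from finid.synthetic_fins import FinSpec, generate_fin


def make_reduced(diffs, retained=None):
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    sig = 1.6 * 2 ** (np.arange(n) / 2)
    if retained is None:
        retained = np.ones_like(diffs, dtype=bool)
    return ReducedDoG(diffs=diffs, sigmas=sig, k=2**0.5, retained=retained)


def make_dog(diffs):
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    return DoGStack(diffs=diffs, sigmas=1.6 * 2 ** (np.arange(n) / 2), k=2**0.5)


def brute_force_extrema(diffs, retained, margin):
    """Exhaustive 26-neighbor scan (oracle)."""
    n, H, W = diffs.shape
    out = []
    for m in range(1, n - 1):
        for y in range(margin, H - margin):
            for x in range(margin, W - margin):
                if not retained[m, y, x]:
                    continue
                v = diffs[m, y, x]
                neigh = [
                    diffs[m + dm, y + dy, x + dx]
                    for dm in (-1, 0, 1)
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if not (dm == 0 and dy == 0 and dx == 0)
                ]
                if all(v > u for u in neigh) or all(v < u for u in neigh):
                    out.append((m, y, x))
    return set(out)


class TestDetectExtrema:
    def test_zero_stack_empty(self):
        assert detect_extrema(make_reduced(np.zeros((3, 16, 16)))) == []

    def test_single_impulse(self):
        diffs = np.zeros((3, 16, 16))
        diffs[1, 7, 9] = 0.5
        (kp,) = detect_extrema(make_reduced(diffs), edge_exclusion=2)
        assert (kp.level, kp.y, kp.x) == (1, 7.0, 9.0)
        assert kp.contrast == 0.5

    @pytest.mark.parametrize("margin", [1, 4])
    def test_matches_exhaustive_scan(self, rng, margin):
        for _ in range(3):
            diffs = rng.normal(size=(3, 16, 16))
            retained = rng.random((3, 16, 16)) < 0.8
            got = detect_extrema(make_reduced(diffs, retained), edge_exclusion=margin)
            got_set = {(k.level, int(k.y), int(k.x)) for k in got}
            assert got_set == brute_force_extrema(diffs, retained, margin)

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            detect_extrema(make_reduced(np.zeros((2, 16, 16))))


class TestLocalize:
    def test_on_grid_vertex_has_zero_offset(self):
        xs = np.arange(11.0)
        ys = np.arange(9.0)
        diffs = np.zeros((3, 9, 11))
        # separable quadratic with maximum exactly on the grid at (m=1, 4, 5)
        diffs[1] = 1.0 - 0.1 * ((xs[None, :] - 5) ** 2 + (ys[:, None] - 4) ** 2)
        kp = localize_keypoint(
            make_dog(diffs), Keypoint(x=5, y=4, level=1, sigma=1.6),
            contrast_threshold=0.0,
        )
        assert kp is not None
        assert np.allclose(kp.offset[:2], 0.0, atol=1e-9)
        assert (kp.x, kp.y) == (5.0, 4.0)

    def test_recovers_planted_parabola_vertex(self):
        """1-D parabola with vertex at x = 5.3 is recovered to 1e-6."""
        xs = np.arange(11.0)
        diffs = np.zeros((3, 5, 11))
        diffs[1, :, :] = -((xs[None, :] - 5.3) ** 2)
        kp = localize_keypoint(
            make_dog(diffs), Keypoint(x=5, y=2, level=1, sigma=1.6),
            contrast_threshold=0.0,
        )
        assert kp is not None
        assert abs(kp.x - 5.3) < 1e-6

    def test_low_contrast_rejected(self):
        diffs = np.zeros((3, 7, 7))
        diffs[1, 3, 3] = 0.01
        kp = localize_keypoint(
            make_dog(diffs), Keypoint(x=3, y=3, level=1, sigma=1.6),
            contrast_threshold=0.03,
        )
        assert kp is None


class TestGradientField:
    def test_constant_raster(self):
        fld = gradient_field(np.full((6, 6), 0.3))
        np.testing.assert_allclose(fld.magnitude, 0.0)
        np.testing.assert_allclose(fld.orientation, 0.0)

    def test_x_ramp(self):
        L = np.tile(np.arange(8.0), (8, 1))
        fld = gradient_field(L)
        np.testing.assert_allclose(fld.magnitude[2:-2, 2:-2], 2.0)
        np.testing.assert_allclose(fld.orientation[2:-2, 2:-2], 0.0)

    def test_y_ramp(self):
        L = np.tile(np.arange(8.0)[:, None], (1, 8))
        fld = gradient_field(L)
        np.testing.assert_allclose(fld.magnitude[2:-2, 2:-2], 2.0)
        np.testing.assert_allclose(fld.orientation[2:-2, 2:-2], np.pi / 2)


class TestOrientations:
    def _kp(self):
        return Keypoint(x=10.0, y=10.0, level=1, sigma=1.0)

    def test_single_direction_single_peak(self):
        theta0 = 1.0
        fld = GradientField(
            magnitude=np.ones((21, 21)), orientation=np.full((21, 21), theta0)
        )
        oriented = assign_orientations(self._kp(), fld, n_bins=36)
        assert len(oriented) == 1
        assert abs(oriented[0].orientations[0] - theta0) <= np.pi / 36

    def test_two_equal_orthogonal_directions(self):
        mag = np.ones((21, 21))
        mag[:, 10] = 0.0  # keep the two half-planes exactly balanced
        ori = np.zeros((21, 21))
        ori[:, 11:] = np.pi / 2
        fld = GradientField(magnitude=mag, orientation=ori)
        oriented = assign_orientations(self._kp(), fld, n_bins=36)
        assert len(oriented) == 2

    def test_zero_gradient_drops_keypoint(self):
        fld = GradientField(magnitude=np.zeros((21, 21)), orientation=np.zeros((21, 21)))
        assert assign_orientations(self._kp(), fld) == []

    def test_window_outside_image_rejected(self):
        fld = GradientField(magnitude=np.ones((21, 21)), orientation=np.zeros((21, 21)))
        kp = Keypoint(x=100.0, y=100.0, level=1, sigma=1.0)
        assert assign_orientations(kp, fld) == []


class TestDescriptor:
    def test_zero_window_rejected(self):
        fld = GradientField(magnitude=np.zeros((40, 40)), orientation=np.zeros((40, 40)))
        kp = Keypoint(x=20.0, y=20.0, level=1, sigma=1.6, orientations=(0.5,))
        assert compute_descriptor(kp, fld) is None

    def test_unit_norm_and_clamp(self, rng):
        fld = gradient_field(rng.random((48, 48)))
        kp = Keypoint(x=24.0, y=24.0, level=1, sigma=2.0, orientations=(1.2,))
        desc = compute_descriptor(kp, fld)
        assert desc is not None
        assert abs(np.linalg.norm(desc.values) - 1.0) < 1e-6
        assert desc.values.max() <= 0.2 + 1e-6

    def test_rotation_invariance_quarter_turn(self):
        """Descriptor of a co-rotated keypoint on the 90-degree-rotated image
        matches the original within L2 0.15."""
        sample = generate_fin(FinSpec(label="right_hooked", noise_sigma=0.0, seed=4))
        img = sample.image.pixels
        H, W = img.shape
        fld = gradient_field(img)
        kp = Keypoint(x=80.0, y=70.0, level=1, sigma=3.0, orientations=(0.7,))
        desc = compute_descriptor(kp, fld)
        rot = np.rot90(img)  # counter-clockwise quarter turn
        fld_r = gradient_field(rot)
        kp_r = Keypoint(
            x=kp.y, y=W - 1 - kp.x, level=1, sigma=3.0,
            orientations=((kp.orientations[0] - np.pi / 2) % (2 * np.pi),),
        )
        desc_r = compute_descriptor(kp_r, fld_r)
        assert desc is not None and desc_r is not None
        assert np.linalg.norm(desc.values - desc_r.values) <= 0.15

    def test_requires_single_orientation(self):
        fld = GradientField(magnitude=np.ones((10, 10)), orientation=np.zeros((10, 10)))
        with pytest.raises(ValueError):
            compute_descriptor(Keypoint(x=5, y=5, level=0, sigma=1.0), fld)


class TestExtractFeatures:
    def test_constant_image_empty(self):
        assert extract_features(GrayImage(np.full((32, 32), 0.5))) == []

    def test_synthetic_fin_yields_descriptors(self):
        sample = generate_fin(FinSpec(label="left_falcate", seed=2,
                                      height_px=128, width_px=128))
        descs = extract_features(sample.image)
        assert len(descs) >= 1

    def test_deterministic(self):
        sample = generate_fin(FinSpec(label="right_triangular", seed=5))
        a = extract_features(sample.image)
        b = extract_features(sample.image)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.values, db.values)

    def test_translation_equivariance(self):
        """Shifting the scene by (5, 5) px shifts keypoints by (5, 5)."""
        sample = generate_fin(
            FinSpec(label="right_falcate", noise_sigma=0.0, seed=8,
                    height_px=128, width_px=128)
        )
        canvas = np.full((160, 160), 0.75)
        a = canvas.copy()
        a[8:136, 8:136] = sample.image.pixels
        b = canvas.copy()
        b[13:141, 13:141] = sample.image.pixels
        kps_a = [(d.keypoint.level, d.keypoint.y, d.keypoint.x)
                 for d in extract_features(GrayImage(a))]
        kps_b = [(d.keypoint.level, d.keypoint.y, d.keypoint.x)
                 for d in extract_features(GrayImage(b))]
        assert kps_a
        matched = 0
        for lvl, y, x in kps_a:
            if any(
                l2 == lvl and abs(y2 - (y + 5)) <= 0.5 and abs(x2 - (x + 5)) <= 0.5
                for l2, y2, x2 in kps_b
            ):
                matched += 1
        assert matched / len(kps_a) >= 0.8

    def test_descriptor_roundtrip(self, tmp_path):
        sample = generate_fin(FinSpec(label="right_hooked", seed=3))
        descs = extract_features(sample.image)
        path = tmp_path / "d.json"
        save_descriptors(descs, path, config_hash=DEFAULT_CONFIG.config_hash)
        loaded, chash = load_descriptors(path)
        assert chash == DEFAULT_CONFIG.config_hash
        assert len(loaded) == len(descs)
        for a, b in zip(descs, loaded):
            np.testing.assert_allclose(a.values, b.values)
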