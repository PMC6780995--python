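import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnclonal import (
    BinaryMask,
    MarkedPointPattern,
    area_fraction,
    compute_ln_boundary,
    extract_point_pattern,
    render_pattern_to_image,
    simulate_csr_pattern,
    threshold_channel,
)
from lnclonal.exceptions import (
    ConfigError,
    DegenerateHullError,
    DegenerateThresholdError,
    EmptyPatternError,
    InvalidMaskError,
)
from lnclonal.imaging import read_image_tiff, write_image_tiff


class TestThreshold:
    def test_manual_step_image(self):
        ch = np.zeros((20, 20))
        ch[5:10, 5:10] = 100.0
        mask = threshold_channel(ch, "manual", manual_value=50.0)
        assert mask.n_true == 25
        assert mask.threshold == 50.0 and mask.method == "manual"

    def test_otsu_lies_between_bimodal_means(self):
        rng = np.random.default_rng(0)
        ch = np.concatenate(
            [rng.normal(20, 3, 5000), rng.normal(200, 10, 5000)]
        ).reshape(100, 100)
        mask = threshold_channel(ch, "otsu")
        assert 20 < mask.threshold < 200

    def test_constant_channel_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            threshold_channel(np.full((10, 10), 7.0), "otsu")

    def test_manual_requires_value(self):
        with pytest.raises(ConfigError):
            threshold_channel(np.zeros((4, 4)), "manual")


def _disc_image(radius_px=2):
    """One noiseless disc in a cRFP channel; returns (stack, n_disc_px)."""
    from skimage.draw import disk

    stack = np.zeros((2, 32, 32))
    rr, cc = disk((16, 16), radius_px + 0.01)
    stack[0, rr, cc] = 100.0
    return stack, len(rr)


class TestExtract:
    def test_pixel_mode_counts_positive_pixels(self):
        stack, n_px = _disc_image()
        ln = BinaryMask(np.ones((32, 32), dtype=bool))
        pat = extract_point_pattern(
            stack, {0: "cRFP", 1: "cYFP"}, ln,
            mode="pixel", manual_thresholds={"cRFP": 50, "cYFP": 50},
        )
        assert pat.n_points == n_px == 13
        assert set(pat.marks) == {"cRFP"}

    def test_centroid_mode_finds_disc_center(self):
        stack, _ = _disc_image()
        ln = BinaryMask(np.ones((32, 32), dtype=bool))
        pat = extract_point_pattern(
            stack, {0: "cRFP", 1: "cYFP"}, ln,
            mode="centroid", manual_thresholds={"cRFP": 50, "cYFP": 50},
        )
        assert pat.n_points == 1
        # disc center is pixel (16, 16) -> point at its center, 16.5 um
        np.testing.assert_allclose(pat.xy[0], [16.5, 16.5], atol=0.5)

    def test_multi_positive_policies(self):
        stack = np.zeros((2, 8, 8))
        stack[0, 4, 4] = 80.0   # cRFP
        stack[1, 4, 4] = 120.0  # cYFP
        ln = BinaryMask(np.ones((8, 8), dtype=bool))
        kw = dict(mode="pixel", manual_thresholds={"cRFP": 50, "cYFP": 50})
        pat = extract_point_pattern(stack, {0: "cRFP", 1: "cYFP"}, ln,
                                    multi_positive="argmax", **kw)
        assert list(pat.marks) == ["cYFP"]
        with pytest.raises(EmptyPatternError):
            extract_point_pattern(stack, {0: "cRFP", 1: "cYFP"}, ln,
                                  multi_positive="exclude", **kw)

    def test_ln_mask_restricts_points(self):
        stack, _ = _disc_image()
        ln = BinaryMask(np.zeros((32, 32), dtype=bool))  # mask excludes disc
        with pytest.raises(EmptyPatternError):
            extract_point_pattern(stack, {0: "cRFP", 1: "cYFP"}, ln,
                                  manual_thresholds={"cRFP": 50, "cYFP": 50})

    def test_missing_channel_is_config_error(self, csr_equal4):
        img = render_pattern_to_image(csr_equal4, pixel_size=0.02, seed=0)
        ln = BinaryMask(np.ones(img.channels.shape[1:], dtype=bool))
        with pytest.raises(ConfigError):
            extract_point_pattern(img, {"nope": "A"}, ln)


class TestBoundary:
    def test_interior_point_excluded(self, unit_square):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0.1, 0.1]], dtype=float)
        hull = compute_ln_boundary(pts)
        assert len(hull.vertices) == 3
        assert hull.area == pytest.approx(0.5)

    def test_hull_of_csr_close_to_square(self, unit_square):
        pat = simulate_csr_pattern(unit_square, {"A": 1000}, 12)
        hull = compute_ln_boundary(pat)
        assert 0.9 <= hull.area <= 1.0
        assert np.all(hull.contains(pat.xy[:, 0], pat.xy[:, 1]))

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateHullError):
            compute_ln_boundary(np.array([[0, 0], [1, 1]], dtype=float))
        with pytest.raises(DegenerateHullError):
            compute_ln_boundary(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=4, max_size=30))
    def test_adding_a_point_never_shrinks_hull(self, coords):
        pts = np.asarray(coords)
        try:
            base = compute_ln_boundary(pts[:-1])
            grown = compute_ln_boundary(pts)
        except DegenerateHullError:
            return
        assert grown.area >= base.area - 1e-9


class TestAreaFraction:
    def test_quarter_coverage(self):
        ln = BinaryMask(np.ones((10, 10), dtype=bool))
        sig = np.zeros((10, 10), dtype=bool)
        sig[:5, :5] = True
        res = area_fraction(BinaryMask(sig), ln)
        assert (res.ln_area_px, res.positive_area_px) == (100, 25)
        assert res.fraction == 0.25

    def test_bounds(self):
        ln_px = np.zeros((10, 10), dtype=bool)
        ln_px[2:8, 2:8] = True
        ln = BinaryMask(ln_px)
        assert area_fraction(BinaryMask(np.ones((10, 10), bool)), ln).fraction == 1.0
        assert area_fraction(BinaryMask(np.zeros((10, 10), bool)), ln).fraction == 0.0

    def test_invariant_to_signal_outside_ln(self):
        ln_px = np.zeros((10, 10), dtype=bool)
        ln_px[2:8, 2:8] = True
        ln = BinaryMask(ln_px)
        sig = np.zeros((10, 10), dtype=bool)
        sig[3:5, 3:5] = True
        base = area_fraction(BinaryMask(sig), ln).fraction
        sig_noisy = sig.copy()
        sig_noisy[0, :] = True  # outside the tissue mask
        assert area_fraction(BinaryMask(sig_noisy), ln).fraction == base

    def test_empty_ln_mask_rejected(self):
        with pytest.raises(InvalidMaskError):
            area_fraction(BinaryMask(np.ones((4, 4), bool)),
                          BinaryMask(np.zeros((4, 4), bool)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidMaskError):
            area_fraction(BinaryMask(np.ones((4, 4), bool)),
                          BinaryMask(np.ones((5, 5), bool)))


class TestRoundTrip:
    def test_render_threshold_extract_recovers_points(self, unit_square):
        """Noiseless, non-overlapping spots: centroid extraction recovers
        the generated point count exactly and positions within 1 px."""
        rng = np.random.default_rng(3)
        # points on a jittered grid so spots never touch
        gx, gy = np.meshgrid(np.arange(10), np.arange(10))
        xy = (np.column_stack([gx.ravel(), gy.ravel()]) * 10 + 5
              + rng.uniform(-1, 1, (100, 2)))
        marks = np.array(rng.choice(["A", "B"], 100), dtype=object)
        from lnclonal import rectangle_domain

        pat = MarkedPointPattern(xy, marks, rectangle_domain(0, 0, 100, 100))
        img = render_pattern_to_image(pat, pixel_size=1.0, spot_radius=2,
                                      background_noise_sd=0.0, seed=0)
        ln = BinaryMask(np.ones(img.channels.shape[1:], dtype=bool))
        rec = extract_point_pattern(
            img, {"A": "A", "B": "B"}, ln, mode="centroid",
            manual_thresholds={"A": 0.5, "B": 0.5},
        )
        assert rec.n_points == pat.n_points
        # match recovered to true points; every distance within 1 px (1 um)
        from scipy.spatial import cKDTree

        d, idx = cKDTree(rec.xy).query(pat.xy)
        assert np.max(d) <= 1.0
        assert all(rec.marks[i] == m for i, m in zip(idx, pat.marks))

    def test_pixel_mode_count_equals_positive_pixels(self, unit_square):
        pat = MarkedPointPattern(
            np.array([[0.5, 0.5]]), np.array(["A"], dtype=object), unit_square
        )
        img = render_pattern_to_image(pat, pixel_size=0.05, spot_radius=2, seed=0)
        ln = BinaryMask(np.ones(img.channels.shape[1:], dtype=bool))
        rec = extract_point_pattern(img, {"A": "A"}, ln, mode="pixel",
                                    manual_thresholds={"A": 0.5})
        assert rec.n_points == int(np.sum(img.channels[0] > 0.5))


def test_tiff_roundtrip(tmp_path, csr_equal4):
    img = render_pattern_to_image(csr_equal4, pixel_size=0.02, spot_radius=1,
                                  background_noise_sd=0.05, seed=9)
    path = tmp_path / "img.tiff"
    write_image_tiff(img, path)
    back = read_image_tiff(path)
    assert back.channel_names == img.channel_names
    assert back.pixel_size == img.pixel_size
    np.testing.assert_allclose(back.channels, img.channels, atol=1e-6)


def test_area_fraction_results_csv(tmp_path):
    from lnclonal.imaging import append_area_fraction_csv

    ln = BinaryMask(np.ones((10, 10), dtype=bool))
    sig = np.zeros((10, 10), dtype=bool)
    sig[:5, :5] = True
    res = area_fraction(BinaryMask(sig), ln)
    path = tmp_path / "area.csv"
    append_area_fraction_csv(path, "LN01", res)
    append_area_fraction_csv(path, "LN02", res)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "sample_id,ln_area_px,positive_area_px,fraction"
    assert lines[1] == "LN01,100,25,0.25"
    assert len(lines) == 3
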