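from dataclasses import replace

import numpy as np
import pytest

from dualae.errors import DegenerateDataError
from dualae.phantom import Image2D
from dualae import patches as pt


def enumerate_windows(shape, stride, win):
    """Reference oracle: all distinct clamped window top-left positions."""
    rows, cols = shape
    h, w = win
    rpos = list(range(0, rows - 16 + 1, stride))
    if rpos[-1] != rows - 16:
        rpos.append(rows - 16)
    cpos = list(range(0, cols - 16 + 1, stride))
    if cpos[-1] != cols - 16:
        cpos.append(cols - 16)
    seen = set()
    for r in rpos:
        for c in cpos:
            seen.add((min(r, rows - h), min(c, cols - w)))
    return sorted(seen)


class TestGrid:
    @pytest.mark.parametrize("shape,expected_h", [
        ((256, 256), 16 * 13),  # 16 row x 13 clamped col positions
        ((64, 64), 4),          # 4 rows x 1 clamped col position
    ])
    def test_window_counts_match_enumeration_oracle(self, shape, expected_h):
        grid = pt.build_grid(shape, 16)
        wins = grid.window_anchors(pt.HORIZONTAL)
        oracle = enumerate_windows(shape, 16, (16, 64))
        assert len(wins) == expected_h
        assert [tuple(a) for a in wins] == oracle

    def test_vertical_windows_match_oracle(self):
        grid = pt.build_grid((192, 256), 16)
        wins = grid.window_anchors(pt.VERTICAL)
        assert [tuple(a) for a in wins] == enumerate_windows(
            (192, 256), 16, (64, 16))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            pt.build_grid((63, 64), 16)

    def test_anchors_sorted_unique_row_major(self):
        grid = pt.build_grid((128, 160), 16)
        anchors = [tuple(a) for a in grid.anchors]
        assert anchors == sorted(set(anchors))

    def test_full_coverage_both_orientations(self):
        grid = pt.build_grid((130, 67), 16)
        for orientation, (h, w) in pt.PATCH_SHAPES.items():
            cov = np.zeros((130, 67), dtype=int)
            for r, c in grid.clamped_anchors(orientation):
                cov[r:r + h, c:c + w] += 1
            assert cov.min() >= 1


class TestExtract:
    def test_constant_image(self):
        grid = pt.build_grid((64, 64))
        img = Image2D(np.full((64, 64), 0.5))
        ps = pt.extract(img, grid, pt.HORIZONTAL)
        assert np.all(ps.data == 0.5)
        assert ps.data.shape == (grid.n_anchors, 1024)

    def test_window_content_is_definitional(self):
        rows, cols = 64, 128
        img = Image2D(np.tile(np.arange(cols) / cols, (rows, 1)))
        grid = pt.build_grid((rows, cols))
        ps = pt.extract(img, grid, pt.HORIZONTAL)
        first_row = ps.data[0][:64]  # anchor (0, 0), first patch row
        assert np.array_equal(first_row, img.pixels[0, 0:64])

    def test_extraction_is_pure(self, small_phantom):
        img, _ = small_phantom
        before = img.pixels.copy()
        grid = pt.build_grid(img.shape)
        pt.extract(img, grid, pt.VERTICAL)
        assert np.array_equal(img.pixels, before)

    @pytest.mark.parametrize("orientation", [pt.HORIZONTAL, pt.VERTICAL])
    def test_extract_reassemble_round_trip(self, small_phantom, orientation):
        img, _ = small_phantom
        grid = pt.build_grid(img.shape)
        ps = pt.extract(img, grid, orientation)
        out, cov = pt.reassemble(ps.data, grid, orientation)
        # mean of identical covering values: exact up to float addition
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=0, atol=1e-12)
        assert cov.min() >= 1


class TestNorm:
    def test_degenerate_constant_data_rejected(self):
        grid = pt.build_grid((64, 64))
        ps = pt.PatchSet(pt.HORIZONTAL, np.full((grid.n_anchors, 1024), 0.3),
                         grid)
        with pytest.raises(DegenerateDataError):
            pt.fit_norm([ps])

    def test_population_convention(self):
        # pooled entries {0, 2} in equal parts -> mean 1, std 1
        grid = pt.build_grid((64, 64))
        data = np.zeros((grid.n_anchors, 1024))
        data[:, ::2] = 2.0
        ps = pt.PatchSet(pt.HORIZONTAL, data, grid)
        norm = pt.fit_norm([ps])
        assert norm.mean == pytest.approx(1.0)
        assert norm.std == pytest.approx(1.0)

    def test_idempotent_under_duplication(self, small_phantom):
        img, _ = small_phantom
        grid = pt.build_grid(img.shape)
        ps = pt.extract(img, grid, pt.HORIZONTAL)
        n1 = pt.fit_norm([ps])
        n2 = pt.fit_norm([ps, ps])
        assert n1 == n2

    def test_mean_maps_to_midpoint_for_symmetric_range(self):
        norm = pt.NormStats(mean=0.5, std=1.0, s_lo=-2.0, s_hi=2.0)
        assert norm.forward(np.array(0.5)) == pytest.approx(0.5)

    def test_standardization_arithmetic(self):
        # mean 10, std 2, x 12 -> standardized 1.0 before range mapping
        norm = pt.NormStats(mean=10.0, std=2.0, s_lo=-3.0, s_hi=3.0)
        y = norm.forward(np.array(12.0))
        s = norm.s_lo + (y - 0.1) * (norm.s_hi - norm.s_lo) / 0.8
        assert s == pytest.approx(1.0)

    def test_round_trip_within_1e10(self, small_phantom):
        img, _ = small_phantom
        grid = pt.build_grid(img.shape)
        ps = pt.extract(img, grid, pt.VERTICAL)
        norm = pt.fit_norm([ps])
        back = pt.denormalize(pt.normalize(ps, norm))
        np.testing.assert_allclose(back.data, ps.data, rtol=0, atol=1e-10)

    def test_training_data_lands_in_target_range(self, small_phantom):
        img, _ = small_phantom
        grid = pt.build_grid(img.shape)
        ps = pt.extract(img, grid, pt.HORIZONTAL)
        norm = pt.fit_norm([ps])
        z = pt.normalize(ps, norm).data
        assert z.min() >= 0.1 - 1e-12 and z.max() <= 0.9 + 1e-12


class TestReassemble:
    def test_constant_patches(self):
        grid = pt.build_grid((64, 64))
        mat = np.full((grid.n_anchors, 1024), 0.7)
        out, _ = pt.reassemble(mat, grid, pt.HORIZONTAL)
        np.testing.assert_allclose(out.pixels, 0.7)

    def test_mean_of_two_disagreeing_patches(self):
        # border clamping collapses two anchors onto one window; give the
        # two patches values 0 and 1 and check shared pixels average to 0.5
        grid2 = pt.build_grid((64, 80), 16)
        dup = grid2.clamped_anchors(pt.HORIZONTAL)
        # find two anchor indices mapping to the same clamped window
        _, first_idx, counts = np.unique(dup, axis=0, return_index=True,
                                         return_counts=True)
        k = int(first_idx[counts > 1][0])
        twin = [i for i, a in enumerate(dup)
                if tuple(a) == tuple(dup[k]) and i != k][0]
        mat2 = np.zeros((grid2.n_anchors, 1024))
        mat2[k] = 0.0
        mat2[twin] = 1.0
        out, cov = pt.reassemble(mat2, grid2, pt.HORIZONTAL)
        r, c = dup[k]
        region = out.pixels[r:r + 16, c:c + 64]
        covr = cov[r:r + 16, c:c + 64]
        assert np.all(region[covr == 2] == 0.5)

    def test_shape_mismatch_rejected(self):
        grid = pt.build_grid((64, 64))
        with pytest.raises(ValueError):
            pt.reassemble(np.zeros((3, 1024)), grid, pt.HORIZONTAL)


def test_patch_set_serialization_round_trip(tmp_path, small_phantom):
    img, _ = small_phantom
    grid = pt.build_grid(img.shape)
    ps = pt.extract(img, grid, pt.HORIZONTAL)
    norm = pt.fit_norm([ps])
    ps = pt.normalize(ps, norm)
    path = tmp_path / "patches.bin"
    pt.save_patch_set(ps, path)
    loaded = pt.load_patch_set(path)
    assert loaded.orientation == ps.orientation
    assert np.array_equal(loaded.data, ps.data)
    assert loaded.norm == ps.norm
    assert np.array_equal(loaded.grid.anchors, ps.grid.anchors)


class TestNormProperties:
    """Normalization inverts exactly for any admissible statistics."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    finite = st.floats(min_value=-100.0, max_value=100.0,
                       allow_nan=False, allow_infinity=False)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(mean=finite, std=st.floats(min_value=1e-3, max_value=100.0),
           x=finite)
    def test_round_trip_for_arbitrary_stats(self, mean, std, x):
        norm = pt.NormStats(mean=mean, std=std, s_lo=-4.0, s_hi=4.0)
        back = norm.inverse(norm.forward(np.array(x)))
        assert back == pytest.approx(x, abs=1e-8 * max(1.0, abs(x), std))
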