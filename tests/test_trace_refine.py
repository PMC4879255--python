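"""Trace resampling and contrast-snapping refinement."""

import numpy as np
import pytest

from crowdoct.trace_refine import (BoundaryTrace, RefineConfig,
                                   _brute_force_best_path, _dp_best_path,
                                   contrast_score, resample_trace,
                                   snap_to_contrast)

from conftest import make_trace


def step_image(height, width, edge_row, low=0.2, high=0.8):
    """Sharp horizontal step: rows <= edge_row are `low`, below are `high`."""
    img = np.full((height, width), low)
    img[edge_row + 1:, :] = high
    return img


class TestResample:
    def test_midpoint_interpolation(self):
        x, y = resample_trace([(0, 10), (4, 18)])
        assert y[list(x).index(2)] == 14.0

    def test_identity_when_already_per_column(self):
        verts = [(i, 5.0 + i) for i in range(10)]
        x, y = resample_trace(verts)
        np.testing.assert_array_equal(x, np.arange(10))
        np.testing.assert_allclose(y, 5.0 + np.arange(10))

    def test_duplicate_x_collapsed_to_mean(self):
        x, y = resample_trace([(0, 10), (0, 20), (2, 30)])
        assert y[0] == 15.0

    def test_unsorted_vertices_handled(self):
        x, y = resample_trace([(4, 18), (0, 10)])
        assert y[2] == 14.0

    def test_matches_segmentwise_oracle(self):
        """Random polylines: np.interp-based resampling equals explicit
        per-segment linear evaluation at every integer column."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 50
            xs = np.sort(rng.uniform(0, 200, size=n))
            xs += np.arange(n) * 1e-6  # distinct
            ys = rng.uniform(0, 100, size=n)
            x, y = resample_trace(np.column_stack([xs, ys]))
            for c, yc in zip(x, y):
                seg = np.searchsorted(xs, c, side="right") - 1
                seg = min(max(seg, 0), n - 2)
                x0, x1 = xs[seg], xs[seg + 1]
                y0, y1 = ys[seg], ys[seg + 1]
                expect = y0 + (y1 - y0) * (c - x0) / (x1 - x0)
                assert abs(yc - expect) < 1e-9

    def test_fewer_than_two_distinct_x_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            resample_trace([(3, 1), (3, 2)])


class TestContrastScore:
    def test_constant_image_scores_zero(self):
        img = np.full((20, 10), 0.5)
        assert contrast_score(img, 3, 10) == 0.0

    def test_step_edge_closed_form(self):
        img = step_image(20, 8, edge_row=9, low=0.1, high=0.7)
        h = 0.6
        # rows adjacent to the step see the full jump across their
        # central difference
        assert contrast_score(img, 0, 9) == pytest.approx(h / 2)
        assert contrast_score(img, 0, 10) == pytest.approx(h / 2)
        assert contrast_score(img, 0, 8) == 0.0

    def test_invariant_to_intensity_offset(self):
        rng = np.random.default_rng(0)
        img = rng.random((15, 6))
        ys = np.arange(15)
        xs = np.full(15, 2)
        np.testing.assert_allclose(
            contrast_score(img, xs, ys), contrast_score(img + 0.3, xs, ys))

    def test_out_of_range_errors(self):
        img = np.zeros((5, 5))
        with pytest.raises(IndexError):
            contrast_score(img, 10, 2)


class TestSnapOracle:
    @pytest.mark.parametrize("width,window", [(8, 1), (12, 1), (6, 2), (8, 2)])
    def test_dp_equals_exhaustive_enumeration(self, width, window):
        """On tiny images the dynamic programme must equal brute-force
        enumeration over all (2w+1)^width offset paths, including ties."""
        rng = np.random.default_rng(width * 10 + window)
        for rep in range(6):
            # dyadic intensities (k/16) make tied path costs bit-exact in
            # any summation order, so tie-breaking is well defined
            img = rng.integers(0, 17, size=(16, width)) / 16.0
            base = rng.integers(4, 12, size=width)
            cols = np.arange(width)
            offsets = np.arange(-window, window + 1)
            jump = 0.0625
            dp_rows, dp_total = _dp_best_path(img, cols, base, offsets, jump)
            bf_rows, bf_total = _brute_force_best_path(
                img, cols, base, offsets, jump)
            assert dp_total == pytest.approx(bf_total, abs=1e-9)
            np.testing.assert_array_equal(dp_rows, bf_rows)


class TestSnapBehaviour:
    def test_offset_trace_snaps_onto_step_edge(self):
        img = step_image(40, 30, edge_row=19)
        trace = make_trace(np.full(30, 23.0))  # +3 px off the lower edge row
        out = snap_to_contrast(img, trace, RefineConfig(window_px=5))
        assert out.source == "refined"
        # both rows adjacent to the step score h/2; the tie-break picks the
        # candidate closer to the drawn trace
        np.testing.assert_array_equal(out.y, np.full(30, 20.0))

    def test_featureless_image_keeps_original(self):
        img = np.full((40, 20), 0.5)
        trace = make_trace(np.full(20, 17.3))
        out = snap_to_contrast(img, trace, RefineConfig(window_px=5))
        assert out.source == "raw"
        np.testing.assert_array_equal(out.y, trace.y)

    def test_zero_window_is_identity(self):
        img = step_image(40, 20, edge_row=19)
        trace = make_trace(np.full(20, 25.0))
        out = snap_to_contrast(img, trace, RefineConfig(window_px=0))
        np.testing.assert_array_equal(out.y, trace.y)

    def test_deviation_bounded_by_window(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.random((60, 40))
            trace = make_trace(rng.uniform(10, 50, size=40))
            for w in (2, 5):
                out = snap_to_contrast(img, trace, RefineConfig(window_px=w))
                assert np.all(np.abs(out.y - np.rint(trace.y)) <= w)

    def test_total_contrast_never_decreases(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            img = rng.random((60, 40))
            trace = make_trace(rng.uniform(10, 50, size=40))
            out = snap_to_contrast(img, trace, RefineConfig(window_px=5))
            rows_in = np.rint(trace.y).astype(int)
            rows_out = np.rint(out.y).astype(int)
            before = contrast_score(img, trace.x, rows_in).sum()
            after = contrast_score(img, out.x, rows_out).sum()
            assert after >= before - 1e-12
            if out.source == "raw":
                assert after == pytest.approx(before)

    def test_improves_noisy_traces_on_speckled_edge(self):
        """Statistical robustness: with speckle and rater noise SD 2 px the
        refined traces sit closer to the true edge than the raw ones."""
        from scipy import ndimage
        rng = np.random.default_rng(21)
        width, edge = 128, 30
        raw_err, ref_err = [], []
        for _ in range(100):
            img = step_image(64, width, edge_row=edge)
            img *= rng.gamma(10.0, 0.1, size=img.shape)
            img = np.clip(ndimage.gaussian_filter(img, 1.0), 0, 1)
            noisy = edge + 0.5 + rng.normal(0, 2.0, size=width)
            trace = make_trace(np.clip(noisy, 0, 63))
            out = snap_to_contrast(img, trace, RefineConfig(window_px=5))
            truth = edge + 0.5  # sub-pixel edge position
            raw_err.append(np.abs(trace.y - truth).mean())
            ref_err.append(np.abs(out.y - truth).mean())
        assert np.mean(ref_err) < np.mean(raw_err)
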