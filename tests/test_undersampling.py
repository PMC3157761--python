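import numpy as np
import pytest
from scipy.interpolate import make_interp_spline

from octgrid.core_io import ThicknessMap
from octgrid.synthetic import DrusenParams, make_map
from octgrid.undersampling import (
    interpolation_error,
    spline_reconstruct,
    subsample_rows,
)


class TestSubsampleRows:
    @pytest.mark.parametrize(
        "n_keep, stride, first",
        [(8, 16, 8), (16, 8, 4), (32, 4, 2), (64, 2, 1)],
    )
    def test_centered_stride_indices(self, constant_map, n_keep, stride, first):
        idx, reduced = subsample_rows(constant_map, n_keep)
        assert len(idx) == n_keep and reduced.n_rows == n_keep
        assert idx[0] == first
        assert np.all(np.diff(idx) == stride)
        assert idx[-1] < constant_map.n_rows

    def test_keep_all_is_identity(self, constant_map):
        idx, reduced = subsample_rows(constant_map, 128)
        assert np.array_equal(idx, np.arange(128))
        assert np.array_equal(reduced.values, constant_map.values)

    def test_every_other_bscan_indices(self, constant_map):
        idx, _ = subsample_rows(constant_map, 64)
        assert np.array_equal(idx, np.arange(1, 128, 2))

    @pytest.mark.parametrize("bad", [0, -8, 7, 100, 256])
    def test_invalid_counts_rejected(self, constant_map, bad):
        with pytest.raises(ValueError):
            subsample_rows(constant_map, bad)


class TestSplineReconstruct:
    def test_kept_rows_reproduced_exactly(self):
        tmap = make_map(seed=2, noise_sd_um=2.0, drusen=DrusenParams())
        for n_keep in (8, 16, 32, 64):
            idx, reduced = subsample_rows(tmap, n_keep)
            recon = spline_reconstruct(reduced, idx, tmap.n_rows)
            assert np.allclose(recon.values[idx], tmap.values[idx], atol=1e-9)

    def test_linear_columns_reconstructed_exactly_between_kept_rows(self):
        rows = np.arange(128, dtype=float)
        vals = 200.0 + rows[:, None] * np.linspace(0.1, 0.9, 16)[None, :]
        tmap = ThicknessMap(values=vals)
        idx, reduced = subsample_rows(tmap, 16)
        recon = spline_reconstruct(reduced, idx, 128)
        interior = slice(idx[0], idx[-1] + 1)
        assert np.allclose(recon.values[interior], vals[interior], atol=1e-9)

    def test_constant_hold_outside_outermost_kept_rows(self):
        rows = np.arange(128, dtype=float)
        vals = np.broadcast_to(200.0 + np.sin(rows / 7)[:, None] * 30, (128, 8)).copy()
        tmap = ThicknessMap(values=vals)
        idx, reduced = subsample_rows(tmap, 8)  # kept rows 8..120
        recon = spline_reconstruct(reduced, idx, 128)
        assert np.allclose(recon.values[: idx[0]], vals[idx[0]], atol=1e-12)
        assert np.allclose(recon.values[idx[-1] + 1 :], vals[idx[-1]], atol=1e-12)

    def test_matches_independent_not_a_knot_spline(self):
        # same mathematical definition through scipy's B-spline route
        rows = np.arange(128, dtype=float)
        vals = 250.0 + 40 * np.sin(rows[:, None] / 9.0 + np.arange(32)[None, :] / 5.0)
        tmap = ThicknessMap(values=vals)
        idx, reduced = subsample_rows(tmap, 16)
        recon = spline_reconstruct(reduced, idx, 128)
        interior = np.arange(idx[0], idx[-1] + 1)
        for col in (0, 13, 31):
            oracle = make_interp_spline(idx, reduced.values[:, col], k=3)
            assert np.allclose(
                recon.values[interior, col], oracle(interior), atol=1e-9
            )

    def test_too_few_rows_rejected(self, constant_map):
        idx, reduced = subsample_rows(constant_map, 2)
        with pytest.raises(ValueError, match=">= 4"):
            spline_reconstruct(reduced, idx, 128)


class TestInterpolationError:
    def test_full_density_gives_zero_error(self):
        tmap = make_map(seed=4, noise_sd_um=2.0)
        rep, diff = interpolation_error(tmap, 128)
        assert np.all(diff == 0)
        assert rep.mean_per_pixel_error_um == 0.0
        assert rep.max_per_pixel_error_um == 0.0
        assert rep.summed_error_um == 0.0

    def test_constant_offset_maps_direct_compare(self, constant_map):
        # sanity of the per-pixel bookkeeping on a hand-built difference
        diff = constant_map.values - (constant_map.values - 2.0)
        assert diff.mean() == pytest.approx(2.0)

    def test_report_invariants(self):
        tmap = make_map(seed=8, noise_sd_um=2.0, drusen=DrusenParams())
        rep, diff = interpolation_error(tmap, 16)
        assert rep.mean_per_pixel_error_um <= rep.max_per_pixel_error_um
        assert rep.mean_per_pixel_error_um == pytest.approx(
            np.abs(diff).mean()
        )
        assert rep.summed_error_um == pytest.approx(
            sum(rep.per_segment_abs_um.values())
        )
        assert rep.n_pixels == 65536

    def test_signed_difference_cancels_across_symmetric_band(self):
        # under/over-representation straddles the pit symmetrically, so the
        # signed error integrates to ~0 over a band symmetric about the pit row
        tmap = make_map(seed=0, noise_sd_um=0.0)
        _, diff = interpolation_error(tmap, 16)
        band = diff[32:96]  # symmetric about the fovea row boundary
        # cancellation is imperfect only through the kept-row phase (first
        # kept row 4, last 124), so a few percent residual is expected
        assert abs(band.sum()) < 0.1 * np.abs(band).sum()

    def test_error_shrinks_with_density(self):
        tmap = make_map(seed=9, noise_sd_um=0.0, drusen=DrusenParams(), fovea_xy_mm=(0.1, 0.05))
        means = [
            interpolation_error(tmap, k)[0].mean_per_pixel_error_um
            for k in (8, 16, 32, 64)
        ]
        assert means[0] > means[1] > means[2] > means[3]
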