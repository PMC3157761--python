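import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assert_plots_identical, oracle_etdrs_plot
from octgrid.core_io import MODEL_EYE_AXIAL_MM, pixel_axes
from octgrid.etdrs import (
    SEGMENT_LABELS,
    EmptyPlotError,
    compare_plots,
    etdrs_plot,
    segment_label,
)
from octgrid.synthetic import make_map


class TestSegmentLabel:
    @pytest.mark.parametrize(
        "dx, dy, eye, expected",
        [
            (0.0, 0.0, "OD", "center"),
            (0.0, 0.49, "OD", "center"),
            (0.0, 0.5, "OD", "center"),  # outer edge of zone belongs inward
            (0.0, 1.0, "OD", "inner_superior"),
            (0.0, -1.0, "OD", "inner_inferior"),
            (2.0, 0.0, "OD", "outer_nasal"),  # nasal = +x in a right eye
            (2.0, 0.0, "OS", "outer_temporal"),
            (-2.0, 0.0, "OD", "outer_temporal"),
            (-2.0, 0.0, "OS", "outer_nasal"),
            (1.0, 1.0, "OD", "inner_superior"),  # diagonal tie -> vertical quadrant
            (1.0, -1.0, "OD", "inner_inferior"),
            (0.0, 3.0, "OD", "outer_superior"),
            (0.0, 3.001, "OD", "outside"),
        ],
    )
    def test_convention_table(self, dx, dy, eye, expected):
        assert segment_label(dx, dy, eye) == expected

    def test_laterality_override(self):
        assert segment_label(2.0, 0.0, "OS", nasal_positive_x=True) == "outer_nasal"

    @settings(max_examples=300, deadline=None)
    @given(
        dx=st.floats(-4, 4, allow_nan=False),
        dy=st.floats(-4, 4, allow_nan=False),
        eye=st.sampled_from(["OD", "OS"]),
    )
    def test_total_function_consistent_with_radius(self, dx, dy, eye):
        label = segment_label(dx, dy, eye)
        r = np.hypot(dx, dy)
        if r > 3.0:
            assert label == "outside"
        elif label == "center":
            assert r <= 0.5
        elif label.startswith("inner"):
            assert 0.5 < r <= 1.5 + 1e-12
        elif label.startswith("outer"):
            assert 1.5 < r <= 3.0 + 1e-12
        else:
            pytest.fail(f"unexpected label {label}")


class TestEtdrsPlot:
    def test_constant_field_yields_constant_segments(self, constant_map):
        for center in [(0.0, 0.0), (1.2, -0.7)]:
            plot = etdrs_plot(constant_map, center)
            assert all(v == pytest.approx(300.0) for v in plot.segments.values())
        # only the volume-centered grid fits entirely inside the scan;
        # pixel-center membership discretizes segment areas at the ~1% level
        centered = etdrs_plot(constant_map, (0.0, 0.0))
        assert all(c == pytest.approx(1.0, abs=0.02) for c in centered.coverage.values())

    def test_classification_partitions_the_disc(self, constant_map):
        plot = etdrs_plot(constant_map, (0.3, -0.2))
        x, y = pixel_axes(constant_map)
        r = np.hypot(x[None, :] - 0.3, y[:, None] + 0.2)
        assert sum(plot.n_pixels.values()) == int((r <= 3.0).sum())

    def test_model_eye_axial_length_matches_uncorrected(self):
        tmap = make_map(seed=3, noise_sd_um=2.0, axial_length_mm=MODEL_EYE_AXIAL_MM)
        a = etdrs_plot(tmap, (0.0, 0.0), None)
        b = etdrs_plot(tmap, (0.0, 0.0), MODEL_EYE_AXIAL_MM)
        assert a.n_pixels == b.n_pixels
        for lab in SEGMENT_LABELS:
            assert a.segments[lab] == b.segments[lab]
            # pixel area picks up one ulp from the 24.46/24.46 division
            assert a.coverage[lab] == pytest.approx(b.coverage[lab], abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        tmap = make_map(seed=21, fovea_xy_mm=(0.2, 0.1), noise_sd_um=2.0,
                        n_rows=32, n_cols=128)
        for center in [(0.0, 0.0), (0.2, 0.1)]:
            assert_plots_identical(
                etdrs_plot(tmap, center), oracle_etdrs_plot(tmap, center)
            )

    def test_translation_invariance_on_synthetic_pit(self):
        # discs fully interior on an oversized grid; shift content and center
        # by the same whole-pixel vector
        shift = (2 * 7.5 / 640, 1 * 7.5 / 160)  # 2 cols, 1 row
        base = make_map(seed=0, noise_sd_um=0.0, n_rows=160, n_cols=640,
                        nominal_size_mm=7.5)
        moved = make_map(seed=0, noise_sd_um=0.0, fovea_xy_mm=shift,
                         n_rows=160, n_cols=640, nominal_size_mm=7.5)
        pa = etdrs_plot(base, (0.0, 0.0))
        pb = etdrs_plot(moved, shift)
        assert pa.n_pixels == pb.n_pixels
        for lab in SEGMENT_LABELS:
            assert pa.segments[lab] == pytest.approx(pb.segments[lab], abs=1e-6)

    def test_radially_symmetric_map_has_matching_quadrants(self):
        tmap = make_map(seed=0, noise_sd_um=0.0)  # pit centered at (0, 0)
        plot = etdrs_plot(tmap, (0.0, 0.0))
        inner = [plot.segments[f"inner_{q}"] for q in
                 ("superior", "nasal", "inferior", "temporal")]
        assert max(inner) - min(inner) <= 0.5  # grid-discretization tolerance

    def test_far_outside_center_raises_empty_plot(self, constant_map):
        with pytest.raises(EmptyPlotError):
            etdrs_plot(constant_map, (50.0, 50.0))

    def test_recentering_truncates_coverage(self, constant_map):
        plot = etdrs_plot(constant_map, (2.0, 0.0))
        assert plot.coverage["outer_nasal"] < 0.6  # half the ring is off-grid
        assert plot.coverage["center"] == pytest.approx(1.0, abs=1e-3)


class TestComparePlots:
    def test_identical_plots_give_zero_error(self, constant_map):
        plot = etdrs_plot(constant_map, (0.0, 0.0))
        rep = compare_plots(plot, plot)
        assert rep.summed_error_um == 0.0
        assert rep.central_subfield_error_um == 0.0

    def test_uniform_offset_adds_up(self, constant_map):
        plot_a = etdrs_plot(constant_map, (0.0, 0.0))
        bumped = constant_map.with_values(constant_map.values + 1.0)
        plot_b = etdrs_plot(bumped, (0.0, 0.0))
        rep = compare_plots(plot_a, plot_b)
        assert rep.summed_error_um == pytest.approx(9.0, abs=1e-9)
        assert all(v == pytest.approx(1.0) for v in rep.per_segment_abs_um.values())
        # percentage errors relative to the 300 um reference
        assert all(
            v == pytest.approx(100.0 / 300.0) for v in rep.per_segment_pct.values()
        )

    def test_summed_error_symmetric_in_plot_order(self):
        tmap = make_map(seed=5, fovea_xy_mm=(0.3, 0.2), noise_sd_um=0.0)
        pa = etdrs_plot(tmap, (0.3, 0.2))
        pb = etdrs_plot(tmap, (0.0, 0.0))
        assert compare_plots(pa, pb).summed_error_um == pytest.approx(
            compare_plots(pb, pa).summed_error_um
        )

    def test_mismatched_laterality_rejected(self, constant_map):
        od = etdrs_plot(constant_map, (0.0, 0.0))
        os_map = dataclasses.replace(constant_map, eye="OS")
        os_plot = etdrs_plot(os_map, (0.0, 0.0))
        with pytest.raises(ValueError, match="eyes"):
            compare_plots(od, os_plot)

    def test_matches_oracle_on_offset_map(self):
        tmap = make_map(seed=17, fovea_xy_mm=(0.25, -0.15), noise_sd_um=2.0,
                        n_rows=32, n_cols=128)
        fast = compare_plots(
            etdrs_plot(tmap, tmap.fovea_xy_mm), etdrs_plot(tmap, (0.0, 0.0))
        )
        slow = compare_plots(
            oracle_etdrs_plot(tmap, tmap.fovea_xy_mm),
            oracle_etdrs_plot(tmap, (0.0, 0.0)),
        )
        assert fast.summed_error_um == slow.summed_error_um
        assert fast.per_segment_abs_um == slow.per_segment_abs_um
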