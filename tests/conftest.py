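"""Shared fixtures and independent oracles.

The ETDRS oracle here classifies every pixel with the scalar
``segment_label`` function in an explicit Python loop — a second, slow
route to the same definition the vectorized plot code implements — and is
the reference the fast path must match exactly.
"""

from math import pi

import numpy as np
import pytest

from octgrid.core_io import ThicknessMap, pixel_axes, scan_side_mm
from octgrid.etdrs import SEGMENT_LABELS, EtdrsPlot, segment_label


def oracle_etdrs_plot(tmap: ThicknessMap, center_xy_mm, axial_length_mm=None) -> EtdrsPlot:
    """Brute-force per-pixel ETDRS plot (scalar classifier, explicit loops)."""
    x, y = pixel_axes(tmap, axial_length_mm)
    cx, cy = center_xy_mm
    members = {lab: [] for lab in SEGMENT_LABELS}
    for rr in range(tmap.n_rows):
        for cc in range(tmap.n_cols):
            lab = segment_label(x[cc] - cx, y[rr] - cy, tmap.eye)
            if lab != "outside":
                members[lab].append(tmap.values[rr, cc])

    side = scan_side_mm(tmap.nominal_size_mm, axial_length_mm)
    pixel_area = (side / tmap.n_cols) * (side / tmap.n_rows)
    areas = {"center": pi * 0.5 * 0.5}
    for quad in ("superior", "nasal", "inferior", "temporal"):
        areas[f"inner_{quad}"] = pi * (1.5 * 1.5 - 0.5 * 0.5) / 4.0
        areas[f"outer_{quad}"] = pi * (3.0 * 3.0 - 1.5 * 1.5) / 4.0

    segments, coverage, n_pixels = {}, {}, {}
    for lab in SEGMENT_LABELS:
        vals = members[lab]
        n_pixels[lab] = len(vals)
        coverage[lab] = min(1.0, len(vals) / (areas[lab] / pixel_area))
        segments[lab] = float(np.mean(np.asarray(vals))) if vals else float("nan")
    return EtdrsPlot(
        center_xy_mm=(float(cx), float(cy)),
        eye=tmap.eye,
        segments=segments,
        coverage=coverage,
        n_pixels=n_pixels,
    )


def assert_plots_identical(a: EtdrsPlot, b: EtdrsPlot) -> None:
    assert a.n_pixels == b.n_pixels
    for lab in SEGMENT_LABELS:
        va, vb = a.segments[lab], b.segments[lab]
        if np.isnan(va) or np.isnan(vb):
            assert np.isnan(va) and np.isnan(vb)
        else:
            assert va == vb, f"{lab}: {va} != {vb}"
        assert a.coverage[lab] == b.coverage[lab]


@pytest.fixture
def oracle_plot():
    return oracle_etdrs_plot


@pytest.fixture
def constant_map() -> ThicknessMap:
    return ThicknessMap(values=np.full((128, 512), 300.0), subject_id="flat")


@pytest.fixture
def small_constant_map() -> ThicknessMap:
    return ThicknessMap(values=np.full((16, 64), 300.0), subject_id="flat-small")
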