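"""B-scan undersampling and cubic-spline reconstruction error.

Commercial macular protocols trade slow-axis sampling density for speed:
a volume may keep only every 2nd/4th/8th/16th B-scan and fill the gaps by
interpolation.  This module builds those undersampled volumes from a native
map, reconstructs full resolution with a column-wise cubic interpolating
spline, and quantifies the damage per pixel and per ETDRS segment, treating
the native map as ground truth.

Kept rows are centered within each stride (stride ``k`` keeps rows
``k//2 + i*k``) so the extrapolation bands at the top and bottom edges are
symmetric.  Beyond the outermost kept rows the reconstruction holds the
nearest kept row's value constant rather than extrapolating the cubic.
Splines use not-a-knot end conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.interpolate import CubicSpline

from .core_io import ThicknessMap
from .etdrs import ErrorReport, compare_plots, etdrs_plot

__all__ = [
    "ErrorReport",
    "interpolation_error",
    "spline_reconstruct",
    "subsample_rows",
]


def subsample_rows(
    tmap: ThicknessMap, n_keep: int
) -> tuple[np.ndarray, ThicknessMap]:
    """Keep ``n_keep`` evenly spaced, stride-centered B-scan rows.

    ``n_keep`` must divide ``n_rows``; the canonical acquisition levels are
    8, 16, 32 and 64 out of 128 (every 16th/8th/4th/2nd B-scan), with
    ``n_keep == n_rows`` the identity.  Returns the kept row indices and the
    reduced map.
    """
    if n_keep < 1 or tmap.n_rows % n_keep != 0:
        raise ValueError(
            f"n_keep={n_keep} must be a positive divisor of n_rows={tmap.n_rows}"
        )
    stride = tmap.n_rows // n_keep
    idx = stride // 2 + stride * np.arange(n_keep)
    return idx, tmap.with_values(tmap.values[idx])


def spline_reconstruct(
    reduced: ThicknessMap, kept_indices: np.ndarray, n_rows: int
) -> ThicknessMap:
    """Reconstruct a full-resolution map from kept B-scan rows.

    Each of the columns is interpolated independently with a cubic spline
    (not-a-knot end conditions) through (kept row index, thickness) and
    evaluated at every row index; rows outside the outermost kept rows take
    the nearest kept row's value.  Kept rows are reproduced exactly.
    """
    idx = np.asarray(kept_indices, dtype=float)
    if idx.size < 4:
        raise ValueError(f"spline reconstruction needs >= 4 kept rows, got {idx.size}")
    if idx.size != reduced.n_rows:
        raise ValueError("kept_indices length must match the reduced map's rows")
    if idx.size == n_rows and np.array_equal(idx, np.arange(n_rows)):
        return reduced.with_values(reduced.values.copy())  # identity selection
    spline = CubicSpline(idx, reduced.values, axis=0, bc_type="not-a-knot")
    rows = np.clip(np.arange(n_rows, dtype=float), idx[0], idx[-1])
    return reduced.with_values(spline(rows))


def interpolation_error(
    native: ThicknessMap,
    n_keep: int,
    center_xy_mm: tuple[float, float] | None = None,
) -> tuple[ErrorReport, np.ndarray]:
    """Quantify the error of reconstructing ``native`` from ``n_keep`` rows.

    Returns the :class:`ErrorReport` (per-pixel summaries plus ETDRS segment
    differences between the native and reconstructed maps, both plotted at
    the same center) and the signed difference map ``native - reconstructed``
    for display.  ETDRS plots are centered at ``center_xy_mm``, defaulting to
    the map's recorded fovea (volume center if unknown), at the map's true
    lateral scale.
    """
    kept, reduced = subsample_rows(native, n_keep)
    recon = spline_reconstruct(reduced, kept, native.n_rows)
    diff = native.values - recon.values

    if center_xy_mm is None:
        center_xy_mm = native.fovea_xy_mm or (0.0, 0.0)
    plot_native = etdrs_plot(native, center_xy_mm, native.axial_length_mm)
    plot_recon = etdrs_plot(recon, center_xy_mm, native.axial_length_mm)
    report = compare_plots(plot_native, plot_recon)
    report = replace(
        report,
        n_pixels=native.n_pixels,
        mean_per_pixel_error_um=float(np.abs(diff).sum() / native.n_pixels),
        max_per_pixel_error_um=float(np.abs(diff).max()),
    )
    return report, diff
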