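"""Beam-coverage geometry of a raster-scanned OCT volume.

A volume "covering" a 6 mm x 6 mm patch only interrogates the retina where
the beam actually lands: each A-scan is a disc of the beam's spot diameter,
the discs line up along B-scan rows, and the rows are spaced far apart
relative to the spot.  This module computes the fraction of the nominal
scan area actually sampled — analytically, via the closed-form union area
of overlapping discs along a row — and the B-scan count required to sample
the full area, with a rasterization oracle for verification.

Analytic model: with spot radius ``r``, A-scan center spacing
``a = L / n_ascans`` and row spacing ``b = L / n_bscans``, a row's union
area is ``n_a * pi r^2 - (n_a - 1) * lens(a, r)`` where ``lens`` is the
intersection area of two discs at distance ``a``:
``lens(a, r) = 2 r^2 acos(a / 2r) - (a/2) sqrt(4 r^2 - a^2)`` for
``a < 2r``, else 0.  Rows do not overlap when ``b >= 2r`` (always true for
clinical rasters); otherwise the rasterization oracle is used.  Discs are
not clipped at the scan boundary (the overhang is below 0.01 percentage
points for a 15 um spot).
"""

from __future__ import annotations

import math

import numpy as np

from .core_io import ScanGeometry

__all__ = [
    "covered_area_fraction",
    "min_bscans_full_coverage",
    "rasterized_coverage",
]


def _lens_area(distance: float, radius: float) -> float:
    """Intersection area of two discs of equal ``radius`` at ``distance``."""
    if distance >= 2.0 * radius:
        return 0.0
    return 2.0 * radius**2 * math.acos(distance / (2.0 * radius)) - (
        distance / 2.0
    ) * math.sqrt(4.0 * radius**2 - distance**2)


def covered_area_fraction(geom: ScanGeometry) -> float:
    """Fraction of the nominal scan area sampled by the beam, in [0, 1].

    Closed form when rows do not overlap (row spacing >= spot diameter);
    falls back to :func:`rasterized_coverage` at 1 um resolution otherwise.
    """
    r = geom.spot_diameter_um / 2.0
    if r == 0.0:
        return 0.0
    if geom.bscan_spacing_um < 2.0 * r:
        return rasterized_coverage(geom, resolution_um=min(1.0, r / 3.0))
    a = geom.ascan_spacing_um
    row_union = geom.n_ascans * math.pi * r**2 - (geom.n_ascans - 1) * _lens_area(a, r)
    frac = geom.n_bscans * row_union / geom.scan_length_um**2
    return min(1.0, frac)


def min_bscans_full_coverage(
    n_ascans: int,
    spot_diameter_um: float = 15.0,
    scan_length_um: float = 6000.0,
) -> int:
    """Smallest B-scan count that samples the entire scan area.

    A row of overlapping discs covers a solid strip of width
    ``w = 2 sqrt(r^2 - (a/2)^2)`` (the chord height at half the A-scan
    spacing); the raster covers the full square when the row spacing is at
    most ``w``, i.e. ``n >= L / w``.  Requires the spot diameter to exceed
    the A-scan spacing — otherwise no row is solid and full coverage is
    unreachable at any B-scan count.
    """
    geom = ScanGeometry(1, n_ascans, spot_diameter_um, scan_length_um)
    r = spot_diameter_um / 2.0
    a = geom.ascan_spacing_um
    if a >= 2.0 * r:
        raise ValueError(
            f"spot diameter {spot_diameter_um} um does not exceed the A-scan "
            f"spacing {a:g} um; rows leave gaps at any B-scan density"
        )
    strip = 2.0 * math.sqrt(r**2 - (a / 2.0) ** 2)
    return max(1, math.ceil(scan_length_um / strip))


def rasterized_coverage(
    geom: ScanGeometry,
    resolution_um: float = 1.0,
    cell_cap: int = 400_000_000,
) -> float:
    """Oracle: exact disc-union membership evaluated at raster cell centers.

    The scan square is divided into cells of roughly ``resolution_um``; a
    cell counts as covered when its center lies within the spot radius of
    some A-scan center.  Because the A-scan centers form a product lattice,
    the nearest-center distance separates per axis, which makes the
    membership test exact (no painting approximation) while remaining
    O(n log n).  Converges to the analytic value as the resolution shrinks.
    """
    r = geom.spot_diameter_um / 2.0
    if r == 0.0:
        return 0.0
    if resolution_um > r / 3.0:
        raise ValueError(
            f"resolution {resolution_um} um too coarse for spot radius {r} um "
            "(need resolution <= radius / 3)"
        )
    L = geom.scan_length_um
    n_cells = int(round(L / resolution_um))
    if n_cells * n_cells > cell_cap:
        raise MemoryError(
            f"rasterization would need {n_cells}^2 cells (cap {cell_cap})"
        )
    pts = (np.arange(n_cells) + 0.5) * (L / n_cells)

    def min_sq_dist(spacing: float, count: int) -> np.ndarray:
        centers_idx = np.clip(np.round(pts / spacing - 0.5), 0, count - 1)
        best = np.full(pts.shape, np.inf)
        for shift in (-1, 0, 1):
            idx = np.clip(centers_idx + shift, 0, count - 1)
            d = pts - (idx + 0.5) * spacing
            best = np.minimum(best, d * d)
        return best

    mx = min_sq_dist(geom.ascan_spacing_um, geom.n_ascans)
    my = min_sq_dist(geom.bscan_spacing_um, geom.n_bscans)
    mx_sorted = np.sort(mx)
    # covered cells per grid row j: count of mx <= r^2 - my[j]
    covered = int(np.searchsorted(mx_sorted, r * r - my, side="right").sum())
    return covered / (n_cells * n_cells)
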