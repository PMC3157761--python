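"""ETDRS nine-segment thickness plots and plot-to-plot error reports.

The ETDRS layout places three concentric circles of 1, 3 and 6 mm diameter
on the macula.  The central 1 mm disc is the central subfield (CSF); the two
annuli are each split into four quadrants by the +/-45 degree diagonals,
giving nine segments in total.  Quadrant names follow retinal anatomy:
superior (+y), inferior (-y), and nasal/temporal, whose x-direction depends
on laterality (nasal is +x for OD, -x for OS).

Segment membership is decided at pixel centers with no partial-area
weighting, which matches grid-sampled thickness data and makes the
classifier exactly reproducible by a brute-force per-pixel loop.  Boundary
rules are deterministic: ring radii compare with ``<=`` on the outer edge of
each zone, and diagonal ties (|dx| == |dy|) belong to the vertical
(superior/inferior) quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np

from .core_io import ThicknessMap, pixel_axes, scan_side_mm

__all__ = [
    "SEGMENT_LABELS",
    "RING_RADII_MM",
    "EmptyPlotError",
    "ErrorReport",
    "EtdrsPlot",
    "compare_plots",
    "etdrs_plot",
    "segment_label",
]

#: Ring radii in mm (CSF edge, inner annulus edge, outer annulus edge).
RING_RADII_MM: tuple[float, float, float] = (0.5, 1.5, 3.0)

#: Canonical segment ordering used in every report.
SEGMENT_LABELS: tuple[str, ...] = (
    "center",
    "inner_superior",
    "inner_nasal",
    "inner_inferior",
    "inner_temporal",
    "outer_superior",
    "outer_nasal",
    "outer_inferior",
    "outer_temporal",
)


class EmptyPlotError(ValueError):
    """Raised when no pixel falls inside any of the nine segments."""


@dataclass(frozen=True)
class EtdrsPlot:
    """Nine segment mean thicknesses plus the geometry that produced them.

    ``coverage`` is, per segment, the fraction of the segment's analytic
    area actually represented by scanned pixels (1.0 for a fully interior
    segment; below 1 when the grid truncates the segment, e.g. after
    recentering or magnification correction shrinks the scanned extent).
    Segment means are NaN where ``n_pixels`` is zero.
    """

    center_xy_mm: tuple[float, float]
    eye: str
    segments: dict[str, float]
    coverage: dict[str, float]
    n_pixels: dict[str, int]
    ring_radii_mm: tuple[float, float, float] = RING_RADII_MM

    def as_dict(self) -> dict:
        return {
            "center_xy_mm": list(self.center_xy_mm),
            "eye": self.eye,
            "ring_radii_mm": list(self.ring_radii_mm),
            "segments_um": dict(self.segments),
            "coverage": dict(self.coverage),
            "n_pixels": dict(self.n_pixels),
        }


@dataclass(frozen=True)
class ErrorReport:
    """Absolute ETDRS differences between two thickness analyses.

    All scalar summaries use absolute differences; signed information, where
    meaningful (per-pixel difference maps), is carried separately by the
    producing operation.  ``per_segment_pct`` expresses each segment error
    as a percentage of the reference plot's segment thickness.
    """

    per_segment_abs_um: dict[str, float]
    summed_error_um: float
    central_subfield_error_um: float
    per_segment_pct: dict[str, float]
    n_pixels: int
    mean_per_pixel_error_um: float | None = None
    max_per_pixel_error_um: float | None = None

    def __post_init__(self) -> None:
        vals = [v for v in self.per_segment_abs_um.values() if np.isfinite(v)]
        if any(v < 0 for v in vals):
            raise ValueError("per-segment absolute errors must be >= 0")
        if (
            self.mean_per_pixel_error_um is not None
            and self.max_per_pixel_error_um is not None
            and self.mean_per_pixel_error_um > self.max_per_pixel_error_um + 1e-12
        ):
            raise ValueError("mean per-pixel error cannot exceed the max")

    def as_dict(self) -> dict:
        return {
            "per_segment_abs_um": dict(self.per_segment_abs_um),
            "summed_error_um": self.summed_error_um,
            "central_subfield_error_um": self.central_subfield_error_um,
            "per_segment_pct": dict(self.per_segment_pct),
            "n_pixels": self.n_pixels,
            "mean_per_pixel_error_um": self.mean_per_pixel_error_um,
            "max_per_pixel_error_um": self.max_per_pixel_error_um,
        }


def segment_label(
    dx: float,
    dy: float,
    eye: str = "OD",
    *,
    nasal_positive_x: bool | None = None,
) -> str:
    """Classify a single offset (mm) from the grid center into a segment.

    Returns one of :data:`SEGMENT_LABELS` or ``"outside"``.  Total function:
    every finite offset gets a label.  ``nasal_positive_x`` overrides the
    default laterality convention (nasal = +x for OD, -x for OS).
    """
    if nasal_positive_x is None:
        if eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")
        nasal_positive_x = eye == "OD"
    r2 = dx * dx + dy * dy
    r0, r1, r2max = RING_RADII_MM
    if r2 > r2max * r2max:
        return "outside"
    if r2 <= r0 * r0:
        return "center"
    ring = "inner" if r2 <= r1 * r1 else "outer"
    adx = abs(dx)
    if adx <= dy:
        quad = "superior"
    elif adx <= -dy:
        quad = "inferior"
    elif dx > 0:
        quad = "nasal" if nasal_positive_x else "temporal"
    else:
        quad = "temporal" if nasal_positive_x else "nasal"
    return f"{ring}_{quad}"


def _segment_areas_mm2() -> dict[str, float]:
    r0, r1, r2 = RING_RADII_MM
    inner_quad = pi * (r1 * r1 - r0 * r0) / 4.0
    outer_quad = pi * (r2 * r2 - r1 * r1) / 4.0
    areas = {"center": pi * r0 * r0}
    for quad in ("superior", "nasal", "inferior", "temporal"):
        areas[f"inner_{quad}"] = inner_quad
        areas[f"outer_{quad}"] = outer_quad
    return areas


_SEGMENT_AREAS = _segment_areas_mm2()


def _classify_grid(dx: np.ndarray, dy: np.ndarray, nasal_positive_x: bool) -> np.ndarray:
    """Vectorized classifier: integer codes indexing SEGMENT_LABELS, -1 outside.

    Uses the identical comparisons as :func:`segment_label` so that a scalar
    per-pixel loop reproduces it bit-for-bit.
    """
    r2 = dx * dx + dy * dy
    r0, r1, rmax = RING_RADII_MM
    codes = np.full(dx.shape, -1, dtype=np.int8)
    inside = r2 <= rmax * rmax
    center = r2 <= r0 * r0
    inner = inside & ~center & (r2 <= r1 * r1)
    outer = inside & ~center & ~inner

    adx = np.abs(dx)
    sup = adx <= dy
    inf = ~sup & (adx <= -dy)
    right = ~sup & ~inf & (dx > 0)
    left = ~sup & ~inf & ~right
    if nasal_positive_x:
        nasal, temporal = right, left
    else:
        nasal, temporal = left, right

    quads = {"superior": sup, "nasal": nasal, "inferior": inf, "temporal": temporal}
    codes[center] = SEGMENT_LABELS.index("center")
    for ring_name, ring_mask in (("inner", inner), ("outer", outer)):
        for quad_name, quad_mask in quads.items():
            codes[ring_mask & quad_mask] = SEGMENT_LABELS.index(
                f"{ring_name}_{quad_name}"
            )
    return codes


def etdrs_plot(
    tmap: ThicknessMap,
    center_xy_mm: tuple[float, float] = (0.0, 0.0),
    axial_length_mm: float | None = None,
    *,
    nasal_positive_x: bool | None = None,
) -> EtdrsPlot:
    """Compute the nine-segment ETDRS plot of ``tmap`` at an arbitrary center.

    Pixel-center coordinates come from :func:`octgrid.core_io.pixel_centers`
    with the given ``axial_length_mm`` (``None`` = nominal scale, so the
    rings are device-nominal; a true axial length makes them physically
    1 / 3 / 6 mm in diameter).  Segment means are unweighted means over
    member pixels; coverage is member count over the analytically expected
    count for a fully interior segment at the same lateral scale.

    Raises :class:`EmptyPlotError` if the center is so far outside the grid
    that all nine segments are empty.
    """
    if nasal_positive_x is None:
        nasal_positive_x = tmap.eye == "OD"
    x, y = pixel_axes(tmap, axial_length_mm)
    cx, cy = float(center_xy_mm[0]), float(center_xy_mm[1])
    dx = np.broadcast_to(x - cx, tmap.values.shape)
    dy = np.broadcast_to((y - cy)[:, None], tmap.values.shape)
    codes = _classify_grid(dx, dy, nasal_positive_x)

    side = scan_side_mm(tmap.nominal_size_mm, axial_length_mm)
    pixel_area = (side / tmap.n_cols) * (side / tmap.n_rows)

    segments: dict[str, float] = {}
    coverage: dict[str, float] = {}
    n_pixels: dict[str, int] = {}
    for k, label in enumerate(SEGMENT_LABELS):
        mask = codes == k
        n = int(mask.sum())
        n_pixels[label] = n
        expected = _SEGMENT_AREAS[label] / pixel_area
        coverage[label] = min(1.0, n / expected) if expected > 0 else 0.0
        segments[label] = float(np.mean(tmap.values[mask])) if n else float("nan")
    if all(n == 0 for n in n_pixels.values()):
        raise EmptyPlotError(
            f"grid center {center_xy_mm} leaves every ETDRS segment empty"
        )
    return EtdrsPlot(
        center_xy_mm=(cx, cy),
        eye=tmap.eye,
        segments=segments,
        coverage=coverage,
        n_pixels=n_pixels,
    )


def compare_plots(a: EtdrsPlot, b: EtdrsPlot) -> ErrorReport:
    """Per-segment absolute differences between two ETDRS plots.

    ``a`` is the reference for percentage errors.  The summed error is the
    plain sum of the nine absolute segment differences; the central-subfield
    error is surfaced separately.
    """
    if a.eye != b.eye:
        raise ValueError(f"cannot compare plots from different eyes: {a.eye} vs {b.eye}")
    if set(a.segments) != set(b.segments):
        raise ValueError("plots carry different segment label sets")
    per_abs: dict[str, float] = {}
    per_pct: dict[str, float] = {}
    for label in SEGMENT_LABELS:
        diff = abs(a.segments[label] - b.segments[label])
        per_abs[label] = diff
        ref = a.segments[label]
        per_pct[label] = 100.0 * diff / ref if ref else float("nan")
    return ErrorReport(
        per_segment_abs_um=per_abs,
        summed_error_um=float(sum(per_abs.values())),
        central_subfield_error_um=per_abs["center"],
        per_segment_pct=per_pct,
        n_pixels=int(sum(a.n_pixels.values())),
    )
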