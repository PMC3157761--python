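"""Thickness-map data model, coordinate conventions and file IO.

An SD-OCT macular volume is reduced upstream (by the device's segmentation
software) to a rectilinear grid of retinal thickness values: one value per
A-scan, ``n_rows`` B-scans (slow axis) by ``n_cols`` A-scans per B-scan
(fast axis), nominally covering a 6 mm x 6 mm patch of retina.  This module
defines that grid as :class:`ThicknessMap`, fixes the coordinate convention
every downstream stage uses, and reads/writes an open on-disk dialect
(CSV matrix + JSON sidecar).

Coordinate convention
---------------------
Volume-centered Cartesian millimetres: +x is image right, +y is image up.
Row 0 is the inferior-most B-scan (row index increases with +y) and column 0
the leftmost A-scan.  Pixels are half-open cells; all geometric membership
is evaluated at cell centers.  For laterality, the nasal retina maps to +x
in a right eye (OD) and to -x in a left eye (OS).

The scanner's galvanometers are calibrated for a model eye of axial length
24.46 mm, so the physical side length of a "6 mm" scan in an eye of axial
length ``L`` is ``6 * L / 24.46``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MODEL_EYE_AXIAL_MM",
    "ParseError",
    "ScanGeometry",
    "ThicknessMap",
    "pixel_axes",
    "pixel_centers",
    "read_map",
    "scan_side_mm",
    "write_map",
]

#: Axial length (mm) of the model eye the scan optics are calibrated to.
MODEL_EYE_AXIAL_MM = 24.46


class ParseError(ValueError):
    """Raised when a thickness matrix file is malformed (ragged/non-numeric)."""


@dataclass(frozen=True)
class ThicknessMap:
    """A retinal thickness grid with its acquisition metadata.

    Parameters
    ----------
    values
        Thickness in micrometres, shape ``(n_rows, n_cols)``; rows are
        B-scans (slow axis), columns are A-scans (fast axis).
    nominal_size_mm
        Nominal scan side length as reported by the device.
    axial_length_mm
        Subject axial length in mm, if measured (e.g. by optical biometry).
    eye
        Laterality, ``"OD"`` (right) or ``"OS"`` (left).
    fovea_xy_mm
        Fovea position in volume-centered coordinates, if known.
    subject_id
        Free-form identifier.
    """

    values: np.ndarray
    nominal_size_mm: float = 6.0
    axial_length_mm: float | None = None
    eye: str = "OD"
    fovea_xy_mm: tuple[float, float] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError(f"thickness grid must be 2-D, got shape {vals.shape}")
        if vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValueError(f"grid must be at least 2x2, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("thickness grid contains non-finite values")
        if vals.min() <= 0.0 or vals.max() >= 1000.0:
            raise ValueError(
                "thickness values must lie strictly inside (0, 1000) um; "
                f"observed range [{vals.min():g}, {vals.max():g}]"
            )
        if self.nominal_size_mm <= 0:
            raise ValueError("nominal_size_mm must be positive")
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.axial_length_mm is not None and self.axial_length_mm <= 0:
            raise ValueError("axial_length_mm must be positive when given")
        if self.fovea_xy_mm is not None:
            fx, fy = self.fovea_xy_mm
            object.__setattr__(self, "fovea_xy_mm", (float(fx), float(fy)))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        """Total A-scan count (65,536 for the default 128 x 512 raster)."""
        return self.values.size

    def with_values(self, values: np.ndarray) -> "ThicknessMap":
        """Copy of this map with a new thickness grid, metadata preserved."""
        return replace(self, values=values)


@dataclass(frozen=True)
class ScanGeometry:
    """Raster sampling parameters of a volume acquisition.

    ``spot_diameter_um`` is the optical beam diameter at the retina; each
    A-scan therefore interrogates a disc of that diameter.
    """

    n_bscans: int
    n_ascans: int
    spot_diameter_um: float = 15.0
    scan_length_um: float = 6000.0

    def __post_init__(self) -> None:
        if self.n_bscans < 1 or self.n_ascans < 1:
            raise ValueError("n_bscans and n_ascans must be >= 1")
        if self.spot_diameter_um < 0:
            raise ValueError("spot_diameter_um must be >= 0")
        if self.scan_length_um <= 0:
            raise ValueError("scan_length_um must be positive")

    @property
    def bscan_spacing_um(self) -> float:
        """Slow-axis spacing between B-scan rows."""
        return self.scan_length_um / self.n_bscans

    @property
    def ascan_spacing_um(self) -> float:
        """Fast-axis spacing between A-scan centers within a row."""
        return self.scan_length_um / self.n_ascans


def scan_side_mm(nominal_size_mm: float, axial_length_mm: float | None) -> float:
    """Physical scan side length after linear axial-length magnification.

    With no axial length the nominal size is returned; otherwise the nominal
    size is scaled by ``axial_length / 24.46`` (model-eye calibration).
    """
    if axial_length_mm is None:
        return float(nominal_size_mm)
    if axial_length_mm <= 0:
        raise ValueError("axial_length_mm must be positive")
    return float(nominal_size_mm) * float(axial_length_mm) / MODEL_EYE_AXIAL_MM


def pixel_axes(
    tmap: ThicknessMap, axial_length_mm: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """1-D arrays of column-center x and row-center y coordinates (mm).

    Coordinates are volume-centered; center ``c`` of ``n`` cells spanning a
    side ``S`` sits at ``-S/2 + (c + 0.5) * S / n``.
    """
    side = scan_side_mm(tmap.nominal_size_mm, axial_length_mm)
    x = -side / 2.0 + (np.arange(tmap.n_cols) + 0.5) * side / tmap.n_cols
    y = -side / 2.0 + (np.arange(tmap.n_rows) + 0.5) * side / tmap.n_rows
    return x, y


def pixel_centers(
    tmap: ThicknessMap, axial_length_mm: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (X, Y) center coordinates in mm, each shaped like ``values``.

    Pass ``axial_length_mm`` to get magnification-corrected (true) positions;
    ``None`` gives the device's nominal lateral scale.
    """
    x, y = pixel_axes(tmap, axial_length_mm)
    return np.broadcast_to(x, tmap.values.shape).copy(), np.broadcast_to(
        y[:, None], tmap.values.shape
    ).copy()


# ---------------------------------------------------------------------------
# File dialect: CSV matrix (rows = B-scans, row 0 inferior) + JSON sidecar.
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(_SIDECAR_SUFFIX)


def write_map(tmap: ThicknessMap, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a map as a CSV thickness matrix plus a JSON metadata sidecar.

    Floats are written with shortest round-trip representation so that
    ``read_map(write_map(m)) == m`` exactly.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in tmap.values:
            writer.writerow([repr(float(v)) for v in row])
    meta: dict = {
        "subject_id": tmap.subject_id,
        "eye": tmap.eye,
        "n_rows": tmap.n_rows,
        "n_cols": tmap.n_cols,
        "nominal_size_mm": tmap.nominal_size_mm,
    }
    if tmap.axial_length_mm is not None:
        meta["axial_length_mm"] = tmap.axial_length_mm
    if tmap.fovea_xy_mm is not None:
        meta["fovea_xy_mm"] = list(tmap.fovea_xy_mm)
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_map(path: str | Path, sidecar: str | Path | None = None) -> ThicknessMap:
    """Read a CSV thickness matrix and its JSON sidecar into a validated map.

    Raises
    ------
    ParseError
        If the matrix is ragged or contains a non-numeric field; the message
        names the offending row and column (0-based).
    ValueError
        If the parsed grid violates a :class:`ThicknessMap` invariant or
        disagrees with the sidecar's declared shape.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, newline="") as fh:
        for i, fields in enumerate(csv.reader(fh)):
            if not fields:
                continue
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ParseError(
                    f"row {i} has {len(fields)} fields, expected {width}"
                )
            parsed = []
            for j, tok in enumerate(fields):
                try:
                    parsed.append(float(tok))
                except ValueError as exc:
                    raise ParseError(
                        f"row {i}, column {j}: could not parse {tok!r} as a number"
                    ) from exc
            rows.append(parsed)
    if not rows:
        raise ParseError(f"{path} contains no data rows")
    values = np.array(rows, dtype=float)

    with open(sidecar) as fh:
        meta = json.load(fh)
    declared = (meta.get("n_rows"), meta.get("n_cols"))
    if declared != (None, None) and declared != values.shape:
        raise ValueError(
            f"matrix shape {values.shape} disagrees with sidecar-declared "
            f"{declared[0]} x {declared[1]}"
        )
    fovea = meta.get("fovea_xy_mm")
    return ThicknessMap(
        values=values,
        nominal_size_mm=float(meta.get("nominal_size_mm", 6.0)),
        axial_length_mm=(
            float(meta["axial_length_mm"]) if meta.get("axial_length_mm") is not None else None
        ),
        eye=meta.get("eye", "OD"),
        fovea_xy_mm=tuple(fovea) if fovea is not None else None,
        subject_id=str(meta.get("subject_id", "")),
    )
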