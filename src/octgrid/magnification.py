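"""Ocular magnification: axial-length correction of the lateral scale.

OCT scan mirrors are calibrated against a model eye (axial length 24.46 mm
here), so the reported "6 mm" scan length is only nominal.  A longer eye
magnifies the retinal patch swept by the same mirror angle; linear scaling
by ``axial_length / 24.46`` recovers the true scan length.  Uncorrected
plots therefore use ETDRS rings whose true diameters differ from 1/3/6 mm,
and their segment thicknesses are biased wherever the thickness contour
changes across a ring boundary.

Correction is a pure coordinate reinterpretation about the volume center:
thickness values are untouched (they are measured axially), only the pixel
positions rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import MODEL_EYE_AXIAL_MM, ThicknessMap
from .etdrs import ErrorReport, compare_plots, etdrs_plot

__all__ = [
    "MagnificationModel",
    "combined_error",
    "magnification_error",
    "scan_length_mm",
]

_AXIAL_SANITY_MM = (15.0, 40.0)


@dataclass(frozen=True)
class MagnificationModel:
    """Linear magnification model: isolates the scaling formula so that
    alternative corrections (e.g. three-parameter schematic-eye models)
    could be slotted in without touching callers."""

    model_eye_axial_mm: float = MODEL_EYE_AXIAL_MM
    nominal_scan_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.model_eye_axial_mm <= 0 or self.nominal_scan_mm <= 0:
            raise ValueError("model parameters must be positive")


def scan_length_mm(
    axial_length_mm: float, model: MagnificationModel = MagnificationModel()
) -> float:
    """True scan side length for an eye of the given axial length (mm).

    ``nominal * axial / model_eye``; identity at the model eye's 24.46 mm.
    Axial lengths outside the physiological sanity range (15, 40) mm are
    rejected.
    """
    lo, hi = _AXIAL_SANITY_MM
    if not lo < axial_length_mm < hi:
        raise ValueError(
            f"axial length {axial_length_mm} mm outside sanity bounds ({lo}, {hi})"
        )
    return model.nominal_scan_mm * axial_length_mm / model.model_eye_axial_mm


def magnification_error(
    tmap: ThicknessMap, fovea_xy_mm: tuple[float, float] | None = None
) -> tuple[ErrorReport, float]:
    """ETDRS error from ignoring the subject's axial length.

    Compares the plot computed at the true lateral scale (rings physically
    1/3/6 mm in diameter; reference) against the nominal-scale plot, both
    anchored at the same center (default: the map's recorded fovea, else
    the volume center).  Returns the report and |axial length - 24.46| mm.
    """
    if tmap.axial_length_mm is None:
        raise ValueError("map carries no axial_length_mm; cannot correct magnification")
    scan_length_mm(tmap.axial_length_mm)  # sanity-bounds check
    center = fovea_xy_mm if fovea_xy_mm is not None else (tmap.fovea_xy_mm or (0.0, 0.0))
    plot_corrected = etdrs_plot(tmap, center, tmap.axial_length_mm)
    plot_nominal = etdrs_plot(tmap, center, None)
    report = compare_plots(plot_corrected, plot_nominal)
    return report, float(abs(tmap.axial_length_mm - MODEL_EYE_AXIAL_MM))


def combined_error(
    tmap: ThicknessMap, fovea_xy_mm: tuple[float, float] | None = None
) -> ErrorReport:
    """Cumulative ETDRS error of the fully uncorrected default analysis.

    Compares the fully corrected plot (fovea-centered, axial-length-scaled;
    reference) against the fully uncorrected one (volume-centered, nominal
    scale) — i.e. what a device reports with neither correction applied.
    """
    if tmap.axial_length_mm is None:
        raise ValueError("map carries no axial_length_mm; cannot correct magnification")
    scan_length_mm(tmap.axial_length_mm)
    fovea = fovea_xy_mm if fovea_xy_mm is not None else (tmap.fovea_xy_mm or (0.0, 0.0))
    fx, fy = fovea
    half = tmap.nominal_size_mm / 2.0
    if abs(fx) > half or abs(fy) > half:
        raise ValueError(f"fovea {fovea} lies outside the scanned grid")
    plot_corrected = etdrs_plot(tmap, (fx, fy), tmap.axial_length_mm)
    plot_uncorrected = etdrs_plot(tmap, (0.0, 0.0), None)
    return compare_plots(plot_corrected, plot_uncorrected)
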