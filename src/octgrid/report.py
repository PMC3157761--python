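"""Cohort batch analysis and agreement statistics.

Runs the full error battery — interpolation error at each B-scan density,
decentration error, magnification error and their combination — over a
cohort of thickness maps, and summarises the results as tidy tables.  Also
provides the Bland–Altman limits-of-agreement statistic used to validate
one thickness pipeline against another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centering import decentration_error, find_fovea
from .core_io import ThicknessMap, read_map
from .magnification import combined_error, magnification_error
from .undersampling import interpolation_error

__all__ = [
    "BlandAltman",
    "CohortConfig",
    "bland_altman",
    "load_manifest",
    "run_cohort",
    "summarize_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference (bias) and 95% limits of agreement."""

    bias: float
    lower: float
    upper: float
    sd_diff: float


def bland_altman(pairs) -> BlandAltman:
    """Bland–Altman agreement between paired measurements.

    ``pairs`` is a sequence of ``(a, b)`` measurements in um.  The bias is
    ``mean(a - b)`` and the limits are ``bias +/- 1.96 * SD(a - b)`` — the
    conventional large-sample 95% limits (1.96, not a t-quantile).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman needs at least 2 (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(bias=bias, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd, sd_diff=sd)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the cohort runner.

    ``threshold_um`` feeds the exceedance counts in the summary (subjects
    whose summed 9-segment error exceeds the threshold); 20 um is the
    conventional cut for a clinically notable ETDRS discrepancy.
    """

    keep_levels: tuple[int, ...] = (8, 16, 32, 64)
    threshold_um: float = 20.0
    fovea_source: str = "sidecar_then_auto"  # or "auto"


def load_manifest(manifest_path: str | Path) -> list[ThicknessMap]:
    """Load every map listed in a cohort manifest (JSON)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return [
        read_map(base / entry["map"], base / entry["sidecar"])
        for entry in manifest["maps"]
    ]


def _subject_row(tmap: ThicknessMap, config: CohortConfig) -> dict:
    if config.fovea_source == "sidecar_then_auto" and tmap.fovea_xy_mm is not None:
        fovea = tmap.fovea_xy_mm
    else:
        fovea = find_fovea(tmap).xy_mm
    row: dict = {
        "subject_id": tmap.subject_id,
        "axial_length_mm": tmap.axial_length_mm,
        "fovea_x_mm": fovea[0],
        "fovea_y_mm": fovea[1],
    }
    for n_keep in config.keep_levels:
        rep, _ = interpolation_error(tmap, n_keep, fovea)
        row[f"pp_err_{n_keep}_um"] = rep.mean_per_pixel_error_um
        row[f"pp_max_{n_keep}_um"] = rep.max_per_pixel_error_um
        row[f"interp_csf_{n_keep}_um"] = rep.central_subfield_error_um
    dec_rep, dec = decentration_error(tmap, fovea)
    row["decentration_mm"] = dec
    row["dec_summed_um"] = dec_rep.summed_error_um
    row["dec_csf_um"] = dec_rep.central_subfield_error_um
    if tmap.axial_length_mm is not None:
        mag_rep, dal = magnification_error(tmap, fovea)
        row["abs_dAL_mm"] = dal
        row["mag_summed_um"] = mag_rep.summed_error_um
        row["mag_csf_um"] = mag_rep.central_subfield_error_um
        comb_rep = combined_error(tmap, fovea)
        row["comb_summed_um"] = comb_rep.summed_error_um
        row["comb_csf_um"] = comb_rep.central_subfield_error_um
    return row


def run_cohort(
    maps, config: CohortConfig = CohortConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every error analysis over a cohort of maps.

    Returns ``(per_subject, summary)``.  Per-subject failures are logged
    and tallied (as rows with only ``subject_id`` and ``error``), never
    fatal.  Deterministic given the maps and config.
    """
    rows = []
    for tmap in maps:
        try:
            rows.append(_subject_row(tmap, config))
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.warning("subject %s failed: %s", tmap.subject_id, exc)
            rows.append({"subject_id": tmap.subject_id, "error": str(exc)})
    per_subject = pd.DataFrame(rows)
    return per_subject, summarize_cohort(per_subject, config)


def summarize_cohort(
    per_subject: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> pd.DataFrame:
    """Cohort mean / SD / max per metric, plus threshold-exceedance counts."""
    numeric = per_subject.select_dtypes(include=[np.number])
    summary = numeric.agg(["mean", "std", "max"]).T
    summary["n"] = numeric.notna().sum()
    counts = {}
    for col in ("dec_summed_um", "mag_summed_um", "comb_summed_um"):
        if col in numeric:
            counts[col] = int((numeric[col] > config.threshold_um).sum())
    summary["n_exceeding_threshold"] = pd.Series(counts)
    if "error" in per_subject:
        summary.attrs["n_failed"] = int(per_subject["error"].notna().sum())
    else:
        summary.attrs["n_failed"] = 0
    return summary
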