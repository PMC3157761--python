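"""Synthetic macular thickness maps and cohorts.

Real exported thickness volumes cannot be redistributed, so every analysis
in this package is exercised against a parametric phantom.  The phantom is
a radially symmetric foveal-pit surface (a parafoveal Gaussian rim minus a
central Gaussian pit on a flat periphery), optionally decorated with
drusen-like Gaussian bumps, decentred by a fixation offset, sampled on the
scanner's raster at the subject's true lateral scale, and corrupted with
additive Gaussian measurement noise.

The pit model is geometric, not anatomical: its job is to provide a smooth
surface with realistic central/peripheral thickness (approx. 180 um CSF,
270 um periphery with the defaults) and a well-defined minimum, so that
interpolation, centering and magnification errors can be measured against
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import MODEL_EYE_AXIAL_MM, ThicknessMap, pixel_centers, write_map

__all__ = [
    "DrusenParams",
    "PitParams",
    "SubjectParams",
    "SyntheticCohortSpec",
    "draw_cohort_params",
    "make_cohort",
    "make_map",
    "pit_profile",
    "write_cohort",
]


@dataclass(frozen=True)
class PitParams:
    """Radial foveal-pit profile parameters (um and mm).

    ``T(r) = periphery + ring_amp * exp(-(r - ring_radius)^2 / (2 ring_sigma^2))
             - pit_amp * exp(-r^2 / (2 pit_sigma^2))``
    """

    periphery_um: float = 270.0
    ring_amp_um: float = 60.0
    ring_radius_mm: float = 1.2
    ring_sigma_mm: float = 0.8
    pit_amp_um: float = 110.0
    pit_sigma_mm: float = 0.35

    def __post_init__(self) -> None:
        if self.ring_amp_um < 0 or self.pit_amp_um < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.ring_sigma_mm <= 0 or self.pit_sigma_mm <= 0:
            raise ValueError("sigmas must be positive")
        # cheap lower bound on the profile: periphery minus full pit depth
        if self.periphery_um - self.pit_amp_um <= 0:
            raise ValueError("pit depth exceeds peripheral thickness")


@dataclass(frozen=True)
class DrusenParams:
    """Drusen-like bump field: Poisson count of isotropic Gaussian bumps."""

    mean_count: float = 8.0
    amp_range_um: tuple[float, float] = (20.0, 120.0)
    sigma_range_mm: tuple[float, float] = (0.05, 0.25)
    edge_margin_mm: float = 0.2  # keep bump centers off the map edge

    def __post_init__(self) -> None:
        for lo, hi in (self.amp_range_um, self.sigma_range_mm):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be ordered and positive")
        if self.mean_count < 0:
            raise ValueError("mean_count must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level distributions and the master seed.

    ``fixation_sd_mm`` is the per-axis SD of the isotropic Gaussian fixation
    offset; the default 0.09 * sqrt(2/pi) makes the mean offset magnitude
    0.09 mm, the typical decentration of a fovea-targeted macular volume.
    Axial lengths are drawn from a truncated normal (default 24.46 +/- 1.2 mm
    on [21, 30.5]).  Each subject's pit parameters are jittered by a
    multiplicative factor with fractional SD ``pit_jitter_frac``.
    """

    n_subjects: int = 10
    axial_mean_mm: float = MODEL_EYE_AXIAL_MM
    axial_sd_mm: float = 1.2
    axial_bounds_mm: tuple[float, float] = (21.0, 30.5)
    fixation_sd_mm: float = 0.09 * float(np.sqrt(2.0 / np.pi))
    pit: PitParams = field(default_factory=PitParams)
    pit_jitter_frac: float = 0.05
    drusen: DrusenParams | None = None
    noise_sd_um: float = 2.0
    seed: int = 0
    n_rows: int = 128
    n_cols: int = 512
    nominal_size_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.axial_sd_mm < 0 or self.fixation_sd_mm < 0 or self.noise_sd_um < 0:
            raise ValueError("SDs must be >= 0")
        lo, hi = self.axial_bounds_mm
        if not lo < hi:
            raise ValueError("axial bounds must be ordered")


def pit_profile(params: PitParams, r) -> np.ndarray | float:
    """Evaluate the radial pit profile at radius ``r`` (mm), in um."""
    r = np.asarray(r, dtype=float)
    ring = params.ring_amp_um * np.exp(
        -((r - params.ring_radius_mm) ** 2) / (2.0 * params.ring_sigma_mm**2)
    )
    pit = params.pit_amp_um * np.exp(-(r**2) / (2.0 * params.pit_sigma_mm**2))
    out = params.periphery_um + ring - pit
    return float(out) if out.ndim == 0 else out


def make_map(
    pit: PitParams = PitParams(),
    drusen: DrusenParams | None = None,
    fovea_xy_mm: tuple[float, float] = (0.0, 0.0),
    axial_length_mm: float | None = None,
    noise_sd_um: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    n_rows: int = 128,
    n_cols: int = 512,
    nominal_size_mm: float = 6.0,
    eye: str = "OD",
    subject_id: str = "synthetic",
) -> ThicknessMap:
    """Render one synthetic thickness map.

    The pit profile is sampled at pixel centers computed with the subject's
    axial length (true lateral scale), with radius measured from
    ``fovea_xy_mm``.  Drusen bumps and i.i.d. Gaussian noise are then added.
    Fully deterministic for a fixed seed; the returned map records the true
    fovea position and axial length in its metadata.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shell = ThicknessMap(
        values=np.full((n_rows, n_cols), 300.0),
        nominal_size_mm=nominal_size_mm,
        axial_length_mm=axial_length_mm,
        eye=eye,
        fovea_xy_mm=tuple(map(float, fovea_xy_mm)),
        subject_id=subject_id,
    )
    X, Y = pixel_centers(shell, axial_length_mm)
    fx, fy = shell.fovea_xy_mm
    r = np.sqrt((X - fx) ** 2 + (Y - fy) ** 2)
    values = np.asarray(pit_profile(pit, r), dtype=float)

    if drusen is not None and drusen.mean_count > 0:
        count = int(rng.poisson(drusen.mean_count))
        half = X.max()  # centers span (-half, half) symmetric
        lo, hi = -half + drusen.edge_margin_mm, half - drusen.edge_margin_mm
        for _ in range(count):
            cx, cy = rng.uniform(lo, hi, size=2)
            amp = rng.uniform(*drusen.amp_range_um)
            sig = rng.uniform(*drusen.sigma_range_mm)
            values += amp * np.exp(
                -((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * sig**2)
            )

    if noise_sd_um > 0:
        values += rng.normal(0.0, noise_sd_um, size=values.shape)

    if values.min() <= 0:
        raise ValueError(
            "generated thickness <= 0 um; offending parameters: "
            f"pit={pit}, drusen={drusen}, noise_sd_um={noise_sd_um}"
        )
    return shell.with_values(values)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject draws realised from a :class:`SyntheticCohortSpec`."""

    subject_id: str
    axial_length_mm: float
    fovea_xy_mm: tuple[float, float]
    pit: PitParams
    drusen: DrusenParams | None
    noise_sd_um: float
    seed_key: tuple[int, int]


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated normal rejection sampling failed")


def draw_cohort_params(spec: SyntheticCohortSpec) -> list[SubjectParams]:
    """Draw per-subject parameters without rendering any maps.

    One RNG stream per subject, keyed ``(spec.seed, subject_index)``, so
    enlarging the cohort never perturbs earlier subjects.
    """
    out = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, i])
        axial = _truncated_normal(
            rng, spec.axial_mean_mm, spec.axial_sd_mm, *spec.axial_bounds_mm
        )
        offset = tuple(rng.normal(0.0, spec.fixation_sd_mm, size=2))
        jitter = {
            name: 1.0 + float(np.clip(rng.normal(0.0, spec.pit_jitter_frac), -0.3, 0.3))
            for name in (
                "periphery_um",
                "ring_amp_um",
                "ring_radius_mm",
                "ring_sigma_mm",
                "pit_amp_um",
                "pit_sigma_mm",
            )
        }
        pit = PitParams(
            **{name: getattr(spec.pit, name) * f for name, f in jitter.items()}
        )
        out.append(
            SubjectParams(
                subject_id=f"synth-{i:04d}",
                axial_length_mm=axial,
                fovea_xy_mm=(float(offset[0]), float(offset[1])),
                pit=pit,
                drusen=spec.drusen,
                noise_sd_um=spec.noise_sd_um,
                seed_key=(spec.seed, i),
            )
        )
    return out


def _render_subject(params: SubjectParams, spec: SyntheticCohortSpec) -> ThicknessMap:
    # fresh stream, advanced past the parameter draws by a fixed jump
    rng = np.random.default_rng([*params.seed_key, 1])
    return make_map(
        pit=params.pit,
        drusen=params.drusen,
        fovea_xy_mm=params.fovea_xy_mm,
        axial_length_mm=params.axial_length_mm,
        noise_sd_um=params.noise_sd_um,
        seed=rng,
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        nominal_size_mm=spec.nominal_size_mm,
        subject_id=params.subject_id,
    )


def make_cohort(spec: SyntheticCohortSpec) -> list[ThicknessMap]:
    """Render the full cohort; reproducible from ``spec.seed`` alone."""
    return [_render_subject(p, spec) for p in draw_cohort_params(spec)]


def write_cohort(spec: SyntheticCohortSpec, outdir: str | Path) -> Path:
    """Render a cohort to ``outdir`` (CSV + sidecar per subject) + manifest.

    Returns the manifest path.  The manifest is a JSON document listing each
    subject's matrix and sidecar file, consumable by the cohort runner.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tmap in make_cohort(spec):
        stem = tmap.subject_id
        write_map(tmap, outdir / f"{stem}.csv")
        entries.append({"map": f"{stem}.csv", "sidecar": f"{stem}.json"})
    manifest = {"n_subjects": spec.n_subjects, "seed": spec.seed, "maps": entries}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest_path
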