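"""Synthetic CARS cohorts with the statistical structure the analysis assumes.

Each pixel spectrum is a sum of Gaussian vibrational bands over a slowly
varying non-resonant background: the CH2 symmetric stretch near 2850 cm^-1
(the "lipid" channel), a CH2 asymmetric shoulder near 2889 cm^-1 and the
CH3 asymmetric stretch near 2940 cm^-1 (the "protein" channel).  The
genotype effect is a multiplier on the lipid-band amplitude: wild-type
(WT) tissue shows a double peak of similar height at 2850/2940 cm^-1,
knockout (KO, the Fabry model with glycosphingolipid accumulation) a
lipid-dominant single peak.

Hierarchy of variability:

* per-mouse log-normal multiplier on the lipid amplitude (biological
  between-animal variation),
* per-image smooth spatial random field multiplying the lipid amplitude
  (tissue heterogeneity: lipid-rich vs protein-rich regions),
* per-pixel additive Gaussian detector noise, clipping at zero and at the
  detector ceiling, and a small fraction of injected saturated pixels.

Randomness is split hierarchically (cohort -> mouse -> image) with
``numpy.random.SeedSequence`` spawn keys, so adding mice or images does not
perturb the data of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .axis import SpectralAxis, build_axis
from .cube_io import CohortManifest, HyperCube, ManifestRecord, write_cube, write_manifest

__all__ = [
    "Band",
    "SimConfig",
    "spectrum_model",
    "simulate_cohort",
    "default_configs",
    "leakage_demo_config",
    "write_cohort",
    "LIPID_CM1",
    "PROTEIN_CM1",
]

#: canonical band centers (cm^-1): CH2 symmetric (lipid), CH2 asymmetric,
#: CH3 asymmetric (protein)
LIPID_CM1 = 2850.0
CH2_ASYM_CM1 = 2889.0
PROTEIN_CM1 = 2940.0


@dataclass(frozen=True)
class Band:
    """A Gaussian vibrational band."""

    center_cm1: float
    sigma_cm1: float
    amplitude: float

    def __post_init__(self):
        if self.sigma_cm1 <= 0:
            raise ValueError(f"sigma_cm1 must be positive, got {self.sigma_cm1}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be nonnegative, got {self.amplitude}")


def _default_wt_bands() -> tuple[Band, ...]:
    return (
        Band(LIPID_CM1, 16.0, 1.0),
        Band(CH2_ASYM_CM1, 14.0, 0.55),
        Band(PROTEIN_CM1, 18.0, 1.0),
    )


def _ko_bands(wt_bands: tuple[Band, ...], lipid_ratio: float) -> tuple[Band, ...]:
    """Scale the band nearest the lipid channel by ``lipid_ratio``."""
    centers = [b.center_cm1 for b in wt_bands]
    lipid_idx = int(np.argmin(np.abs(np.asarray(centers) - LIPID_CM1)))
    return tuple(
        replace(b, amplitude=b.amplitude * lipid_ratio) if i == lipid_idx else b
        for i, b in enumerate(wt_bands)
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the acquisition geometry (804.0-826.4 nm pump sweep,
    0.7 nm step, 1064 nm Stokes -> 33 channels) at a desk-scale image side
    of 128 px; 1024 px cubes are accepted.
    """

    start_nm: float = 804.0
    stop_nm: float = 826.4
    step_nm: float = 0.7
    stokes_nm: float = 1064.0
    image_side: int = 128
    n_mice_wt: int = 8
    n_mice_ko: int = 10
    images_per_mouse: int = 1
    bands_wt: tuple[Band, ...] = field(default_factory=_default_wt_bands)
    bands_ko: tuple[Band, ...] = field(
        default_factory=lambda: _ko_bands(_default_wt_bands(), 1.6)
    )
    mouse_sd: float = 0.10
    field_scale: float = 16.0
    field_sd: float = 0.3
    baseline_level: float = 0.3
    baseline_slope: float = -5e-4
    noise_sd: float = 0.05
    sat_value: float = 4.0
    sat_fraction: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.image_side < 1:
            bad.append(f"image_side={self.image_side} (must be >= 1)")
        for name in ("n_mice_wt", "n_mice_ko", "images_per_mouse"):
            if getattr(self, name) < 1:
                bad.append(f"{name}={getattr(self, name)} (must be >= 1)")
        for name in ("mouse_sd", "field_sd", "noise_sd"):
            if getattr(self, name) < 0:
                bad.append(f"{name}={getattr(self, name)} (must be >= 0)")
        if not (0 <= self.sat_fraction < 1):
            bad.append(f"sat_fraction={self.sat_fraction} (must be in [0, 1))")
        if self.sat_value <= self.baseline_level:
            bad.append(
                f"sat_value={self.sat_value} (must exceed "
                f"baseline_level={self.baseline_level})"
            )
        if self.field_scale <= 0:
            bad.append(f"field_scale={self.field_scale} (must be > 0)")
        if bad:
            raise ValueError("invalid SimConfig: " + "; ".join(bad))

    def build_axis(self) -> SpectralAxis:
        return build_axis(self.start_nm, self.stop_nm, self.step_nm, self.stokes_nm)


def spectrum_model(
    bands,
    baseline_level: float,
    baseline_slope: float,
    axis: SpectralAxis,
) -> np.ndarray:
    """Noise-free model spectrum on the axis grid, clipped at zero.

    ``baseline_level + baseline_slope * (wn - mean(wn))`` plus a Gaussian
    per band.
    """
    if axis.n_channels < 1:
        raise ValueError("axis must be non-empty")
    wn = axis.wavenumbers_cm1
    out = baseline_level + baseline_slope * (wn - wn.mean())
    for b in bands:
        out = out + b.amplitude * np.exp(-((wn - b.center_cm1) ** 2) / (2 * b.sigma_cm1**2))
    return np.clip(out, 0.0, None)


def _band_profiles(bands, axis: SpectralAxis):
    """Split the band sum into the (unit-amplitude) lipid profile and the rest."""
    wn = axis.wavenumbers_cm1
    centers = np.array([b.center_cm1 for b in bands]) if bands else np.empty(0)
    lipid_idx = int(np.argmin(np.abs(centers - LIPID_CM1))) if len(centers) else -1
    lipid_profile = np.zeros_like(wn)
    other = np.zeros_like(wn)
    lipid_amp = 0.0
    for i, b in enumerate(bands):
        g = np.exp(-((wn - b.center_cm1) ** 2) / (2 * b.sigma_cm1**2))
        if i == lipid_idx:
            lipid_profile = g
            lipid_amp = b.amplitude
        else:
            other = other + b.amplitude * g
    return lipid_profile, lipid_amp, other


def _spatial_field(rng: np.random.Generator, side: int, scale: float, sd: float) -> np.ndarray:
    """Smooth log-normal field with unit median: exp(sd * z), z a standardized
    low-pass-filtered white-noise field with correlation length ``scale`` px."""
    if sd == 0:
        return np.ones((side, side))
    z = rng.standard_normal((side, side))
    z = ndimage.gaussian_filter(z, sigma=scale, mode="wrap")
    s = z.std()
    if s < 1e-12:  # filter wider than the image: field degenerates to flat
        return np.ones((side, side))
    z = (z - z.mean()) / s
    return np.exp(sd * z)


def _simulate_image(
    rng: np.random.Generator,
    config: SimConfig,
    axis: SpectralAxis,
    bands,
    mouse_multiplier: float,
):
    side = config.image_side
    wn = axis.wavenumbers_cm1
    baseline = config.baseline_level + config.baseline_slope * (wn - wn.mean())
    lipid_profile, lipid_amp, other = _band_profiles(bands, axis)

    fld = _spatial_field(rng, side, config.field_scale, config.field_sd)
    amp = lipid_amp * mouse_multiplier * fld.ravel()  # per-pixel lipid amplitude
    spectra = baseline + other + amp[:, None] * lipid_profile[None, :]
    np.clip(spectra, 0.0, None, out=spectra)
    if config.noise_sd > 0:
        spectra += rng.normal(0.0, config.noise_sd, size=spectra.shape)
    np.clip(spectra, 0.0, config.sat_value, out=spectra)

    if config.sat_fraction > 0:
        hot = rng.random(side * side) < config.sat_fraction
        hot_idx = np.flatnonzero(hot)
        channels = rng.integers(0, axis.n_channels, size=hot_idx.size)
        spectra[hot_idx, channels] = config.sat_value
    return spectra.reshape(side, side, axis.n_channels).astype(np.float32), fld


def simulate_cohort(
    config: SimConfig, return_truth: bool = False
) -> tuple[CohortManifest, list[HyperCube]] | tuple[CohortManifest, list[HyperCube], dict]:
    """Generate a cohort of cubes; deterministic given ``config.seed``.

    With ``return_truth=True`` additionally returns the latent ground truth
    (per-mouse lipid multipliers and per-image spatial fields) for
    validation against the generator's own model.
    """
    config.validate()
    axis = config.build_axis()
    records: list[ManifestRecord] = []
    cubes: list[HyperCube] = []
    truth: dict = {"mouse_multiplier": {}, "field": {}}

    groups = [
        ("WT", 0, config.n_mice_wt, config.bands_wt),
        ("KO", 1, config.n_mice_ko, config.bands_ko),
    ]
    for genotype, gcode, n_mice, bands in groups:
        for m in range(n_mice):
            mouse_id = f"{genotype}{m + 1:02d}"
            mouse_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(gcode, m, 0))
            )
            mult = float(np.exp(mouse_rng.normal(0.0, config.mouse_sd))) if config.mouse_sd > 0 else 1.0
            truth["mouse_multiplier"][mouse_id] = mult
            for img in range(config.images_per_mouse):
                image_id = f"{mouse_id}_img{img:02d}"
                img_rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(gcode, m, 1 + img))
                )
                values, fld = _simulate_image(img_rng, config, axis, bands, mult)
                meta = {
                    "image_id": image_id,
                    "mouse_id": mouse_id,
                    "genotype": genotype,
                    "sat_value": float(config.sat_value),
                }
                cubes.append(HyperCube(values=values, axis=axis, meta=meta))
                records.append(
                    ManifestRecord(
                        image_path=f"{image_id}.tiff",
                        image_id=image_id,
                        mouse_id=mouse_id,
                        genotype=genotype,
                    )
                )
                truth["field"][image_id] = fld
    manifest = CohortManifest(records=records)
    if return_truth:
        return manifest, cubes, truth
    return manifest, cubes


def default_configs(seed: int = 0) -> tuple[SimConfig, SimConfig]:
    """(Dataset-III analogue, matched null) configurations.

    The Dataset-III analogue mirrors the one-image-per-mouse cohort design
    (8 WT vs 10 KO mice) with the KO lipid amplitude 1.6x the WT value; the
    null is identical except the KO band set equals the WT set (zero
    genotype effect), for calibration of the cross-validated sensitivity.
    """
    dataset3 = SimConfig(seed=seed)
    null = replace(dataset3, bands_ko=dataset3.bands_wt)
    return dataset3, null


def leakage_demo_config(seed: int = 0) -> SimConfig:
    """Cohort built to expose subject-level leakage in naive image-level CV.

    Zero genotype effect, but a strong per-mouse batch effect (log-normal
    lipid-ratio SD 0.5) and few mice contributing many images each
    (2 WT / 2 KO mice, 8 images per mouse).  Grouped leave-one-mouse-out CV
    stays near chance on such data; leave-one-image-out CV trains on the
    held-out image's litter-mates and inflates sensitivity.
    """
    base = SimConfig(seed=seed)
    return replace(
        base,
        n_mice_wt=2,
        n_mice_ko=2,
        images_per_mouse=8,
        mouse_sd=0.5,
        bands_ko=base.bands_wt,
    )


def write_cohort(config: SimConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write cubes + ``manifest.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, cubes = simulate_cohort(config)
    for rec, cube in zip(manifest, cubes):
        write_cube(cube, out_dir / rec.image_path)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
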