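"""Phantom cohorts with the statistical structure the analysis assumes.

The generator emulates a two-class cohort of diffusion-weighted volumes with
per-slice elliptical lesion ROIs. The two classes share a common baseline
signal and differ only in the *texture* of the lesion:

* non-significant lesions (label 0) contain i.i.d. symmetric Gaussian noise
  around a constant lesion mean;
* significant lesions (label 1) additionally carry (a) a smooth random mean
  field (white noise low-pass filtered at a ~5 mm correlation length) whose
  standard deviation is ``heterogeneity_effect``, and (b) right-skewed noise
  (shifted log-normal, zero mean, ``noise_sd`` spread) with skewness
  ``asymmetry_effect``.

The two mechanisms mimic the heterogeneity and asymmetry of local
cellularity that distinguish aggressive lesions. Each significant lesion
draws a *phenotype trade-off*: a uniform variate splits the configured
effect budget between heterogeneity and asymmetry (anti-correlated
per-patient magnitudes, class means equal to the configured effects). This
reproduces a key property of the target analysis: the two discriminant
feature families stay essentially uncorrelated across patients even though
both separate the classes, so a feature couple can pass a strict
redundancy filter while remaining jointly discriminant. Setting
``phenotype_tradeoff = 0`` plants identical effects in every significant
lesion.

Generation is bit-exact reproducible: one ``seed`` spawns an independent
substream per patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .io import ImageVolume, LesionMask, write_mask, write_volume

MANIFEST_COLUMNS = ("patient_id", "label", "image", "mask", "spacing_mm")


@dataclass(frozen=True)
class CohortConfig:
    """Phantom cohort parameters.

    Defaults mirror the target acquisition (in-plane spacing within
    [1.41, 1.67] mm, 3 mm slices) and a cohort of 26 non-significant plus
    50 significant lesions. Signal units are arbitrary; effects are sized
    so that each mechanism separates the classes strongly at these sample
    sizes (the study never reports effects in raw units).
    """

    n_ncs: int = 26
    n_cs: int = 50
    seed: int = 0
    pixel_spacing_mm: float = 1.5
    slice_thickness_mm: float = 3.0
    slices_per_lesion: tuple[int, int] = (3, 6)
    lesion_axes_mm: tuple[float, float] = (4.0, 9.0)  # semi-axis range
    background_mean: float = 100.0
    background_sd: float = 15.0
    heterogeneity_effect: float = 30.0
    asymmetry_effect: float = 1.5
    noise_sd: float = 15.0
    phenotype_tradeoff: float = 1.0
    field_correlation_mm: float = 5.0

    def validate(self) -> None:
        if self.n_ncs < 1 or self.n_cs < 1:
            raise ConfigurationError("class sizes must be >= 1")
        for name in ("pixel_spacing_mm", "slice_thickness_mm", "background_sd",
                     "noise_sd", "field_correlation_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        lo, hi = self.slices_per_lesion
        if lo < 1 or hi < lo:
            raise ConfigurationError("slices_per_lesion must be a valid count range")
        alo, ahi = self.lesion_axes_mm
        if alo <= 0 or ahi < alo:
            raise ConfigurationError("lesion_axes_mm must be a positive range")
        if self.heterogeneity_effect < 0 or self.asymmetry_effect < 0:
            raise ConfigurationError("effect sizes must be >= 0")
        if not 0.0 <= self.phenotype_tradeoff <= 1.0:
            raise ConfigurationError("phenotype_tradeoff must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomPatient:
    volume: ImageVolume
    mask: LesionMask
    label: int
    patient_id: str
    #: ground-truth per-lesion effect magnitudes (0 for the ncs class),
    #: kept for parameter-recovery checks
    planted_heterogeneity: float = 0.0
    planted_asymmetry: float = 0.0


def _lognormal_sigma_for_skewness(skewness: float) -> float:
    """Log-scale sigma of a log-normal with the requested skewness.

    Solves (w + 2) * sqrt(w - 1) = skewness with w = exp(sigma^2), i.e. the
    real root > 1 of w^3 + 3 w^2 - (4 + skewness^2) = 0.
    """
    roots = np.roots([1.0, 3.0, 0.0, -(4.0 + skewness**2)])
    real = roots[np.isreal(roots)].real
    w = real[real > 1.0]
    if w.size == 0:  # pragma: no cover - cubic always has one root > 1 for skew > 0
        raise ConfigurationError(f"cannot match skewness {skewness}")
    return float(np.sqrt(np.log(w[0])))


def skewed_noise(rng: np.random.Generator, size, sd: float, skewness: float) -> np.ndarray:
    """Zero-mean noise with standard deviation ``sd`` and given skewness.

    Gaussian for ``skewness = 0``; otherwise a shifted, rescaled log-normal
    (right-skewed for positive ``skewness``).
    """
    if skewness == 0.0:
        return rng.normal(0.0, sd, size)
    sigma = _lognormal_sigma_for_skewness(skewness)
    raw = np.exp(sigma * rng.normal(0.0, 1.0, size))
    mean = np.exp(sigma**2 / 2.0)
    var = (np.exp(sigma**2) - 1.0) * np.exp(sigma**2)
    return (raw - mean) * (sd / np.sqrt(var))


def _slice_profile(n_slices: int) -> np.ndarray:
    """Axis scale per lesion slice, shrinking toward the first/last slice."""
    if n_slices == 1:
        return np.array([1.0])
    u = np.linspace(-1.0, 1.0, n_slices)
    return np.sqrt(1.0 - 0.75 * u**2)


def _generate_patient(
    config: CohortConfig, label: int, patient_id: str, rng: np.random.Generator
) -> PhantomPatient:
    sp = config.pixel_spacing_mm
    n_slices = int(rng.integers(config.slices_per_lesion[0], config.slices_per_lesion[1] + 1))
    a_mm, b_mm = rng.uniform(*config.lesion_axes_mm, size=2)
    a_px, b_px = a_mm / sp, b_mm / sp

    max_px = config.lesion_axes_mm[1] / sp
    size = int(2 * np.ceil(max_px) + 18)  # margin keeps patches off the border
    shape = (n_slices + 2, size, size)

    volume = config.background_mean + rng.normal(0.0, config.background_sd, shape)

    center = (size - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mask = np.zeros(shape, dtype=np.uint8)
    for j, scale in enumerate(_slice_profile(n_slices)):
        ellipse = (
            ((rr - center[0]) / (a_px * scale)) ** 2
            + ((cc - center[1]) / (b_px * scale)) ** 2
        ) <= 1.0
        mask[j + 1] = ellipse
    if mask.sum() == 0:
        raise ConfigurationError(
            f"degenerate lesion geometry (axes {a_mm:.2f}x{b_mm:.2f} mm at {sp} mm spacing)"
        )

    inside = mask > 0
    n_vox = int(inside.sum())

    if label == 0:
        heterogeneity, asymmetry = 0.0, 0.0
    else:
        # phenotype trade-off: one uniform variate splits the effect budget
        u = rng.uniform()
        t = config.phenotype_tradeoff
        heterogeneity = config.heterogeneity_effect * (1.0 + t * (2.0 * u - 1.0))
        asymmetry = config.asymmetry_effect * (1.0 - t * (2.0 * u - 1.0))

    lesion = np.full(n_vox, config.background_mean)
    if heterogeneity > 0.0:
        white = rng.normal(0.0, 1.0, shape)
        sigma_px = config.field_correlation_mm / sp
        smooth = gaussian_filter(white, sigma=(0.0, sigma_px, sigma_px), mode="reflect")
        smooth /= smooth.std()
        lesion = lesion + heterogeneity * smooth[inside]
    lesion = lesion + skewed_noise(rng, n_vox, config.noise_sd, asymmetry)
    volume[inside] = lesion

    vol = ImageVolume(
        voxels=volume,
        pixel_spacing_mm=(sp, sp),
        slice_thickness_mm=config.slice_thickness_mm,
    )
    return PhantomPatient(
        volume=vol,
        mask=LesionMask(mask),
        label=label,
        patient_id=patient_id,
        planted_heterogeneity=heterogeneity,
        planted_asymmetry=asymmetry,
    )


def generate_cohort(config: CohortConfig) -> list[PhantomPatient]:
    """Generate ``n_ncs + n_cs`` phantom patients, deterministic under seed."""
    config.validate()
    n_total = config.n_ncs + config.n_cs
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    patients = []
    for i in range(config.n_ncs):
        rng = np.random.default_rng(streams[i])
        patients.append(_generate_patient(config, 0, f"ncs-{i + 1:03d}", rng))
    for i in range(config.n_cs):
        rng = np.random.default_rng(streams[config.n_ncs + i])
        patients.append(_generate_patient(config, 1, f"cs-{i + 1:03d}", rng))
    return patients


def couple_tags_planted_mechanisms(
    couple: tuple[str, str],
    cs_features: pd.DataFrame,
    planted_heterogeneity,
    alpha: float = 0.05,
) -> bool:
    """Whether a selected couple recovers the two planted mechanisms.

    Several of the 84 features respond to the same planted mechanism (the
    spreads of the local-mean, local-median and local-CV maps all track the
    heterogeneity field), so recovery is judged against the generator's
    ground truth rather than by feature name: across the significant-class
    lesions, each member of the couple must show a significant Spearman
    association (p < ``alpha``) with the planted per-lesion heterogeneity
    magnitude, and the two members must tag *different* mechanisms. Under
    the phenotype trade-off the heterogeneity and asymmetry magnitudes are
    anti-correlated, so the association's sign identifies the mechanism:
    positive tags heterogeneity, negative tags asymmetry.
    """
    from scipy.stats import spearmanr

    h = np.asarray(planted_heterogeneity, dtype=float)
    tags = set()
    for member in couple:
        res = spearmanr(cs_features[member], h)
        if res.pvalue >= alpha:
            return False
        tags.add("heterogeneity" if res.statistic > 0 else "asymmetry")
    return tags == {"heterogeneity", "asymmetry"}


def write_cohort(patients: list[PhantomPatient], directory: str | Path) -> Path:
    """Write one image + one mask NIfTI per patient plus a CSV manifest.

    Returns the manifest path; paths in the manifest are relative to it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        img_name = f"{p.patient_id}_image.nii"
        mask_name = f"{p.patient_id}_mask.nii"
        write_volume(p.volume, directory / img_name)
        write_mask(p.mask, p.volume, directory / mask_name)
        rows.append({
            "patient_id": p.patient_id,
            "label": p.label,
            "image": img_name,
            "mask": mask_name,
            "spacing_mm": p.volume.pixel_spacing_mm[0],
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest
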