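"""Local first-order radiomic features on a sliding square patch.

For every in-mask pixel, seven first-order statistics (mean, median,
skewness, kurtosis, interquartile range, coefficient of variation, entropy)
are computed over a square in-slice window centered on the pixel. The window
side is derived from the pixel spacing so that the patch explores at least
0.5 cm from the central pixel along rows and columns (roughly a 1 cm^2
tissue unit). Each of the seven per-pixel maps, pooled over all lesion
voxels of a patient, is then condensed into twelve global summaries,
yielding 7 x 12 = 84 features per patient.

Estimator conventions
---------------------
* mean: arithmetic; median and percentiles: linear-interpolation empirical
  quantiles; IQR = q75 - q25.
* skewness: bias-uncorrected Fisher-Pearson g1 = m3 / m2^(3/2).
* kurtosis: excess g2 = m4 / m2^2 - 3 (normal -> 0).
* CV: population standard deviation divided by the mean.
* entropy: Shannon entropy (bits) of a 16-bin histogram spanning the
  sample's own min-max range.
* Degenerate samples (zero variance): skewness, kurtosis, CV and entropy
  are 0 by convention; a zero mean with nonzero spread yields CV = 0 with
  a logged warning.
* "Last decile" summaries use the values at or above the empirical 90th
  percentile.

Windows are truncated at image borders and are *not* restricted to the
mask: surrounding context pixels contribute to the local statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import io as lio
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Short codes of the 7 local (per-pixel) statistics, in canonical order.
LOCAL_CODES = ("m", "M", "s", "k", "iqr", "cv", "e")
LOCAL_NAMES = ("mean", "median", "skewness", "kurtosis", "iqr", "cv", "entropy")

#: Short codes of the 12 global summaries, in canonical order.
GLOBAL_CODES = ("mean", "M", "s", "k", "iqr", "CV", "e", "max", "sigma", "mad", "m90th", "M90th")

#: Canonical 84 feature names, local-statistic major, global-summary minor.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{loc}_{glob}" for loc in LOCAL_CODES for glob in GLOBAL_CODES
)

N_LOCAL = len(LOCAL_CODES)
N_GLOBAL = len(GLOBAL_CODES)
ENTROPY_BINS = 16


def window_side_from_spacing(pixel_spacing_mm: float, reach_mm: float = 5.0) -> int:
    """Odd window side (pixels) exploring ``reach_mm`` from the central pixel.

    ``side = 2 * floor(reach_mm / spacing) + 1``, clamped to >= 3. At the
    protocol spacing extremes 1.41 mm and 1.67 mm this gives sides 7 and 5.
    """
    if pixel_spacing_mm <= 0:
        raise ConfigurationError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    side = 2 * math.floor(reach_mm / pixel_spacing_mm) + 1
    return max(side, 3)


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def _batch_first_order(patches: np.ndarray) -> np.ndarray:
    """Seven first-order statistics per row of a (n, k) sample matrix.

    Returns an (n, 7) array ordered as :data:`LOCAL_NAMES`.
    """
    P = np.asarray(patches, dtype=float)
    n, k = P.shape
    out = np.empty((n, N_LOCAL), dtype=float)

    mean = P.mean(axis=1)
    q25, med, q75 = np.quantile(P, [0.25, 0.5, 0.75], axis=1)
    d = P - mean[:, None]
    m2 = np.mean(d * d, axis=1)
    m3 = np.mean(d**3, axis=1)
    m4 = np.mean(d**4, axis=1)

    lo = P.min(axis=1)
    hi = P.max(axis=1)
    degenerate = hi == lo  # constant sample: zero-variance conventions apply

    m2_safe = np.where(degenerate, 1.0, m2)
    mean_safe = np.where(mean == 0, 1.0, mean)
    skew = np.where(degenerate, 0.0, m3 / m2_safe**1.5)
    kurt = np.where(degenerate, 0.0, m4 / m2_safe**2 - 3.0)
    sd = np.sqrt(m2)
    cv = np.where(degenerate | (mean == 0), 0.0, sd / mean_safe)
    if np.any((mean == 0) & ~degenerate):
        logger.warning("CV undefined for zero-mean sample; reported as 0 by convention")

    # entropy of a 16-bin histogram over each row's own range
    entropy = np.zeros(n, dtype=float)
    live = ~degenerate
    if np.any(live):
        Pl = P[live]
        rng = (hi[live] - lo[live])[:, None]
        bins = np.floor((Pl - lo[live][:, None]) / rng * ENTROPY_BINS).astype(np.intp)
        np.clip(bins, 0, ENTROPY_BINS - 1, out=bins)
        offsets = np.arange(bins.shape[0], dtype=np.intp)[:, None] * ENTROPY_BINS
        counts = np.bincount(
            (bins + offsets).ravel(), minlength=bins.shape[0] * ENTROPY_BINS
        ).reshape(bins.shape[0], ENTROPY_BINS)
        p = counts / k
        logp = np.log2(p, out=np.zeros_like(p), where=p > 0)
        entropy[live] = -(p * logp).sum(axis=1)

    out[:, 0] = mean
    out[:, 1] = med
    out[:, 2] = skew
    out[:, 3] = kurt
    out[:, 4] = q75 - q25
    out[:, 5] = cv
    out[:, 6] = entropy
    return out


def local_first_order_stats(patch: np.ndarray) -> np.ndarray:
    """Seven first-order statistics of one sample (any shape, flattened).

    Order: mean, median, skewness, kurtosis, IQR, CV, entropy.
    """
    values = np.asarray(patch, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("empty patch")
    return _batch_first_order(values[None, :])[0]


# ---------------------------------------------------------------------------
# patch sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalStatMaps:
    """Per-voxel local statistics at every in-mask voxel.

    ``values[i, j]`` is statistic ``stat_names[j]`` at voxel ``coords[i]``
    (coords are ``(slice, row, col)`` in ``np.argwhere`` order).
    """

    values: np.ndarray  # (n_voxels, 7)
    coords: np.ndarray  # (n_voxels, 3)
    stat_names: tuple[str, ...] = LOCAL_NAMES

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.stat_names.index(name)]


def sweep_patches(volume: lio.ImageVolume, mask: lio.LesionMask, side: int) -> LocalStatMaps:
    """Compute the 7 local statistics for every in-mask voxel.

    The window is the ``side x side`` in-slice square centered on the voxel,
    truncated at image borders and not restricted to the mask.
    """
    lio.check_congruent(volume, mask)
    if side < 3 or side % 2 == 0:
        raise ConfigurationError(f"window side must be odd and >= 3, got {side}")
    coords = np.argwhere(mask.voxels > 0)
    if coords.shape[0] == 0:
        raise ValidationError("empty mask")

    h = side // 2
    n_slices, n_rows, n_cols = volume.shape
    values = np.empty((coords.shape[0], N_LOCAL), dtype=float)

    interior = (
        (coords[:, 1] >= h)
        & (coords[:, 1] < n_rows - h)
        & (coords[:, 2] >= h)
        & (coords[:, 2] < n_cols - h)
        & (n_rows >= side)
        & (n_cols >= side)
    )

    # full windows: gathered per slice via a sliding-window view
    idx_interior = np.flatnonzero(interior)
    if idx_interior.size:
        for z in np.unique(coords[idx_interior, 0]):
            sel = idx_interior[coords[idx_interior, 0] == z]
            windows = sliding_window_view(volume.voxels[z], (side, side))
            rows = coords[sel, 1] - h
            cols = coords[sel, 2] - h
            patches = windows[rows, cols].reshape(sel.size, side * side)
            values[sel] = _batch_first_order(patches)

    # truncated windows at borders, one by one
    for i in np.flatnonzero(~interior):
        z, r, c = coords[i]
        patch = volume.voxels[
            z,
            max(r - h, 0): min(r + h + 1, n_rows),
            max(c - h, 0): min(c + h + 1, n_cols),
        ]
        values[i] = _batch_first_order(patch.reshape(1, -1))[0]

    return LocalStatMaps(values=values, coords=coords)


# ---------------------------------------------------------------------------
# global summaries
# ---------------------------------------------------------------------------

def _global_summaries(values: np.ndarray) -> np.ndarray:
    """Twelve global summaries of a pooled local-statistic distribution.

    Order matches :data:`GLOBAL_CODES`: mean, median, skewness, kurtosis,
    IQR, CV, entropy, max, population SD, median absolute deviation, and
    mean/median of the last decile (values >= the 90th percentile).
    """
    first7 = _batch_first_order(values[None, :])[0]
    med = first7[1]
    sd = values.std(ddof=0)
    mad = float(np.median(np.abs(values - med)))
    q90 = np.quantile(values, 0.9)
    top = values[values >= q90]
    return np.concatenate([
        first7,
        [values.max(), sd, mad, top.mean(), float(np.median(top))],
    ])


@dataclass(frozen=True)
class FeatureVector:
    """The 84 named radiomic features of one patient."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValidationError("feature names and values differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names are not unique")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def summarize_global(maps: LocalStatMaps) -> FeatureVector:
    """Condense the 7 pooled local-statistic distributions into 84 features."""
    if maps.values.shape[0] == 0:
        raise ValidationError("empty local statistic maps")
    blocks = [_global_summaries(maps.values[:, j]) for j in range(N_LOCAL)]
    return FeatureVector(names=FEATURE_NAMES, values=np.concatenate(blocks))


def extract_features(
    volume: lio.ImageVolume,
    mask: lio.LesionMask,
    window_side: int | None = None,
) -> FeatureVector:
    """Full per-patient extraction: window sizing, patch sweep, summaries.

    The window side defaults to :func:`window_side_from_spacing` evaluated at
    the mean in-plane spacing. All lesion voxels of all slices are pooled
    before the global summaries, producing one feature vector per patient.
    """
    if window_side is None:
        spacing = float(np.mean(volume.pixel_spacing_mm))
        window_side = window_side_from_spacing(spacing)
    maps = sweep_patches(volume, mask, window_side)
    return summarize_global(maps)


def extract_cohort_features(
    manifest_path: str | Path, window_side: int | None = None
) -> lio.CohortTable:
    """Extract the 84 features for every patient listed in a cohort manifest."""
    manifest = lio.read_manifest(manifest_path)
    records = []
    for row in manifest.itertuples(index=False):
        volume, mask = lio.read_patient(row.image, row.mask)
        fv = extract_features(volume, mask, window_side=window_side)
        rec = {"patient_id": row.patient_id, "label": int(row.label)}
        rec.update(dict(zip(fv.names, fv.values)))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=["patient_id", "label", *FEATURE_NAMES])
    return lio.CohortTable(df, FEATURE_NAMES)
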