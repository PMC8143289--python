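import numpy as np
import pytest

from locrad.errors import ConfigurationError, ValidationError
from locrad.io import ImageVolume, LesionMask
from locrad.local_radiomics import (
    FEATURE_NAMES,
    extract_features,
    local_first_order_stats,
    summarize_global,
    sweep_patches,
    window_side_from_spacing,
)

from _reference import naive_local_stats, naive_sweep

STAT = {"mean": 0, "median": 1, "skew": 2, "kurt": 3, "iqr": 4, "cv": 5, "entropy": 6}


@pytest.mark.parametrize(
    "spacing, side",
    [(1.41, 7), (1.67, 5), (5.0, 3), (1.0, 11), (2.4, 5)],
)
def test_window_side_from_spacing(spacing, side):
    """Side covers >= 5 mm from the center per direction, clamped to >= 3."""
    assert window_side_from_spacing(spacing) == side


@pytest.mark.parametrize("bad", [0.0, -1.5])
def test_window_side_rejects_nonpositive_spacing(bad):
    with pytest.raises(ConfigurationError):
        window_side_from_spacing(bad)


def test_local_stats_constant_patch():
    """Zero-variance samples follow the degenerate conventions."""
    got = local_first_order_stats(np.full(25, 7.5))
    assert np.array_equal(got, [7.5, 7.5, 0.0, 0.0, 0.0, 0.0, 0.0])


def test_local_stats_one_to_nine():
    """Hand-checked values for the sample {1..9}."""
    got = local_first_order_stats(np.arange(1.0, 10.0))
    # population moments: m2 = 60/9, m4 = 708/9; 9 distinct values fill
    # 9 of 16 equal-width bins, one point each
    assert got[STAT["mean"]] == 5.0
    assert got[STAT["median"]] == 5.0
    assert got[STAT["skew"]] == 0.0
    assert got[STAT["kurt"]] == pytest.approx((708 / 9) / (60 / 9) ** 2 - 3, abs=1e-12)
    assert got[STAT["iqr"]] == 4.0
    assert got[STAT["cv"]] == pytest.approx(np.sqrt(60 / 9) / 5, abs=1e-12)
    assert got[STAT["entropy"]] == pytest.approx(np.log2(9), abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_local_stats_match_scipy_reference(seed):
    patch = np.random.default_rng(seed).normal(50, 12, size=49)
    got = local_first_order_stats(patch)
    want = naive_local_stats(patch)
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


def test_local_stats_rejects_empty():
    with pytest.raises(ValidationError):
        local_first_order_stats(np.array([]))


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

def _volume(vox):
    return ImageVolume(voxels=vox, pixel_spacing_mm=(1.5, 1.5), slice_thickness_mm=3.0)


def test_sweep_single_voxel_mask(rng):
    vox = rng.normal(size=(1, 9, 9))
    mask = np.zeros_like(vox)
    mask[0, 4, 4] = 1
    maps = sweep_patches(_volume(vox), LesionMask(mask), side=5)
    assert maps.values.shape == (1, 7)
    np.testing.assert_allclose(
        maps.values[0], naive_local_stats(vox[0, 2:7, 2:7]), rtol=1e-10
    )


def test_sweep_constant_image():
    vox = np.full((2, 8, 8), 3.0)
    mask = np.zeros_like(vox)
    mask[:, 2:5, 2:5] = 1
    maps = sweep_patches(_volume(vox), LesionMask(mask), side=3)
    assert np.all(maps.values[:, 0] == 3.0)
    assert np.all(maps.values[:, 2:] == 0.0)


def test_sweep_planted_block_matches_naive():
    """Bright 3x3 block on an 11x11 slice, side 5, versus the double loop."""
    vox = np.zeros((1, 11, 11))
    vox[0] = np.random.default_rng(3).normal(10, 1, (11, 11))
    vox[0, 4:7, 4:7] += 50.0
    mask = np.ones_like(vox)
    maps = sweep_patches(_volume(vox), LesionMask(mask), side=5)
    want = naive_sweep(vox, mask, side=5)
    for i, (z, r, c) in enumerate(maps.coords):
        np.testing.assert_allclose(
            maps.values[i], want[(z, r, c)], rtol=1e-10, atol=1e-12,
            err_msg=f"voxel ({z},{r},{c})",
        )


def test_sweep_rejects_empty_mask_and_bad_side(toy_volume):
    vol, mask = toy_volume
    with pytest.raises(ValidationError):
        sweep_patches(vol, LesionMask(np.zeros(vol.shape)), side=5)
    with pytest.raises(ConfigurationError):
        sweep_patches(vol, mask, side=4)


# ---------------------------------------------------------------------------
# global summaries
# ---------------------------------------------------------------------------

def test_summarize_yields_84_named_features(toy_volume):
    vol, mask = toy_volume
    fv = summarize_global(sweep_patches(vol, mask, side=5))
    assert fv.names == FEATURE_NAMES
    assert len(fv.values) == 84
    assert np.all(np.isfinite(fv.values))
    for name in ("M_CV", "k_iqr", "m_sigma", "s_M90th"):
        assert name in fv.names


def test_summarize_constant_maps():
    vox = np.full((1, 9, 9), 4.0)
    mask = np.ones_like(vox)
    fv = summarize_global(sweep_patches(_volume(vox), LesionMask(mask), side=3))
    # the local mean map is constant 4: max = mean = median; spreads vanish
    assert fv["m_max"] == fv["m_mean"] == fv["m_M"] == 4.0
    assert fv["m_sigma"] == fv["m_iqr"] == fv["m_mad"] == 0.0


def test_last_decile_of_20_values():
    """With 20 distinct values the last decile is exactly the top two."""
    from locrad.local_radiomics import _global_summaries

    values = np.random.default_rng(9).permutation(np.linspace(3.0, 60.0, 20))
    out = _global_summaries(values)
    top2 = np.sort(values)[-2:]
    idx = {code: i for i, code in enumerate(
        ("mean", "M", "s", "k", "iqr", "CV", "e", "max", "sigma", "mad", "m90th", "M90th"))}
    assert out[idx["m90th"]] == pytest.approx(top2.mean(), abs=1e-12)
    assert out[idx["M90th"]] == pytest.approx(np.median(top2), abs=1e-12)
    assert out[idx["max"]] == values.max()


# ---------------------------------------------------------------------------
# extraction composition
# ---------------------------------------------------------------------------

def test_extract_deterministic_and_translation_invariant(rng):
    vox = rng.normal(100, 15, size=(3, 20, 20))
    mask = np.zeros_like(vox)
    mask[1, 8:12, 8:12] = 1
    vol = _volume(vox)
    fv1 = extract_features(vol, LesionMask(mask))
    fv2 = extract_features(vol, LesionMask(mask))
    assert np.array_equal(fv1.values, fv2.values)

    # integer translation away from borders leaves every feature unchanged
    vox_t = np.roll(vox, shift=(2, -3), axis=(1, 2))
    mask_t = np.roll(mask, shift=(2, -3), axis=(1, 2))
    fv3 = extract_features(_volume(vox_t), LesionMask(mask_t))
    assert np.array_equal(fv1.values, fv3.values)


def test_intensity_shift_property(toy_volume):
    """+c shifts location features by c, fixes spreads, lowers CVs."""
    vol, mask = toy_volume
    c = 37.0
    base = extract_features(vol, mask, window_side=5)
    shifted = extract_features(
        ImageVolume(vol.voxels + c, vol.pixel_spacing_mm, vol.slice_thickness_mm),
        mask,
        window_side=5,
    )
    for glob in ("mean", "M", "max", "m90th", "M90th"):
        for loc in ("m", "M"):
            assert shifted[f"{loc}_{glob}"] == pytest.approx(base[f"{loc}_{glob}"] + c, abs=1e-9)
    for name in ("m_sigma", "m_iqr", "m_mad", "M_sigma", "iqr_mean", "s_mean", "k_mean"):
        assert shifted[name] == pytest.approx(base[name], abs=1e-9)
    assert shifted["m_CV"] < base["m_CV"]
    assert shifted["cv_mean"] < base["cv_mean"]


def test_monotone_heterogeneity_response():
    """Expected m_sigma rises strictly with the planted heterogeneity."""
    from scipy.stats import spearmanr

    from locrad.synthetic_cohort import CohortConfig, generate_cohort

    levels = [0.0, 10.0, 20.0, 30.0, 40.0]
    mean_feature = []
    for h in levels:
        vals = []
        for seed in range(8):
            cfg = CohortConfig(
                n_ncs=1, n_cs=1, seed=seed, heterogeneity_effect=h,
                asymmetry_effect=0.0, phenotype_tradeoff=0.0,
            )
            p = generate_cohort(cfg)[1]
            vals.append(extract_features(p.volume, p.mask)["m_sigma"])
        mean_feature.append(np.mean(vals))
    rho = spearmanr(levels, mean_feature).statistic
    assert rho > 0.9
    assert np.all(np.diff(mean_feature) > 0)
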