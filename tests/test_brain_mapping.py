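"""Voxel rank-sum maps, empirical calibration, and region summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mescreen.brain_mapping import (
    BrainStack,
    RegionAtlas,
    calibrate_threshold,
    median_difference,
    region_quantify,
    significance_map,
    stack_group,
    sum_of_slices,
    total_signal,
    voxel_zmap,
)
from mescreen.synthetic import EffectSpec, SimConfig, make_atlas, simulate_brain_cohort


# ---------------------------------------------------------------------------
# independent oracle: per-voxel rank-sum z via scipy's U statistic
# ---------------------------------------------------------------------------

def oracle_ranksum_z(a_vals, b_vals):
    """Tie-corrected rank-sum z for one voxel, without continuity correction.

    U from scipy.stats.mannwhitneyu; tie term from explicit value counts.
    """
    n_a, n_b = len(a_vals), len(b_vals)
    n = n_a + n_b
    u = stats.mannwhitneyu(a_vals, b_vals, alternative="two-sided",
                           method="asymptotic").statistic
    mu = n_a * n_b / 2.0
    _, counts = np.unique(np.concatenate([a_vals, b_vals]), return_counts=True)
    tie = (counts**3 - counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (u - mu) / np.sqrt(var)


def test_zmap_matches_brute_force_oracle_per_voxel():
    rng = np.random.default_rng(21)
    a = rng.normal(size=(4, 5, 5, 4))
    b = rng.normal(size=(4, 5, 5, 4))
    # inject ties at some voxels to exercise the tie correction
    a[:, 0, 0, 0] = [1.0, 1.0, 2.0, 3.0]
    b[:, 0, 0, 0] = [1.0, 2.0, 2.0, 4.0]
    a[:, 1, 1, 1] = 5.0
    b[:, 1, 1, 1] = 5.0  # fully tied voxel -> z = 0
    z = voxel_zmap(a, b)
    for idx in np.ndindex(*a.shape[1:]):
        expected = oracle_ranksum_z(a[(slice(None),) + idx], b[(slice(None),) + idx])
        assert z[idx] == pytest.approx(expected, abs=1e-10), idx


def test_extreme_configuration_closed_form():
    """All five a-values above all five b-values: |Z| = 12.5/sqrt(275/12)."""
    a = np.arange(10, 15, dtype=float).reshape(5, 1, 1, 1)
    b = np.arange(0, 5, dtype=float).reshape(5, 1, 1, 1)
    z = voxel_zmap(a, b)
    assert z[0, 0, 0] == pytest.approx(12.5 / np.sqrt(5 * 5 * 11 / 12.0))
    assert z[0, 0, 0] == pytest.approx(2.611, abs=1e-3)


def test_group_swap_antisymmetry():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(5, 3, 4, 2))
    b = rng.normal(size=(6, 3, 4, 2))
    np.testing.assert_allclose(voxel_zmap(a, b), -voxel_zmap(b, a), atol=1e-12)


def test_same_groups_relabeled_give_zero_z():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 2, 2, 2))
    z = voxel_zmap(x, x)  # every voxel fully tied across the two groups
    # with identical samples the rank sums are equal, z == 0 everywhere
    np.testing.assert_allclose(z, 0.0, atol=1e-12)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        voxel_zmap(np.zeros((3, 2, 2, 2)), np.zeros((3, 2, 2, 3)))


def test_minimum_group_size_enforced():
    with pytest.raises(ValueError, match="at least 2"):
        voxel_zmap(np.zeros((1, 2, 2, 2)), np.zeros((3, 2, 2, 2)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_target_half_threshold_is_pooled_median():
    rng = np.random.default_rng(5)
    controls = rng.normal(size=(8, 4, 8, 8))
    cal = calibrate_threshold(controls, target_fraction=0.5, n_splits=10, seed=0)
    # reproduce the pooled |z| sample with the same seed stream
    cal2 = calibrate_threshold(controls, target_fraction=0.5, n_splits=10, seed=0)
    assert cal.z_threshold == cal2.z_threshold
    assert 0.0 < cal.z_threshold < 1.5  # median of null |Z| is well below 1.5


def test_target_fraction_boundaries_rejected():
    controls = np.random.default_rng(0).normal(size=(6, 2, 4, 4))
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            calibrate_threshold(controls, target_fraction=bad)


def test_too_few_controls_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        calibrate_threshold(np.zeros((3, 2, 2, 2)))


def test_threshold_stability_under_more_splits():
    """Doubling the split count moves the threshold by less than the
    split-to-split spread of single-split thresholds."""
    rng = np.random.default_rng(8)
    controls = rng.normal(size=(12, 8, 16, 16))
    t20 = calibrate_threshold(controls, 0.01, n_splits=20, seed=1).z_threshold
    t40 = calibrate_threshold(controls, 0.01, n_splits=40, seed=2).z_threshold
    singles = [
        calibrate_threshold(controls, 0.01, n_splits=1, seed=100 + k).z_threshold
        for k in range(10)
    ]
    assert abs(t40 - t20) <= max(np.std(singles), 1e-6) * 3


def test_calibration_deterministic_under_seed():
    rng = np.random.default_rng(9)
    controls = rng.normal(size=(8, 4, 8, 8))
    c1 = calibrate_threshold(controls, 0.01, n_splits=5, seed=42)
    c2 = calibrate_threshold(controls, 0.01, n_splits=5, seed=42)
    assert c1 == c2


# ---------------------------------------------------------------------------
# significance maps
# ---------------------------------------------------------------------------

def test_infinite_threshold_blanks_map():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(3, 4, 5))
    sig = significance_map(z, z.copy(), np.inf)
    assert not sig.any()


def test_signed_effect_passes_through_threshold():
    z = np.zeros((2, 2, 2))
    z[0, 0, 0] = 5.0
    z[1, 1, 1] = -5.0
    effect = np.full((2, 2, 2), 9.0)
    effect[1, 1, 1] = -4.0
    sig = significance_map(z, effect, 3.0)
    assert sig[0, 0, 0] == 9.0
    assert sig[1, 1, 1] == -4.0
    assert (sig != 0).sum() == 2


def test_significance_map_group_swap_antisymmetry():
    rng = np.random.default_rng(13)
    a = rng.normal(size=(5, 3, 4, 4))
    b = rng.normal(size=(5, 3, 4, 4))
    thr = 1.0
    sig_ab = significance_map(voxel_zmap(a, b), median_difference(a, b), thr)
    sig_ba = significance_map(voxel_zmap(b, a), median_difference(b, a), thr)
    np.testing.assert_allclose(sig_ab, -sig_ba, atol=1e-12)


# ---------------------------------------------------------------------------
# region quantification and projections
# ---------------------------------------------------------------------------

def test_uniform_region_value_independent_of_size(small_atlas):
    sig = np.zeros(small_atlas.labels.shape)
    sig[small_atlas.mask(1)] = 7.0
    sig[small_atlas.mask(2)] = 7.0
    rq = region_quantify(sig, small_atlas).set_index("region")
    assert rq.loc[1, "increased"] == pytest.approx(7.0)
    assert rq.loc[2, "increased"] == pytest.approx(7.0)
    assert rq.loc[1, "decreased"] == 0.0


def test_half_region_value_averages_down(small_atlas):
    mask = small_atlas.mask(3)
    coords = np.argwhere(mask)
    half = coords[: len(coords) // 2]
    sig = np.zeros(small_atlas.labels.shape)
    sig[tuple(half.T)] = 4.0
    rq = region_quantify(sig, small_atlas).set_index("region")
    expected = 4.0 * len(half) / mask.sum()
    assert rq.loc[3, "increased"] == pytest.approx(expected)
    assert expected == pytest.approx(2.0, abs=4.0 / mask.sum())


def test_all_zero_map_zero_summaries(small_atlas):
    rq = region_quantify(np.zeros(small_atlas.labels.shape), small_atlas)
    assert (rq["increased"] == 0).all() and (rq["decreased"] == 0).all()


def test_total_signal_hand_sum():
    sig = np.zeros((2, 3, 3))
    sig[0, 0, :3] = 2.0     # +2 at 3 voxels
    sig[1, 1, :2] = -1.0    # -1 at 4 voxels
    sig[1, 2, :2] = -1.0
    assert total_signal(sig) == 10.0
    assert total_signal(-sig) == 10.0
    assert total_signal(np.zeros((2, 2, 2))) == 0.0


def test_projection_single_voxel_and_linearity():
    sig = np.zeros((4, 5, 6))
    sig[2, 3, 1] = 7.0
    pz = sum_of_slices(sig, "z")
    assert pz.shape == (5, 6)
    assert pz[3, 1] == 7.0 and np.count_nonzero(pz) == 1
    rng = np.random.default_rng(4)
    m1, m2 = rng.normal(size=(2, 4, 5, 6))
    np.testing.assert_allclose(
        sum_of_slices(m1 + m2, "x"), sum_of_slices(m1, "x") + sum_of_slices(m2, "x"),
        atol=1e-12,
    )


def test_projection_conserves_signed_total():
    rng = np.random.default_rng(6)
    sig = rng.normal(size=(4, 5, 6))
    assert sum_of_slices(sig, "z").sum() == pytest.approx(sig.sum())


def test_invalid_axis_rejected():
    with pytest.raises(ValueError, match="axis"):
        sum_of_slices(np.zeros((2, 2, 2)), "y")


# ---------------------------------------------------------------------------
# planted-effect recovery and the structure channel
# ---------------------------------------------------------------------------

def _planted_cohort(delta, channel="activity", seed=31, n=10, scale=1.0):
    atlas = make_atlas((6, 16, 16), 4, seed=7)
    cfg = SimConfig(
        n_per_genotype=n, genotypes=("+/+", "-/-"),
        effect_spec=EffectSpec(regional_activity_delta=delta, regional_scale=scale,
                               target_region=2),
        seed=seed,
    )
    stacks, gmap = simulate_brain_cohort(cfg, atlas, channel)
    a = stack_group(stacks, gmap.ids_of("-/-"))
    b = stack_group(stacks, gmap.ids_of("+/+"))
    return atlas, a, b


def test_planted_increase_concentrates_in_target_region():
    atlas, a, b = _planted_cohort(delta=5.0)
    cal = calibrate_threshold(b, 0.0005, n_splits=20, seed=1)
    sig = significance_map(voxel_zmap(a, b), median_difference(a, b), cal)
    nonzero = sig != 0
    assert nonzero.any()
    inside = (nonzero & atlas.mask(2)).sum() / nonzero.sum()
    assert inside >= 0.8
    rq = region_quantify(sig, atlas)
    assert rq.loc[rq["increased"].idxmax(), "region"] == 2


def test_structure_channel_negative_scale_reports_decrease():
    atlas, a, b = _planted_cohort(delta=0.0, channel="structure", scale=0.8)
    cal = calibrate_threshold(b, 0.0005, n_splits=20, seed=2)
    sig = significance_map(voxel_zmap(a, b), median_difference(a, b), cal)
    rq = region_quantify(sig, atlas).set_index("region")
    assert rq.loc[2, "decreased"] > 0
    assert rq.loc[2, "decreased"] > rq.loc[2, "increased"]
    assert rq.loc[2, "decreased"] == rq["decreased"].max()


# ---------------------------------------------------------------------------
# atlas container
# ---------------------------------------------------------------------------

def test_atlas_rejects_empty_named_region():
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0, 0, 0] = 1
    with pytest.raises(ValueError, match="empty"):
        RegionAtlas(labels, names={1: "a", 2: "ghost"})


def test_region_resolution_by_name_and_label(small_atlas):
    lab = small_atlas.region_labels[0]
    assert small_atlas.resolve(small_atlas.names[lab]) == lab
    with pytest.raises(KeyError):
        small_atlas.resolve("not_a_region")


def test_stack_container_validation():
    with pytest.raises(ValueError, match="3D"):
        BrainStack(np.zeros((2, 2)), "f0")
    with pytest.raises(ValueError, match="finite"):
        BrainStack(np.full((2, 2, 2), np.nan), "f0")
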