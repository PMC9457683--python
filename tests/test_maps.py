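"""Voxel maps, profiles, resampling inference and FDR."""

import numpy as np
import pandas as pd
import pytest

from fpvs.maps import (ap_profile, bh_fdr, bootstrap_ci,
                       bootstrap_proportion_p, match_threshold,
                       permutation_test, proportion_contrast_index,
                       split_half_profile_ci, voxel_map, winsorized_mean)


def contact_frame(x, y, z=None):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame({
        "tal_x": x, "tal_y": np.asarray(y, dtype=float),
        "tal_z": np.zeros_like(x) if z is None else np.asarray(z),
    })


class TestWinsorizedMean:
    def test_constant_sample(self):
        assert winsorized_mean([3.0] * 10) == 3.0

    def test_hand_worked_example(self):
        # 0 -> 2 and 1000 -> 9: mean 55/10
        vals = [0, 2, 3, 4, 5, 6, 7, 8, 9, 1000]
        assert winsorized_mean(vals, 0.10) == pytest.approx(5.5)

    def test_zero_fraction_is_plain_mean(self, rng):
        v = rng.standard_normal(50)
        assert winsorized_mean(v, 0.0) == pytest.approx(v.mean())

    def test_small_samples_untouched(self):
        assert winsorized_mean([1, 2, 100], 0.10) == pytest.approx(103 / 3)

    def test_matches_brute_force(self, rng):
        for _ in range(300):
            n = rng.integers(5, 40)
            v = rng.standard_normal(n)
            k = int(round(0.1 * n))
            s = np.sort(v)
            if k:
                s[:k] = s[k]
                s[-k:] = s[-k - 1]
            assert winsorized_mean(v) == pytest.approx(s.mean())


class TestVoxelMap:
    def test_lone_significant_contact(self):
        df = contact_frame([0.0], [0.0])
        grid = voxel_map(df, [True])
        assert (grid.table["proportion"] == 1.0).all()

    def test_interior_contact_covered_by_16_xy_voxels(self):
        df = contact_frame([0.5], [0.5])
        grid = voxel_map(df, [True])
        assert len(grid.table) == 16  # 4 x-windows x 4 y-windows

    def test_grid_geometry_defaults(self):
        grid = voxel_map(contact_frame([0.0], [0.0]), [False])
        assert grid.size == (12.0, 12.0, 100.0)
        assert grid.step == (3.0, 3.0, 100.0)

    def test_proportions_in_unit_interval(self, rng):
        df = contact_frame(rng.uniform(-40, 40, 200),
                           rng.uniform(-70, -10, 200))
        grid = voxel_map(df, rng.random(200) < 0.3)
        p = grid.table["proportion"]
        assert ((p >= 0) & (p <= 1)).all()
        assert (grid.table["proportion"]
                == grid.table["n_significant"]
                / grid.table["n_recorded"]).all()

    def test_amplitude_mode_uses_winsorized_mean(self, rng):
        df = contact_frame(np.zeros(20), np.zeros(20))
        v = rng.standard_normal(20)
        grid = voxel_map(df, v, mode="amplitude")
        assert grid.table["amplitude"].iloc[0] == pytest.approx(
            winsorized_mean(v))


class TestBootstrapProportionP:
    def test_all_significant(self):
        assert bootstrap_proportion_p([True] * 5) == 0.0

    def test_none_significant(self):
        assert bootstrap_proportion_p([False] * 5) == 1.0

    def test_half_significant_matches_binomial(self):
        # P(resample of 2 has zero significant) = 0.5^2 = 0.25
        p = bootstrap_proportion_p([True, False], B=2000, seed=4)
        assert p == pytest.approx(0.25, abs=0.03)


class TestAPProfile:
    def test_flat_flags_give_flat_profile(self, rng):
        df = contact_frame(np.zeros(500), rng.uniform(-70, -10, 500))
        prof = ap_profile(df, np.ones(500) * 0.4)
        assert np.allclose(prof.values, 0.4)

    def test_normalized_profile_zero_mean_unit_sd(self, rng):
        df = contact_frame(np.zeros(300), rng.uniform(-70, -10, 300))
        prof = ap_profile(df, rng.random(300), normalize=True)
        assert prof.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.values.std() == pytest.approx(1.0)

    def test_monotone_gradient_gives_monotone_profile(self, rng):
        y = rng.uniform(-70, -10, 2000)
        df = contact_frame(np.zeros_like(y), y)
        prof = ap_profile(df, -y)  # strictly decreasing in y
        assert np.all(np.diff(prof.values) < 0)


class TestProportionContrast:
    @pytest.mark.parametrize("p_lf,p_hf,expected", [
        (0.2, 0.2, 0.0), (0.3, 0.0, 1.0), (0.3, 0.1, 0.5),
    ])
    def test_values(self, p_lf, p_hf, expected):
        assert proportion_contrast_index(p_lf, p_hf) == pytest.approx(
            expected)

    def test_undefined_at_zero(self):
        with pytest.raises(ValueError):
            proportion_contrast_index(0.0, 0.0)


class TestMatchThreshold:
    def test_enumerated_example(self):
        assert match_threshold([1, 2, 3, 4, 5], 2) == 3.0

    def test_n_zero_returns_max(self):
        assert match_threshold([1, 2, 3], 0) == 3.0

    def test_full_count_just_below_min(self):
        z = [1.0, 2.0, 3.0]
        t = match_threshold(z, 3)
        assert t < 1.0 and np.sum(np.array(z) > t) == 3

    def test_matches_brute_force(self, rng):
        for _ in range(300):
            z = rng.standard_normal(rng.integers(3, 30))
            n = int(rng.integers(0, len(z) + 1))
            t = match_threshold(z, n)
            assert int((z > t).sum()) == n  # continuous z: no ties


class TestPermutationTest:
    def test_identical_groups(self, rng):
        a = rng.standard_normal(10)
        p = permutation_test(a, a.copy(), B=500, seed=0)
        assert p > 0.5

    def test_label_swap_symmetry(self, rng):
        a, b = rng.standard_normal((2, 12))
        p1 = permutation_test(a, b, B=2000, seed=1)
        p2 = permutation_test(b, a, B=2000, seed=1)
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_fully_separated_groups(self):
        a = np.arange(8) + 100.0
        b = np.arange(8.0)
        assert permutation_test(a, b, B=10000, seed=2) < 0.01

    def test_paired_variant(self, rng):
        a = rng.standard_normal(15)
        p = permutation_test(a + 5.0, a, B=2000, seed=3, paired=True)
        assert p < 0.01


class TestBHFDR:
    def test_hand_step_up_all_rejected(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).all()

    def test_all_ones_none_rejected(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    def test_hand_step_up_partial(self):
        flags = bh_fdr([0.001, 0.5])
        assert flags.tolist() == [True, False]

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(300):
            p = rng.random(rng.integers(1, 25))
            n = len(p)
            order = np.argsort(p)
            thresh = 0.05 * (np.arange(1, n + 1)) / n
            passed = np.flatnonzero(p[order] <= thresh)
            expected = np.zeros(n, dtype=bool)
            if passed.size:
                expected[order[:passed.max() + 1]] = True
            assert np.array_equal(bh_fdr(p), expected)


class TestBootstrapCI:
    def test_constant_values(self):
        lo, hi = bootstrap_ci([2.0] * 20)
        assert lo == hi == 2.0

    def test_level_zero_degenerates_to_point(self, rng):
        v = rng.standard_normal(30)
        lo, hi = bootstrap_ci(v, level=0.0, B=200)
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_coverage_of_normal_mean(self, rng):
        hits = 0
        for i in range(40):
            v = rng.standard_normal(400)
            lo, hi = bootstrap_ci(v, B=400, level=0.99, seed=i)
            hits += lo <= 0.0 <= hi
        assert hits >= 36  # >= 90% empirical coverage at 99% nominal


class TestSplitHalf:
    def test_shared_gradient_between_within_overlap(self, rng):
        """LF and HF sharing the same spatial profile: between-signal
        split-half correlations overlap the within-signal ones."""
        n = 800
        y = rng.uniform(-70, -10, n)
        profile = np.exp((y + 70) / -30.0) * 10
        df = pd.DataFrame({
            "tal_y": y,
            "z_lf": profile + rng.standard_normal(n),
            "z_hf": profile + rng.standard_normal(n),
        })
        out = split_half_profile_ci(df, B=200, seed=7)
        lo_w = min(out["ci_within_lf"][0], out["ci_within_hf"][0])
        hi_w = max(out["ci_within_lf"][1], out["ci_within_hf"][1])
        lo_b, hi_b = out["ci_between"]
        assert lo_b <= hi_w and lo_w <= hi_b  # intervals overlap
        assert np.median(out["r_between"]) > 0.8

    def test_single_split_degenerate(self, rng):
        df = pd.DataFrame({
            "tal_y": rng.uniform(-70, -10, 100),
            "z_lf": rng.standard_normal(100),
            "z_hf": rng.standard_normal(100),
        })
        out = split_half_profile_ci(df, B=1, seed=0)
        assert out["n_splits_used"] <= 1
        assert np.isnan(out["ci_between"][0]) or out["n_splits_used"] == 1
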