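"""Comparison battery: median/IQR, screening tests, KW, Dunn, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import inactigraphy as ig
from inactigraphy.comparison import dunn_posthoc, kruskal_wallis


class TestMedianIqr:
    @pytest.mark.parametrize("values,expected", [
        ([5], (5, 5, 5)),
        ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
        ([1, 2, 3], (2, 1.5, 2.5)),
    ])
    def test_linear_interpolation_convention(self, values, expected):
        assert ig.median_iqr(values) == pytest.approx(expected)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ig.median_iqr([])


class TestNormalityCheck:
    def test_level_under_normal_data(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=500)
            if not ig.normality_check(x).normal:
                rejections += 1
        assert 0.005 <= rejections / 200 <= 0.12  # nominal 0.05

    def test_power_against_exponential(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            if not ig.normality_check(x).normal:
                rejections += 1
        assert rejections == 100

    def test_constant_vector_degenerate(self):
        res = ig.normality_check([2.0] * 10)
        assert res.degenerate and not res.normal

    def test_too_small(self):
        with pytest.raises(ValueError):
            ig.normality_check([1.0, 2.0])


class TestVarianceHomogeneity:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        w, p = ig.variance_homogeneity([g, list(g)])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_detects_variance_ratio(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 3, 200)
        _, p = ig.variance_homogeneity([a, b])
        assert p < 0.01

    def test_type_i_rate_equal_variances(self):
        rejections = 0
        n_reps = 500
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(size=40) for _ in range(3)]
            if ig.variance_homogeneity(groups)[1] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            ig.variance_homogeneity([[1.0], [1.0, 2.0]])


def kw_h_oracle(groups):
    """Independent brute-force H: explicit sort-based mid-ranks and the
    direct formula with tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    return h / (1 - tie / (n ** 3 - n))


class TestKruskalWallis:
    def test_worked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2
        assert res.p_value == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_label_permutation_symmetry(self):
        groups = [[1, 5, 3], [2, 2, 9], [7, 4]]
        h1 = kruskal_wallis(groups).H
        h2 = kruskal_wallis([groups[2], groups[0], groups[1]]).H
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_matches_bruteforce_ranker_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            k = int(rng.integers(2, 5))
            groups = [np.round(rng.normal(size=rng.integers(3, 12)), 1)
                      for _ in range(k)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            assert kruskal_wallis(groups).H == \
                pytest.approx(kw_h_oracle(groups), abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            groups = [np.round(rng.normal(size=8), 1) for _ in range(3)]
            mine = kruskal_wallis(groups)
            h, p = stats.kruskal(*groups)
            assert mine.H == pytest.approx(h, abs=1e-9)
            assert mine.p_value == pytest.approx(p, abs=1e-12)

    def test_two_groups_equal_mann_whitney_normal_approx(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = np.round(rng.normal(size=15), 1)
            b = np.round(rng.normal(0.4, 1, size=12), 1)
            kw_p = kruskal_wallis([a, b]).p_value
            mw_p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic",
                                      use_continuity=False).pvalue
            assert kw_p == pytest.approx(mw_p, abs=1e-6)

    def test_all_identical_degenerate(self):
        res = kruskal_wallis([[3, 3], [3, 3, 3]])
        assert res.degenerate
        assert res.H == 0.0
        assert res.p_value == 1.0

    def test_permutation_mode_agrees_roughly(self):
        groups = [[1, 2, 3, 4], [3, 4, 5, 6], [6, 7, 8, 9]]
        p_chi2 = kruskal_wallis(groups).p_value
        p_perm = kruskal_wallis(groups, method="permutation",
                                n_permutations=4000, seed=0).p_value
        assert abs(p_chi2 - p_perm) < 0.05


class TestDunnPosthoc:
    def test_worked_example_extreme_pair(self):
        res = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], adjustment="none")
        extreme = res[(res["group_i"] == 0) & (res["group_j"] == 2)]
        assert extreme["z"].iloc[0] == pytest.approx(-6 / np.sqrt(5), abs=1e-12)
        assert len(res) == 3  # k(k-1)/2

    def test_identical_groups_z_zero(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3]], adjustment="none")
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_holm_smallest_p_times_m(self):
        res = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], adjustment="holm")
        smallest = res.sort_values("p_raw").iloc[0]
        assert smallest["p_adjusted"] == \
            pytest.approx(min(1.0, smallest["p_raw"] * 3))

    def test_holm_monotone_in_raw_p(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(loc, 1, 20) for loc in (0, 0.3, 0.9, 1.4)]
        res = dunn_posthoc(groups, adjustment="holm").sort_values("p_raw")
        assert res["p_adjusted"].is_monotonic_increasing
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-15).all()

    def test_k2_raw_p_equals_kw_p(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = np.round(rng.normal(size=10), 1)
            b = np.round(rng.normal(0.5, 1, size=12), 1)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            kw_p = kruskal_wallis([a, b]).p_value
            dunn_p = dunn_posthoc([a, b], adjustment="none")["p_raw"].iloc[0]
            assert kw_p == pytest.approx(dunn_p, abs=1e-6)


def profiles_for(values_by_level, grouping="gender"):
    rows = []
    pids = []
    i = 0
    for level, values in values_by_level.items():
        for _ in values:
            pid = f"p{i:04d}"
            pids.append(pid)
            rows.append({"participant_id": pid, "gender": level,
                         "age_range": "18-<35", "highest_degree": "master",
                         "employment": "full_time", "use_type": "private_only"})
            i += 1
    profiles = pd.DataFrame(rows)
    values = pd.DataFrame({
        "participant_id": pids,
        "metric": np.concatenate([np.asarray(v, float)
                                  for v in values_by_level.values()]),
    })
    return values, profiles


class TestCompareGroups:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(14)
        values, profiles = profiles_for({
            "female": rng.normal(7.5, 0.9, 80),
            "male": rng.normal(7.0, 0.9, 80),
        })
        res = ig.compare_groups(values, profiles, "gender", "metric")
        assert res.p_value < 0.05
        assert len(res.pairwise) == 1
        assert set(res.summary["level"]) == {"female", "male"}

    def test_excluded_level_dropped(self):
        rng = np.random.default_rng(15)
        values, profiles = profiles_for({
            "female": rng.normal(size=20),
            "male": rng.normal(size=20),
            "excluded": rng.normal(size=5),
        })
        res = ig.compare_groups(values, profiles, "gender", "metric")
        assert set(res.summary["level"]) == {"female", "male"}
        assert int(res.summary["n"].sum()) == 40

    def test_single_level_error(self):
        rng = np.random.default_rng(16)
        values, profiles = profiles_for({"female": rng.normal(size=20)})
        with pytest.raises(ValueError):
            ig.compare_groups(values, profiles, "gender", "metric")

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        n_reps = 400
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            values, profiles = profiles_for({
                "female": rng.normal(size=40),
                "male": rng.normal(size=40),
            })
            res = ig.compare_groups(values, profiles, "gender", "metric")
            if res.p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.09
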