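"""Cluster-normalized histograms, weighted rank test, bootstrap CIs."""

import numpy as np
import pytest
from scipy import stats as sps

from allocomp.redundancy import LigandCluster
from allocomp.weighted_stats import (
    SetVectors,
    bin_width,
    bootstrap_ci,
    cluster_weights,
    compare_descriptor,
    robust_verdict,
    set_vectors,
    weighted_histogram,
    weighted_mean,
    weighted_median,
    weighted_wilcoxon,
)


def _cluster(cid, members, center=None):
    return LigandCluster(
        cluster_id=cid,
        family_id="F",
        member_ligand_ids=tuple(members),
        center_ligand_id=center or members[0],
    )


class TestWeights:
    def test_cluster_of_four(self):
        w = cluster_weights([_cluster("c", ["a", "b", "c", "d"])])
        assert all(v == 0.25 for v in w.values())

    def test_singleton_and_total(self):
        w = cluster_weights([_cluster("c1", ["a", "b"]), _cluster("c2", list("vwxyz"))])
        assert sum(w.values()) == pytest.approx(2.0)
        assert w[("c1", "a")] == 0.5


class TestHistogram:
    def test_one_cluster_masses(self):
        d = weighted_histogram([1, 1, 3], [1 / 3] * 3, "a_don", n_clusters=1)
        assert d.bins == pytest.approx({1: 2 / 3, 3: 1 / 3})

    def test_two_singleton_clusters(self):
        d = weighted_histogram([1, 3], [1.0, 1.0], "a_don", n_clusters=2)
        assert d.bins == {1: 1.0, 3: 1.0}
        assert d.normalized() == {1: 0.5, 3: 0.5}

    def test_continuous_floor_binning(self):
        d = weighted_histogram([3.4214], [1.0], "SlogP", n_clusters=1)
        assert d.bins == {3421: 1.0}
        assert bin_width("SlogP") == 0.001 and bin_width("a_don") == 1.0

    def test_nonfinite_excluded(self):
        d = weighted_histogram([1.0, np.nan, np.inf], [1, 1, 1], "a_don", 3)
        assert d.total_mass == pytest.approx(1.0)


class TestWeightedMedian:
    def test_half_mass_convention(self):
        d = weighted_histogram([1, 3], [0.5, 0.5], "a_don", 1)
        assert weighted_median(d) == 1.0

    def test_equals_plain_median_for_singletons_odd_n(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.integers(0, 30, size=int(rng.integers(3, 40)) * 2 + 1)
            d = weighted_histogram(vals, np.ones(vals.size), "a_don", vals.size)
            assert weighted_median(d) == np.median(vals)

    def test_redundancy_invariance_of_median(self):
        # one cluster of 100 copies of 7 plus a singleton at 9 -> median 7;
        # duplicating the big cluster's members x10 changes nothing
        vals = [7.0] * 100 + [9.0]
        w = [1 / 100] * 100 + [1.0]
        d = weighted_histogram(vals, w, "a_don", 2)
        assert weighted_median(d) == 7
        vals10 = [7.0] * 1000 + [9.0]
        w10 = [1 / 1000] * 1000 + [1.0]
        d10 = weighted_histogram(vals10, w10, "a_don", 2)
        assert weighted_median(d10) == 7

    def test_mean_and_empty(self):
        d = weighted_histogram([1, 3], [1.0, 1.0], "a_don", 2)
        assert weighted_mean(d) == 2.0
        with pytest.raises(ValueError):
            weighted_median(weighted_histogram([], [], "a_don", 0))


class TestWeightedWilcoxon:
    def test_identical_groups(self):
        assert weighted_wilcoxon([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_equal_weights_match_classical_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            na, nb = rng.integers(5, 50, 2)
            a, b = rng.normal(0, 1, na), rng.normal(0.4, 1, nb)
            ours = weighted_wilcoxon(a, np.ones(na), b, np.ones(nb))
            oracle = sps.mannwhitneyu(
                a, b, use_continuity=False, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(ours - oracle) < 1e-9

    def test_equal_weights_match_oracle_with_ties(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            na, nb = rng.integers(5, 40, 2)
            a = rng.integers(0, 5, na).astype(float)
            b = rng.integers(1, 6, nb).astype(float)
            ours = weighted_wilcoxon(a, np.ones(na), b, np.ones(nb))
            oracle = sps.mannwhitneyu(
                a, b, use_continuity=False, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(ours - oracle) < 1e-9

    def test_duplicated_cluster_gives_identical_p(self):
        vals_b, w_b, cl_b = [3.0, 4.0, 1.5], [1, 1, 1], [0, 1, 2]
        vals_a, w_a, cl_a = [1.0, 2.0, 2.5, 5.0], [1, 0.5, 0.5, 1], [0, 1, 1, 2]
        p_ref = weighted_wilcoxon(vals_a, w_a, vals_b, w_b, cl_a, cl_b)
        k = 50
        vals_dup = [1.0] + [2.0, 2.5] * k + [5.0]
        w_dup = [1.0] + [1 / (2 * k)] * (2 * k) + [1.0]
        cl_dup = [0] + [1] * (2 * k) + [2]
        p_dup = weighted_wilcoxon(vals_dup, w_dup, vals_b, w_b, cl_dup, cl_b)
        assert abs(p_ref - p_dup) < 1e-12

    def test_degenerate_and_errors(self):
        assert weighted_wilcoxon([2, 2], [1, 1], [2, 2, 2], [1, 1, 1]) == 1.0
        with pytest.raises(ValueError):
            weighted_wilcoxon([], [], [1], [1])
        with pytest.raises(ValueError):
            weighted_wilcoxon([1], [0.0], [2], [1])


class TestBootstrapCI:
    def test_degenerate_distribution(self):
        d = weighted_histogram([5.0], [1.0], "a_don", 1)
        assert bootstrap_ci(d, "median", 2000, 50, seed=0) == (5.0, 5.0)

    def test_mean_ci_brackets_true_mean(self):
        d = weighted_histogram([0.0, 2.0], [1.0, 1.0], "a_don", 2)
        lo, hi = bootstrap_ci(d, "mean", 4000, 400, seed=1)
        assert lo < 1.0 < hi and hi - lo < 0.5

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(10, 2, 200)
        d = weighted_histogram(vals, np.ones(200), "SlogP", 200)
        a = bootstrap_ci(d, "median", 5000, seed=7)
        b = bootstrap_ci(d, "median", 5000, seed=7)
        c = bootstrap_ci(d, "median", 5000, seed=8)
        assert a == b
        assert a != c

    def test_halving_sample_size_widens_median_ci(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 500)
        d = weighted_histogram(vals, np.ones(500), "SlogP", 500)
        widths = []
        for n in (400, 200, 100, 50):
            lo, hi = bootstrap_ci(d, "median", 20000, n, seed=5)
            widths.append(hi - lo)
        assert widths == sorted(widths)


def _sv(values, cluster_codes=None):
    values = np.asarray(values, dtype=float)
    codes = (
        np.arange(values.size) if cluster_codes is None else np.asarray(cluster_codes)
    )
    return SetVectors(values=values, cluster_codes=codes, is_center=codes >= 0)


class TestCompareDescriptor:
    def test_identical_inputs_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(3, 1, 100)
        r = compare_descriptor("SlogP", _sv(vals), _sv(vals), n_boot=2000, seed=0)
        assert not r.significant_at_level
        assert r.p_value == pytest.approx(1.0)
        assert r.direction == "none"

    def test_shifted_singleton_clusters_detected(self):
        # a_don shifted by +1 in one set, 200 singleton clusters each
        rng = np.random.default_rng(1)
        base = rng.poisson(1.0, 200).astype(float)  # stable median away from a bin edge
        r = compare_descriptor("a_don", _sv(base + 1), _sv(base), n_boot=5000, seed=0)
        assert r.significant_at_level and r.direction == "allo_higher"

    def test_schemes_agree_in_direction_on_shifted_sets(self):
        rng = np.random.default_rng(2)
        a = _sv(rng.normal(1.0, 0.5, 300))
        b = _sv(rng.normal(0.6, 0.5, 300))
        rw = compare_descriptor("SlogP", a, b, scheme="weighted", n_boot=3000, seed=0)
        rc = compare_descriptor("SlogP", a, b, scheme="centers", n_boot=3000, seed=0)
        assert rw.direction == rc.direction == "allo_higher"

    def test_lazy_ci_mode_skips_bootstrap_only_when_insignificant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 50)
        r = compare_descriptor("SlogP", _sv(vals), _sv(vals + 0.01), n_boot=2000,
                               seed=0, ci_mode="lazy")
        assert r.ci95_allo is None and not r.significant_at_level

    def test_set_vectors_builder(self):
        clusters = [_cluster("c1", ["a", "b"]), _cluster("c2", ["c"], center="c")]
        sv = set_vectors(clusters, {"a": 1.0, "b": 2.0, "c": 5.0})
        assert sv.n_clusters == 2
        assert sv.weights.tolist() == [0.5, 0.5, 1.0]
        assert sv.is_center.tolist() == [True, False, True]


class TestRobustVerdict:
    def _result(self, level, sig, direction):
        from allocomp.weighted_stats import ComparisonResult

        return ComparisonResult(
            descriptor_code="a_don", level_label=level, scheme="weighted",
            median_allo=1, median_comp=2, ci95_allo=(1, 1), ci95_comp=(2, 2),
            p_value=1e-6 if sig else 0.5, significant_at_level=sig, direction=direction,
        )

    def test_four_of_four_same_direction(self):
        res = [self._result(l, True, "comp_higher") for l in "ABCD"]
        v = robust_verdict(res)
        assert v.significant_all_levels and v.direction == "comp_higher"

    def test_three_of_four_fails(self):
        res = [self._result(l, l != "D", "comp_higher") for l in "ABCD"]
        assert not robust_verdict(res).significant_all_levels

    def test_mixed_directions_fail(self):
        dirs = ["comp_higher", "comp_higher", "allo_higher", "comp_higher"]
        res = [self._result(l, True, d) for l, d in zip("ABCD", dirs)]
        assert not robust_verdict(res).significant_all_levels

    def test_missing_level_is_error(self):
        res = [self._result(l, True, "comp_higher") for l in "ABC"]
        with pytest.raises(ValueError):
            robust_verdict(res)
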