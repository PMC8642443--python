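"""Repeated-measures F maps, clustering, and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from megalpha.cluster_stats import (
    ClusterResult,
    DesignSpec,
    FMap,
    PermutationConfig,
    cluster_permutation_test,
    form_clusters,
    forming_threshold,
    paired_cluster_test,
    paired_f_map,
    paired_oneway_f_map,
    rm_anova_f_map,
    to_cell_array,
)

DESIGN_2x2x2 = DesignSpec(
    factors=(
        ("time", ("baseline", "post")),
        ("eyes", ("EC", "EO")),
        ("exposure", ("real", "sham")),
    )
)

ALL_EFFECTS = [
    "time",
    "eyes",
    "exposure",
    ("time", "eyes"),
    ("time", "exposure"),
    ("eyes", "exposure"),
    ("time", "eyes", "exposure"),
]


class TestRmAnova:
    def test_constant_data_zero_f(self):
        data = np.full((5, 8, 3), 2.5)
        for effect in ALL_EFFECTS:
            fm = rm_anova_f_map(data, DESIGN_2x2x2, effect)
            np.testing.assert_array_equal(fm.f_values, 0.0)

    def test_single_factor_equals_squared_paired_t(self, rng):
        design = DesignSpec(factors=(("cond", ("a", "b")),))
        data = rng.standard_normal((12, 2, 7))
        fm = rm_anova_f_map(data, design, "cond")
        t = scipy.stats.ttest_rel(data[:, 0, :], data[:, 1, :]).statistic
        assert np.abs(fm.f_values - t**2).max() < 1e-10
        assert (fm.df_effect, fm.df_error) == (1, 11)

    def test_matches_statsmodels_anova_rm(self, rng):
        # independent oracle: statsmodels AnovaRM on the full 2x2x2 design
        from statsmodels.stats.anova import AnovaRM

        data = rng.standard_normal((8, 8, 2))
        rows = []
        for s in range(8):
            for ci, cell in enumerate(DESIGN_2x2x2.cells()):
                rows.append(
                    dict(subject=s, time=cell[0], eyes=cell[1],
                         exposure=cell[2], y=data[s, ci, 0])
                )
        df = pd.DataFrame(rows)
        res = AnovaRM(df, "y", "subject",
                      within=["time", "eyes", "exposure"]).fit()
        table = res.anova_table
        for effect in ALL_EFFECTS:
            fm = rm_anova_f_map(data, DESIGN_2x2x2, effect)
            label = ":".join(effect) if isinstance(effect, tuple) else effect
            assert fm.f_values[0] == pytest.approx(
                table.loc[label, "F Value"], rel=1e-8
            )

    def test_subject_constant_invariance(self, rng):
        data = rng.standard_normal((6, 8, 4))
        shifted = data.copy()
        shifted[2] += 17.3  # add a constant to all of one subject's cells
        for effect in ALL_EFFECTS:
            a = rm_anova_f_map(data, DESIGN_2x2x2, effect)
            b = rm_anova_f_map(shifted, DESIGN_2x2x2, effect)
            np.testing.assert_allclose(a.f_values, b.f_values, rtol=1e-9)

    def test_incomplete_data_rejected(self, rng):
        data = rng.standard_normal((5, 8, 2))
        data[1, 3, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite|incomplete"):
            rm_anova_f_map(data, DESIGN_2x2x2, "time")

    def test_unknown_factor_rejected(self, rng):
        data = rng.standard_normal((5, 8, 2))
        with pytest.raises(ValueError, match="unknown factor"):
            rm_anova_f_map(data, DESIGN_2x2x2, "caffeine")


class TestPairedF:
    def test_identical_conditions_zero(self, rng):
        x = rng.standard_normal((8, 10))
        fm = paired_f_map(x, x.copy())
        np.testing.assert_array_equal(fm.f_values, 0.0)

    def test_equals_textbook_paired_t(self, rng):
        x, y = rng.standard_normal((2, 15, 9))
        fm = paired_f_map(x, y)
        t = scipy.stats.ttest_rel(x, y).statistic
        assert np.abs(fm.f_values - t**2).max() < 1e-10

    def test_zero_residual_separation_flagged_finite(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        y = x + 2.0  # constant offset, zero residual SD
        fm = paired_f_map(x, y)
        assert np.isfinite(fm.f_values).all()
        assert (fm.f_values == np.finfo(float).max).all()

    def test_long_format_wrapper_checks_subjects(self):
        real = pd.DataFrame(
            dict(subject=["a", "b"], sensor=[0, 0], log_power=[1.0, 2.0])
        )
        sham = real.copy()
        sham["subject"] = ["a", "c"]
        with pytest.raises(ValueError, match="subject"):
            paired_oneway_f_map(real, sham)


def bfs_components(mask, adjacency):
    """Brute-force connected-components oracle (breadth-first search)."""
    nodes = [i for i in range(len(mask)) if mask[i]]
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            v = queue.pop(0)
            comp.append(v)
            for w in range(len(mask)):
                if adjacency[v, w] and mask[w] and w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(tuple(sorted(comp)))
    return set(comps)


class TestFormClusters:
    def line_adjacency(self, n):
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_isolated_element(self):
        f = np.array([0.0, 7.0, 0.0])
        clusters = form_clusters(f, 3.0, self.line_adjacency(3))
        assert len(clusters) == 1
        assert clusters[0].members == (1,)
        assert clusters[0].mass == pytest.approx(7.0)

    def test_adjacent_pair_mass_summed(self):
        f = np.array([6.0, 8.0, 0.0])
        clusters = form_clusters(f, 5.0, self.line_adjacency(3))
        assert len(clusters) == 1
        assert clusters[0].members == (0, 1)
        assert clusters[0].mass == pytest.approx(14.0)

    def test_threshold_is_strict(self):
        f = np.array([5.0, 8.0])
        clusters = form_clusters(f, 5.0, self.line_adjacency(2))
        assert clusters[0].members == (1,)  # F == threshold excluded

    def test_empty_supra_threshold_set(self):
        assert form_clusters(np.zeros(4), 1.0, self.line_adjacency(4)) == []

    def test_descending_mass_order(self, adjacency20, rng):
        f = rng.exponential(2.0, size=20)
        clusters = form_clusters(f, 1.5, adjacency20)
        masses = [c.mass for c in clusters]
        assert masses == sorted(masses, reverse=True)

    def test_matches_bfs_oracle_on_random_maps(self, adjacency102, rng):
        for _ in range(200):
            f = rng.exponential(1.0, size=102)
            thr = rng.uniform(0.5, 3.0)
            clusters = form_clusters(f, thr, adjacency102)
            got = {c.members for c in clusters}
            expected = bfs_components(f > thr, adjacency102)
            assert got == expected


def exhaustive_max_mass_p(x, y, adjacency, cluster_alpha=0.05):
    """Exact enumeration oracle for the paired sign-flip cluster test."""
    n = x.shape[0]
    d = x - y
    thr = forming_threshold(1, n - 1, cluster_alpha)

    def f_of(diff):
        m, v = diff.mean(0), diff.var(0, ddof=1)
        f = np.zeros(diff.shape[1])
        ok = v > 0
        f[ok] = n * m[ok] ** 2 / v[ok]
        return f

    observed = form_clusters(f_of(d), thr, adjacency)
    null_max = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        fd = f_of(np.array(signs)[:, None] * d)
        cl = form_clusters(fd, thr, adjacency)
        null_max.append(cl[0].mass if cl else 0.0)
    null_max = np.array(null_max)
    return [
        (c.members, float((null_max >= c.mass).mean())) for c in observed
    ]


class TestPairedClusterTest:
    def test_exhaustive_mode_matches_enumeration_oracle(self, rng):
        adj = np.zeros((6, 6), dtype=bool)
        for i in range(5):
            adj[i, i + 1] = adj[i + 1, i] = True
        x = rng.standard_normal((4, 6)) + np.array([2.0, 2, 0, 0, 0, 0])
        y = rng.standard_normal((4, 6))
        cfg = PermutationConfig(n_permutations=1000, seed=0)  # 2^4 = 16 <= 1000
        clusters = paired_cluster_test(x, y, adj, cfg)
        oracle = dict(exhaustive_max_mass_p(x, y, adj))
        assert len(clusters) == len(oracle)
        for c in clusters:
            assert c.p_monte_carlo == oracle[c.members]  # bit-equal

    def test_p_values_bounded_and_monotone(self, adjacency20, rng):
        x = rng.standard_normal((10, 20)) + 1.2
        y = rng.standard_normal((10, 20))
        cfg = PermutationConfig(n_permutations=200, seed=3)
        clusters = paired_cluster_test(x, y, adjacency20, cfg)
        assert clusters, "expected at least one cluster under a strong effect"
        for c in clusters:
            assert 1 / 201 <= c.p_monte_carlo <= 1.0
        masses = np.array([c.mass for c in clusters])
        ps = np.array([c.p_monte_carlo for c in clusters])
        order = np.argsort(masses)
        assert (np.diff(ps[order]) <= 0).all()

    def test_seed_reproducible(self, adjacency20, rng):
        x = rng.standard_normal((12, 20)) + 0.8
        y = rng.standard_normal((12, 20))
        cfg = PermutationConfig(n_permutations=150, seed=9)
        a = paired_cluster_test(x, y, adjacency20, cfg)
        b = paired_cluster_test(x, y, adjacency20, cfg)
        assert a == b

    def test_strict_percentile_estimator(self, adjacency20, rng):
        x = rng.standard_normal((10, 20)) + 2.0
        y = rng.standard_normal((10, 20))
        cfg_strict = PermutationConfig(n_permutations=100, seed=1,
                                       p_estimator="strict_percentile")
        cfg_addone = PermutationConfig(n_permutations=100, seed=1)
        strict = paired_cluster_test(x, y, adjacency20, cfg_strict)
        addone = paired_cluster_test(x, y, adjacency20, cfg_addone)
        # same null draws: the strict rule only drops the +1 guard, so its p
        # is smaller by exactly that guard and may reach 0
        for s, a in zip(strict, addone):
            assert s.p_monte_carlo < a.p_monte_carlo
            assert s.p_monte_carlo >= 0.0


class TestFactorialClusterTest:
    def make_data(self, rng, n_subj=10, n_elem=20, effect_size=0.0):
        data = rng.standard_normal((n_subj, 8, n_elem))
        # plant an exposure effect on the first 5 elements in post cells
        for ci, cell in enumerate(DESIGN_2x2x2.cells()):
            if cell[0] == "post" and cell[2] == "real":
                data[:, ci, :5] += effect_size
        return data

    def test_main_effect_detects_planted_exposure(self, adjacency20, rng):
        data = self.make_data(rng, effect_size=1.5)
        cfg = PermutationConfig(n_permutations=300, seed=2)
        clusters = cluster_permutation_test(
            data, DESIGN_2x2x2, "exposure", adjacency20, cfg
        )
        assert clusters[0].p_monte_carlo < 0.05
        assert set(clusters[0].members) & set(range(5))

    def test_interaction_cell_permutation_scheme(self, adjacency20, rng):
        data = self.make_data(rng, effect_size=1.5)
        cfg = PermutationConfig(n_permutations=200, seed=4)
        clusters = cluster_permutation_test(
            data, DESIGN_2x2x2, ("time", "exposure"), adjacency20, cfg
        )
        # the planted effect is a time x exposure interaction
        assert clusters and clusters[0].p_monte_carlo < 0.05

    def test_interaction_sign_flip_scheme_agrees_on_detection(self, adjacency20,
                                                              rng):
        data = self.make_data(rng, effect_size=1.5)
        cfg = PermutationConfig(n_permutations=200, seed=4,
                                interaction_scheme="sign_flip")
        clusters = cluster_permutation_test(
            data, DESIGN_2x2x2, ("time", "exposure"), adjacency20, cfg
        )
        assert clusters and clusters[0].p_monte_carlo < 0.05

    def test_null_data_rarely_significant(self, adjacency20, rng):
        cfg = PermutationConfig(n_permutations=200, seed=5)
        n_sig = 0
        for rep in range(20):
            data = rng.standard_normal((10, 8, 20))
            clusters = cluster_permutation_test(
                data, DESIGN_2x2x2, "exposure", adjacency20, cfg
            )
            if clusters and clusters[0].p_monte_carlo < 0.05:
                n_sig += 1
        assert n_sig <= 3

    def test_multi_level_factor_rejected(self, adjacency20, rng):
        design = DesignSpec(factors=(("run", ("r1", "r2", "r3")),))
        data = rng.standard_normal((6, 3, 20))
        with pytest.raises(NotImplementedError):
            cluster_permutation_test(data, design, "run", adjacency20)


class TestToCellArray:
    def test_round_trip(self, rng):
        design = DesignSpec(
            factors=(("eyes", ("EC", "EO")), ("exposure", ("real", "sham")))
        )
        vals = rng.standard_normal((3, 4, 2))
        rows = []
        for si, subj in enumerate(["S1", "S2", "S3"]):
            for ci, cell in enumerate(design.cells()):
                for ei in range(2):
                    rows.append(
                        dict(subject=subj, eyes=cell[0], exposure=cell[1],
                             sensor=ei, log_power=vals[si, ci, ei])
                    )
        df = pd.DataFrame(rows).sample(frac=1, random_state=0)  # shuffle rows
        arr, subjects, elements = to_cell_array(df, design)
        np.testing.assert_allclose(arr, vals)
        assert subjects == ["S1", "S2", "S3"]

    def test_missing_cell_detected(self):
        design = DesignSpec(factors=(("exposure", ("real", "sham")),))
        df = pd.DataFrame(
            dict(subject=["S1", "S1"], exposure=["real", "real"],
                 sensor=[0, 1], log_power=[1.0, 2.0])
        )
        with pytest.raises(ValueError, match="missing|incomplete"):
            to_cell_array(df, design)
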