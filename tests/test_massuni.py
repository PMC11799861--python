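"""F-maps, cluster finding, and the cluster-mass permutation test,
checked against naive independent oracles."""

import numpy as np
import pytest

from cfserp.cluster import (
    FMap,
    cbp_test,
    cluster_table,
    extract_cluster_average,
    find_clusters,
    fmap_from_cells,
    rm_fmap,
)
from cfserp.preproc import ConditionMeans
from cfserp.synth import EXPRESSIONS, MAIN_LEVELS, make_layout


# ---------------------------------------------------------------------------
# naive oracles (deliberately dumb, loop-based)


def naive_twoway_f(Y, effect):
    """Textbook sums of squares for one (channel, time) point; Y is (S, A, B)."""
    S, A, B = Y.shape
    grand = Y.mean()
    if effect in ("a", "b"):
        axis_other = 2 if effect == "a" else 1
        C = Y.mean(axis=axis_other)  # S x K
        K = C.shape[1]
        ss_k = 0.0
        for k in range(K):
            ss_k += S * (C[:, k].mean() - C.mean()) ** 2
        ss_err = 0.0
        for s in range(S):
            for k in range(K):
                ss_err += (
                    C[s, k] - C[s].mean() - C[:, k].mean() + C.mean()
                ) ** 2
        df1, df2 = K - 1, (K - 1) * (S - 1)
        # scale back to the full-data SS (collapsing divides by the other
        # factor's level count; the F ratio is unaffected)
        return (ss_k / df1) / (ss_err / df2), df1, df2
    # interaction
    ss = 0.0
    for a in range(A):
        for b in range(B):
            dev = Y[:, a, b].mean() - Y[:, a, :].mean() - Y[:, :, b].mean() + grand
            ss += S * dev**2
    ss_err = 0.0
    for s in range(S):
        for a in range(A):
            for b in range(B):
                dev = (
                    Y[s, a, b]
                    - Y[:, a, b].mean()
                    - Y[s, a, :].mean()
                    - Y[s, :, b].mean()
                    + Y[:, a, :].mean()
                    + Y[:, :, b].mean()
                    + Y[s].mean()
                    - grand
                )
                ss_err += dev**2
    df1 = (A - 1) * (B - 1)
    df2 = df1 * (S - 1)
    return (ss / df1) / (ss_err / df2), df1, df2


def flood_fill_clusters(supra, adjacency, min_size=2):
    """Iterative region growth over the supra-threshold mask."""
    n_ch, n_t = supra.shape
    visited = np.zeros_like(supra, dtype=bool)
    comps = []
    for ch in range(n_ch):
        for t in range(n_t):
            if not supra[ch, t] or visited[ch, t]:
                continue
            frontier = {(ch, t)}
            comp = set()
            while frontier:
                c, s = frontier.pop()
                if visited[c, s]:
                    continue
                visited[c, s] = True
                comp.add((c, s))
                if s > 0 and supra[c, s - 1]:
                    frontier.add((c, s - 1))
                if s < n_t - 1 and supra[c, s + 1]:
                    frontier.add((c, s + 1))
                for other in range(n_ch):
                    if adjacency[c, other] and supra[other, s]:
                        frontier.add((other, s))
            if len(comp) >= min_size:
                comps.append(frozenset(comp))
    return set(comps)


def random_cells(rng, S=5, A=2, B=3, C=3, T=4):
    return rng.normal(size=(S, A, B, C, T))


EFFECT_MAP = {"expression": "a", "contrast": "b", "interaction": "ab"}


class TestFMap:
    @pytest.mark.parametrize("effect", ["expression", "contrast", "interaction"])
    def test_matches_naive_oracle(self, effect):
        rng = np.random.default_rng(123)
        for _ in range(25):
            Y = random_cells(rng)
            fm = fmap_from_cells(Y, effect)
            for c in range(Y.shape[3]):
                for t in range(Y.shape[4]):
                    want, df1, df2 = naive_twoway_f(
                        Y[:, :, :, c, t], EFFECT_MAP[effect][:2]
                        if effect != "interaction"
                        else "ab",
                    )
                    assert fm.values[c, t] == pytest.approx(want, rel=1e-10)
                    assert (fm.df_effect, fm.df_error) == (df1, df2)

    def test_two_level_effect_equals_squared_t(self):
        rng = np.random.default_rng(7)
        Y = random_cells(rng, S=8)
        fm = fmap_from_cells(Y, "expression")
        diff = Y.mean(2)[:, 0] - Y.mean(2)[:, 1]  # S x C x T
        t = diff.mean(0) / (diff.std(0, ddof=1) / np.sqrt(diff.shape[0]))
        np.testing.assert_allclose(fm.values, t**2, rtol=1e-10)
        assert fm.df_effect == 1 and fm.df_error == 7

    def test_constant_data_gives_zero_f(self):
        Y = np.ones((5, 2, 3, 2, 2))
        fm = fmap_from_cells(Y, "interaction")
        assert np.all(fm.values == 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fmap_from_cells(np.zeros((1, 2, 3, 2, 2)), "expression")
        with pytest.raises(ValueError):
            fmap_from_cells(np.zeros((4, 2, 3, 2, 2)), "nonsense")


def _fmap(values):
    values = np.asarray(values, dtype=float)
    return FMap(
        values=values,
        df_effect=1,
        df_error=10,
        effect="expression",
        times=np.arange(values.shape[1], dtype=float) * 8,
        channel_names=[f"ch{i}" for i in range(values.shape[0])],
    )


class TestFindClusters:
    def test_subthreshold_map_is_empty(self):
        adj = np.zeros((3, 3), dtype=bool)
        assert find_clusters(_fmap(np.ones((3, 5))), 5.0, adj) == []

    def test_two_adjacent_points_mass(self):
        vals = np.zeros((2, 5))
        vals[0, 1], vals[0, 2] = 5.1, 6.2
        adj = np.zeros((2, 2), dtype=bool)
        (cl,) = find_clusters(_fmap(vals), 5.0, adj)
        assert cl.mass == pytest.approx(11.3)
        assert cl.n_points == 2
        assert cl.peak_time == 2 * 8.0

    def test_singletons_discarded(self):
        vals = np.zeros((3, 5))
        vals[1, 3] = 99.0
        adj = np.zeros((3, 3), dtype=bool)
        assert find_clusters(_fmap(vals), 5.0, adj) == []

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            supra = rng.random((6, 10)) < 0.25
            adj = rng.random((6, 6)) < 0.3
            adj = adj | adj.T
            np.fill_diagonal(adj, False)
            vals = np.where(supra, 1.0 + rng.random((6, 10)), 0.0)
            got = {
                frozenset(cl.members)
                for cl in find_clusters(_fmap(vals), 0.5, adj)
            }
            want = flood_fill_clusters(supra, adj)
            assert got == want

    def test_mass_additive_over_disjoint_clusters(self):
        rng = np.random.default_rng(5)
        supra = rng.random((6, 10)) < 0.3
        vals = np.where(supra, 1.0 + rng.random((6, 10)), 0.0)
        adj = np.zeros((6, 6), dtype=bool)
        cls = find_clusters(_fmap(vals), 0.5, adj, min_size=1)
        assert sum(c.mass for c in cls) == pytest.approx(vals[supra].sum())


def _toy_cond_means(Y):
    """Wrap a (S, 2, 3, C, T) cell array as CFS-only ConditionMeans."""
    S, A, B, C, T = Y.shape
    cells = [(e, l, True) for l in MAIN_LEVELS for e in EXPRESSIONS]
    data = np.empty((S, len(cells), C, T))
    for i, (e, l, v) in enumerate(cells):
        data[:, i] = Y[:, EXPRESSIONS.index(e), MAIN_LEVELS.index(l)]
    return ConditionMeans(
        data=data,
        cells=cells,
        times=np.arange(T, dtype=float) * 8,
        sampling_rate=125.0,
        channel_names=[f"ch{i}" for i in range(C)],
    )


class TestCBP:
    def test_window_correction_doubles_p(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(10, 2, 3, 4, 6))
        Y[:, 0, :, :2, :] += 1.5  # expression effect on two channels
        cm = _toy_cond_means(Y)
        adj = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(adj, False)
        one = cbp_test(cm, "expression", True, adj, n_perm=99, n_windows=1, seed=3)
        two = cbp_test(cm, "expression", True, adj, n_perm=99, n_windows=2, seed=3)
        assert one and two
        for c1, c2 in zip(one, two):
            assert c2.p_corrected == pytest.approx(min(1.0, 2 * c1.p_raw))
            assert c1.p_raw == pytest.approx(c2.p_raw)

    def test_estimator_forms(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(8, 2, 3, 3, 5))
        Y[:, 0] += 2.0
        cm = _toy_cond_means(Y)
        adj = np.ones((3, 3), dtype=bool)
        np.fill_diagonal(adj, False)
        a = cbp_test(cm, "expression", True, adj, n_perm=49, seed=1)
        b = cbp_test(cm, "expression", True, adj, n_perm=49, seed=1, estimator="proportion")
        for ca, cb in zip(a, b):
            assert ca.p_raw >= cb.p_raw
            assert ca.p_raw == pytest.approx((1 + cb.p_raw * 49) / 50)

    def test_channel_relabeling_invariance(self):
        """Permutation p-values survive a consistent channel relabeling."""
        rng = np.random.default_rng(17)
        Y = rng.normal(size=(9, 2, 3, 5, 6))
        Y[:, 0, :, 1:3] += 1.2
        g = make_layout(5)
        perm = rng.permutation(5)
        cmA = _toy_cond_means(Y)
        cmB = _toy_cond_means(Y[:, :, :, perm])
        adjA = g.adjacency
        adjB = g.adjacency[np.ix_(perm, perm)]
        a = cbp_test(cmA, "expression", True, adjA, n_perm=99, seed=5)
        b = cbp_test(cmB, "expression", True, adjB, n_perm=99, seed=5)
        assert sorted(round(c.mass, 9) for c in a) == sorted(
            round(c.mass, 9) for c in b
        )
        assert sorted(c.p_raw for c in a) == sorted(c.p_raw for c in b)

    def test_nperm_validation(self):
        cm = _toy_cond_means(np.zeros((4, 2, 3, 2, 2)))
        adj = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            cbp_test(cm, "expression", True, adj, n_perm=0)

    def test_null_false_positive_rate_is_plausible(self):
        """Cheap null check: FWER over 60 small null datasets stays near 5%."""
        rng = np.random.default_rng(23)
        hits = 0
        adj = make_layout(6).adjacency
        for i in range(60):
            Y = rng.normal(size=(10, 2, 3, 6, 8))
            cm = _toy_cond_means(Y)
            cls = cbp_test(cm, "expression", True, adj, n_perm=99,
                           n_windows=1, seed=1000 + i)
            if any(c.p_raw <= 0.05 for c in cls):
                hits += 1
        assert hits <= 9  # P(X > 9 | p=0.05, n=60) < 0.3%


class TestClusterAverages:
    def test_single_point_and_constant(self):
        Y = np.full((4, 2, 3, 3, 4), 2.0)
        cm = _toy_cond_means(Y)
        fm = rm_fmap(cm, "expression", cfs=True)
        from cfserp.cluster import ClusterResult

        cl = ClusterResult(
            channels=np.array([1]), samples=np.array([2]), mass=1.0,
            effect="expression", times=cm.times,
        )
        avg = extract_cluster_average(cm, cl)
        np.testing.assert_allclose(avg, 2.0)
        assert avg.shape == (4, 6)

    def test_hand_built_three_point_mean(self):
        rng = np.random.default_rng(31)
        Y = rng.normal(size=(3, 2, 3, 4, 5))
        cm = _toy_cond_means(Y)
        from cfserp.cluster import ClusterResult

        cl = ClusterResult(
            channels=np.array([0, 0, 1]), samples=np.array([1, 2, 2]),
            mass=1.0, effect="expression", times=cm.times,
        )
        avg = extract_cluster_average(cm, cl)
        want = (cm.data[:, :, 0, 1] + cm.data[:, :, 0, 2] + cm.data[:, :, 1, 2]) / 3
        np.testing.assert_allclose(avg, want, atol=1e-12)

    def test_out_of_extent_raises(self):
        cm = _toy_cond_means(np.zeros((3, 2, 3, 2, 2)))
        from cfserp.cluster import ClusterResult

        cl = ClusterResult(
            channels=np.array([5]), samples=np.array([0]), mass=1.0,
            effect="expression", times=cm.times,
        )
        with pytest.raises(ValueError):
            extract_cluster_average(cm, cl)


def test_cluster_table_columns():
    rng = np.random.default_rng(3)
    Y = rng.normal(size=(8, 2, 3, 3, 5))
    Y[:, 0] += 2.0
    cm = _toy_cond_means(Y)
    adj = np.ones((3, 3), dtype=bool)
    np.fill_diagonal(adj, False)
    tab = cluster_table(cbp_test(cm, "expression", True, adj, n_perm=49, seed=1))
    assert list(tab.columns) == [
        "effect", "mass", "p_raw", "p_corrected",
        "t_start", "t_end", "peak_time", "n_points",
    ]
    assert (tab.mass > 0).all()
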