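"""Clonal analysis: normalization, triple-positivity, TOST, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import isletq as q
from isletq import clones as cl
from isletq.errors import (DegenerateSignalError, InsufficientDataError,
                           InvalidConfigError)

from conftest import make_cell, make_cells

# ---------------------------------------------------------------------------
# Independent TOST oracle.  Deliberately coded along a different route than
# the implementation: the delta-method variance uses a numerical gradient,
# and the one-sided Welch tests go through scipy.stats.ttest_ind_from_stats
# with margin-shifted means rather than hand-built t statistics.


def _oracle_norm_var(means, sds, n):
    means = np.asarray(means, float)
    f = lambda m: m / m.sum() * 100.0
    eps = 1e-6
    var = np.zeros(3)
    for ch in range(3):
        grad = np.zeros(3)
        for k in range(3):
            up, dn = means.copy(), means.copy()
            up[k] += eps
            dn[k] -= eps
            grad[k] = (f(up)[ch] - f(dn)[ch]) / (2 * eps)
        var[ch] = np.sum(grad**2 * np.asarray(sds, float) ** 2 / n)
    return f(means), var


def oracle_tost(cell_a, cell_b, margin, alpha):
    """Textbook TOST: two one-sided Welch t-tests per channel."""
    pa, va = _oracle_norm_var(
        [cell_a[f"{c}_mean"] for c in "rgb"],
        [cell_a[f"{c}_sd"] for c in "rgb"], cell_a["n_pixels"])
    pb, vb = _oracle_norm_var(
        [cell_b[f"{c}_mean"] for c in "rgb"],
        [cell_b[f"{c}_sd"] for c in "rgb"], cell_b["n_pixels"])
    na, nb = cell_a["n_pixels"], cell_b["n_pixels"]
    for ch in range(3):
        if va[ch] + vb[ch] == 0:
            if abs(pa[ch] - pb[ch]) >= margin:
                return False
            continue
        # ttest_ind_from_stats expects per-observation sds; scale back
        sd_a, sd_b = np.sqrt(va[ch] * na), np.sqrt(vb[ch] * nb)
        p_greater = stats.ttest_ind_from_stats(
            pa[ch] + margin, sd_a, na, pb[ch], sd_b, nb,
            equal_var=False, alternative="greater").pvalue
        p_less = stats.ttest_ind_from_stats(
            pa[ch] - margin, sd_a, na, pb[ch], sd_b, nb,
            equal_var=False, alternative="less").pvalue
        if max(p_greater, p_less) >= alpha:
            return False
    return True


# ---------------------------------------------------------------------------


class TestBackgroundAndNormalization:
    def test_background_subtracts_green_blue_only(self):
        cells = make_cells([("a", (30.0, 50.0, 20.0))])
        bg = cl.BackgroundEstimate(10.0, 10.0)
        out = cl.subtract_background(cells, bg)
        assert out.loc[0, "g_mean"] == 40.0
        assert out.loc[0, "b_mean"] == 10.0
        assert out.loc[0, "r_mean"] == 30.0  # red untouched
        assert out.loc[0, "g_sd"] == cells.loc[0, "g_sd"]

    def test_background_clamps_at_zero(self):
        cells = make_cells([("a", (30.0, 5.0, 20.0))])
        out = cl.subtract_background(cells, cl.BackgroundEstimate(10.0, 0.0))
        assert out.loc[0, "g_mean"] == 0.0

    def test_zero_background_is_identity(self):
        cells = make_cells([("a", (30.0, 5.0, 20.0))])
        out = cl.subtract_background(cells, cl.BackgroundEstimate(0.0, 0.0))
        pd.testing.assert_frame_equal(out, cells)

    @pytest.mark.parametrize(
        "means,expected",
        [((2, 1, 1), (50, 25, 25)), ((10, 0, 0), (100, 0, 0))],
    )
    def test_normalization_examples(self, means, expected):
        out = cl.normalize_signature(make_cells([("a", means)]))
        got = tuple(out.loc[0, [f"{c}_pct" for c in "rgb"]])
        assert got == pytest.approx(expected)

    def test_zero_sum_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            cl.normalize_signature(make_cells([("a", (0.0, 0.0, 0.0))]))

    @given(st.tuples(*[st.floats(0, 1e4) for _ in range(3)])
           .filter(lambda m: sum(m) > 1e-6))
    def test_normalization_conserves_100(self, means):
        out = cl.normalize_signature(make_cells([("a", means)]))
        total = sum(out.loc[0, f"{c}_pct"] for c in "rgb")
        assert abs(total - 100.0) < 1e-9


class TestTriplePositive:
    @pytest.mark.parametrize(
        "means,expected",
        [((10, 10, 10), True), ((10, 10, 2), False), ((2.58, 10, 10), False)],
    )
    def test_examples(self, means, expected):
        cells = make_cells([("a", means, (1.0, 1.0, 1.0))])
        assert cl.is_triple_positive(cells).iloc[0] == expected

    def test_zero_channel_false_call_rate_about_one_percent(self):
        """A channel with true mean 0 should almost never test positive.

        C_mean - 2.58 C_sd > 0 with the empirical pixel mean and sd of pure
        noise is far rarer than the nominal two-sided 1% bound behind 2.58.
        """
        rng = np.random.default_rng(1)
        n_pix, reps = 5, 4000
        px = rng.normal(0.0, 3.0, size=(reps, n_pix))
        false_calls = px.mean(axis=1) - cl.TRIPLE_POSITIVE_Z * px.std(axis=1, ddof=1) > 0
        assert false_calls.mean() <= 0.01


class TestTost:
    def test_identical_cells_are_equivalent(self):
        a = make_cell("a", (50, 30, 20), (1, 1, 1), n_pixels=100)
        assert cl.tost_pair(a, a, cl.TostParams(margin_pct=5.0))

    def test_distant_signatures_not_equivalent(self):
        a = make_cell("a", (90, 5, 5), (2, 2, 2))
        b = make_cell("b", (5, 90, 5), (2, 2, 2))
        assert not cl.tost_pair(a, b, cl.TostParams(margin_pct=5.0))

    def test_decision_matches_independent_oracle(self):
        rng = np.random.default_rng(12)
        params = cl.TostParams(margin_pct=10.0, alpha=0.05)
        n_agree = 0
        for i in range(150):
            base = rng.uniform(10, 200, size=3)
            shift = rng.normal(0, rng.uniform(0, 30), size=3)
            a = make_cell("a", base, rng.uniform(1, 25, 3),
                          n_pixels=int(rng.integers(5, 120)))
            b = make_cell("b", np.clip(base + shift, 1, None),
                          rng.uniform(1, 25, 3),
                          n_pixels=int(rng.integers(5, 120)))
            got = cl.tost_pair(a, b, params)
            want = oracle_tost(a, b, params.margin_pct, params.alpha)
            assert got == want, (i, dict(a), dict(b))
            n_agree += got
        assert 0 < n_agree < 150  # both decisions exercised

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(1.0, 30.0),
    )
    def test_symmetry(self, seed, margin):
        rng = np.random.default_rng(seed)
        a = make_cell("a", rng.uniform(5, 150, 3), rng.uniform(0.5, 20, 3),
                      n_pixels=int(rng.integers(4, 90)))
        b = make_cell("b", rng.uniform(5, 150, 3), rng.uniform(0.5, 20, 3),
                      n_pixels=int(rng.integers(4, 90)))
        p = cl.TostParams(margin_pct=margin)
        assert cl.tost_pair(a, b, p) == cl.tost_pair(b, a, p)

    def test_tiny_roi_rejected(self):
        a = make_cell("a", (50, 30, 20), n_pixels=1)
        with pytest.raises(InsufficientDataError):
            cl.tost_pair(a, a, cl.TostParams())


def _random_islet_frame(rng, n_cells):
    rows = []
    for i in range(n_cells):
        rows.append(make_cell(f"c{i}", rng.uniform(5, 120, 3),
                              rng.uniform(0.5, 15, 3),
                              n_pixels=int(rng.integers(5, 80))))
    return make_cells(rows)


def networkx_clone_oracle(cells, params):
    """Brute force: TOST graph + connected components via networkx."""
    import networkx as nx

    tp = cells[cl.is_triple_positive(cells)]
    g = nx.Graph()
    g.add_nodes_from(tp["cell_id"])
    rows = list(tp.iterrows())
    for (_, a), (_, b) in itertools.combinations(rows, 2):
        if cl.tost_pair(a, b, params):
            g.add_edge(a["cell_id"], b["cell_id"])
    return {frozenset(c) for c in nx.connected_components(g)}


class TestClustering:
    def test_transitive_chain_forms_one_clone(self):
        p = cl.TostParams(margin_pct=10.0)
        a = make_cell("A", (40, 30, 30), (1.5, 1.5, 1.5), 60)
        b = make_cell("B", (48, 26, 26), (1.5, 1.5, 1.5), 60)
        c = make_cell("C", (56, 22, 22), (1.5, 1.5, 1.5), 60)
        assert cl.tost_pair(a, b, p) and cl.tost_pair(b, c, p)
        assert not cl.tost_pair(a, c, p)
        cs = cl.cluster_clones(make_cells([a, b, c]), p)
        assert cs.clones == [frozenset({"A", "B", "C"})]

    def test_no_equivalent_pairs_gives_singletons(self):
        p = cl.TostParams(margin_pct=4.0)
        cells = make_cells([
            make_cell("A", (80, 10, 10), (1, 1, 1), 60),
            make_cell("B", (10, 80, 10), (1, 1, 1), 60),
            make_cell("C", (10, 10, 80), (1, 1, 1), 60),
            make_cell("D", (40, 40, 20), (1, 1, 1), 60),
        ])
        cs = cl.cluster_clones(cells, p)
        assert len(cs.clones) == 4 and cs.n_single == 4

    def test_empty_input(self):
        cells = make_cells([]).reindex(columns=make_cell("x", (1, 1, 1)).index)
        cs = cl.cluster_clones(cells, cl.TostParams())
        assert cs.clones == [] and cs.excluded == frozenset()

    def test_non_triple_positive_cells_excluded(self):
        cells = make_cells([
            make_cell("A", (40, 30, 30), (1, 1, 1), 60),
            make_cell("dim", (40, 30, 1.0), (1, 1, 1), 60),
        ])
        cs = cl.cluster_clones(cells, cl.TostParams())
        assert cs.excluded == frozenset({"dim"})
        assert all("dim" not in c for c in cs.clones)

    @pytest.mark.parametrize("seed,n_cells", [(0, 10), (1, 25), (2, 50), (3, 40)])
    def test_matches_bruteforce_oracle(self, seed, n_cells):
        rng = np.random.default_rng(seed)
        cells = _random_islet_frame(rng, n_cells)
        params = cl.TostParams(margin_pct=12.0)
        cs = cl.cluster_clones(cells, params)
        assert set(cs.clones) == networkx_clone_oracle(cells, params)

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_larger_margin_never_splits_clones(self, seed):
        rng = np.random.default_rng(seed)
        cells = _random_islet_frame(rng, 30)
        small = cl.cluster_clones(cells, cl.TostParams(margin_pct=6.0))
        large = cl.cluster_clones(cells, cl.TostParams(margin_pct=18.0))
        for clone in small.clones:
            assert any(clone <= big for big in large.clones)


class TestSummaries:
    def test_summary_percentages(self):
        cs = cl.CloneSet("i", [frozenset("A"), frozenset("B"),
                               frozenset({"C", "D"})])
        s = cl.clonality_summary(cs)
        assert s["pct_single"] == pytest.approx(200 / 3)
        assert s["pct_multi"] == pytest.approx(100 / 3)
        assert s["pct_single"] + s["pct_multi"] == pytest.approx(100.0)

    def test_all_singletons(self):
        cs = cl.CloneSet("i", [frozenset("A"), frozenset("B")])
        s = cl.clonality_summary(cs)
        assert (s["pct_single"], s["pct_multi"]) == (100.0, 0.0)

    def test_size_histogram(self):
        cs = cl.CloneSet("i", [frozenset("A"), frozenset("B"),
                               frozenset({"C", "D"}),
                               frozenset({"E", "F", "G", "H"})])
        assert cl.clonality_summary(cs)["size_histogram"] == {1: 2, 2: 1, 4: 1}

    def test_zero_clones_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            cl.clonality_summary(cl.CloneSet("i", []))


def hypergeom_fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = p_of(a)
    return sum(p_of(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if p_of(x) <= p_obs + 1e-12)


class TestCompareClonality:
    def test_identical_proportions_give_p_one(self):
        assert cl.compare_clonality((10, 10), (10, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [((5, 0), (0, 5)), ((8, 2), (3, 7)),
                                       ((12, 1), (5, 9))])
    def test_matches_hypergeometric_enumeration(self, table):
        got = cl.compare_clonality(*table)
        assert got == pytest.approx(hypergeom_fisher_oracle(table), rel=1e-9)

    def test_all_zero_table_p_one_by_convention(self):
        assert cl.compare_clonality((0, 0), (0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidConfigError):
            cl.compare_clonality((-1, 2), (3, 4))


class TestTernary:
    def test_pure_red_maps_to_red_vertex(self):
        assert cl.ternary_coordinates(100, 0, 0) == pytest.approx(
            tuple(cl.TERNARY_VERTICES["r"]))

    def test_equal_mix_maps_to_centroid(self):
        centroid = np.mean(
            [cl.TERNARY_VERTICES[c] for c in "rgb"], axis=0)
        got = cl.ternary_coordinates(100 / 3, 100 / 3, 100 / 3)
        assert got == pytest.approx(tuple(centroid))

    def test_barycentric_weights(self):
        want = (0.5 * cl.TERNARY_VERTICES["r"] + 0.25 * cl.TERNARY_VERTICES["g"]
                + 0.25 * cl.TERNARY_VERTICES["b"])
        assert cl.ternary_coordinates(50, 25, 25) == pytest.approx(tuple(want))
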