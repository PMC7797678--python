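from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from m6apattern import ExpressionMatrix, GeneSetCollection
from m6apattern.enrichment import (
    bh_adjust,
    estimate_scores,
    ips_score,
    ora_test,
    ssgsea_scores,
)


def expr_from(arr, genes=None, samples=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=genes or [f"G{i}" for i in range(arr.shape[0])],
            columns=samples or [f"S{i}" for i in range(arr.shape[1])],
        )
    )


def brute_force_es(values, members, alpha):
    """Direct positional enumeration of the weighted ECDF difference."""
    n = len(values)
    ranks = rankdata(values)
    order = sorted(range(n), key=lambda i: -values[i])
    in_weights = [ranks[i] ** alpha if i in members else 0.0 for i in order]
    total_in = sum(in_weights)
    n_out = n - len(members)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        cum_in += in_weights[pos]
        cum_out += 0.0 if i in members else 1.0
        es += cum_in / total_in - cum_out / n_out
    return es


class TestSsgsea:
    def test_matches_brute_force_enumeration(self):
        values = [5.0, 3.0, 4.0, 1.0, 2.0]
        mat = expr_from(np.array(values)[:, None])
        sets = GeneSetCollection({"S": ["G1", "G2"]})  # genes at ranks 3 and 4
        es = ssgsea_scores(mat, sets).raw.iloc[0, 0]
        expected = brute_force_es(values, {1, 2}, alpha=0.25)
        assert es == pytest.approx(expected, abs=1e-12)

    def test_top_ranked_set_scores_higher(self):
        # set genes top-ranked in sample 0, bottom-ranked in sample 1
        mat = expr_from([[9, 1], [8, 2], [1, 8], [2, 9], [5, 5]])
        es = ssgsea_scores(mat, GeneSetCollection({"S": ["G0", "G1"]})).raw["S"]
        assert es.iloc[0] > es.iloc[1]

    def test_normalized_scores_span_unit_interval(self, default_cohort):
        scores = ssgsea_scores(
            default_cohort.expression, default_cohort.immune_panels, normalize=True
        ).normalized
        np.testing.assert_allclose(scores.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scores.max(axis=0), 1.0, atol=1e-12)

    def test_recovers_planted_immune_ordering(self, default_cohort):
        c = default_cohort
        es = ssgsea_scores(c.expression, c.immune_panels, normalize=True).normalized
        pat = c.pattern_labels
        for panel in ("CD8_T", "NK"):  # planted hot in pattern 0, cold in 2
            means = es[panel].groupby(pat).mean()
            assert means[0] > means[1] > means[2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=12)
        sets = GeneSetCollection({"S": ["G2", "G5", "G7"]})
        a = ssgsea_scores(expr_from(vals[:, None]), sets).raw.iloc[0, 0]
        b = ssgsea_scores(expr_from(np.exp(vals)[:, None] * 3), sets).raw.iloc[0, 0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_absent_set_and_full_cover_errors(self):
        mat = expr_from([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="no member present"):
            ssgsea_scores(mat, GeneSetCollection({"S": ["NOPE"]}))
        with pytest.raises(ValueError, match="covers every gene"):
            ssgsea_scores(mat, GeneSetCollection({"S": ["G0", "G1"]}))


class TestEstimate:
    def test_purity_closed_form_at_zero_combined(self):
        # cos(0.6049872018) evaluated directly
        from m6apattern.enrichment import _PURITY_A

        assert np.cos(_PURITY_A) == pytest.approx(0.8223, abs=5e-4)

    def test_immune_high_sample_has_low_purity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 1, size=(30, 6))
        X[:10, 0] += 5.0  # sample 0: immune genes maximal
        mat = expr_from(X)
        immune = [f"G{i}" for i in range(10)]
        stromal = [f"G{i}" for i in range(10, 20)]
        res = estimate_scores(mat, stromal, immune).table
        assert res["immune"].idxmax() == "S0"
        assert res["purity"].idxmin() == "S0"

    def test_purity_decreasing_in_combined_score(self, default_cohort):
        panels = default_cohort.immune_panels
        res = estimate_scores(
            default_cohort.expression, panels["Macrophage"], panels["CD8_T"]
        ).table
        ordered = res.sort_values("combined")
        assert (np.diff(ordered["purity"]) <= 1e-12).all()


class TestIps:
    def test_identical_samples_give_zero(self):
        mat = expr_from(np.tile([[3.0], [4.0], [5.0]], (1, 4)))
        panels = GeneSetCollection(
            {"mhc": ["G0"], "ec": ["G1"], "sc": ["G2"]},
            {"mhc": {"ips_class": "MHC"}, "ec": {"ips_class": "EC"},
             "sc": {"ips_class": "SC"}},
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ips_score(mat, panels)
        np.testing.assert_allclose(res.ips.to_numpy(), 0.0)

    def test_effector_upshift_maximizes_ips(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 10))
        X[2:4, 3] += 4.0  # sample 3: EC genes up
        mat = expr_from(X)
        panels = GeneSetCollection(
            {"ec": ["G2", "G3"], "sc": ["G4", "G5"]},
            {"ec": {"ips_class": "EC"}, "sc": {"ips_class": "SC"}},
        )
        res = ips_score(mat, panels)
        assert res.ips.idxmax() == "S3"

    def test_hand_computed_weighted_z_sum(self):
        # 3 genes, 2 classes, 2 samples; Z of each gene is (-1/sqrt2, 1/sqrt2)
        mat = expr_from([[1.0, 2.0], [4.0, 6.0], [10.0, 0.0]])
        panels = GeneSetCollection(
            {"a": ["G0", "G1"], "b": ["G2"]},
            {"a": {"ips_class": "EC"}, "b": {"ips_class": "SC"}},
        )
        res = ips_score(mat, panels)
        z = 1 / np.sqrt(2)
        # EC avg Z = (-z, z); SC avg Z = (z, -z); IPS = EC - SC
        np.testing.assert_allclose(res.ips.to_numpy(), [-2 * z, 2 * z], atol=1e-12)

    def test_linear_in_class_weights(self):
        rng = np.random.default_rng(2)
        mat = expr_from(rng.normal(size=(4, 5)))
        panels = GeneSetCollection(
            {"a": ["G0", "G1"], "b": ["G2", "G3"]},
            {"a": {"ips_class": "EC"}, "b": {"ips_class": "CP"}},
        )
        base = ips_score(mat, panels)
        doubled = ips_score(mat, panels, class_weights={"EC": 2.0, "CP": -2.0})
        np.testing.assert_allclose(
            doubled.ips.to_numpy(), 2 * base.ips.to_numpy(), atol=1e-12
        )


def brute_force_hypergeom_tail(M, K, N, k):
    """P(overlap >= k) by direct enumeration."""
    return sum(
        comb(K, x) * comb(M - K, N - x) for x in range(k, min(K, N) + 1)
    ) / comb(M, N)


class TestOra:
    def test_matches_combinatorial_enumeration(self):
        universe = [f"G{i}" for i in range(20)]
        sets = GeneSetCollection({"S": universe[:6]})
        query = universe[:4] + universe[10:12]
        table = ora_test(query, universe, sets)
        expected = brute_force_hypergeom_tail(20, 6, 6, 4)
        assert table.loc["S", "p"] == pytest.approx(expected, abs=1e-12)
        assert table.loc["S", "overlap"] == 4

    def test_whole_set_query_is_extreme(self):
        universe = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection({"S": universe[:5], "T": universe[50:80]})
        table = ora_test(universe[:5], universe, sets)
        assert table.loc["S", "p"] == pytest.approx(
            brute_force_hypergeom_tail(100, 5, 5, 5), abs=1e-15
        )
        assert table.loc["S", "p"] < 1e-7

    def test_disjoint_query_has_p_one(self):
        universe = [f"G{i}" for i in range(30)]
        sets = GeneSetCollection({"S": universe[:5]})
        table = ora_test(universe[10:15], universe, sets)
        assert table.loc["S", "overlap"] == 0
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            ora_test([], ["G1"], GeneSetCollection({"S": ["G1"]}))


class TestBhAdjust:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_step_up_brute_force(self, pvals):
        ours = bh_adjust(np.array(pvals))
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(ours, expected, atol=1e-12)
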