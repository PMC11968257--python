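"""Hop-distance matrix, the nearest-neighbor path-distance statistic,
its permutation null, and the hypergeometric overlap test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathspace import (
    DistanceMatrix,
    GeneList,
    OverlapTestParams,
    hypergeom_upper_tail,
    nn_path_distance,
    null_distribution,
    path_distance_test,
    shortest_path_matrix,
    shortest_paths_from,
)
from pathspace.pathdist import read_distance_tsv, write_distance_tsv

from conftest import floyd_warshall, make_graph, nn_oracle, random_graph


class TestShortestPathMatrix:
    def test_path_graph(self, path_abc):
        D = shortest_path_matrix(path_abc)
        i = {n: k for k, n in enumerate(D.labels)}
        assert D.d[i["A"], i["C"]] == 2
        assert D.d[i["A"], i["B"]] == D.d[i["B"], i["C"]] == 1

    def test_disconnected_vertices_infinite(self):
        g = make_graph(["A", "B"], [])
        D = shortest_path_matrix(g)
        assert math.isinf(D.d[0, 1])
        assert D.d[0, 0] == D.d[1, 1] == 0

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_graph(rng, int(rng.integers(3, 13)), p=0.3)
            D = shortest_path_matrix(g)
            np.testing.assert_array_equal(D.d, floyd_warshall(g))

    def test_symmetry_zero_diagonal_triangle(self):
        g = random_graph(np.random.default_rng(11), 12, p=0.25)
        d = shortest_path_matrix(g).d
        np.testing.assert_array_equal(d, d.T)
        assert (np.diag(d) == 0).all()
        n = len(d)
        for i, j, k in itertools.product(range(n), repeat=3):
            if np.isfinite(d[i, k]) and np.isfinite(d[k, j]):
                assert d[i, j] <= d[i, k] + d[k, j]

    def test_row_wise_variant_agrees_with_full_matrix(self, toy):
        D = shortest_path_matrix(toy.graph)
        rows = shortest_paths_from(toy.graph, toy.L1)
        idx = D.index_of(toy.L1.ids)
        np.testing.assert_array_equal(rows.to_numpy(), D.d[idx])
        assert list(rows.columns) == list(D.labels)

    def test_tsv_roundtrip(self, toy, tmp_path):
        D = shortest_path_matrix(toy.graph)
        p = tmp_path / "d.tsv"
        write_distance_tsv(D, p)
        D2 = read_distance_tsv(p)
        assert D2.labels == D.labels
        np.testing.assert_allclose(D2.d, D.d)


class TestNNPathDistance:
    def test_from_equals_to_is_zero(self, toy):
        D = shortest_path_matrix(toy.graph)
        assert nn_path_distance(D, toy.L1, toy.L1) == 0.0

    def test_toy_worked_value(self, toy):
        D = shortest_path_matrix(toy.graph)
        assert nn_path_distance(D, toy.L1, toy.L2) == 1.25
        assert nn_path_distance(D, toy.L1, toy.L2, "symmetric") == 1.25

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            g = random_graph(rng, 10, p=0.35)
            D = shortest_path_matrix(g)
            fi = rng.choice(10, 3, replace=False)
            ti = rng.choice(10, 4, replace=False)
            if not np.isfinite(D.d[np.ix_(fi, ti)].min(axis=1)).any():
                continue
            lf = GeneList(tuple(g.vertex_names[i] for i in fi))
            lt = GeneList(tuple(g.vertex_names[i] for i in ti))
            assert nn_path_distance(D, lf, lt) == pytest.approx(nn_oracle(D.d, fi, ti))

    def test_symmetric_direction_is_symmetric(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 12, p=0.4)
        D = shortest_path_matrix(g)
        lf = GeneList(tuple(g.vertex_names[i] for i in [0, 3, 7]))
        lt = GeneList(tuple(g.vertex_names[i] for i in [1, 2, 8, 9]))
        assert nn_path_distance(D, lf, lt, "symmetric") == pytest.approx(
            nn_path_distance(D, lt, lf, "symmetric")
        )

    def test_from_to_asymmetry_counterexample(self, path_abc):
        # A-B-C: {A}->{B,C} = 1, but {B,C}->{A} = (1+2)/2 = 1.5
        D = shortest_path_matrix(path_abc)
        assert nn_path_distance(D, GeneList(("A",)), GeneList(("B", "C"))) == 1.0
        assert nn_path_distance(D, GeneList(("B", "C")), GeneList(("A",))) == 1.5

    def test_enlarging_to_never_increases(self):
        rng = np.random.default_rng(33)
        g = random_graph(rng, 12, p=0.4)
        D = shortest_path_matrix(g)
        lf = GeneList(tuple(g.vertex_names[i] for i in [0, 5, 9]))
        lt = [g.vertex_names[1], g.vertex_names[4]]
        prev = nn_path_distance(D, lf, GeneList(tuple(lt)))
        for extra in [2, 3, 6, 7, 8]:
            lt.append(g.vertex_names[extra])
            cur = nn_path_distance(D, lf, GeneList(tuple(lt)))
            assert cur <= prev + 1e-12
            prev = cur

    def test_zero_iff_subset(self):
        g = random_graph(np.random.default_rng(2), 10, p=0.5)
        D = shortest_path_matrix(g)
        names = g.vertex_names
        sub = GeneList(names[:3])
        sup = GeneList(names[:5])
        assert nn_path_distance(D, sub, sup) == 0.0
        assert nn_path_distance(D, sup, sub) > 0.0

    def test_unreachable_terms_excluded(self, caplog):
        # two components: A-B and C-D; from spans both, to in one
        g = make_graph(["A", "B", "C", "D"], [("A", "B"), ("C", "D")])
        D = shortest_path_matrix(g)
        val = nn_path_distance(D, GeneList(("A", "C")), GeneList(("B",)))
        assert val == 1.0  # C excluded, only A->B counted

    def test_all_unreachable_error(self):
        g = make_graph(["A", "B", "C"], [("A", "B")])
        D = shortest_path_matrix(g)
        with pytest.raises(ValueError, match="unreachable"):
            nn_path_distance(D, GeneList(("C",)), GeneList(("A", "B")))

    def test_unknown_label_error(self, toy):
        D = shortest_path_matrix(toy.graph)
        with pytest.raises(KeyError):
            nn_path_distance(D, GeneList(("NOPE",)), toy.L2)


class TestNullDistribution:
    def test_reproducible_given_seed(self, toy):
        D = shortest_path_matrix(toy.graph)
        a = null_distribution(D, 3, 4, nperm=5, seed=99)
        b = null_distribution(D, 3, 4, nperm=5, seed=99)
        np.testing.assert_array_equal(a, b)
        c = null_distribution(D, 3, 4, nperm=5, seed=100)
        assert not np.array_equal(a, c)

    def test_full_size_lists_give_zero(self, toy):
        D = shortest_path_matrix(toy.graph)
        n = D.n
        null = null_distribution(D, n, n, nperm=5, seed=1)
        np.testing.assert_array_equal(null, np.zeros(5))

    def test_replicates_match_oracle_on_complete_graph(self):
        g = make_graph(
            [f"K{i}" for i in range(10)],
            [(f"K{i}", f"K{j}") for i in range(10) for j in range(i + 1, 10)],
        )
        D = shortest_path_matrix(g)
        rng = np.random.default_rng(4)
        null = null_distribution(D, 2, 2, nperm=20, seed=4)
        for r in range(20):
            fi = rng.choice(10, 2, replace=False)
            ti = rng.choice(10, 2, replace=False)
            assert null[r] == pytest.approx(nn_oracle(D.d, fi, ti))

    def test_size_exceeding_vertices_error(self, toy):
        D = shortest_path_matrix(toy.graph)
        with pytest.raises(ValueError):
            null_distribution(D, D.n + 1, 2, nperm=2, seed=0)


class TestPathDistanceTest:
    def test_result_fields_and_p_formula(self, toy):
        D = shortest_path_matrix(toy.graph)
        res = path_distance_test(D, toy.L1, toy.L2, nperm=199, seed=7)
        assert res.observed == 1.25
        assert len(res.null_sample) == 199
        expect_p = (1 + np.sum(res.null_sample <= res.observed)) / 200
        assert res.p_value == pytest.approx(expect_p)
        mu, sd = res.null_sample.mean(), res.null_sample.std(ddof=1)
        assert res.z_score == pytest.approx((1.25 - mu) / sd)
        assert 1 / 200 <= res.p_value <= 1

    def test_identical_lists_observed_zero(self, toy):
        D = shortest_path_matrix(toy.graph)
        res = path_distance_test(D, toy.L1, toy.L1, nperm=49, seed=3)
        assert res.observed == 0.0
        assert res.p_value == (1 + np.sum(res.null_sample <= 0)) / 50

    def test_degenerate_null_z_nan_p_valid(self, toy):
        D = shortest_path_matrix(toy.graph)
        n = D.n
        full = GeneList(D.labels)
        res = path_distance_test(D, full, full, nperm=19, seed=0)
        assert math.isnan(res.z_score)
        assert res.p_value == 1.0  # all null values 0 <= observed 0

    def test_z_invariant_under_name_relabeling(self, toy):
        D = shortest_path_matrix(toy.graph)
        res = path_distance_test(D, toy.L1, toy.L2, nperm=99, seed=11)
        relabel = {v: f"X_{v}" for v in D.labels}
        D2 = DistanceMatrix(tuple(relabel[v] for v in D.labels), D.d)
        L1r = GeneList(tuple(relabel[v] for v in toy.L1.ids))
        L2r = GeneList(tuple(relabel[v] for v in toy.L2.ids))
        res2 = path_distance_test(D2, L1r, L2r, nperm=99, seed=11)
        assert res2.z_score == pytest.approx(res.z_score)
        assert res2.p_value == res.p_value

    def test_json_roundtrip(self, toy, tmp_path):
        D = shortest_path_matrix(toy.graph)
        res = path_distance_test(D, toy.L1, toy.L2, nperm=29, seed=5)
        p = tmp_path / "res.json"
        res.to_json(p)
        import json

        d = json.loads(p.read_text())
        assert d["schema_version"] == 1
        assert d["observed"] == 1.25
        assert len(d["null_sample"]) == 29


class TestHypergeomUpperTail:
    def test_protocol_worked_value(self):
        p = hypergeom_upper_tail(OverlapTestParams(q=11, m=50, n=123, k=50))
        assert round(p, 2) == 0.86

    def test_max_overlap_gives_zero(self):
        assert hypergeom_upper_tail(OverlapTestParams(q=2, m=2, n=5, k=2)) == 0.0

    def test_tiny_enumeration_oracle(self):
        # urn of 2 white + 2 black, draw 2: P(X=2) = C(2,2)/C(4,2) = 1/6
        p = hypergeom_upper_tail(OverlapTestParams(q=1, m=2, n=2, k=2))
        assert p == pytest.approx(1 / 6)

    def test_matches_enumeration_on_small_urns(self):
        # exhaustive enumeration over all subsets as independent oracle
        m, n, k = 4, 3, 3
        white = set(range(m))
        total = 0
        counts = {}
        for draw in itertools.combinations(range(m + n), k):
            q = len(white.intersection(draw))
            counts[q] = counts.get(q, 0) + 1
            total += 1
        for q in range(0, min(m, k) + 1):
            expect = sum(c for qq, c in counts.items() if qq > q) / total
            got = hypergeom_upper_tail(OverlapTestParams(q=q, m=m, n=n, k=k))
            assert got == pytest.approx(expect)

    @given(
        st.integers(1, 20), st.integers(1, 20), st.integers(1, 20),
        st.integers(0, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_tail_is_probability_and_monotone_in_q(self, m, n, k, q):
        k = min(k, m + n)
        q = min(q, min(m, k))
        p = hypergeom_upper_tail(OverlapTestParams(q=q, m=m, n=n, k=k))
        assert 0.0 <= p <= 1.0
        if q > 0:
            p_prev = hypergeom_upper_tail(OverlapTestParams(q=q - 1, m=m, n=n, k=k))
            assert p <= p_prev + 1e-12

    @pytest.mark.parametrize(
        "kw",
        [
            dict(q=3, m=2, n=2, k=2),   # q > min(m, k)
            dict(q=0, m=0, n=2, k=1),   # m not positive
            dict(q=0, m=2, n=2, k=5),   # k exceeds universe
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            OverlapTestParams(**kw)
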