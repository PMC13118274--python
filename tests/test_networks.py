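"""Partial correlations, tail edge selection, and the partitioning ratio Q."""

import numpy as np
import pandas as pd
import pytest

from icitau.censorship import NotApplicableError
from icitau.matrix import AbundanceMatrix, pairwise_icikt
from icitau.networks import (
    WeightedEdgeList,
    partial_correlations,
    partition_ratio,
    select_edges,
)


def edge_list(triples):
    df = pd.DataFrame(triples, columns=["feature_a", "feature_b", "weight"])
    nodes = tuple(sorted(set(df["feature_a"]) | set(df["feature_b"])))
    return WeightedEdgeList(edges=df, nodes=nodes)


class TestPartialCorrelations:
    def test_identity_maps_to_identity(self):
        res = partial_correlations(np.eye(4))
        assert np.allclose(res.matrix, np.eye(4))
        assert res.shrinkage == 0.0

    def test_two_by_two_equals_raw(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = partial_correlations(C)
        assert res.matrix[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_chain_structure_vanishes(self):
        # corr(0,2) fully explained by 1: classic 3-variable partialling
        a, b = 0.6, 0.5
        C = np.array([[1, a, a * b], [a, 1, b], [a * b, b, 1]], dtype=float)
        res = partial_correlations(C)
        assert res.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        expected_01 = (a - a * b * b) / np.sqrt((1 - (a * b) ** 2) * (1 - b**2))
        assert res.matrix[0, 1] == pytest.approx(expected_01, abs=1e-12)

    def test_singular_matrix_gets_shrunk(self):
        # rank-1 correlation: plain inversion impossible
        v = np.array([1.0, -1.0, 1.0, -1.0])
        C = np.outer(v, v)
        res = partial_correlations(C)
        assert 0.0 < res.shrinkage < 1.0
        assert np.isfinite(res.matrix).all()
        assert np.allclose(res.matrix, res.matrix.T)

    def test_nan_cells_imputed_to_zero(self):
        C = np.array([[1.0, np.nan], [np.nan, 1.0]])
        res = partial_correlations(C)
        assert res.matrix[0, 1] == pytest.approx(0.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            partial_correlations(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestSelectEdges:
    def test_matches_sort_based_oracle(self, rng):
        n = 40
        A = rng.normal(size=(n, n))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        tail = 0.025
        got = select_edges(P, tail_fraction=tail)
        # oracle: explicit linear-interpolation quantiles on the sorted values
        iu = np.triu_indices(n, 1)
        vals = np.sort(P[iu])
        m = vals.size

        def quant(q):
            pos = q * (m - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, m - 1)
            return vals[lo] + (pos - lo) * (vals[hi] - vals[lo])

        lo_t, hi_t = quant(tail), quant(1 - tail)
        expect = {
            tuple(sorted((f"feature_{i}", f"feature_{j}"))): P[i, j]
            for i, j in zip(*iu)
            if (P[i, j] <= lo_t or P[i, j] >= hi_t) and P[i, j] > 0
        }
        got_map = {
            (r.feature_a, r.feature_b): r.weight for r in got.edges.itertuples(index=False)
        }
        assert got_map.keys() == expect.keys()
        for k in expect:
            assert got_map[k] == pytest.approx(expect[k], abs=1e-15)

    def test_symmetric_distribution_halved_by_positivity(self, rng):
        n = 60
        A = rng.normal(size=(n, n))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        got = select_edges(P, tail_fraction=0.05)
        n_off = n * (n - 1) // 2
        pre_trim = int(np.ceil(0.05 * n_off)) * 2  # both tails
        assert 0.3 * pre_trim <= len(got.edges) <= 0.7 * pre_trim

    def test_small_matrix_warns(self):
        P = np.eye(3)
        with pytest.warns(UserWarning, match="tail_fraction"):
            select_edges(P, tail_fraction=0.025)

    def test_all_weights_positive_and_canonical(self, rng):
        A = rng.normal(size=(20, 20))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        got = select_edges(P)
        assert (got.edges["weight"] > 0).all()
        assert (got.edges["feature_a"] < got.edges["feature_b"]).all()


class TestPartitionRatio:
    def test_single_annotation_covering_everything(self):
        edges = edge_list([("a", "b", 2.0), ("b", "c", 3.0)])
        res = partition_ratio(edges, {"A1": {"a", "b", "c"}})
        assert res.q_ratio == pytest.approx(1.0)

    def test_disjoint_within_only(self):
        edges = edge_list([("a", "b", 1.0), ("c", "d", 4.0)])
        res = partition_ratio(edges, {"A1": {"a", "b"}, "A2": {"c", "d"}})
        assert res.q_ratio == pytest.approx(1.0)
        within = dict(zip(res.per_annotation["annotation"], res.per_annotation["within_sum"]))
        assert within == {"A1": 1.0, "A2": 4.0}

    def test_all_crossing_gives_minus_two(self):
        edges = edge_list([("a", "c", 1.0), ("b", "d", 2.0)])
        res = partition_ratio(edges, {"A1": {"a", "b"}, "A2": {"c", "d"}})
        assert res.q_ratio == pytest.approx(-2.0)

    def test_single_direction_counting_halves_outer(self):
        edges = edge_list([("a", "c", 1.0)])
        ann = {"A1": {"a"}, "A2": {"c"}}
        both = partition_ratio(edges, ann, count_both_directions=True)
        one = partition_ratio(edges, ann, count_both_directions=False)
        assert sum(both.per_annotation["outer_sum"]) == 2 * sum(one.per_annotation["outer_sum"])

    def test_uniform_rescaling_invariance(self, rng):
        triples = [(f"n{i}", f"n{j}", float(rng.uniform(0.1, 2)))
                   for i in range(8) for j in range(i + 1, 8) if rng.random() < 0.5]
        ann = {"A": {f"n{i}" for i in range(4)}, "B": {f"n{i}" for i in range(4, 8)}}
        e1 = edge_list(triples)
        e2 = edge_list([(a, b, 10.0 * w) for a, b, w in triples])
        assert partition_ratio(e1, ann).q_ratio == pytest.approx(
            partition_ratio(e2, ann).q_ratio, rel=1e-12
        )

    def test_unannotated_edges_are_excluded_from_annotated_total(self):
        edges = edge_list([("a", "b", 1.0), ("x", "y", 100.0)])
        res = partition_ratio(edges, {"A1": {"a", "b"}})
        assert res.annotated_total == 1.0
        assert res.q_ratio == pytest.approx(1.0)

    def test_no_annotated_edges_is_undefined(self):
        edges = edge_list([("x", "y", 1.0)])
        with pytest.raises(NotApplicableError):
            partition_ratio(edges, {"A1": {"a"}})


def block_cohort(seed, n_blocks=4, per_block=10, n_samples=20):
    """Features in independent correlated blocks; blocks act as annotations."""
    rng = np.random.default_rng(seed)
    n_features = n_blocks * per_block
    latent = rng.normal(size=(n_blocks, n_samples))
    data = np.vstack(
        [latent[b] + 0.6 * rng.normal(size=(per_block, n_samples)) for b in range(n_blocks)]
    )
    m = AbundanceMatrix(
        values=data,
        missing_mask=np.zeros_like(data, dtype=bool),
        feature_ids=[f"f{i}" for i in range(n_features)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )
    annotations = {
        f"block{b}": {f"f{i}" for i in range(b * per_block, (b + 1) * per_block)}
        for b in range(n_blocks)
    }
    return m, annotations


class TestBlockStructureRecovery:
    def test_true_annotations_beat_permuted(self):
        """Q from block-structured networks exceeds Q under permuted labels."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            m, annotations = block_cohort(seed)
            cset = pairwise_icikt(m, axis="features")
            pres = partial_correlations(cset.tau)
            edges = select_edges(pres.matrix, node_ids=list(cset.ids))
            q_true = partition_ratio(edges, annotations).q_ratio
            rng = np.random.default_rng(10_000 + seed)
            perm = rng.permutation(list(m.feature_ids))
            relabel = dict(zip(m.feature_ids, perm))
            permuted = {k: {relabel[f] for f in v} for k, v in annotations.items()}
            q_perm = partition_ratio(edges, permuted).q_ratio
            wins += q_true > q_perm
        assert wins >= 0.95 * n_rep
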