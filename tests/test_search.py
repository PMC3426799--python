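"""Greedy search against exhaustive-enumeration oracles."""

import numpy as np
import pytest

from bnbag.core import forward_sample
from bnbag.scoring import NetworkScorer, ScoreConfig, network_log_score
from bnbag.search import (
    SearchConfig,
    empty_parents,
    hill_climb,
    neighbors,
    select_candidates,
    sparse_candidate_search,
)
from bnbag.synthetic import noisy_copy_chain

from conftest import make_data, skeleton_of

SMALL = SearchConfig(k=2, c_rounds=2, m1=10, m2=5, retain=5)


def full_candidates(n):
    return tuple(tuple(j for j in range(n) if j != i) for i in range(n))


class TestSelectCandidates:
    def test_three_nodes_large_k_gives_all_others(self):
        rng = np.random.default_rng(0)
        data = make_data(rng.integers(0, 2, size=(30, 3)))
        scorer = NetworkScorer(data, None, ScoreConfig("k2"))
        cands = select_candidates(scorer, k=6)
        assert cands == full_candidates(3)

    def test_strong_parent_ranks_first(self):
        """Z noisily copies X while Y is independent: X tops Z's candidates."""
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=400)
        y = rng.integers(0, 2, size=400)
        z = np.where(rng.random(400) < 0.9, x, 1 - x)
        data = make_data(np.column_stack([x, y, z]))
        scorer = NetworkScorer(data, None, ScoreConfig("k2"))
        cands = select_candidates(scorer, k=1)
        assert cands[2] == (0,)
        # oracle: exhaustive single-edge scoring agrees
        gains = {
            j: scorer.family_score(2, (j,)) - scorer.family_score(2, ())
            for j in (0, 1)
        }
        assert max(gains, key=gains.get) == 0

    def test_never_contains_self_and_keeps_current_parents(self):
        rng = np.random.default_rng(2)
        data = make_data(rng.integers(0, 2, size=(50, 4)))
        scorer = NetworkScorer(data, None, ScoreConfig("k2"))
        current = ((), (0,), (0, 1), ())
        cands = select_candidates(scorer, k=2, current=current)
        for i, c in enumerate(cands):
            assert i not in c
            assert set(current[i]) <= set(c)
            assert len(c) <= 2 or set(c) == set(current[i])


class TestNeighbors:
    def test_empty_graph_three_nodes_has_six_single_edge_neighbors(self):
        nbs = list(neighbors(empty_parents(3), full_candidates(3), k=6))
        assert len(nbs) == 6
        assert len(set(nbs)) == 6

    def test_chain_neighbors_match_enumeration_oracle(self, dags3):
        """One-move neighborhood of 0->1->2 equals the brute-force move set."""
        chain = ((), (0,), (1,))
        got = set(neighbors(chain, full_candidates(3), k=6))
        edges = {(p, c) for c, ps in enumerate(chain) for p in ps}
        expected = set()
        for dag in dags3:
            dag_edges = {(p, c) for c, ps in enumerate(dag) for p in ps}
            if len(dag_edges ^ edges) == 1:
                expected.add(dag)  # one addition or one deletion
            if (
                len(dag_edges) == len(edges)
                and len(dag_edges - edges) == 1
            ):
                (new,) = dag_edges - edges
                (old,) = edges - dag_edges
                if new == (old[1], old[0]):
                    expected.add(dag)  # one reversal
        assert got == expected

    def test_neighbor_is_never_input(self):
        start = ((), (0,), (1,))
        assert start not in set(neighbors(start, full_candidates(3), k=6))


class TestHillClimb:
    def test_fixed_point_at_global_optimum(self, dags3):
        rng = np.random.default_rng(3)
        data = make_data(rng.integers(0, 2, size=(50, 3)))
        cfg = ScoreConfig("k2")
        scorer = NetworkScorer(data, None, cfg)
        best = max(dags3, key=lambda s: network_log_score(data, None, s, cfg))
        result, _ = hill_climb(best, full_candidates(3), scorer, {}, k=6)
        assert result == best

    def test_visited_cache_grows_and_is_never_rescored(self):
        rng = np.random.default_rng(4)
        data = make_data(rng.integers(0, 2, size=(40, 3)))
        scorer = NetworkScorer(data, None, ScoreConfig("k2"))
        visited = {}
        hill_climb(empty_parents(3), full_candidates(3), scorer, visited, k=6)
        first = len(visited)
        evals_after_first = scorer.n_family_evals
        hill_climb(empty_parents(3), full_candidates(3), scorer, visited, k=6)
        assert len(visited) >= first  # nothing forgotten
        # second climb from the same start finds everything visited
        assert scorer.n_family_evals == evals_after_first


class TestSparseCandidateSearch:
    @pytest.mark.parametrize("metric", ["k2", "dpsm", "bde", "bic", "mdl"])
    def test_attains_enumeration_optimum_three_nodes(self, metric, dags3):
        rng = np.random.default_rng(5)
        data = make_data(rng.integers(0, 2, size=(60, 3)))
        cfg = ScoreConfig(metric, lam=0.5)
        best_enum = max(network_log_score(data, None, s, cfg) for s in dags3)
        res = sparse_candidate_search(data, None, cfg, SMALL, np.random.default_rng(0))
        assert res.best_score == pytest.approx(best_enum, abs=1e-9)

    def test_deterministic_given_seed(self):
        data = forward_sample(noisy_copy_chain(4), 150, seed=6)
        cfg = ScoreConfig("dpsm", lam=1.0)
        a = sparse_candidate_search(data, None, cfg, SMALL, np.random.default_rng(9))
        b = sparse_candidate_search(data, None, cfg, SMALL, np.random.default_rng(9))
        assert a == b

    def test_result_scores_non_increasing_and_distinct(self):
        data = forward_sample(noisy_copy_chain(4), 100, seed=7)
        res = sparse_candidate_search(
            data, None, ScoreConfig("k2"), SMALL, np.random.default_rng(1)
        )
        scores = [s for _, s in res.networks]
        assert scores == sorted(scores, reverse=True)
        structures = [p for p, _ in res.networks]
        assert len(set(structures)) == len(structures)

    def test_never_worse_than_empty_network(self):
        rng = np.random.default_rng(8)
        data = make_data(rng.integers(0, 3, size=(40, 4)), arities=[3, 3, 3, 3])
        cfg = ScoreConfig("mdl")
        res = sparse_candidate_search(data, None, cfg, SMALL, np.random.default_rng(2))
        empty_score = network_log_score(data, None, empty_parents(4), cfg)
        assert res.best_score >= empty_score - 1e-12

    def test_respects_max_parents(self):
        rng = np.random.default_rng(9)
        data = make_data(rng.integers(0, 2, size=(80, 5)))
        res = sparse_candidate_search(
            data,
            None,
            ScoreConfig("dpsm", lam=0.1),
            SearchConfig(k=2, c_rounds=2, m1=6, m2=3, retain=5),
            np.random.default_rng(3),
        )
        for parents, _ in res.networks:
            assert all(len(ps) <= 2 for ps in parents)

    def test_chain_skeleton_recovered_across_replicates(self):
        """The true 4-node chain skeleton tops the search on ~90% of datasets."""
        bn = noisy_copy_chain(4, fidelity=0.9)
        truth = skeleton_of(bn.structure.parents)
        cfg = ScoreConfig("dpsm", lam=1.0)
        hits = 0
        for seed in range(30):
            data = forward_sample(bn, 500, seed=400 + seed)
            res = sparse_candidate_search(
                data, None, cfg, SMALL, np.random.default_rng(seed)
            )
            hits += skeleton_of(res.best) == truth
        assert hits >= 26
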