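"""Sparse-candidate greedy hill-climbing with randomized restarts.

Structure learning is posed as maximizing a decomposable score over DAGs.
Exhaustive search is NP-complete, so the search used here is local:

1. For each node, a candidate parent set of size <= ``k`` is chosen by
   ranking prospective parents on the family-score gain of a single edge.
2. Greedy hill-climbing explores neighbors differing by one edge
   addition (parent drawn from the child's candidate set), one deletion,
   or one reversal, moving only to strictly higher scores.
3. At a local optimum the candidate sets are re-estimated given the
   current parents (current parents are always retained), and climbing
   resumes — up to ``c_rounds`` rounds or until a previously seen
   candidate assignment recurs.
4. The whole procedure restarts ``m1`` times from random structures with
   at most two edges, then ``m2`` more times from structures chosen
   randomly among everything visited so far.

Every structure ever scored is recorded in a run-wide visited cache and
never rescored; features are read off the highest-scoring structures
visited across all restarts.

Structures are represented compactly as a tuple of sorted parent-index
tuples (one per variable), which also serves as the canonical cache key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core import DataTable
from .scoring import NetworkScorer, ScoreConfig

__all__ = [
    "SearchConfig",
    "SearchResult",
    "select_candidates",
    "neighbors",
    "hill_climb",
    "sparse_candidate_search",
]

ParentsTuple = tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the restart/candidate protocol.

    ``k``: max parents per node and candidate-set size.  ``c_rounds``:
    max candidate re-selection rounds per restart.  ``m1``/``m2``: number
    of first-phase (fresh start) and second-phase (revisit) restarts.
    ``retain``: how many distinct top structures the result keeps.
    """

    k: int = 6
    c_rounds: int = 10
    m1: int = 25
    m2: int = 25
    retain: int = 10

    def __post_init__(self) -> None:
        if self.k < 1 or self.c_rounds < 1 or self.m1 < 1 or self.m2 < 0:
            raise ValueError("k, c_rounds, m1 must be >= 1 and m2 >= 0")
        if self.retain < 1:
            raise ValueError("retain must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    """Ranked distinct top structures and the search-effort counter."""

    networks: tuple[tuple[ParentsTuple, float], ...]
    n_evaluated: int

    @property
    def best(self) -> ParentsTuple:
        return self.networks[0][0]

    @property
    def best_score(self) -> float:
        return self.networks[0][1]


def empty_parents(n: int) -> ParentsTuple:
    return tuple(() for _ in range(n))


def _has_path(parents: ParentsTuple, src: int, dst: int) -> bool:
    """True if a directed path src -> ... -> dst exists."""
    if src == dst:
        return True
    n = len(parents)
    children = [[] for _ in range(n)]
    for c, ps in enumerate(parents):
        for p in ps:
            children[p].append(c)
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def select_candidates(
    scorer: NetworkScorer,
    k: int,
    current: ParentsTuple | None = None,
) -> tuple[tuple[int, ...], ...]:
    """Candidate parent sets of size <= k for every node.

    Initially (``current=None``) node ``i``'s candidates are the ``k``
    nodes ``j`` maximizing the score of the single-edge network ``j->i``,
    i.e. the family-score gain of adding ``j`` as sole parent.  On
    re-selection, gains are computed relative to the node's current
    parents, which are always retained in the candidate set so the
    incumbent structure stays feasible.  Ties break toward the lower
    node index.
    """
    n = scorer.n_vars
    out = []
    for i in range(n):
        base = () if current is None else current[i]
        base_set = set(base)
        base_score = scorer.family_score(i, base)
        gains = []
        for j in range(n):
            if j == i or j in base_set:
                continue
            gain = scorer.family_score(i, tuple(sorted(base + (j,)))) - base_score
            gains.append((-gain, j))
        gains.sort()
        room = max(k - len(base), 0)
        chosen = sorted(base_set | {j for _, j in gains[:room]})
        out.append(tuple(chosen))
    return tuple(out)


def neighbors(
    parents: ParentsTuple,
    candidates: Sequence[Sequence[int]],
    k: int,
) -> Iterator[ParentsTuple]:
    """All legal one-move neighbors, in deterministic enumeration order.

    Moves are ordered by child index, then add < delete < reverse, then
    parent index.  An addition requires the new parent to be in the
    child's candidate set, the child to stay within ``k`` parents, and
    acyclicity; a reversal additionally requires the old parent to accept
    the old child as parent under the same rules.
    """
    n = len(parents)
    for child in range(n):
        ps = parents[child]
        ps_set = set(ps)
        if len(ps) < k:
            for p in candidates[child]:
                if p == child or p in ps_set:
                    continue
                if _has_path(parents, child, p):
                    continue  # p -> child would close a cycle
                new = list(parents)
                new[child] = tuple(sorted(ps + (p,)))
                yield tuple(new)
        for p in ps:
            new = list(parents)
            new[child] = tuple(x for x in ps if x != p)
            yield tuple(new)
        for p in ps:
            # reverse p->child into child->p
            if child not in candidates[p] or len(parents[p]) >= k:
                continue
            removed = list(parents)
            removed[child] = tuple(x for x in ps if x != p)
            if _has_path(tuple(removed), p, child):
                continue  # another p..child path survives; reversal cycles
            removed[p] = tuple(sorted(parents[p] + (child,)))
            yield tuple(removed)


def hill_climb(
    start: ParentsTuple,
    candidates: Sequence[Sequence[int]],
    scorer: NetworkScorer,
    visited: dict[ParentsTuple, float],
    k: int,
) -> tuple[ParentsTuple, float]:
    """Greedy ascent from ``start`` within the candidate-restricted space.

    Moves to the best-scoring unvisited neighbor only when its score is
    strictly higher than the current structure's (ties prefer the
    incumbent; ties between neighbors resolve to the first in enumeration
    order).  Every scored structure is added to ``visited`` and never
    rescored.  Stops when no unvisited neighbor improves.
    """
    current = start
    cur_score = visited.get(current)
    if cur_score is None:
        cur_score = scorer.structure_score(current)
        visited[current] = cur_score
    while True:
        best = None
        best_score = -np.inf
        for nb in neighbors(current, candidates, k):
            if nb in visited:
                continue
            s = scorer.structure_score(nb)
            visited[nb] = s
            if s > best_score:
                best, best_score = nb, s
        if best is None or best_score <= cur_score:
            return current, cur_score
        current, cur_score = best, best_score


def _random_start(
    candidates: Sequence[Sequence[int]],
    rng: np.random.Generator,
    n: int,
) -> ParentsTuple:
    """A random candidate-respecting structure with 0, 1 or 2 edges.

    Sampling is uniform over the edge count then over admissible edges,
    rejecting duplicate pairs and 2-cycles; materializing the full start
    list would be infeasible for large n.
    """
    n_edges = int(rng.integers(0, 3))
    parents = [list() for _ in range(n)]
    chosen: set[tuple[int, int]] = set()
    admissible = [
        (p, c) for c in range(n) for p in candidates[c] if p != c
    ]
    if not admissible:
        return empty_parents(n)
    tries = 0
    while len(chosen) < n_edges and tries < 100:
        tries += 1
        p, c = admissible[int(rng.integers(len(admissible)))]
        if (p, c) in chosen or (c, p) in chosen:
            continue
        chosen.add((p, c))
        parents[c].append(p)
    return tuple(tuple(sorted(ps)) for ps in parents)


def _candidate_key(candidates: Sequence[Sequence[int]]) -> tuple:
    return tuple(tuple(c) for c in candidates)


def sparse_candidate_search(
    data: DataTable,
    weights: np.ndarray | None,
    score_config: ScoreConfig,
    search_config: SearchConfig,
    rng: np.random.Generator | int | None = None,
) -> SearchResult:
    """Full restart protocol; returns the distinct top structures.

    Deterministic given the RNG state: two runs with equal seeds return
    identical results.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = search_config
    scorer = NetworkScorer(data, weights, score_config)
    n = data.n_vars
    base_candidates = select_candidates(scorer, cfg.k)
    visited: dict[ParentsTuple, float] = {}

    def one_restart(start: ParentsTuple) -> None:
        cand = base_candidates
        seen_cand = {_candidate_key(cand)}
        current = start
        for _ in range(cfg.c_rounds):
            current, _score = hill_climb(current, cand, scorer, visited, cfg.k)
            cand = select_candidates(scorer, cfg.k, current=current)
            key = _candidate_key(cand)
            if key in seen_cand:
                break
            seen_cand.add(key)

    for _ in range(cfg.m1):
        one_restart(_random_start(base_candidates, rng, n))
    snapshot = sorted(visited)  # deterministic order for sampling
    for _ in range(cfg.m2):
        start = snapshot[int(rng.integers(len(snapshot)))]
        one_restart(start)

    ranked = sorted(visited.items(), key=lambda kv: (-kv[1], kv[0]))
    top = tuple((s, sc) for s, sc in ranked[: cfg.retain])
    return SearchResult(top, n_evaluated=len(visited))
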