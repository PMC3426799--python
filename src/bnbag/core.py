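"""Discrete Bayesian networks: structure, parameters, and forward sampling.

A Bayesian network over discrete variables ``X_1 .. X_n`` is a directed
acyclic graph (DAG) together with one conditional probability table (CPT)
per variable, giving ``P(X_i | U_i)`` where ``U_i`` are the parents of
``X_i``.  The joint distribution factorizes as the product of these
conditionals.  This module provides the containers every other part of
the package manipulates, plus the three primitive operations the rest of
the pipeline needs: topological ordering, ancestral (forward) sampling,
and joint log-probability evaluation.

Conventions
-----------
* Variable states are 0-based integers internally; external labels map to
  indices by declaration order.
* A parent configuration is indexed by the mixed-radix encoding of the
  parent states in ascending parent-index order, with the *last* (highest
  index) parent varying fastest.  The same encoding is used by the CPTs
  here and by the sufficient statistics in :mod:`bnbag.scoring`.
* Data must be complete; missing values are rejected at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

__all__ = [
    "CycleError",
    "VariableSpec",
    "NetworkStructure",
    "ConditionalTable",
    "BayesianNetwork",
    "DataTable",
    "parent_config_index",
    "topological_order",
    "forward_sample",
    "joint_log_probability",
    "joint_distribution",
]

_PROB_TOL = 1e-9


class CycleError(ValueError):
    """Raised when a directed cycle is found where a DAG is required."""


@dataclass(frozen=True)
class VariableSpec:
    """A named discrete variable with ``r_i >= 2`` labelled states."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def arity(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class NetworkStructure:
    """A DAG over an ordered list of variables.

    ``parents[i]`` is the sorted tuple of parent indices of variable ``i``.
    Acyclicity is verified at construction.
    """

    variables: tuple[VariableSpec, ...]
    parents: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != n:
            raise ValueError("variable names must be unique")
        if len(self.parents) != n:
            raise ValueError("parents must list one parent set per variable")
        norm = tuple(tuple(sorted(set(ps))) for ps in self.parents)
        object.__setattr__(self, "parents", norm)
        for i, ps in enumerate(norm):
            for p in ps:
                if p == i:
                    raise ValueError(f"variable {i} cannot be its own parent")
                if not 0 <= p < n:
                    raise ValueError(f"parent index {p} of variable {i} out of range")
        topological_order(self)  # raises CycleError on a cycle

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def arities(self) -> tuple[int, ...]:
        return tuple(v.arity for v in self.variables)

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as (parent, child) pairs."""
        return [(p, c) for c, ps in enumerate(self.parents) for p in ps]

    def skeleton(self) -> set[frozenset[int]]:
        """Undirected edge set."""
        return {frozenset((p, c)) for p, c in self.edges()}

    def n_parent_configs(self, i: int) -> int:
        """q_i: the number of joint parent states of variable i."""
        q = 1
        for p in self.parents[i]:
            q *= self.variables[p].arity
        return q


@dataclass(frozen=True)
class ConditionalTable:
    """CPT for one child: ``table[j, k] = P(X_child = k | U_child = j)``.

    Rows are indexed by the mixed-radix parent configuration ``j`` and must
    each sum to one.
    """

    child: int
    table: np.ndarray  # shape (q_i, r_i)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", t)
        if t.ndim != 2:
            raise ValueError("CPT must be 2-D (parent configs x child states)")
        if np.any(t < -_PROB_TOL) or np.any(t > 1 + _PROB_TOL):
            raise ValueError("CPT entries must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=_PROB_TOL, rtol=0):
            raise ValueError("every CPT row must sum to 1")


@dataclass(frozen=True)
class BayesianNetwork:
    """A structure plus one conditional table per variable."""

    structure: NetworkStructure
    tables: tuple[ConditionalTable, ...]

    def __post_init__(self) -> None:
        s = self.structure
        if len(self.tables) != s.n:
            raise ValueError("need exactly one CPT per variable")
        for i, ct in enumerate(self.tables):
            if ct.child != i:
                raise ValueError("tables must be listed in variable order")
            q, r = ct.table.shape
            if r != s.variables[i].arity:
                raise ValueError(f"CPT of {s.variables[i].name!r} has wrong arity")
            if q != s.n_parent_configs(i):
                raise ValueError(
                    f"CPT of {s.variables[i].name!r} has {q} rows, "
                    f"expected {s.n_parent_configs(i)}"
                )

    @property
    def n(self) -> int:
        return self.structure.n

    def state_space_size(self) -> int:
        return int(np.prod([v.arity for v in self.structure.variables]))


@dataclass(frozen=True)
class DataTable:
    """N complete cases over the given variables, as 0-based state indices."""

    variables: tuple[VariableSpec, ...]
    values: np.ndarray  # shape (N, n), integer

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] != len(self.variables):
            raise ValueError("values must be N x n with one column per variable")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("values must be integers (complete data, no NaN)")
        v = np.ascontiguousarray(v, dtype=np.int64)
        object.__setattr__(self, "values", v)
        for i, spec in enumerate(self.variables):
            col = v[:, i]
            if col.size and (col.min() < 0 or col.max() >= spec.arity):
                raise ValueError(
                    f"column {spec.name!r} contains states outside [0, {spec.arity})"
                )

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def arities(self) -> tuple[int, ...]:
        return tuple(v.arity for v in self.variables)


def parent_config_index(
    values: np.ndarray, parents: Sequence[int], arities: Sequence[int]
) -> np.ndarray:
    """Mixed-radix index of each row's joint parent state.

    Parents are taken in ascending index order with the last one varying
    fastest, so ``j = ((s[p0] * r[p1] + s[p1]) * r[p2] + ...)``.  Returns
    zeros when the parent set is empty.
    """
    j = np.zeros(values.shape[0], dtype=np.int64)
    for p in sorted(parents):
        j = j * arities[p] + values[:, p]
    return j


def topological_order(structure: NetworkStructure | Sequence[Sequence[int]]) -> list[int]:
    """Variable indices ordered so every parent precedes its children.

    Accepts either a :class:`NetworkStructure` or a bare parent-set list.
    Kahn's algorithm with ascending-index tie-breaks, so the result is
    deterministic.  Raises :class:`CycleError` naming one offending edge
    if the graph is cyclic.
    """
    parents = structure.parents if isinstance(structure, NetworkStructure) else structure
    n = len(parents)
    remaining = [set(ps) for ps in parents]
    done: list[int] = []
    placed = [False] * n
    while len(done) < n:
        ready = [i for i in range(n) if not placed[i] and not remaining[i]]
        if not ready:
            cyc = next(i for i in range(n) if not placed[i])
            edge_parent = next(iter(remaining[cyc]))
            raise CycleError(
                f"cycle detected: edge {edge_parent}->{cyc} lies on a directed cycle"
            )
        for i in ready:
            placed[i] = True
            done.append(i)
        for rem in remaining:
            rem.difference_update(ready)
    return done


def forward_sample(
    bn: BayesianNetwork, n_cases: int, seed: int | np.random.Generator
) -> DataTable:
    """Draw ``n_cases`` i.i.d. rows from the network's joint distribution.

    Ancestral sampling: variables are visited in topological order and each
    is drawn from its CPT row selected by the already-sampled parent states.
    Deterministic given the seed.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = bn.structure
    arities = s.arities
    out = np.zeros((n_cases, s.n), dtype=np.int64)
    for i in topological_order(s):
        j = parent_config_index(out, s.parents[i], arities)
        probs = bn.tables[i].table[j]  # (n_cases, r_i)
        cdf = np.cumsum(probs, axis=1)
        u = rng.random(n_cases)
        out[:, i] = np.minimum(
            (u[:, None] >= cdf).sum(axis=1), arities[i] - 1
        )
    return DataTable(s.variables, out)


def joint_log_probability(bn: BayesianNetwork, row: Sequence[int]) -> float:
    """log P(row) under the factorized joint; ``-inf`` if any factor is 0."""
    r = np.asarray(row)
    if r.shape != (bn.n,):
        raise ValueError(f"assignment must be complete: expected {bn.n} values")
    arr = r.reshape(1, -1)
    total = 0.0
    s = bn.structure
    for i in range(s.n):
        j = int(parent_config_index(arr, s.parents[i], s.arities)[0])
        theta = bn.tables[i].table[j, r[i]]
        if theta <= 0.0:
            return -math.inf
        total += math.log(theta)
    return total


def joint_distribution(bn: BayesianNetwork, limit: int = 4096) -> dict[tuple[int, ...], float]:
    """Exhaustively enumerate the joint distribution (small networks only).

    Intended for validation and as an exact oracle; refuses state spaces
    larger than ``limit``.
    """
    size = bn.state_space_size()
    if size > limit:
        raise ValueError(f"state space {size} exceeds enumeration limit {limit}")
    out: dict[tuple[int, ...], float] = {}
    for assignment in product(*(range(v.arity) for v in bn.structure.variables)):
        lp = joint_log_probability(bn, assignment)
        out[assignment] = 0.0 if lp == -math.inf else math.exp(lp)
    return out
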