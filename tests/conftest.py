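"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from itertools import product

import networkx as nx
import numpy as np
import pytest

from bnbag.core import (
    BayesianNetwork,
    ConditionalTable,
    DataTable,
    NetworkStructure,
    VariableSpec,
)


def binary_vars(n: int) -> tuple[VariableSpec, ...]:
    return tuple(VariableSpec(f"X{i}", ("s0", "s1")) for i in range(n))


def make_data(values, arities=None) -> DataTable:
    values = np.asarray(values, dtype=np.int64)
    n = values.shape[1]
    if arities is None:
        arities = [max(2, int(values[:, i].max()) + 1) for i in range(n)]
    specs = tuple(
        VariableSpec(f"X{i}", tuple(f"s{k}" for k in range(arities[i])))
        for i in range(n)
    )
    return DataTable(specs, values)


def all_dags(n: int) -> list[tuple[tuple[int, ...], ...]]:
    """Enumerate every labelled DAG on n nodes as a parents tuple.

    Independent oracle: acyclicity is delegated to networkx.
    """
    subsets = [
        tuple(s) for m in range(n) for s in itertools.combinations(range(n), m)
    ]
    out = []
    for combo in product(*[[s for s in subsets if i not in s] for i in range(n)]):
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for child, ps in enumerate(combo):
            for p in ps:
                g.add_edge(p, child)
        if nx.is_directed_acyclic_graph(g):
            out.append(tuple(tuple(sorted(ps)) for ps in combo))
    return out


def skeleton_of(parents) -> set[frozenset]:
    return {
        frozenset((p, c)) for c, ps in enumerate(parents) for p in ps
    }


@pytest.fixture(scope="session")
def dags3():
    return all_dags(3)


@pytest.fixture(scope="session")
def dags4():
    return all_dags(4)


@pytest.fixture
def coin_pair() -> BayesianNetwork:
    """Two independent fair binary coins."""
    variables = binary_vars(2)
    structure = NetworkStructure(variables, ((), ()))
    t = ConditionalTable
    return BayesianNetwork(
        structure, (t(0, np.array([[0.5, 0.5]])), t(1, np.array([[0.5, 0.5]])))
    )
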