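"""Random ground-truth networks and benchmark fixtures.

The simulation studies need known networks to sample data from.  Rather
than bundling published benchmark networks, this module generates
statistical look-alikes: random DAGs with a requested node count, edge
count, arity range (2-4 states by default) and per-row Dirichlet CPTs.
A small named suite of seeded fixtures ships with the package as BIF
files; regenerating a fixture from its seed reproduces the file
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .core import BayesianNetwork, ConditionalTable, NetworkStructure, VariableSpec
from .io import read_bif, write_bif

__all__ = [
    "GeneratorSpec",
    "random_network",
    "noisy_copy_chain",
    "noisy_copy_tree",
    "independence_network",
    "benchmark_suite",
    "load_fixture",
    "FIXTURE_SEEDS",
]

# seeds that generated the shipped fixture files
FIXTURE_SEEDS = {"alarm_like_37": 424246}


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape of a random ground-truth network.

    ``arity_range`` is inclusive; the default 2-4 states per node mirrors
    classic medical-diagnosis benchmarks.  ``cpt_concentration`` is the
    symmetric Dirichlet parameter for CPT rows: values below 1 give
    skewed rows, i.e. strong parent-child dependence.
    """

    n_nodes: int
    n_edges: int
    max_parents: int = 4
    arity_range: tuple[int, int] = (2, 4)
    cpt_concentration: float = 0.5

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_edges < 0:
            raise ValueError("need n_nodes >= 1 and n_edges >= 0")
        lo, hi = self.arity_range
        if lo < 2 or hi < lo:
            raise ValueError("arity_range must satisfy 2 <= lo <= hi")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")

    def max_feasible_edges(self) -> int:
        return sum(min(pos, self.max_parents) for pos in range(self.n_nodes))


def _random_cpt(q: int, r: int, conc: float, rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.full(r, conc), size=q)


def random_network(spec: GeneratorSpec, seed: int | np.random.Generator) -> BayesianNetwork:
    """A uniformly ordered random DAG with the requested edge count.

    A random topological order is drawn; edges are then added one at a
    time, uniformly over the currently admissible (order-respecting,
    parent-budget-respecting) slots, so the exact edge count is achieved
    whenever feasible.  CPT rows are i.i.d. symmetric Dirichlet.
    """
    if spec.n_edges > spec.max_feasible_edges():
        raise ValueError(
            f"{spec.n_edges} edges infeasible for {spec.n_nodes} nodes "
            f"with max_parents={spec.max_parents}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_nodes
    order = rng.permutation(n)  # order[pos] = node at topological position pos
    lo, hi = spec.arity_range
    arities = rng.integers(lo, hi + 1, size=n)
    parents: list[set[int]] = [set() for _ in range(n)]
    # admissible slots: (parent position, child position), parent earlier
    slots = [
        (pp, cp) for cp in range(n) for pp in range(cp)
    ]
    for _ in range(spec.n_edges):
        open_slots = [
            (pp, cp)
            for pp, cp in slots
            if order[pp] not in parents[order[cp]]
            and len(parents[order[cp]]) < spec.max_parents
        ]
        pp, cp = open_slots[int(rng.integers(len(open_slots)))]
        parents[int(order[cp])].add(int(order[pp]))

    variables = tuple(
        VariableSpec(f"X{i}", tuple(f"s{k}" for k in range(arities[i])))
        for i in range(n)
    )
    structure = NetworkStructure(
        variables, tuple(tuple(sorted(ps)) for ps in parents)
    )
    tables = []
    for i in range(n):
        q = structure.n_parent_configs(i)
        tables.append(
            ConditionalTable(i, _random_cpt(q, arities[i], spec.cpt_concentration, rng))
        )
    return BayesianNetwork(structure, tuple(tables))


def _noisy_copy_table(r: int, fidelity: float) -> np.ndarray:
    """CPT of a child that copies its parent with probability ``fidelity``."""
    off = (1.0 - fidelity) / (r - 1)
    t = np.full((r, r), off)
    np.fill_diagonal(t, fidelity)
    return t


def noisy_copy_chain(
    n_nodes: int = 4, fidelity: float = 0.9, arity: int = 2
) -> BayesianNetwork:
    """Binary-by-default chain X0 -> X1 -> ... with noisy-copy CPTs."""
    variables = tuple(
        VariableSpec(f"X{i}", tuple(f"s{k}" for k in range(arity)))
        for i in range(n_nodes)
    )
    parents = tuple(() if i == 0 else (i - 1,) for i in range(n_nodes))
    structure = NetworkStructure(variables, parents)
    tables = [ConditionalTable(0, np.full((1, arity), 1.0 / arity))]
    for i in range(1, n_nodes):
        tables.append(ConditionalTable(i, _noisy_copy_table(arity, fidelity)))
    return BayesianNetwork(structure, tuple(tables))


def mixed_strength_net4() -> BayesianNetwork:
    """4 binary nodes with deliberately heterogeneous edge strengths.

    Edges 0->1 (copy fidelity 0.95), 1->2 (0.72) and 0->3 (0.62) span
    strong to barely-detectable dependence, so posterior edge
    probabilities are well separated — useful when rank agreement
    between estimators is the quantity of interest.
    """
    variables = tuple(VariableSpec(f"X{i}", ("s0", "s1")) for i in range(4))
    structure = NetworkStructure(variables, ((), (0,), (1,), (0,)))
    tables = (
        ConditionalTable(0, np.array([[0.5, 0.5]])),
        ConditionalTable(1, _noisy_copy_table(2, 0.95)),
        ConditionalTable(2, _noisy_copy_table(2, 0.72)),
        ConditionalTable(3, _noisy_copy_table(2, 0.62)),
    )
    return BayesianNetwork(structure, tables)


def noisy_copy_tree(fidelity: float = 0.85) -> BayesianNetwork:
    """An 8-node binary out-tree (each child noisily copies its parent)."""
    edges = [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6), (3, 7)]
    parents: list[tuple[int, ...]] = [()] * 8
    for p, c in edges:
        parents[c] = (p,)
    variables = tuple(VariableSpec(f"X{i}", ("s0", "s1")) for i in range(8))
    structure = NetworkStructure(variables, tuple(parents))
    tables = [ConditionalTable(0, np.array([[0.5, 0.5]]))]
    for i in range(1, 8):
        tables.append(ConditionalTable(i, _noisy_copy_table(2, fidelity)))
    return BayesianNetwork(structure, tuple(tables))


def independence_network(n_nodes: int = 6, arity: int = 2) -> BayesianNetwork:
    """No edges: every variable uniform and independent (a null model)."""
    variables = tuple(
        VariableSpec(f"X{i}", tuple(f"s{k}" for k in range(arity)))
        for i in range(n_nodes)
    )
    structure = NetworkStructure(variables, tuple(() for _ in range(n_nodes)))
    tables = tuple(
        ConditionalTable(i, np.full((1, arity), 1.0 / arity)) for i in range(n_nodes)
    )
    return BayesianNetwork(structure, tables)


def _build_fixture(name: str) -> BayesianNetwork:
    if name == "chain4":
        return noisy_copy_chain(4, fidelity=0.9)
    if name == "tree8":
        return noisy_copy_tree(fidelity=0.85)
    if name == "alarm_like_37":
        spec = GeneratorSpec(
            n_nodes=37, n_edges=46, max_parents=3, arity_range=(2, 4)
        )
        return random_network(spec, FIXTURE_SEEDS[name])
    raise KeyError(f"unknown fixture {name!r}")


FIXTURE_NAMES = ("chain4", "tree8", "alarm_like_37")


def benchmark_suite() -> dict[str, BayesianNetwork]:
    """The named seeded fixtures, rebuilt from their generating recipes."""
    return {name: _build_fixture(name) for name in FIXTURE_NAMES}


def load_fixture(name: str) -> BayesianNetwork:
    """Load a shipped fixture from its BIF file."""
    ref = resources.files("bnbag") / "fixtures" / f"{name}.bif"
    with resources.as_file(ref) as path:
        return read_bif(path)


def write_fixture_files(directory: str | Path) -> None:
    """Regenerate the shipped BIF fixture files (maintenance helper)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, bn in benchmark_suite().items():
        write_bif(bn, directory / f"{name}.bif", name=name)
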