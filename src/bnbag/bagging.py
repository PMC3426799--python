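"""Bootstrap aggregation (bagging) of edge features.

For each of ``B`` resamples: draw case weights, learn structure(s) by
sparse-candidate search on the re-weighted data, and record which
directed edges appear.  Three aggregation modes are supported:

``single_best``
    The indicator features of the single top-scoring structure.
``double_simple``
    The unweighted mean of indicators over the ``top_m`` distinct
    top structures of the resample (double averaging).
``double_bayesian``
    The mean weighted by each retained structure's normalized posterior
    weight ``exp(score - max score)`` (a Bayesian average within the
    resample, before bagging across resamples).

The final edge-probability matrix is the mean over resamples.  Per-edge
direction frequencies are retained for reporting, but downstream
thresholding and evaluation use the undirected sum of both directions.

Reproducibility: one root seed spawns an independent child seed per
resample, so results are identical whether resamples run serially or in
parallel, and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .core import DataTable
from .resampling import draw_weights
from .scoring import ScoreConfig
from .search import ParentsTuple, SearchConfig, sparse_candidate_search

__all__ = ["BaggingConfig", "EdgeProbabilityMatrix", "bag_structures"]

MODES = ("single_best", "double_simple", "double_bayesian")


@dataclass(frozen=True)
class BaggingConfig:
    """Number of resamples, bootstrap flavor, and aggregation mode."""

    n_resamples: int = 2500
    bootstrap_type: str = "bayesian"
    mode: str = "single_best"
    top_m: int = 10

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.bootstrap_type not in ("ordinary", "bayesian"):
            raise ValueError("bootstrap_type must be 'ordinary' or 'bayesian'")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")


@dataclass(frozen=True)
class EdgeProbabilityMatrix:
    """Bagged edge frequencies: per-direction and undirected views.

    ``directed[a, b]`` is the bagged frequency of the directed edge
    ``a -> b``; the undirected frequency of the pair is the sum of both
    directions (they are mutually exclusive within any one DAG, so the
    sum stays within [0, 1]).
    """

    directed: np.ndarray  # (n, n), zero diagonal
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.directed, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("directed matrix must be square")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if d.min() < 0 or (d + d.T).max() > 1 + 1e-9:
            raise ValueError("frequencies must lie in [0, 1]")
        object.__setattr__(self, "directed", d)

    @property
    def n(self) -> int:
        return self.directed.shape[0]

    @property
    def undirected(self) -> np.ndarray:
        return self.directed + self.directed.T

    def pair_values(self) -> np.ndarray:
        """Upper-triangle undirected frequencies, row-major pair order."""
        u = self.undirected
        iu = np.triu_indices(self.n, k=1)
        return u[iu]


def _indicator(parents: ParentsTuple, n: int) -> np.ndarray:
    a = np.zeros((n, n))
    for child, ps in enumerate(parents):
        for p in ps:
            a[p, child] = 1.0
    return a


def _aggregate_resample(
    networks: tuple[tuple[ParentsTuple, float], ...],
    n: int,
    mode: str,
    top_m: int,
) -> np.ndarray:
    """Per-resample directed feature probabilities under one mode."""
    kept = networks[: 1 if mode == "single_best" else top_m]
    if mode == "double_bayesian":
        scores = np.array([s for _, s in kept])
        w = np.exp(scores - scores.max())
        w /= w.sum()
    else:
        w = np.full(len(kept), 1.0 / len(kept))
    out = np.zeros((n, n))
    for (parents, _), wt in zip(kept, w):
        out += wt * _indicator(parents, n)
    return out


def _one_resample(
    data: DataTable,
    index: int,
    child_seed: np.random.SeedSequence,
    bagging: BaggingConfig,
    score_config: ScoreConfig,
    search_config: SearchConfig,
) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(child_seed)
    weights = draw_weights(bagging.bootstrap_type, data.n_cases, rng)
    try:
        result = sparse_candidate_search(
            data, weights, score_config, search_config, rng
        )
    except Exception as exc:  # surface which resample broke
        raise RuntimeError(f"structure search failed on resample {index}") from exc
    mat = _aggregate_resample(result.networks, data.n_vars, bagging.mode, bagging.top_m)
    record = {
        "best_score": result.best_score,
        "n_evaluated": result.n_evaluated,
        "n_retained": min(
            len(result.networks), 1 if bagging.mode == "single_best" else bagging.top_m
        ),
    }
    return mat, record


def bag_structures(
    data: DataTable,
    bagging_config: BaggingConfig,
    score_config: ScoreConfig,
    search_config: SearchConfig,
    seed: int | np.random.SeedSequence = 0,
    n_jobs: int = 1,
) -> tuple[EdgeProbabilityMatrix, list[dict]]:
    """Run the full bagging loop; returns (edge probabilities, records).

    ``records`` holds one dict per resample (best score, search effort,
    structures retained) in resample order.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(bagging_config.n_resamples)
    if n_jobs == 1:
        results = [
            _one_resample(data, i, cs, bagging_config, score_config, search_config)
            for i, cs in enumerate(children)
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_resample)(
                data, i, cs, bagging_config, score_config, search_config
            )
            for i, cs in enumerate(children)
        )
    total = np.zeros((data.n_vars, data.n_vars))
    records = []
    for mat, rec in results:
        total += mat
        records.append(rec)
    names = tuple(v.name for v in data.variables)
    directed = total / bagging_config.n_resamples
    # guard against fp drift pushing a pair sum over 1
    return EdgeProbabilityMatrix(np.clip(directed, 0.0, 1.0), names), records
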