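"""Scoring learned edge probabilities against a known reference network.

Edge direction is not assessed: a pair of variables counts as connected
when the sum of its two directed bagged frequencies reaches the
threshold, and the reference is reduced to its undirected skeleton.  An
edge whose frequency is exactly the threshold counts as present (the
``>= t`` convention, fixed globally across the package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bagging import BaggingConfig, EdgeProbabilityMatrix, bag_structures
from .core import BayesianNetwork, NetworkStructure, forward_sample
from .scoring import ScoreConfig
from .search import SearchConfig

__all__ = [
    "EvaluationCurve",
    "confusion_at_threshold",
    "tradeoff_curve",
    "replicate_experiment",
    "average_curves",
]


@dataclass(frozen=True)
class EvaluationCurve:
    """Per-threshold confusion counts over all unordered variable pairs."""

    grid: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tp: np.ndarray
    tn: np.ndarray

    @property
    def total_errors(self) -> np.ndarray:
        return self.fp + self.fn

    @property
    def min_total_errors(self) -> float:
        return float(self.total_errors.min())


def _reference_mask(reference: NetworkStructure) -> np.ndarray:
    n = reference.n
    adj = np.zeros((n, n), dtype=bool)
    for p, c in reference.edges():
        adj[p, c] = adj[c, p] = True
    return adj[np.triu_indices(n, k=1)]


def confusion_at_threshold(
    P: EdgeProbabilityMatrix,
    reference: NetworkStructure,
    threshold: float,
) -> tuple[float, float, float, float]:
    """(FP, FN, TP, TN) at one threshold.

    FP: pair present (frequency >= t) but absent from the reference
    skeleton.  FN: reference pair with frequency < t.
    """
    if P.n != reference.n:
        raise ValueError("probability matrix and reference differ in variable count")
    present = P.pair_values() >= threshold
    truth = _reference_mask(reference)
    fp = float(np.sum(present & ~truth))
    fn = float(np.sum(~present & truth))
    tp = float(np.sum(present & truth))
    tn = float(np.sum(~present & ~truth))
    return fp, fn, tp, tn


def tradeoff_curve(
    P: EdgeProbabilityMatrix,
    reference: NetworkStructure,
    grid: np.ndarray | None = None,
) -> EvaluationCurve:
    """Evaluate the confusion counts over a threshold grid."""
    if grid is None:
        grid = np.round(np.arange(0.0, 1.005, 0.01), 10)
    rows = np.array([confusion_at_threshold(P, reference, t) for t in grid])
    return EvaluationCurve(grid, rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3])


def average_curves(curves: list[EvaluationCurve]) -> EvaluationCurve:
    """Pointwise mean of curves sharing a grid."""
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.array_equal(c.grid, grid):
            raise ValueError("curves must share a threshold grid")
    stack = lambda attr: np.mean([getattr(c, attr) for c in curves], axis=0)
    return EvaluationCurve(grid, stack("fp"), stack("fn"), stack("tp"), stack("tn"))


def replicate_experiment(
    ground_truth: BayesianNetwork,
    n_datasets: int,
    n_cases: int,
    bagging_config: BaggingConfig,
    score_config: ScoreConfig,
    search_config: SearchConfig,
    seed: int | np.random.SeedSequence = 0,
    grid: np.ndarray | None = None,
    n_jobs: int = 1,
) -> tuple[EvaluationCurve, list[EvaluationCurve], dict]:
    """Full simulation protocol: sample datasets, bag each, average curves.

    Each replicate draws an independent dataset from the ground truth,
    runs the bagging pipeline, and scores the result against the true
    skeleton; curves are averaged pointwise.  Returns the averaged
    curve, the per-replicate curves, and a manifest of the child seeds
    used, so any replicate can be reproduced in isolation.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    curves = []
    manifest: dict = {"root_entropy": ss.entropy, "replicates": []}
    for i, child in enumerate(ss.spawn(n_datasets)):
        data_seed, bag_seed = child.spawn(2)
        data = forward_sample(
            ground_truth, n_cases, np.random.default_rng(data_seed)
        )
        P, _ = bag_structures(
            data, bagging_config, score_config, search_config, bag_seed, n_jobs
        )
        curves.append(tradeoff_curve(P, ground_truth.structure, grid))
        manifest["replicates"].append(
            {
                "index": i,
                "data_seed": data_seed.spawn_key,
                "bag_seed": bag_seed.spawn_key,
            }
        )
    return average_curves(curves), curves, manifest


def plot_tradeoff(curves: dict[str, EvaluationCurve], path=None):
    """FP-vs-FN tradeoff plot plus total errors vs threshold (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 8))
    for label, c in curves.items():
        ax1.plot(c.fp, c.fn, label=label)
        ax2.plot(c.grid, c.total_errors, label=label)
    ax1.set_xlabel("false positives")
    ax1.set_ylabel("false negatives")
    ax2.set_xlabel("threshold")
    ax2.set_ylabel("total errors (FP + FN)")
    ax1.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
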