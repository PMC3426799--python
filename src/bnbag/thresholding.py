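"""Permutation-null threshold selection for bagged edge features.

Bagging produces an edge frequency in [0, 1] for every variable pair,
and a final model needs a global inclusion threshold.  The null model
here is data whose columns have been independently permuted: marginals
are preserved exactly while every inter-variable dependence is
destroyed.  Bagging permuted data still finds edges by chance, and the
count of null edges above a threshold estimates (conservatively) the
number of incorrect edges above that threshold in the real run.

From the observed count ``t_f`` (edges at frequency >= f) and the
permutation-average ``p_f``, an edge confidence is derived from the
local slopes: among edges arriving at frequency f, the fraction not
attributable to the null is ``1 - dp_f / dt_f``.  Slopes are smoothed by
averaging centered finite differences over several widths, the ratio is
clipped to [0, 1], and a monotone envelope is applied so confidence
never increases as the threshold decreases.  The selected threshold is
the smallest grid value whose confidence reaches the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bagging import BaggingConfig, EdgeProbabilityMatrix, bag_structures
from .core import DataTable
from .scoring import ScoreConfig
from .search import SearchConfig

__all__ = [
    "ThresholdCurves",
    "ConsensusResult",
    "DEFAULT_WIDTHS",
    "permute_dataset",
    "edges_above_threshold",
    "permutation_null_curve",
    "edge_confidence",
    "build_threshold_curves",
    "select_threshold",
]

DEFAULT_WIDTHS = (0.02, 0.04, 0.06, 0.08, 0.10)


@dataclass(frozen=True)
class ThresholdCurves:
    """Edge counts and derived confidence on a common threshold grid."""

    grid: np.ndarray  # thresholds f, ascending
    t_f: np.ndarray  # observed edge count at frequency >= f
    p_f: np.ndarray  # permutation-null mean edge count
    d_f: np.ndarray  # t_f - p_f
    l_f: np.ndarray  # monotone edge confidence in [0, 1]


@dataclass(frozen=True)
class ConsensusResult:
    """Selected threshold and the edges it admits."""

    threshold: float | None
    edges: tuple[tuple[int, int, float, float], ...]  # (a, b, freq, confidence)
    diagnostic: str = ""


def permute_dataset(data: DataTable, rng: np.random.Generator | int) -> DataTable:
    """Independently permute each column (exact marginals, no dependence)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = data.values.copy()
    for i in range(data.n_vars):
        out[:, i] = out[rng.permutation(data.n_cases), i]
    return DataTable(data.variables, out)


def default_grid(step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def edges_above_threshold(P: EdgeProbabilityMatrix, grid: np.ndarray) -> np.ndarray:
    """Count of undirected edges with bagged frequency >= f, per grid f."""
    vals = P.pair_values()
    return np.array([(vals >= f).sum() for f in grid], dtype=float)


def permutation_null_curve(
    data: DataTable,
    n_perm: int,
    bagging_config: BaggingConfig,
    score_config: ScoreConfig,
    search_config: SearchConfig,
    seed: int | np.random.SeedSequence = 0,
    grid: np.ndarray | None = None,
    n_jobs: int = 1,
) -> np.ndarray:
    """Mean null edge-count curve over ``n_perm`` permuted replicates."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = default_grid()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    total = np.zeros_like(grid, dtype=float)
    for child in ss.spawn(n_perm):
        perm_seed, bag_seed = child.spawn(2)
        permuted = permute_dataset(data, np.random.default_rng(perm_seed))
        P, _ = bag_structures(
            permuted, bagging_config, score_config, search_config, bag_seed, n_jobs
        )
        total += edges_above_threshold(P, grid)
    return total / n_perm


def _smoothed_slope(curve: np.ndarray, grid: np.ndarray, widths) -> np.ndarray:
    """Mean magnitude of centered finite differences over several widths.

    Curves here are non-increasing in f, so the slope magnitude at index
    i and width w is (curve[i-m] - curve[i+m]) / span.  Indices below
    the grid clamp to the bottom (one-sided difference); indices above
    the top read as 0, because no edge frequency can exceed 1 — this
    lets a cluster of saturated edges sitting exactly at f = 1
    contribute its arrival slope at the top of the grid.
    """
    step = float(grid[1] - grid[0])
    n = len(grid)
    slopes = np.zeros(n)
    for i in range(n):
        acc, cnt = 0.0, 0
        for w in widths:
            m = max(1, round(w / step))
            lo, hi = max(0, i - m), i + m
            hi_val = curve[hi] if hi < n else 0.0
            span = (hi - lo) * step
            if span <= 0:
                continue
            acc += (curve[lo] - hi_val) / span
            cnt += 1
        slopes[i] = acc / cnt if cnt else 0.0
    return slopes


def edge_confidence(
    t_curve: np.ndarray,
    p_curve: np.ndarray,
    grid: np.ndarray,
    widths=DEFAULT_WIDTHS,
) -> np.ndarray:
    """Confidence L_f that an edge arriving at frequency f is real.

    Raw value ``1 - dp_f/dt_f`` (0 where the observed slope vanishes),
    clipped to [0, 1], then replaced by its running maximum in ascending
    f — the minimal upper envelope under which confidence never
    increases as the threshold decreases.

    Confidence is additionally forced to 0 wherever the excess edge
    count ``t_f - p_f`` is non-positive: there the permutation estimate
    already accounts for every edge above f, so no marginal edge at f
    can be credited as real no matter what the local slopes do.  (On
    structured data the excess is strongly positive in the region of
    interest, so this guard only matters near the null.)
    """
    t_curve = np.asarray(t_curve, float)
    p_curve = np.asarray(p_curve, float)
    if t_curve.shape != grid.shape or p_curve.shape != grid.shape:
        raise ValueError("curves and grid must share a common shape")
    dt = _smoothed_slope(t_curve, grid, widths)
    dp = _smoothed_slope(p_curve, grid, widths)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(dt > 0, 1.0 - dp / np.where(dt > 0, dt, 1.0), 0.0)
    raw = np.where(t_curve - p_curve > 0, raw, 0.0)
    raw = np.clip(raw, 0.0, 1.0)
    return np.maximum.accumulate(raw)


def build_threshold_curves(
    data: DataTable,
    bagging_config: BaggingConfig,
    score_config: ScoreConfig,
    search_config: SearchConfig,
    n_perm: int = 60,
    seed: int | np.random.SeedSequence = 0,
    grid_step: float = 0.01,
    widths=DEFAULT_WIDTHS,
    null_bagging_config: BaggingConfig | None = None,
    n_jobs: int = 1,
) -> tuple[ThresholdCurves, EdgeProbabilityMatrix]:
    """Bag the observed data, bag permuted replicates, derive curves.

    ``null_bagging_config`` optionally runs the permutations at a reduced
    resample budget as a cost knob; by default the null reuses the main
    bagging configuration.
    """
    grid = default_grid(grid_step)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    main_seed, null_seed = ss.spawn(2)
    P, _ = bag_structures(
        data, bagging_config, score_config, search_config, main_seed, n_jobs
    )
    t_f = edges_above_threshold(P, grid)
    p_f = permutation_null_curve(
        data,
        n_perm,
        null_bagging_config or bagging_config,
        score_config,
        search_config,
        null_seed,
        grid,
        n_jobs,
    )
    l_f = edge_confidence(t_f, p_f, grid, widths)
    curves = ThresholdCurves(grid, t_f, p_f, t_f - p_f, l_f)
    return curves, P


def select_threshold(
    curves: ThresholdCurves,
    P: EdgeProbabilityMatrix,
    target_confidence: float = 0.9,
) -> ConsensusResult:
    """Smallest grid threshold whose confidence reaches the target.

    Edges with bagged frequency >= that threshold form the consensus
    set; each is annotated with the confidence at its own frequency.
    """
    if not 0.0 < target_confidence <= 1.0:
        raise ValueError("target_confidence must lie in (0, 1]")
    ok = np.nonzero(curves.l_f >= target_confidence)[0]
    if len(ok) == 0:
        return ConsensusResult(
            None,
            (),
            diagnostic=(
                f"no threshold reaches confidence {target_confidence}; "
                f"max attained {curves.l_f.max():.3f}"
            ),
        )
    idx = int(ok[0])
    thr = float(curves.grid[idx])
    und = P.undirected
    edges = []
    for a in range(P.n):
        for b in range(a + 1, P.n):
            freq = und[a, b]
            if freq >= thr and freq > 0:
                pos = int(np.searchsorted(curves.grid, freq, side="right")) - 1
                edges.append((a, b, float(freq), float(curves.l_f[pos])))
    return ConsensusResult(thr, tuple(edges))
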