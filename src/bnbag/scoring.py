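"""Decomposable scoring metrics for discrete Bayesian networks.

All five metrics score a structure as a sum over families (a child plus
its parent set), and every family score is a function of the weighted
sufficient statistics ``N_ijk``: the total case weight with child ``i``
in state ``k`` and its parents in joint configuration ``j``.  Using
weighted counts lets one code path serve the original data (unit
weights), ordinary bootstrap resamples (multinomial integer weights) and
Bayesian bootstrap resamples (continuous Dirichlet weights).

Metrics (all returned as natural-log scores, higher is better):

``k2`` (UPSM)
    Bayesian-Dirichlet marginal likelihood with a uniform prior,
    ``alpha_ijk = 1``.
``dpsm``
    Dirichlet Prior Scoring Metric: ``alpha_ijk = lambda`` for every
    parameter.  ``lambda = 1`` recovers K2 exactly; small ``lambda``
    (default 0.1) is deliberately promiscuous — it readily adds edges,
    which is what makes it effective inside bagging.
``bde``
    Likelihood-equivalent Bayesian-Dirichlet score (the BDeu choice):
    ``alpha_ijk = N' / (r_i q_i)`` with equivalent sample size ``N'``
    (default 1).
``bic``
    Maximized log-likelihood minus ``(d/2) ln N`` with
    ``d = (r_i - 1) q_i`` free parameters per family.
``mdl``
    Negated description length of graph + parameters + data, in bits;
    see :func:`family_log_score` for the exact encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, xlogy

from .core import DataTable, NetworkStructure, parent_config_index

__all__ = [
    "ScoreConfig",
    "FamilyCounts",
    "validate_weights",
    "family_counts",
    "family_log_score",
    "free_parameter_count",
    "NetworkScorer",
    "network_log_score",
]

METRICS = ("k2", "dpsm", "bde", "bic", "mdl")
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoreConfig:
    """Choice of metric and its hyperparameters.

    Parameters
    ----------
    metric:
        One of ``k2``, ``dpsm``, ``bde``, ``bic``, ``mdl``.
    lam:
        Dirichlet order for DPSM (every prior count set to this constant).
    ess:
        Equivalent sample size ``N'`` for BDe.
    """

    metric: str = "dpsm"
    lam: float = 0.1
    ess: float = 1.0

    def __post_init__(self) -> None:
        m = self.metric.lower()
        if m not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        object.__setattr__(self, "metric", m)
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.ess <= 0:
            raise ValueError("ess must be > 0")


@dataclass(frozen=True)
class FamilyCounts:
    """Weighted sufficient statistics for one child-parents family."""

    child: int
    parents: tuple[int, ...]
    n_ijk: np.ndarray  # shape (q_i, r_i)
    total: float  # total case-weight mass N

    @property
    def n_ij(self) -> np.ndarray:
        return self.n_ijk.sum(axis=1)


def validate_weights(weights: np.ndarray, n_cases: int, tol: float = 1e-6) -> np.ndarray:
    """Check a case-weight vector: nonnegative, length N, total mass N."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_cases,):
        raise ValueError(f"weights must have length {n_cases}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - n_cases) > tol * max(1.0, n_cases):
        raise ValueError("weights must sum to the number of cases")
    return w


def family_counts(
    data: DataTable,
    weights: np.ndarray | None,
    child: int,
    parents: Sequence[int],
) -> FamilyCounts:
    """Accumulate weighted counts ``N_ijk`` for one family.

    ``weights=None`` means unit weights.  Parent configurations use the
    package-wide mixed-radix convention from :mod:`bnbag.core`.
    """
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError("a variable cannot be its own parent")
    arities = data.arities
    r = arities[child]
    q = 1
    for p in parents:
        q *= arities[p]
    j = parent_config_index(data.values, parents, arities)
    idx = j * r + data.values[:, child]
    if weights is None:
        counts = np.bincount(idx, minlength=q * r).astype(float)
        total = float(data.n_cases)
    else:
        counts = np.bincount(idx, weights=weights, minlength=q * r)
        total = float(np.sum(weights))
    return FamilyCounts(child, parents, counts.reshape(q, r), total)


def free_parameter_count(structure: NetworkStructure) -> int:
    """d = sum_i (r_i - 1) q_i, the free parameters of the CPTs."""
    return sum(
        (structure.variables[i].arity - 1) * structure.n_parent_configs(i)
        for i in range(structure.n)
    )


def _dirichlet_family_score(n_ijk: np.ndarray, alpha_ijk: float) -> float:
    """Log Bayesian-Dirichlet marginal likelihood of one family.

    sum_j [ lnG(a_ij) - lnG(a_ij + N_ij) + sum_k ( lnG(a_ijk + N_ijk)
    - lnG(a_ijk) ) ] with constant prior count ``alpha_ijk`` per cell.
    """
    q, r = n_ijk.shape
    a_ij = alpha_ijk * r
    n_ij = n_ijk.sum(axis=1)
    score = q * gammaln(a_ij) - gammaln(a_ij + n_ij).sum()
    score += gammaln(alpha_ijk + n_ijk).sum() - q * r * gammaln(alpha_ijk)
    return float(score)


def _family_log_likelihood(n_ijk: np.ndarray) -> float:
    """Maximized log-likelihood sum_jk N_ijk ln(N_ijk / N_ij); 0*ln0 = 0."""
    n_ij = n_ijk.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_ij > 0, n_ijk / np.where(n_ij > 0, n_ij, 1.0), 0.0)
    return float(xlogy(n_ijk, ratio).sum())


def family_log_score(
    counts: FamilyCounts,
    config: ScoreConfig,
    arity: int,
    n_vars: int,
) -> float:
    """Score one family under the configured metric (higher is better).

    ``arity`` is r_i of the child; ``n_vars`` is the total number of
    variables (needed only by MDL's graph-encoding term).  Fractional
    counts are handled throughout via log-gamma / x·log x forms.
    """
    n_ijk = counts.n_ijk
    q = n_ijk.shape[0]
    m = config.metric
    if m == "k2":
        return _dirichlet_family_score(n_ijk, 1.0)
    if m == "dpsm":
        return _dirichlet_family_score(n_ijk, config.lam)
    if m == "bde":
        return _dirichlet_family_score(n_ijk, config.ess / (arity * q))
    d_family = (arity - 1) * q
    ll = _family_log_likelihood(n_ijk)
    n_total = max(counts.total, 1.0)
    if m == "bic":
        return ll - 0.5 * d_family * math.log(n_total)
    # mdl: description length of parent list + parameters + data, in bits,
    # returned negated so higher is better
    dl_graph = len(counts.parents) * (math.log2(n_vars) if n_vars > 1 else 0.0)
    dl_params = 0.5 * math.log2(n_total) * d_family
    dl_data = -ll / _LN2
    return -(dl_graph + dl_params + dl_data)


class NetworkScorer:
    """Memoized family scoring bound to one (data, weights, config) triple.

    Greedy search rescopes the same families thousands of times; caching
    per (child, parent-set) makes rescoring a one-edge move O(1) families.
    A fresh scorer must be built whenever the weights change (e.g. per
    bootstrap resample).
    """

    def __init__(
        self,
        data: DataTable,
        weights: np.ndarray | None,
        config: ScoreConfig,
    ) -> None:
        self.data = data
        self.weights = (
            None if weights is None else validate_weights(weights, data.n_cases)
        )
        self.config = config
        self.n_vars = data.n_vars
        self._arities = data.arities
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self.n_family_evals = 0

    def family_score(self, child: int, parents: Sequence[int]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts = family_counts(self.data, self.weights, child, key[1])
        score = family_log_score(
            counts, self.config, self._arities[child], self.n_vars
        )
        self._cache[key] = score
        self.n_family_evals += 1
        return score

    def structure_score(self, parents: Sequence[Sequence[int]]) -> float:
        return sum(self.family_score(i, ps) for i, ps in enumerate(parents))


def network_log_score(
    data: DataTable,
    weights: np.ndarray | None,
    structure: NetworkStructure | Sequence[Sequence[int]],
    config: ScoreConfig,
) -> float:
    """Total log-score of a structure: the sum of its family scores."""
    parents = (
        structure.parents if isinstance(structure, NetworkStructure) else structure
    )
    return NetworkScorer(data, weights, config).structure_score(parents)
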