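"""Bootstrap case-weight generation and the resample-count bound.

Both resampling schemes are expressed as per-case weights with total
mass ``N``, so the weighted scoring machinery is oblivious to which one
produced them:

* Ordinary bootstrap: integer weights from Multinomial(N, 1/N) — the
  number of times each case appears in a same-size resample drawn with
  replacement.  Roughly a fraction 1/e (about 37%) of cases receive
  weight zero in each resample.
* Bayesian bootstrap: continuous weights ``N * g`` with ``g`` drawn from
  a flat Dirichlet(1, ..., 1).  Almost surely no case is dropped, so the
  discreteness bias of the ordinary bootstrap is avoided while every
  case is still randomly re-weighted.

Treating each resample's feature indicator as a 0/1 Bernoulli draw with
success probability ``p``, the bagged feature probability over ``B``
resamples has variance ``p(1-p)/B`` (at most ``0.25/B``), which yields a
closed-form bound on how many resamples a target standard deviation
requires.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "ordinary_bootstrap_weights",
    "bayesian_bootstrap_weights",
    "draw_weights",
    "resample_variance_bound",
    "required_resamples",
]


def ordinary_bootstrap_weights(n_cases: int, rng: np.random.Generator) -> np.ndarray:
    """Integer occurrence counts of each case in one with-replacement resample."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return rng.multinomial(n_cases, np.full(n_cases, 1.0 / n_cases)).astype(float)


def bayesian_bootstrap_weights(n_cases: int, rng: np.random.Generator) -> np.ndarray:
    """Continuous Dirichlet(1,...,1) weights scaled to total mass ``n_cases``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if n_cases == 1:
        return np.ones(1)
    return n_cases * rng.dirichlet(np.ones(n_cases))


def draw_weights(
    bootstrap_type: str, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    if bootstrap_type == "ordinary":
        return ordinary_bootstrap_weights(n_cases, rng)
    if bootstrap_type == "bayesian":
        return bayesian_bootstrap_weights(n_cases, rng)
    raise ValueError(f"unknown bootstrap type {bootstrap_type!r}")


def resample_variance_bound(p: float, n_resamples: int) -> float:
    """Variance p(1-p)/B of a bagged 0/1 feature probability."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    return p * (1.0 - p) / n_resamples


def required_resamples(p: float, sigma: float) -> int:
    """Smallest B with sqrt(p(1-p)/B) <= sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return int(math.ceil(p * (1.0 - p) / sigma**2))
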