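"""Rank correlation with ties and permutation p-values.

Spearman's rho is the Pearson correlation of mid-ranks (ties get average
ranks). Significance uses permutation tests rather than the t
approximation: exact enumeration of all n! pairings for n <= 9, and a
seeded Monte-Carlo permutation test with the add-one estimator
``(b + 1) / (n_perm + 1)`` otherwise. Tied ranks at the small n typical of
character tables make the asymptotic approximation poor, and permutation
results are exactly reproducible given the seed.
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["spearman_rho", "two_tailed_p"]

#: |rho_perm| >= |rho_obs| comparisons use this slack against float noise.
_TIE_EPS = 1e-12

EXACT_MAX_N = 9


def _as_array(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(xa) < 3:
        raise ValueError(f"need n >= 3, got n = {len(xa)}")
    return xa, ya


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Returns NaN — never a silent 0 — when either vector has zero rank
    variance; raises for n < 3.
    """
    xa, ya = _as_array(x, y)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return float("nan")
    rho = sps.spearmanr(xa, ya).statistic
    return float(rho)


def _rho_against_perms(
    rank_x: np.ndarray, perm_rank_y: np.ndarray
) -> np.ndarray:
    """Pearson correlation of fixed rank_x against each row of permuted ranks."""
    n = len(rank_x)
    cx = rank_x - rank_x.mean()
    cy = perm_rank_y - perm_rank_y.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(cx @ cx)) * np.sqrt((cy * cy).sum(axis=1))
    return (cy @ cx) / denom


def two_tailed_p(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-tailed permutation p-value for Spearman's rho.

    ``method`` is ``exact`` (all n! permutations; refused for n > 9),
    ``monte_carlo`` (``n_perm`` seeded resamples of y, add-one estimator),
    or ``auto`` (exact when n <= 9). Returns NaN when rho is undefined
    (zero rank variance).
    """
    xa, ya = _as_array(x, y)
    n = len(xa)
    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "monte_carlo"
    if method not in ("exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and n > EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration refused for n = {n} > {EXACT_MAX_N}; "
            "use method='monte_carlo'"
        )
    obs = spearman_rho(xa, ya)
    if math.isnan(obs):
        return float("nan")
    rank_x = sps.rankdata(xa)
    rank_y = sps.rankdata(ya)

    if method == "exact":
        perms = np.array(list(permutations(rank_y)), dtype=float)
        rhos = _rho_against_perms(rank_x, perms)
        hits = int(np.count_nonzero(np.abs(rhos) >= abs(obs) - _TIE_EPS))
        return hits / len(perms)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(rank_y, (n_perm, n)).copy(), axis=1
    )
    rhos = _rho_against_perms(rank_x, perms)
    b = int(np.count_nonzero(np.abs(rhos) >= abs(obs) - _TIE_EPS))
    return (b + 1) / (n_perm + 1)
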