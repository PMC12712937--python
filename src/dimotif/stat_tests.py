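"""The three statistical procedures the pipeline relies on.

Hypergeometric set enrichment (exact integer summation), Benjamini-Hochberg
step-up adjustment (delegated to statsmodels), and Mann-Whitney U with an
exact midrank-enumeration path for small samples and a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["HypergeomSpec", "hypergeom_tail", "bh_adjust", "mann_whitney"]


@dataclass(frozen=True)
class HypergeomSpec:
    """Counts for an enrichment test: draw n from N containing K successes,
    observe k successes."""

    N_pop: int
    K_succ: int
    n_draw: int
    k_obs: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k_obs <= min(self.K_succ, self.n_draw)
            and self.n_draw <= self.N_pop
            and self.K_succ <= self.N_pop
        )
        if not ok:
            raise ValueError(f"inconsistent hypergeometric counts: {self}")


def hypergeom_tail(spec: HypergeomSpec) -> float:
    """Upper-tail P(X >= k_obs) under hypergeometric(N, K, n), exact.

    Summed with integer binomial coefficients so the result is the correctly
    rounded float of an exact rational.
    """
    N, K, n, k = spec.N_pop, spec.K_succ, spec.n_draw, spec.k_obs
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / comb(N, n)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    U is the statistic of ``x`` computed from midranks, so ties contribute
    half counts.  ``mode='exact'`` enumerates all pooled rank assignments
    (chosen automatically for n_x + n_y <= 20); otherwise the tie-corrected
    normal approximation is used.  The exact two-sided p is the probability
    of a U at least as far from its null mean n_x*n_y/2 as observed.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if len(x) + len(y) <= 20 else "normal"

    u_obs = _u_midrank(x, y)
    if mode == "normal":
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return u_obs, float(p)

    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu)
    if len(set(pooled)) == len(pooled):
        # tie-free: exact null distribution of the rank sum by counting
        # subsets of {1..N} of size nx with each possible sum
        return u_obs, _exact_p_tiefree(nx, ny, dev)
    if nx + ny > 24:
        raise ValueError(
            "exact mode with ties is limited to 24 pooled observations"
        )
    ranks = _midranks(pooled)
    total = comb(nx + ny, nx)
    hits = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        u = sum(ranks[i] for i in idx) - nx * (nx + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def _exact_p_tiefree(nx: int, ny: int, dev: float) -> float:
    """P(|U - nx*ny/2| >= dev) by dynamic programming over rank subsets."""
    N = nx + ny
    max_u = nx * ny
    # f[k][u]: subsets of size k with U statistic u, built rank by rank
    f = np.zeros((nx + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, nx), 0, -1):
            # adding rank r as the k-th smallest contributes u += r - k
            shift = r - k
            if shift == 0:
                f[k, :] += f[k - 1, :]
            elif shift <= max_u:
                f[k, shift:] += f[k - 1, :max_u + 1 - shift]
    counts = f[nx]
    mu = max_u / 2.0
    us = np.arange(max_u + 1)
    hits = counts[np.abs(us - mu) >= dev - 1e-12].sum()
    return float(hits / counts.sum())


def _midranks(sorted_vals: list[float]) -> list[float]:
    ranks = [0.0] * len(sorted_vals)
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[k] = mid
        i = j + 1
    return ranks


def _u_midrank(x: list[float], y: list[float]) -> float:
    pooled = sorted(x + y)
    ranks = _midranks(pooled)
    # map values to ranks, consuming duplicates in order
    from collections import defaultdict, deque

    by_val: dict[float, deque] = defaultdict(deque)
    for v, r in zip(pooled, ranks):
        by_val[v].append(r)
    rx = sum(by_val[v].popleft() for v in sorted(x))
    return rx - len(x) * (len(x) + 1) / 2.0
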