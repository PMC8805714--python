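"""Benjamini–Hochberg FDR control and lambda-0 q-values over a test grid.

The design fixes the number of tests ``m`` a priori (tissues x outcomes:
16 for the longevity grids, 10 per exposure for the disease/trait grids)
even when some grid cells produce no p-value for lack of instruments:
untestable cells contribute no p but still count toward m. With lambda = 0
the q-value equals the BH-adjusted p-value, computed here against the
designed m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CorrectedGrid", "bh_qvalues", "bh_threshold", "correct_grid"]


@dataclass(frozen=True)
class CorrectedGrid:
    """q-values and FDR flags for one family of tests."""

    pvals: np.ndarray
    m: int
    qvals: np.ndarray
    fdr_level: float
    significant: np.ndarray  # boolean, q <= fdr_level
    p_cutoff: float


def _check_pvals(pvals: np.ndarray, m: int) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m < len(p):
        raise ValueError(f"designed m={m} smaller than the number of supplied p-values {len(p)}")
    return p


def bh_qvalues(pvals, m: int | None = None) -> np.ndarray:
    """BH-adjusted p-values (equivalently lambda-0 q-values) against a
    designed family size m.

    q_(j) = min_{k >= j} p_(k) * m / k over the ascending-sorted p-values,
    clamped at 1 and mapped back to the input order. With m equal to the
    list length this is the classical BH adjustment.
    """
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = len(p)
    p = _check_pvals(p, m)
    n = len(p)
    if n == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def bh_threshold(pvals, m: int | None = None, fdr: float = 0.10) -> tuple[float, np.ndarray]:
    """BH step-up p-value cutoff at the given FDR over a designed m.

    The cutoff is the largest sorted p_(k) with p_(k) <= k * fdr / m, or 0
    when none qualifies; flags mark p <= cutoff.
    """
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = len(p)
    p = _check_pvals(p, m)
    n = len(p)
    if n == 0:
        return 0.0, np.zeros(0, dtype=bool)
    p_sorted = np.sort(p)
    ok = p_sorted <= np.arange(1, n + 1) * fdr / m
    cutoff = float(p_sorted[np.flatnonzero(ok)[-1]]) if ok.any() else 0.0
    return cutoff, p <= cutoff


def correct_grid(pvals, m: int, fdr_level: float = 0.10) -> CorrectedGrid:
    """q-values plus BH flags for one family; flags are q <= fdr_level."""
    p = _check_pvals(np.asarray(pvals, dtype=float), m)
    q = bh_qvalues(p, m)
    cutoff, _ = bh_threshold(p, m, fdr_level)
    return CorrectedGrid(
        pvals=p, m=m, qvals=q, fdr_level=fdr_level,
        significant=q <= fdr_level, p_cutoff=cutoff,
    )
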