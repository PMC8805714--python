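"""MR-PRESSO horizontal-pleiotropy diagnostics.

Monte-Carlo residual-sum-of-squares framework with three parts:

* **global test** — the observed weighted RSS of leave-one-out IVW
  residuals is compared with its parametric null distribution, simulated
  by redrawing each instrument's effects from normals centred on the
  no-pleiotropy expectation;
* **outlier test** — per-instrument empirical p-values from the simulated
  residual distributions, Bonferroni-adjusted across instruments;
* **distortion test** — whether removing the flagged outliers shifts the
  IVW estimate more than removing the same number of instruments at
  random.

Empirical p-values use the add-one estimator (k+1)/(n+1), so p = 0 is
never reported and the resolution is bounded by the simulation count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .instruments import InstrumentSet, subset
from .mr_core import MrResult, mr_ivw

__all__ = [
    "PressoResult",
    "NotEstimableError",
    "presso_global",
    "presso_outliers",
    "presso_distortion",
    "run_presso",
]

MIN_SNPS_PRESSO = 4  # leave-one-out IVW needs >= 3 remaining


class NotEstimableError(ValueError):
    """Too few instruments (or all flagged) for the requested test."""


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray | None
    outlier_pvals_bonferroni: np.ndarray | None
    outliers: tuple[int, ...]
    beta_raw: float
    beta_corrected: float | None
    corrected: MrResult | None
    distortion_pval: float | None
    n_sim: int
    seed: int | None
    status: str = "ok"


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over the left-out index."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def _weighted_loo_residuals_sq(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> np.ndarray:
    """Per-SNP squared residual (by_j - theta_(-j) bx_j)^2 / seY_j^2."""
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)
    return w * (by - theta_loo * bx) ** 2


def presso_global(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    _retain_residuals: bool = False,
):
    """MR-PRESSO global test.

    Observed statistic: weighted RSS of the leave-one-out IVW residuals.
    Null replicates redraw beta_X*_j ~ N(beta_X_j, seX_j) and beta_Y*_j ~
    N(theta_(-j) * beta_X_j, seY_j) and recompute the same statistic.
    Returns (rss_obs, global_pval, simulated_rss); with
    ``_retain_residuals`` additionally the observed and simulated per-SNP
    weighted squared residuals, as the outlier test needs them.
    """
    j = instruments.n_snp
    if j < MIN_SNPS_PRESSO:
        raise NotEstimableError(f"MR-PRESSO needs >= {MIN_SNPS_PRESSO} instruments, got {j}")
    bx = np.array([i.beta_exp for i in instruments.instruments])
    sx = np.array([i.se_exp for i in instruments.instruments])
    by = np.array([i.beta_out for i in instruments.instruments])
    sy = np.array([i.se_out for i in instruments.instruments])
    w = 1.0 / sy**2

    r2_obs = _weighted_loo_residuals_sq(bx, by, sy)
    rss_obs = float(np.sum(r2_obs))

    theta_loo = _loo_slopes(bx, by, w)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))

    # vectorised LOO over all replicates at once
    s_xy = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_star * bx_star, axis=1, keepdims=True)
    theta_star = (s_xy - w * bx_star * by_star) / (s_xx - w * bx_star * bx_star)
    r2_star = w * (by_star - theta_star * bx_star) ** 2
    rss_star = np.sum(r2_star, axis=1)

    global_pval = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    if _retain_residuals:
        return rss_obs, global_pval, rss_star, r2_obs, r2_star
    return rss_obs, global_pval, rss_star


def presso_outliers(
    r2_obs: np.ndarray,
    r2_star: np.ndarray,
    alpha: float = 0.05,
) -> tuple[tuple[int, ...], np.ndarray, np.ndarray]:
    """Per-instrument outlier test from retained simulated residuals.

    p_j = (1 + #{sim r*_j^2 >= r_j^2}) / (n_sim + 1); an instrument is
    flagged when its Bonferroni-adjusted p (times J) falls below ``alpha``.
    Warns when the simulation resolution makes any flag impossible.
    """
    n_sim, j = r2_star.shape
    pvals = (1 + np.sum(r2_star >= r2_obs[None, :], axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(pvals * j, 1.0)
    if j / (n_sim + 1) >= alpha:
        warnings.warn(
            f"minimum achievable Bonferroni-adjusted p is {j}/{n_sim + 1} >= alpha={alpha}; "
            "no outlier can be flagged at this simulation count",
            stacklevel=2,
        )
    outliers = tuple(int(i) for i in np.flatnonzero(p_bonf < alpha))
    return outliers, pvals, p_bonf


def presso_distortion(
    instruments: InstrumentSet,
    outliers: tuple[int, ...],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Distortion test: does outlier removal shift the IVW estimate more
    than removing the same number of instruments at random?

    D = (beta_raw - beta_corrected) / |beta_corrected|; the null
    distribution re-draws |outliers| instruments to drop uniformly without
    replacement. Two-sided empirical p with the add-one estimator.
    """
    j = instruments.n_snp
    if not outliers:
        raise NotEstimableError("distortion test needs a nonempty outlier set")
    keep = [i for i in range(j) if i not in set(outliers)]
    if not keep:
        raise NotEstimableError("all instruments flagged as outliers")
    beta_raw = mr_ivw(instruments).beta
    beta_corrected = mr_ivw(subset(instruments, keep)).beta
    d_obs = (beta_raw - beta_corrected) / abs(beta_corrected)

    rng = np.random.default_rng(seed)
    k = len(outliers)
    d_null = np.empty(n_boot)
    for b in range(n_boot):
        drop = rng.choice(j, size=k, replace=False)
        kept = [i for i in range(j) if i not in set(drop.tolist())]
        beta_b = mr_ivw(subset(instruments, kept)).beta
        d_null[b] = (beta_raw - beta_b) / abs(beta_b)
    pval = (1 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_boot + 1)
    return beta_raw, beta_corrected, float(pval)


def run_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """Full MR-PRESSO: global test, outlier test, and — when the global
    test is significant and outliers were found — the distortion test with
    the outlier-corrected IVW estimate."""
    try:
        rss_obs, global_pval, _, r2_obs, r2_star = presso_global(
            instruments, n_sim=n_sim, seed=seed, _retain_residuals=True
        )
    except NotEstimableError as exc:
        return PressoResult(
            rss_obs=math.nan, global_pval=math.nan, outlier_pvals=None,
            outlier_pvals_bonferroni=None, outliers=(), beta_raw=math.nan,
            beta_corrected=None, corrected=None, distortion_pval=None,
            n_sim=n_sim, seed=seed, status=f"not_estimable: {exc}",
        )
    beta_raw = mr_ivw(instruments).beta
    outliers: tuple[int, ...] = ()
    pvals = p_bonf = None
    beta_corrected = corrected = distortion_pval = None
    if global_pval < alpha:
        outliers, pvals, p_bonf = presso_outliers(r2_obs, r2_star, alpha=alpha)
        if outliers and len(outliers) < instruments.n_snp:
            keep = [i for i in range(instruments.n_snp) if i not in set(outliers)]
            corrected = mr_ivw(subset(instruments, keep))
            beta_corrected = corrected.beta
            _, _, distortion_pval = presso_distortion(
                instruments, outliers, n_boot=n_sim, seed=seed
            )
    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval, outlier_pvals=pvals,
        outlier_pvals_bonferroni=p_bonf, outliers=outliers, beta_raw=beta_raw,
        beta_corrected=beta_corrected, corrected=corrected,
        distortion_pval=distortion_pval, n_sim=n_sim, seed=seed,
    )
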