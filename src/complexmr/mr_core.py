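"""Two-sample MR causal estimators on a harmonized instrument set.

All estimators regress per-SNP outcome effects beta_Y (log-OR) on exposure
effects beta_X (NES), weighting by the inverse outcome variance:

* IVW — zero-intercept weighted regression; the primary causal estimate.
  Default standard errors are multiplicative random effects (the fixed SE
  inflated by the residual scale, floored at 1), so the point estimate is
  identical between fixed and random modes.
* MR-Egger — weighted regression with a free intercept; the intercept
  estimates the average directional pleiotropy, the slope remains a causal
  estimate under the InSIDE assumption. Instruments are pre-oriented to
  beta_X >= 0 since Egger is not invariant to per-SNP sign conventions.
* Weighted median — the inverse-variance weighted median of per-SNP Wald
  ratios; consistent when instruments carrying at least half the weight are
  valid. SE by seeded parametric bootstrap.
* Cochran's Q — heterogeneity of the per-SNP estimates around a slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .instruments import InstrumentSet

__all__ = [
    "MrResult",
    "wald_ratios",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "cochran_q",
]

Method = Literal["ivw", "egger", "weighted_median"]

# minimum instrument counts per estimator
MIN_SNPS = {"ivw": 1, "egger": 3, "weighted_median": 3}


@dataclass(frozen=True)
class MrResult:
    """One estimator's output for one cell.

    ``beta`` is the causal estimate theta-hat in outcome log-OR per unit
    NES. A cell with too few instruments yields ``status ==
    "not_estimable"`` with NaN estimates rather than an exception, so grid
    runs record the cell and continue.
    """

    method: Method
    beta: float
    se: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q_stat: float | None = None
    q_pval: float | None = None
    status: str = "ok"

    @classmethod
    def not_estimable(cls, method: Method, n_snp: int, reason: str) -> "MrResult":
        return cls(method=method, beta=math.nan, se=math.nan, pval=math.nan,
                   n_snp=n_snp, status=f"not_estimable: {reason}")


def _arrays(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exp for i in instruments.instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments.instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments.instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments.instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratios(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates beta_Y/beta_X with first-order SE seY/|beta_X|.

    Instruments with beta_X == 0 have no defined ratio and are excluded with
    a warning (kept instruments should never carry one).
    """
    bx, _, by, sy = _arrays(instruments)
    nz = bx != 0
    if not np.all(nz):
        warnings.warn(
            f"{int((~nz).sum())} instrument(s) with beta_exp == 0 excluded from Wald ratios",
            stacklevel=2,
        )
    return by[nz] / bx[nz], sy[nz] / np.abs(bx[nz])


def ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Closed-form IVW slope: weighted zero-intercept regression of by on bx."""
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def mr_ivw(
    instruments: InstrumentSet,
    effects_mode: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
) -> MrResult:
    """Inverse-variance-weighted estimate with Cochran's Q heterogeneity.

    theta-hat = sum(w bx by) / sum(w bx^2), w = 1/seY^2; the point estimate
    does not depend on ``effects_mode``. The multiplicative-random SE
    multiplies the fixed SE by max(1, sqrt(RSS_w/(J-1))); with one
    instrument it reduces to the Wald ratio with fixed SE. P two-sided
    normal.
    """
    j = instruments.n_snp
    if j < MIN_SNPS["ivw"]:
        return MrResult.not_estimable("ivw", j, "IVW needs >= 1 instrument")
    bx, _, by, sy = _arrays(instruments)
    w = 1.0 / sy**2
    theta = ivw_point(bx, by, sy)
    se_fixed = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    if effects_mode == "multiplicative_random" and j >= 2:
        rss_w = float(np.sum(w * (by - theta * bx) ** 2))
        scale = max(1.0, math.sqrt(rss_w / (j - 1)))
    else:
        scale = 1.0
    se = se_fixed * scale
    pval = float(2 * stats.norm.sf(abs(theta) / se))
    q_stat, q_pval = cochran_q(instruments, theta) if j >= 2 else (None, None)
    return MrResult(method="ivw", beta=theta, se=se, pval=max(pval, np.finfo(float).tiny),
                    n_snp=j, q_stat=q_stat, q_pval=q_pval)


def mr_egger(instruments: InstrumentSet) -> MrResult:
    """MR-Egger regression: weighted fit of beta_Y = a + theta * beta_X.

    Instruments are oriented so every beta_X >= 0 (flipping beta_Y
    alongside) before the fit. Slope and intercept SEs share the residual
    scale max(1, sqrt(RSS_w/(J-2))); p-values from t with J-2 df.
    """
    j = instruments.n_snp
    if j < MIN_SNPS["egger"]:
        return MrResult.not_estimable("egger", j, "Egger needs >= 3 instruments")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    scale2 = max(1.0, rss_w / (j - 2))
    cov = np.linalg.inv(xtwx) * scale2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tdist = stats.t(df=j - 2)
    p_slope = float(2 * tdist.sf(abs(slope) / se_slope)) if se_slope > 0 else 1.0
    p_int = float(2 * tdist.sf(abs(intercept) / se_int)) if se_int > 0 else 1.0
    return MrResult(
        method="egger", beta=slope, se=se_slope, pval=max(p_slope, np.finfo(float).tiny),
        n_snp=j, intercept=intercept, intercept_se=se_int,
        intercept_pval=max(p_int, np.finfo(float).tiny),
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of cumulative mid-weights.

    With ratios sorted ascending and normalized weights w_j, the cumulative
    mid-weight is p_j = sum_{k<=j} w_k - w_j/2; the estimate interpolates
    between the ratios whose p_j bracket 1/2.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5))  # first index with p >= 0.5
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


def mr_weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-median estimate over Wald ratios, inverse-variance weights.

    SE by parametric bootstrap: beta_X and beta_Y are resampled from
    normals centred at the observed values with their SEs, the estimate is
    recomputed ``n_boot`` times, and the SE is the standard deviation of
    the replicates. Deterministic given ``seed``. P two-sided normal.
    """
    j = instruments.n_snp
    if j < MIN_SNPS["weighted_median"]:
        return MrResult.not_estimable("weighted_median", j, "weighted median needs >= 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    ratios, ratio_se = by / bx, sy / np.abs(bx)
    weights = 1.0 / ratio_se**2
    theta = weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx_star[b]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        r = by_star[b] / bxs
        est[b] = weighted_median_point(r, (np.abs(bxs) / sy) ** 2)
    se = float(np.std(est, ddof=1))
    pval = float(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else 1.0
    return MrResult(method="weighted_median", beta=theta, se=se,
                    pval=max(pval, np.finfo(float).tiny), n_snp=j)


def cochran_q(instruments: InstrumentSet, theta: float) -> tuple[float, float]:
    """Cochran's Q around slope theta: sum of squared weighted residuals,
    chi-square reference with J-1 df."""
    bx, _, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    q = float(np.sum((by - theta * bx) ** 2 / sy**2))
    return q, float(stats.chi2.sf(q, df=j - 1))
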