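"""Synthetic two-sample MR summary statistics with known ground truth.

Implements the generative model the estimators assume: per instrument j,

    beta_Y_j = theta * beta_X_j(true) + alpha_j + eps_j

with observed exposure effects beta_X_j(obs) ~ N(beta_X_j(true), seX_j)
and outcome noise eps_j ~ N(0, seY_j). The pleiotropy term alpha_j is 0
(``none``), centred on 0 (``balanced``), centred off 0 but independent of
instrument strength (``directional`` — the InSIDE assumption holds), or
correlated with |beta_X| (``inside_violating``).

Outputs are the same objects and TSV dialects the readers consume:
a per-gene cis-eQTL exposure table, an rsid-keyed outcome GWAS table with
configurable palindromic and allele-swapped fractions, a block LD matrix,
and a truth record for parameter-recovery tests. Everything is
deterministic given the config seed.

Default effect and SE scales are chosen so the mean instrument F-statistic
(beta_X/seX)^2 exceeds 30, mimicking significant GTEx cis-eQTLs, which are
strong instruments by construction; outcome effects are drawn directly on
the log-odds-ratio scale, as in a case/control longevity GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
from scipy import stats

from .sumstats_io import (
    EqtlAssociation,
    GwasAssociation,
    LdMatrix,
    VariantId,
)

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_instruments", "implant_outlier"]

PleiotropyMode = Literal["none", "balanced", "directional", "inside_violating"]

# non-palindromic allele pairs (effect allele listed first)
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated exposure/outcome dataset."""

    n_snp: int = 10                  # instruments per gene
    n_genes: int = 4                 # genes per set
    theta: float = -0.13             # true causal effect, log-OR per NES unit
    pleiotropy_mode: PleiotropyMode = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    se_exp_range: tuple[float, float] = (0.05, 0.10)
    se_out_range: tuple[float, float] = (0.02, 0.05)
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_block: float = 0.0            # within-gene r2; 0 = independent
    frac_palindromic: float = 0.0
    frac_swapped: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1 or self.n_genes < 1:
            raise ValueError("n_snp and n_genes must be >= 1")
        for name in ("se_exp_range", "se_out_range", "maf_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if not 0 < self.maf_range[1] < 0.5:
            raise ValueError("maf_range must lie inside (0, 0.5)")
        for name in ("frac_palindromic", "frac_swapped"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 <= self.ld_block <= 1:
            raise ValueError("ld_block must be in [0,1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated dataset."""

    theta: float
    alpha: np.ndarray          # per-SNP pleiotropic effect
    beta_exp_true: np.ndarray  # per-SNP true beta_X
    outlier_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimDataset:
    exposure: list[EqtlAssociation]
    outcome: list[GwasAssociation]
    ld: LdMatrix
    truth: SimTruth
    tissue: str = "synthetic_tissue"

    def __iter__(self) -> Iterator:
        return iter((self.exposure, self.outcome, self.ld, self.truth))


def _two_sided_p(beta: float, se: float) -> float:
    return max(float(2 * stats.norm.sf(abs(beta) / se)), np.finfo(float).tiny)


def simulate_instruments(config: SimConfig, tissue: str = "synthetic_tissue") -> SimDataset:
    """Draw one dataset under ``config``; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    j = config.n_snp * config.n_genes

    bx_true = rng.uniform(0.3, 0.8, size=j) * rng.choice([-1.0, 1.0], size=j)
    sx = rng.uniform(*config.se_exp_range, size=j)
    sy = rng.uniform(*config.se_out_range, size=j)

    mode = config.pleiotropy_mode
    if mode == "none":
        alpha = np.zeros(j)
    elif mode == "balanced":
        alpha = rng.normal(0.0, config.pleio_sd, size=j)
    elif mode == "directional":
        alpha = rng.normal(config.pleio_mean, config.pleio_sd, size=j)
    elif mode == "inside_violating":
        # direct effects proportional to instrument strength: InSIDE fails
        alpha = config.pleio_mean * np.abs(bx_true) + rng.normal(0.0, config.pleio_sd, size=j)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown pleiotropy mode {mode!r}")

    bx_obs = bx_true + rng.normal(0.0, sx)
    by_obs = config.theta * bx_true + alpha + rng.normal(0.0, sy)

    maf = rng.uniform(*config.maf_range, size=j)
    eaf_alt = np.where(rng.random(j) < 0.5, maf, 1 - maf)  # ALT may be major
    is_pal = rng.random(j) < config.frac_palindromic
    is_swap = rng.random(j) < config.frac_swapped

    exposure: list[EqtlAssociation] = []
    outcome: list[GwasAssociation] = []
    snp_ids: list[str] = []
    for i in range(j):
        gene = i // config.n_snp
        if is_pal[i]:
            eff, oth = _PALINDROMIC[int(rng.integers(len(_PALINDROMIC)))]
        else:
            eff, oth = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
        rsid = f"rs{i + 1}"
        snp_ids.append(rsid)
        variant = VariantId(chrom=f"chr{gene + 1}", pos=10_000 + 1_000 * i,
                            ref=oth, alt=eff, rsid=rsid)
        exposure.append(
            EqtlAssociation(
                variant=variant, gene_id=f"GENE{gene + 1}", tissue=tissue,
                nes=float(bx_obs[i]), se_nes=float(sx[i]),
                pval=_two_sided_p(bx_obs[i], sx[i]),
                maf=float(maf[i]), eaf=float(eaf_alt[i]),
            )
        )
        if is_swap[i]:
            # outcome file states the effect for the exposure REF allele
            outcome.append(
                GwasAssociation(
                    rsid=rsid, effect_allele=oth, other_allele=eff,
                    eaf=float(1 - eaf_alt[i]), beta=float(-by_obs[i]),
                    se=float(sy[i]), pval=_two_sided_p(by_obs[i], sy[i]),
                )
            )
        else:
            outcome.append(
                GwasAssociation(
                    rsid=rsid, effect_allele=eff, other_allele=oth,
                    eaf=float(eaf_alt[i]), beta=float(by_obs[i]),
                    se=float(sy[i]), pval=_two_sided_p(by_obs[i], sy[i]),
                )
            )

    r2 = np.eye(j)
    if config.ld_block > 0:
        for g in range(config.n_genes):
            lo, hi = g * config.n_snp, (g + 1) * config.n_snp
            block = np.full((config.n_snp, config.n_snp), config.ld_block)
            np.fill_diagonal(block, 1.0)
            r2[lo:hi, lo:hi] = block
    ld = LdMatrix(tuple(snp_ids), r2)

    truth = SimTruth(theta=config.theta, alpha=alpha, beta_exp_true=bx_true)
    return SimDataset(exposure=exposure, outcome=outcome, ld=ld, truth=truth, tissue=tissue)


def implant_outlier(dataset: SimDataset, index: int, displacement: float) -> SimDataset:
    """Shift the outcome effect of one instrument by ``displacement`` times
    its outcome SE (on the exposure-ALT-aligned scale) and record it in the
    truth; displacement 0 returns the dataset unchanged."""
    if not 0 <= index < len(dataset.outcome):
        raise IndexError(f"instrument index {index} out of range")
    if displacement == 0:
        return dataset
    g = dataset.outcome[index]
    alt = dataset.exposure[index].variant.alt
    sign = 1.0 if g.effect_allele == alt else -1.0  # keep the shift aligned to ALT
    shifted = replace(g, beta=g.beta + sign * displacement * g.se)
    outcome = list(dataset.outcome)
    outcome[index] = shifted
    truth = replace(
        dataset.truth,
        outlier_indices=tuple(sorted(set(dataset.truth.outlier_indices) | {index})),
    )
    return replace(dataset, outcome=outcome, truth=truth)
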