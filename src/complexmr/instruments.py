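"""Instrument assembly for one (gene set, tissue, outcome) cell.

The exposure is the pooled expression of a gene complex: all significant
cis-eQTLs for any gene in the set are pooled into a single instrument list,
deduplicated across genes, LD-pruned to approximate independence
(r2 <= 0.1, keeping the smaller eQTL p in each violating pair), and
harmonized against the outcome GWAS so that, per SNP, beta_X and beta_Y
refer to the same effect allele. Palindromic (A/T, C/G) SNPs whose strand
cannot be resolved from allele frequencies are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .sumstats_io import EqtlAssociation, GeneSet, GwasAssociation, LdMatrix

__all__ = [
    "HarmonizedInstrument",
    "InstrumentSet",
    "NoInstrumentsError",
    "pool_gene_set",
    "ld_prune",
    "harmonize",
    "PALINDROMIC_WINDOW",
]

# TwoSampleMR-convention ambiguity window on the effect-allele frequency:
# palindromic SNPs with either EAF in (0.42, 0.58) are unresolvable.
PALINDROMIC_WINDOW: tuple[float, float] = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

Status = Literal["kept", "dropped_palindromic", "dropped_unmatched", "dropped_invalid"]


class NoInstrumentsError(ValueError):
    """Raised when a cell has no pooled eQTLs; callers record the cell as
    not-testable rather than aborting the grid."""


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP after allele alignment: the unit of all MR arithmetic.

    (beta_exp, se_exp) are the eQTL NES and its SE; (beta_out, se_out) the
    outcome log-OR and SE, sign-aligned to the exposure effect allele.
    """

    snp_id: str
    gene_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None
    status: Status = "kept"

    def __post_init__(self) -> None:
        if self.status == "kept":
            if not self.se_exp > 0 or not self.se_out > 0:
                raise ValueError(f"{self.snp_id}: kept instrument needs positive SEs")
            if self.beta_exp == 0:
                raise ValueError(f"{self.snp_id}: kept instrument needs beta_exp != 0")


@dataclass(frozen=True)
class InstrumentSet:
    """Kept instruments for one exposure/outcome pair plus filtering provenance."""

    exposure_label: str
    outcome_label: str
    instruments: tuple[HarmonizedInstrument, ...]
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.instruments)


def pool_gene_set(
    eqtls: Sequence[EqtlAssociation],
    gene_set: GeneSet,
    tissue: str,
    dedupe_policy: Literal["min_p", "keep_all"] = "min_p",
) -> list[EqtlAssociation]:
    """Pool cis-eQTLs across all genes of a complex into one instrument list.

    A variant that is an eQTL for two or more genes of the set would count
    the same allele twice, so under the default ``min_p`` policy exactly one
    record per variant survives: the one with the smallest eQTL p-value.
    Output is sorted by p ascending (ties broken by variant key for
    determinism).

    Raises :class:`NoInstrumentsError` when the pool is empty — the cell is
    then not-testable, as for the sparse small-intestine data.
    """
    members = set(gene_set.gene_ids)
    pooled = [e for e in eqtls if e.tissue == tissue and e.gene_id in members]
    if dedupe_policy == "min_p":
        best: dict[str, EqtlAssociation] = {}
        for e in pooled:
            k = e.variant.key
            if k not in best or e.pval < best[k].pval:
                best[k] = e
        pooled = list(best.values())
    pooled.sort(key=lambda e: (e.pval, e.variant.key))
    if not pooled:
        raise NoInstrumentsError(
            f"no cis-eQTL instruments for gene set {gene_set.name!r} in tissue {tissue!r}"
        )
    return pooled


def ld_prune(
    eqtls: Sequence[EqtlAssociation],
    ld: LdMatrix,
    r2_threshold: float = 0.1,
) -> list[EqtlAssociation]:
    """Greedy LD pruning: keep the stronger instrument of correlated pairs.

    SNPs are visited in ascending eQTL-p order; a SNP is accepted iff its r2
    with every already-accepted SNP is at most the threshold. The result is
    admissible (no retained pair exceeds the threshold) and deterministic,
    and in each violating pair it is the larger-p record that is removed.
    Pairs absent from the LD source are treated as independent.
    """
    ordered = sorted(eqtls, key=lambda e: (e.pval, e.variant.key))
    kept: list[EqtlAssociation] = []
    for cand in ordered:
        ck = cand.variant.key
        if all(ld.get(ck, k.variant.key) <= r2_threshold for k in kept):
            kept.append(cand)
    return kept


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: Sequence[EqtlAssociation],
    outcome: Sequence[GwasAssociation],
    palindromic_eaf_window: tuple[float, float] = PALINDROMIC_WINDOW,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele (ALT), SNP by SNP.

    Per matched SNP:

    * alleles identical -> signs unchanged;
    * alleles swapped (outcome effect allele is the exposure REF) -> flip
      the sign of beta_Y and replace the outcome EAF by 1 - EAF;
    * non-palindromic strand mismatch -> resolved by complementing the
      outcome alleles, then as above;
    * palindromic SNP -> orientation inferred by comparing effect-allele
      frequencies; dropped (``dropped_palindromic``) when either frequency
      falls inside the ambiguity window around 0.5;
    * allele sets that cannot be reconciled, or SNPs missing from the
      outcome -> ``dropped_unmatched``.

    Every drop is counted in the returned provenance; harmonizing an
    already-aligned set is a no-op.
    """
    lo, hi = palindromic_eaf_window
    by_rsid = {g.rsid: g for g in outcome}
    kept: list[HarmonizedInstrument] = []
    prov = {"pooled": len(exposure), "kept": 0, "dropped_palindromic": 0,
            "dropped_unmatched": 0, "dropped_invalid": 0}

    for e in exposure:
        v = e.variant
        g = by_rsid.get(v.rsid) if v.rsid else None
        if g is None:
            prov["dropped_unmatched"] += 1
            continue
        exp_eff, exp_oth = v.alt, v.ref  # NES is the effect of ALT vs REF
        exp_eaf = e.eaf

        beta_out, out_eaf = None, None
        if _is_palindromic(exp_eff, exp_oth):
            if {g.effect_allele, g.other_allele} != {exp_eff, exp_oth}:
                prov["dropped_unmatched"] += 1
                continue
            # Strand is unresolvable from alleles; use frequencies.
            if (exp_eaf is not None and lo < exp_eaf < hi) or lo < g.eaf < hi:
                prov["dropped_palindromic"] += 1
                continue
            if exp_eaf is None:
                # no exposure frequency to compare against: unresolvable
                prov["dropped_palindromic"] += 1
                continue
            # Allele labels cannot identify the physical allele across
            # strands (A<->T, C<->G), but its frequency can: frequencies on
            # the same side of 0.5 mean the outcome effect allele IS the
            # exposure effect allele.
            same_side = (exp_eaf < 0.5) == (g.eaf < 0.5)
            beta_out = g.beta if same_side else -g.beta
            out_eaf = g.eaf if same_side else 1 - g.eaf
        else:
            pairs = {
                (g.effect_allele, g.other_allele): +1,
                (g.other_allele, g.effect_allele): -1,
                (_COMPLEMENT.get(g.effect_allele, "?"), _COMPLEMENT.get(g.other_allele, "?")): +1,
                (_COMPLEMENT.get(g.other_allele, "?"), _COMPLEMENT.get(g.effect_allele, "?")): -1,
            }
            sign = pairs.get((exp_eff, exp_oth))
            if sign is None:
                prov["dropped_unmatched"] += 1
                continue
            beta_out = sign * g.beta
            out_eaf = g.eaf if sign == +1 else 1 - g.eaf

        if e.nes == 0:
            prov["dropped_invalid"] += 1
            continue
        kept.append(
            HarmonizedInstrument(
                snp_id=v.key,
                gene_id=e.gene_id,
                beta_exp=e.nes,
                se_exp=e.se_nes,
                beta_out=beta_out,
                se_out=g.se,
                eaf=out_eaf,
                status="kept",
            )
        )
        prov["kept"] += 1

    return InstrumentSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        instruments=tuple(kept),
        provenance=prov,
    )


def subset(instruments: InstrumentSet, keep_idx: Sequence[int]) -> InstrumentSet:
    """A new InstrumentSet restricted to the given instrument indices."""
    keep = tuple(instruments.instruments[i] for i in keep_idx)
    return replace(instruments, instruments=keep)
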