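"""Readers and writers for the tabular summary-statistics dialects.

All inputs and outputs are tab-separated text: cis-eQTL association tables
in the GTEx v8 single-tissue export dialect, outcome GWAS summary
statistics, pairwise LD as long-form r-squared triples, two-column gene-set
definitions, and the per-cell results grid. Every reader validates each row
against the domain invariants; a row is either parsed into a record or
rejected with a reason, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")

__all__ = [
    "VariantId",
    "EqtlAssociation",
    "GwasAssociation",
    "LdMatrix",
    "GeneSet",
    "RowRejection",
    "FormatError",
    "read_eqtl_table",
    "write_eqtl_table",
    "read_gwas_sumstats",
    "write_gwas_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "write_results_grid",
    "read_results_grid",
]


class FormatError(ValueError):
    """A file-level problem: missing column, duplicate key, bad matrix."""


@dataclass(frozen=True)
class RowRejection:
    """One rejected input row: validation is total (parsed + rejected = rows)."""

    line: int
    reason: str


@dataclass(frozen=True)
class VariantId:
    """A sequence variant; positions are 1-based as in VCF.

    ``ref``/``alt`` follow the reference genome; the eQTL effect allele is
    ALT by the NES convention. ``rsid`` is the cross-file join key against
    rsid-keyed GWAS summary statistics.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) for variant at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele string")

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _SNP_ALLELES
            and self.alt in _SNP_ALLELES
        )

    @property
    def key(self) -> str:
        """Identity used across files: rsid when known, else position + alleles."""
        if self.rsid:
            return self.rsid
        return f"{self.chrom}_{self.pos}_{'_'.join(sorted((self.ref, self.alt)))}"


# GTEx-style positional token, e.g. chr5_100_A_G_b38
_VARIANT_TOKEN = re.compile(
    r"^(?P<chrom>\w+)_(?P<pos>\d+)_(?P<ref>[ACGT]+)_(?P<alt>[ACGT]+)(?:_(?P<build>\w+))?$"
)


def parse_variant_token(token: str, rsid: str | None = None) -> VariantId:
    m = _VARIANT_TOKEN.match(token.strip())
    if m is None:
        raise ValueError(f"unparsable variant id {token!r}")
    return VariantId(
        chrom=m.group("chrom"),
        pos=int(m.group("pos")),
        ref=m.group("ref").upper(),
        alt=m.group("alt").upper(),
        rsid=rsid or None,
    )


@dataclass(frozen=True)
class EqtlAssociation:
    """One cis-eQTL record (the exposure side of the MR).

    ``nes`` is the normalized effect size of the ALT allele relative to REF
    — the slope of normalized expression on ALT dosage — and carries the
    instrument's beta_X; ``se_nes`` its standard error (se_X).
    """

    variant: VariantId
    gene_id: str
    tissue: str
    nes: float
    se_nes: float
    pval: float
    maf: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not self.se_nes > 0:
            raise ValueError(f"se_nes must be > 0, got {self.se_nes}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"pval must be in (0,1], got {self.pval}")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0,0.5], got {self.maf}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")


@dataclass(frozen=True)
class GwasAssociation:
    """One outcome GWAS record; beta is the natural-log odds ratio for
    case/control outcomes such as the longevity percentile definitions."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect_allele == other_allele for {self.rsid}")
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"pval must be in (0,1], got {self.pval}")
        if not 0 < self.eaf < 1:
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")


@dataclass(frozen=True)
class LdMatrix:
    """Pairwise squared correlations between candidate instruments.

    Symmetric with unit diagonal; pairs absent from the source file are
    taken as r2 = 0 (no LD).
    """

    snp_ids: tuple[str, ...]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 shape {r2.shape} does not match {n} snp ids")
        if np.any((r2 < 0) | (r2 > 1)):
            raise FormatError("r2 entries must lie in [0,1]")
        if not np.allclose(np.diag(r2), 1.0):
            raise FormatError("r2 diagonal must be exactly 1")
        if not np.allclose(r2, r2.T):
            raise FormatError("r2 matrix must be symmetric")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.snp_ids)})

    def get(self, a: str, b: str) -> float:
        """r2 between two snps; unknown ids or absent pairs are 0 (1 if a==b)."""
        if a == b:
            return 1.0
        idx: Mapping[str, int] = self._index  # type: ignore[attr-defined]
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LdMatrix":
        return cls(tuple(snp_ids), np.eye(len(snp_ids)))


@dataclass(frozen=True)
class GeneSet:
    """A named complex (pol1, pol2, pol3, rp, rp_longevity_subset) and its genes."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.name!r} has duplicate gene ids")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


# ---------------------------------------------------------------------------
# eQTL tables (GTEx v8 single-tissue export dialect)
# ---------------------------------------------------------------------------

_EQTL_REQUIRED = ("gene_id", "variant_id", "pval_nominal", "slope", "slope_se", "maf")
_EQTL_OPTIONAL = ("rs_id", "eaf")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_eqtl_table(
    path: str | Path,
    tissue: str,
    rejections: list[RowRejection] | None = None,
) -> list[EqtlAssociation]:
    """Read a GTEx-dialect cis-eQTL table for one tissue.

    Rows that violate the record invariants (non-positive SE, p outside
    (0,1], MAF outside (0,0.5], unparsable variant id, indel alleles) are
    rejected with a per-row reason, logged, and — when ``rejections`` is
    supplied — appended to it so callers can audit that parsed + rejected
    equals the row total.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _EQTL_REQUIRED, path)
    records: list[EqtlAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            rsid = getattr(row, "rs_id", None)
            rsid = None if rsid is None or pd.isna(rsid) else str(rsid)
            variant = parse_variant_token(str(row.variant_id), rsid=rsid)
            if not variant.is_snp:
                raise ValueError(f"non-SNP alleles {variant.ref}/{variant.alt}")
            eaf_raw = getattr(row, "eaf", None)
            eaf = None if eaf_raw is None or pd.isna(eaf_raw) else float(eaf_raw)
            records.append(
                EqtlAssociation(
                    variant=variant,
                    gene_id=str(row.gene_id),
                    tissue=tissue,
                    nes=float(row.slope),
                    se_nes=float(row.slope_se),
                    pval=float(row.pval_nominal),
                    maf=float(row.maf),
                    eaf=eaf,
                )
            )
        except (ValueError, TypeError) as exc:
            rej = RowRejection(line=i, reason=str(exc))
            logger.warning("%s line %d rejected: %s", path, rej.line, rej.reason)
            if rejections is not None:
                rejections.append(rej)
    return records


def write_eqtl_table(records: Sequence[EqtlAssociation], path: str | Path) -> None:
    rows = []
    for r in records:
        v = r.variant
        rows.append(
            {
                "gene_id": r.gene_id,
                "variant_id": f"{v.chrom}_{v.pos}_{v.ref}_{v.alt}_b38",
                "rs_id": v.rsid if v.rsid else "",
                "pval_nominal": r.pval,
                "slope": r.nes,
                "slope_se": r.se_nes,
                "maf": r.maf,
                "eaf": "" if r.eaf is None else r.eaf,
            }
        )
    cols = ["gene_id", "variant_id", "rs_id", "pval_nominal", "slope", "slope_se", "maf", "eaf"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Outcome GWAS summary statistics
# ---------------------------------------------------------------------------

_GWAS_REQUIRED = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")


def read_gwas_sumstats(
    path: str | Path,
    rejections: list[RowRejection] | None = None,
) -> list[GwasAssociation]:
    """Read outcome GWAS summary statistics; one unique record per rsid.

    Duplicate rsids are a file-level error: the outcome lookup must be
    unambiguous per SNP.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _GWAS_REQUIRED, path)
    dups = df["rsid"][df["rsid"].duplicated()].unique().tolist()
    if dups:
        raise FormatError(f"{path}: duplicate rsid(s): {', '.join(map(str, dups))}")
    records: list[GwasAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            n_raw = getattr(row, "n", None)
            n = None if n_raw is None or pd.isna(n_raw) or n_raw == "" else float(n_raw)
            records.append(
                GwasAssociation(
                    rsid=str(row.rsid),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    eaf=float(row.eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    n=n,
                )
            )
        except (ValueError, TypeError) as exc:
            rej = RowRejection(line=i, reason=str(exc))
            logger.warning("%s line %d rejected: %s", path, rej.line, rej.reason)
            if rejections is not None:
                rejections.append(rej)
    return records


def write_gwas_sumstats(records: Sequence[GwasAssociation], path: str | Path) -> None:
    rows = [
        {
            "rsid": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pval,
            "n": "" if r.n is None else r.n,
        }
        for r in records
    ]
    cols = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------


def read_ld_matrix(path: str | Path, snp_ids: Sequence[str] | None = None) -> LdMatrix:
    """Read pairwise LD from long-form triples ``snpA snpB r2``.

    Pairs not present default to r2 = 0; a pair listed in both orders with
    conflicting values is a symmetry violation. ``snp_ids`` declares ids to
    include even when absent from the file (an empty file then yields the
    identity matrix).
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["a", "b", "r2"], dtype={"a": str, "b": str},
        comment="#", skip_blank_lines=True, float_precision="round_trip",
    )
    # tolerate a header line
    if len(df) and not _is_number(df.iloc[0]["r2"]):
        df = df.iloc[1:].reset_index(drop=True)
    ids: list[str] = list(snp_ids) if snp_ids is not None else []
    seen = set(ids)
    for col in ("a", "b"):
        for s in df[col]:
            if s not in seen:
                seen.add(s)
                ids.append(s)
    n = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    r2 = np.eye(n)
    filled: dict[tuple[int, int], float] = {}
    for _, row in df.iterrows():
        val = float(row["r2"])
        if not 0 <= val <= 1:
            raise FormatError(f"{path}: r2 {val} outside [0,1] for pair {row['a']},{row['b']}")
        ia, ib = idx[row["a"]], idx[row["b"]]
        if ia == ib:
            if val != 1.0:
                raise FormatError(f"{path}: diagonal entry for {row['a']} must be 1, got {val}")
            continue
        key = (min(ia, ib), max(ia, ib))
        if key in filled and filled[key] != val:
            raise FormatError(
                f"{path}: asymmetric r2 for pair {row['a']},{row['b']}: "
                f"{filled[key]} vs {val}"
            )
        filled[key] = val
        r2[ia, ib] = r2[ib, ia] = val
    return LdMatrix(tuple(ids), r2)


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        n = len(ld.snp_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if ld.r2[i, j] != 0.0:
                    fh.write(f"{ld.snp_ids[i]}\t{ld.snp_ids[j]}\t{float(ld.r2[i, j])!r}\n")


def _is_number(x: object) -> bool:
    try:
        float(x)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read two-column (set_name, gene_id) TSV into named GeneSets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("set_name", "gene_id"), path)
    out: dict[str, GeneSet] = {}
    for name, grp in df.groupby("set_name", sort=False):
        out[str(name)] = GeneSet(str(name), tuple(grp["gene_id"]))
    return out


def write_gene_sets(gene_sets: Mapping[str, GeneSet], path: str | Path) -> None:
    rows = [
        {"set_name": gs.name, "gene_id": g}
        for gs in gene_sets.values()
        for g in gs.gene_ids
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results grid
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "exposure_set",
    "tissue",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "pval",
    "qval",
    "significant_fdr10",
    "status",
]


def write_results_grid(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell results table in a deterministic column order,
    full float precision (repr round-trips exactly)."""
    df = results.copy()
    for col in RESULTS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RESULTS_COLUMNS + [c for c in results.columns if c not in RESULTS_COLUMNS]]
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_results_grid(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
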