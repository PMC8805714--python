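"""Grid orchestration: gene set x tissue x outcome cells to a results table.

Each cell runs pool -> LD-prune -> harmonize -> {IVW, Egger, weighted
median} -> MR-PRESSO; cells with too few instruments are recorded as
not-testable with the reason rather than aborting the grid. IVW p-values
are then corrected per family — per gene set across the tissue x
longevity-outcome grid (designed m, default 16), and per (gene set,
tissue) across disease/trait outcomes (designed m, default 10) — with BH
flags at 10% FDR and lambda-0 q-values.

All stochastic components (weighted-median bootstrap, MR-PRESSO) consume
child seeds spawned deterministically from the study seed, so an identical
config reproduces the grid bit for bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr
from . import mr_core, mr_presso, multiple_testing, sumstats_io
from .instruments import InstrumentSet, NoInstrumentsError
from .mr_core import MrResult
from .mr_presso import PressoResult
from .sumstats_io import (
    EqtlAssociation,
    GeneSet,
    GwasAssociation,
    LdMatrix,
    RESULTS_COLUMNS,
    write_results_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "CellResult",
    "run_cell",
    "run_grid",
    "plot_scatter",
    "reproduce_headline",
]


@dataclass
class StudyConfig:
    """Parsed study configuration (see ``StudyConfig.from_yaml``)."""

    gene_sets: dict[str, GeneSet]
    tissues: list[str]
    eqtl_files: dict[str, str]                    # tissue -> path
    outcome_files: dict[str, dict]                # name -> {file, type}
    ld_files: dict[str, str] = field(default_factory=dict)
    r2_threshold: float = 0.1
    palindromic_window: tuple[float, float] = instr.PALINDROMIC_WINDOW
    dedupe_policy: str = "min_p"
    effects_mode: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    fdr_level: float = 0.10
    m_longevity: int = 16
    m_outcomes: int = 10
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def _p(rel: str) -> str:
            q = Path(rel)
            return str(q if q.is_absolute() else base / q)

        inst = raw.get("instruments", {})
        est = raw.get("estimators", {})
        presso = raw.get("presso", {})
        fdr = raw.get("fdr", {})
        return cls(
            gene_sets=sumstats_io.read_gene_sets(_p(raw["gene_sets"])),
            tissues=list(raw["tissues"]),
            eqtl_files={t: _p(f) for t, f in raw["eqtl"].items()},
            outcome_files={
                name: {"file": _p(spec["file"]), "type": spec.get("type", "longevity")}
                for name, spec in raw["outcomes"].items()
            },
            ld_files={t: _p(f) for t, f in raw.get("ld", {}).items()},
            r2_threshold=float(inst.get("r2_threshold", 0.1)),
            palindromic_window=tuple(inst.get("palindromic_window", instr.PALINDROMIC_WINDOW)),
            dedupe_policy=inst.get("dedupe_policy", "min_p"),
            effects_mode=est.get("effects_mode", "multiplicative_random"),
            n_boot=int(est.get("n_boot", 1000)),
            presso_n_sim=int(presso.get("n_sim", 1000)),
            presso_alpha=float(presso.get("alpha", 0.05)),
            fdr_level=float(fdr.get("fdr_level", 0.10)),
            m_longevity=int(fdr.get("m_longevity", 16)),
            m_outcomes=int(fdr.get("m_outcomes", 10)),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "results"),
        )


@dataclass(frozen=True)
class CellResult:
    """Everything computed for one (gene set, tissue, outcome) cell."""

    gene_set: str
    tissue: str
    outcome: str
    instrument_set: InstrumentSet | None
    mr_results: tuple[MrResult, ...]
    presso: PressoResult | None
    status: str  # "ok" | "not_testable: <reason>"

    @property
    def ivw(self) -> MrResult | None:
        for r in self.mr_results:
            if r.method == "ivw" and r.status == "ok":
                return r
        return None


def _cell_seed(study_seed: int, gene_set: str, tissue: str, outcome: str) -> int:
    """Deterministic child seed below 2^31 for one cell's stochastic steps."""
    label = zlib.crc32(f"{gene_set}|{tissue}|{outcome}".encode())
    ss = np.random.SeedSequence([study_seed, label])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    eqtls: Sequence[EqtlAssociation],
    outcome_records: Sequence[GwasAssociation],
    ld: LdMatrix,
    gene_set: GeneSet,
    tissue: str,
    outcome_label: str,
    config: StudyConfig,
) -> CellResult:
    """pool -> prune -> harmonize -> IVW/Egger/weighted-median -> PRESSO."""
    seed = _cell_seed(config.seed, gene_set.name, tissue, outcome_label)
    try:
        pooled = instr.pool_gene_set(eqtls, gene_set, tissue, dedupe_policy=config.dedupe_policy)  # type: ignore[arg-type]
    except NoInstrumentsError as exc:
        logger.info("cell (%s, %s, %s) not testable: %s", gene_set.name, tissue, outcome_label, exc)
        return CellResult(gene_set.name, tissue, outcome_label, None, (), None,
                          status=f"not_testable: {exc}")
    pruned = instr.ld_prune(pooled, ld, r2_threshold=config.r2_threshold)
    iset = instr.harmonize(
        pruned, outcome_records,
        palindromic_eaf_window=config.palindromic_window,
        exposure_label=f"{gene_set.name}|{tissue}", outcome_label=outcome_label,
    )
    iset.provenance["pruned"] = len(pooled) - len(pruned)
    if iset.n_snp == 0:
        return CellResult(gene_set.name, tissue, outcome_label, iset, (), None,
                          status="not_testable: no instruments after harmonization")
    results = (
        mr_core.mr_ivw(iset, effects_mode=config.effects_mode),  # type: ignore[arg-type]
        mr_core.mr_egger(iset),
        mr_core.mr_weighted_median(iset, n_boot=config.n_boot, seed=seed),
    )
    presso = mr_presso.run_presso(iset, n_sim=config.presso_n_sim, seed=seed,
                                  alpha=config.presso_alpha)
    return CellResult(gene_set.name, tissue, outcome_label, iset, results, presso, status="ok")


def run_grid(config: StudyConfig) -> tuple[pd.DataFrame, list[CellResult]]:
    """Run every gene set x tissue x outcome cell and FDR-correct per family.

    Returns the long-form results table (one row per cell x estimable
    method, plus a marker row for each not-testable cell) and the per-cell
    bundles. Writes the grid to ``<out_dir>/results_grid.tsv``.
    """
    eqtls_by_tissue: dict[str, list[EqtlAssociation]] = {}
    for tissue in config.tissues:
        eqtls_by_tissue[tissue] = sumstats_io.read_eqtl_table(config.eqtl_files[tissue], tissue)
    ld_by_tissue = {
        t: (sumstats_io.read_ld_matrix(config.ld_files[t]) if t in config.ld_files
            else LdMatrix((), np.empty((0, 0))))
        for t in config.tissues
    }
    outcomes = {
        name: (sumstats_io.read_gwas_sumstats(spec["file"]), spec["type"])
        for name, spec in config.outcome_files.items()
    }

    cells: list[CellResult] = []
    for gs in config.gene_sets.values():
        for tissue in config.tissues:
            for oname, (orecords, _otype) in outcomes.items():
                cells.append(
                    run_cell(eqtls_by_tissue[tissue], orecords, ld_by_tissue[tissue],
                             gs, tissue, oname, config)
                )

    table = _grid_table(cells, config, outcomes)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_grid(table, out_dir / "results_grid.tsv")
    return table, cells


def _grid_table(
    cells: list[CellResult],
    config: StudyConfig,
    outcomes: Mapping[str, tuple],
) -> pd.DataFrame:
    rows: list[dict] = []
    for c in cells:
        if c.status != "ok":
            rows.append({"exposure_set": c.gene_set, "tissue": c.tissue, "outcome": c.outcome,
                         "method": "none", "n_snp": 0, "status": c.status})
            continue
        for r in c.mr_results:
            rows.append({
                "exposure_set": c.gene_set, "tissue": c.tissue, "outcome": c.outcome,
                "method": r.method, "n_snp": r.n_snp, "beta": r.beta, "se": r.se,
                "pval": r.pval, "status": r.status,
            })
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    df["significant_fdr10"] = df["significant_fdr10"].astype(object)

    # FDR families over IVW p-values: longevity -> per gene set (designed
    # m_longevity); disease/trait -> per (gene set, tissue) (m_outcomes)
    longevity = {n for n, (_, t) in outcomes.items() if t == "longevity"}
    ivw = (df["method"] == "ivw") & (df["status"] == "ok")
    fam_long = df["outcome"].isin(longevity)
    for _, idx in df[ivw & fam_long].groupby("exposure_set").groups.items():
        _apply_family(df, list(idx), config.m_longevity, config.fdr_level)
    for _, idx in df[ivw & ~fam_long].groupby(["exposure_set", "tissue"]).groups.items():
        _apply_family(df, list(idx), config.m_outcomes, config.fdr_level)
    return df


def _apply_family(df: pd.DataFrame, idx: list, m: int, fdr_level: float) -> None:
    pvals = df.loc[idx, "pval"].to_numpy(dtype=float)
    m_eff = max(m, len(pvals))  # never correct against fewer tests than run
    grid = multiple_testing.correct_grid(pvals, m=m_eff, fdr_level=fdr_level)
    df.loc[idx, "qval"] = grid.qvals
    df.loc[idx, "significant_fdr10"] = grid.significant


def plot_scatter(
    instrument_set: InstrumentSet,
    mr_results: Sequence[MrResult],
    path: str | Path,
) -> None:
    """MR scatter plot: per-SNP (beta_X, beta_Y) with SE bars and the
    fitted IVW (through the origin) and Egger lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if instrument_set.n_snp < 1:
        raise ValueError("scatter plot needs at least one instrument")
    bx = np.array([i.beta_exp for i in instrument_set.instruments])
    by = np.array([i.beta_out for i in instrument_set.instruments])
    sx = np.array([i.se_exp for i in instrument_set.instruments])
    sy = np.array([i.se_out for i in instrument_set.instruments])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", color="black",
                ecolor="green", elinewidth=1, capsize=2, ms=4)
    xs = np.linspace(min(0.0, bx.min()) - 0.05, bx.max() + 0.05, 50)
    for r in mr_results:
        if r.status != "ok":
            continue
        if r.method == "ivw":
            ax.plot(xs, r.beta * xs, label=f"IVW (b={r.beta:.3f})")
        elif r.method == "egger":
            ax.plot(xs, (r.intercept or 0.0) + r.beta * xs, "--",
                    label=f"MR-Egger (b={r.beta:.3f})")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("Expression beta (NES)")
    ax.set_ylabel("Outcome beta (log OR)")
    ax.set_title(f"{instrument_set.exposure_label} vs {instrument_set.outcome_label}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reproduce_headline(
    harmonized_path: str | Path,
    presso: bool = False,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Run IVW (and optionally MR-PRESSO) on an externally harmonized
    instrument table.

    The table must be tab-separated with columns ``snp_id, beta_exp,
    se_exp, beta_out, se_out`` — the layout of instrument-level harmonized
    data releases. Intended for reproducing published per-cell estimates
    from their deposited instrument tables.
    """
    df = pd.read_csv(harmonized_path, sep="\t")
    needed = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise sumstats_io.FormatError(f"{harmonized_path}: missing column(s) {missing}")
    insts = tuple(
        instr.HarmonizedInstrument(
            snp_id=str(r.snp_id), gene_id=str(getattr(r, "gene_id", "")),
            beta_exp=float(r.beta_exp), se_exp=float(r.se_exp),
            beta_out=float(r.beta_out), se_out=float(r.se_out), eaf=None,
        )
        for r in df.itertuples(index=False)
    )
    iset = InstrumentSet(exposure_label=str(harmonized_path), outcome_label="outcome",
                         instruments=insts)
    out = {"ivw": mr_core.mr_ivw(iset), "egger": mr_core.mr_egger(iset),
           "weighted_median": mr_core.mr_weighted_median(iset, seed=seed)}
    if presso:
        out["presso"] = mr_presso.run_presso(iset, n_sim=n_sim, seed=seed)
    return out
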