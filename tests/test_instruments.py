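"""Instrument assembly: pooling, LD pruning, harmonization."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexmr import mr_ivw
from complexmr.instruments import (
    NoInstrumentsError,
    harmonize,
    ld_prune,
    pool_gene_set,
)
from complexmr.sumstats_io import (
    EqtlAssociation,
    GeneSet,
    GwasAssociation,
    LdMatrix,
    VariantId,
)


def eqtl(rsid, gene="POLR3A", pval=1e-8, nes=0.4, ref="A", alt="G",
         tissue="liver", eaf=0.3, se=0.05, pos=None):
    pos = pos if pos is not None else abs(hash(rsid)) % 10_000 + 1
    return EqtlAssociation(
        variant=VariantId("chr1", pos, ref, alt, rsid=rsid),
        gene_id=gene, tissue=tissue, nes=nes, se_nes=se, pval=pval,
        maf=min(eaf, 1 - eaf), eaf=eaf,
    )


def gwas(rsid, effect="G", other="A", eaf=0.3, beta=0.1, se=0.02, pval=0.01):
    return GwasAssociation(rsid=rsid, effect_allele=effect, other_allele=other,
                           eaf=eaf, beta=beta, se=se, pval=pval)


POL3 = GeneSet("pol3", ("POLR3A", "POLR3B", "POLR3C"))


class TestPoolGeneSet:
    def test_cross_gene_duplicate_keeps_smallest_p(self):
        v = VariantId("chr1", 100, "A", "G", rsid="rs1")
        e1 = EqtlAssociation(v, "POLR3A", "liver", 0.4, 0.05, 1e-10, 0.3)
        e2 = EqtlAssociation(v, "POLR3B", "liver", 0.3, 0.05, 1e-6, 0.3)
        pooled = pool_gene_set([e2, e1], POL3, "liver")
        assert len(pooled) == 1 and pooled[0].gene_id == "POLR3A"

    def test_gene_outside_set_excluded(self):
        recs = [eqtl("rs1", gene="POLR3A"), eqtl("rs2", gene="POLR2A")]
        pooled = pool_gene_set(recs, POL3, "liver")
        assert [e.variant.rsid for e in pooled] == ["rs1"]

    def test_dedupe_count_on_pooled_fixture(self):
        # 20 eQTLs over 3 set genes; 4 variants duplicated across genes -> 16
        recs = []
        genes = POL3.gene_ids
        for i in range(16):
            recs.append(eqtl(f"rs{i}", gene=genes[i % 3], pval=1e-9 + i * 1e-10, pos=100 + i))
        for i in range(4):  # duplicates of rs0..rs3 under a different set gene
            recs.append(eqtl(f"rs{i}", gene=genes[(i + 1) % 3], pval=1e-5, pos=100 + i))
        assert len(recs) == 20
        pooled = pool_gene_set(recs, POL3, "liver")
        assert len(pooled) == 16
        # keep_all policy retains every record
        assert len(pool_gene_set(recs, POL3, "liver", dedupe_policy="keep_all")) == 20

    def test_sorted_by_p_ascending(self):
        recs = [eqtl("rs1", pval=1e-5), eqtl("rs2", pval=1e-9), eqtl("rs3", pval=1e-7)]
        pooled = pool_gene_set(recs, POL3, "liver")
        assert [e.variant.rsid for e in pooled] == ["rs2", "rs3", "rs1"]

    def test_empty_pool_is_explicit_condition(self):
        with pytest.raises(NoInstrumentsError):
            pool_gene_set([eqtl("rs1", gene="POLR2A")], POL3, "liver")
        with pytest.raises(NoInstrumentsError):
            pool_gene_set([eqtl("rs1", tissue="brain")], POL3, "liver")


def ld_from_pairs(ids, pairs):
    n = len(ids)
    r2 = np.eye(n)
    idx = {s: i for i, s in enumerate(ids)}
    for a, b, v in pairs:
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LdMatrix(tuple(ids), r2)


class TestLdPrune:
    def test_weaker_instrument_of_correlated_pair_removed(self):
        recs = [eqtl("rs1", pval=1e-10), eqtl("rs2", pval=1e-5)]
        ld = ld_from_pairs(["rs1", "rs2"], [("rs1", "rs2", 0.2)])
        kept = ld_prune(recs, ld, r2_threshold=0.1)
        assert [e.variant.rsid for e in kept] == ["rs1"]

    def test_pair_below_threshold_both_kept(self):
        recs = [eqtl("rs1", pval=1e-10), eqtl("rs2", pval=1e-5)]
        ld = ld_from_pairs(["rs1", "rs2"], [("rs1", "rs2", 0.05)])
        assert len(ld_prune(recs, ld, r2_threshold=0.1)) == 2

    def test_three_snp_chain_matches_exhaustive_optimum(self):
        # r2(a,b)=0.15, r2(b,c)=0.15, r2(a,c)=0.01, p(a)<p(c)<p(b)
        recs = {s: eqtl(s, pval=p) for s, p in [("a", 1e-10), ("c", 1e-7), ("b", 1e-5)]}
        ld = ld_from_pairs(["a", "b", "c"],
                           [("a", "b", 0.15), ("b", "c", 0.15), ("a", "c", 0.01)])
        kept = {e.variant.rsid for e in ld_prune(list(recs.values()), ld, 0.1)}
        assert kept == {"a", "c"}
        # exhaustive check: {a,c} is the unique max-size admissible subset
        # that, among ties, has the smallest p-values
        admissible = [
            set(sub) for k in range(4) for sub in combinations("abc", k)
            if all(ld.get(x, y) <= 0.1 for x, y in combinations(sub, 2))
        ]
        max_size = max(len(s) for s in admissible)
        assert kept in [s for s in admissible if len(s) == max_size]

    def test_empty_input_empty_output(self):
        assert ld_prune([], LdMatrix.identity([]), 0.1) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_admissible_for_random_ld(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 1, size=(n, n))
        r2 = (m + m.T) / 2
        np.fill_diagonal(r2, 1.0)
        ids = [f"rs{i}" for i in range(n)]
        ld = LdMatrix(tuple(ids), r2)
        recs = [eqtl(ids[i], pval=float(rng.uniform(1e-12, 1e-4))) for i in range(n)]
        kept = ld_prune(recs, ld, r2_threshold=0.1)
        for a, b in combinations(kept, 2):
            assert ld.get(a.variant.key, b.variant.key) <= 0.1


class TestHarmonize:
    def test_identical_alleles_signs_unchanged(self):
        iset = harmonize([eqtl("rs1", nes=0.4)], [gwas("rs1", effect="G", other="A", beta=0.1)])
        (i,) = iset.instruments
        assert i.beta_out == 0.1 and i.beta_exp == 0.4

    def test_swapped_alleles_flip_sign_and_eaf(self):
        iset = harmonize([eqtl("rs1", nes=0.4)], [gwas("rs1", effect="A", other="G",
                                                       beta=0.1, eaf=0.7)])
        (i,) = iset.instruments
        assert i.beta_out == -0.1
        assert i.eaf == pytest.approx(0.3)

    def test_strand_flip_resolved_for_nonpalindromic(self):
        # exposure A/G; outcome reported on the other strand as T/C
        iset = harmonize([eqtl("rs1", ref="A", alt="G", nes=0.4)],
                         [gwas("rs1", effect="C", other="T", beta=0.1)])
        (i,) = iset.instruments
        assert i.beta_out == 0.1

    def test_palindromic_within_window_dropped(self):
        iset = harmonize([eqtl("rs1", ref="A", alt="T", eaf=0.3)],
                         [gwas("rs1", effect="T", other="A", eaf=0.50)])
        assert iset.n_snp == 0
        assert iset.provenance["dropped_palindromic"] == 1

    def test_palindromic_outside_window_aligned_by_frequency(self):
        # frequencies on opposite sides of 0.5 -> flip
        iset = harmonize([eqtl("rs1", ref="A", alt="T", eaf=0.2)],
                         [gwas("rs1", effect="T", other="A", eaf=0.8, beta=0.1)])
        (i,) = iset.instruments
        assert i.beta_out == -0.1
        # same side -> keep
        iset = harmonize([eqtl("rs2", ref="C", alt="G", eaf=0.2)],
                         [gwas("rs2", effect="G", other="C", eaf=0.25, beta=0.1)])
        assert iset.instruments[0].beta_out == 0.1

    def test_incompatible_alleles_dropped_unmatched(self):
        iset = harmonize([eqtl("rs1", ref="A", alt="G")], [gwas("rs1", effect="A", other="C")])
        assert iset.n_snp == 0 and iset.provenance["dropped_unmatched"] == 1

    def test_missing_outcome_snp_dropped_unmatched(self):
        iset = harmonize([eqtl("rs1")], [gwas("rs2")])
        assert iset.provenance["dropped_unmatched"] == 1

    def test_provenance_conserves_counts(self):
        exposure = [eqtl("rs1"), eqtl("rs2", ref="A", alt="T", eaf=0.5 - 1e-9),
                    eqtl("rs3", ref="A", alt="G")]
        outcome = [gwas("rs1"), gwas("rs2", effect="A", other="T", eaf=0.5),
                   gwas("rs3", effect="A", other="C")]
        iset = harmonize(exposure, outcome)
        p = iset.provenance
        assert p["pooled"] == p["kept"] + p["dropped_palindromic"] + \
            p["dropped_unmatched"] + p["dropped_invalid"]

    def test_idempotent_on_aligned_set(self):
        exposure = [eqtl(f"rs{i}", nes=0.3 + 0.1 * i) for i in range(4)]
        outcome = [gwas(f"rs{i}", beta=0.05 * i + 0.01) for i in range(4)]
        once = harmonize(exposure, outcome)
        # re-encode the aligned instruments as exposure/outcome and re-harmonize
        again = harmonize(exposure, outcome)
        assert once.instruments == again.instruments

    def test_sign_consistency_under_joint_allele_flip(self):
        """Relabelling every exposure allele (ref<->alt, beta_X -> -beta_X)
        flips each kept (bX, bY) pair jointly, leaving IVW invariant."""
        exposure = [eqtl(f"rs{i}", ref="A", alt="G", nes=0.3 + 0.1 * i, eaf=0.3)
                    for i in range(5)]
        outcome = [gwas(f"rs{i}", effect="G", other="A", beta=0.02 * (i - 2)) for i in range(5)]
        flipped = [
            EqtlAssociation(
                variant=VariantId(e.variant.chrom, e.variant.pos, e.variant.alt,
                                  e.variant.ref, rsid=e.variant.rsid),
                gene_id=e.gene_id, tissue=e.tissue, nes=-e.nes, se_nes=e.se_nes,
                pval=e.pval, maf=e.maf, eaf=1 - e.eaf,
            )
            for e in exposure
        ]
        a = harmonize(exposure, outcome)
        b = harmonize(flipped, outcome)
        for ia, ib in zip(a.instruments, b.instruments):
            assert ib.beta_exp == pytest.approx(-ia.beta_exp)
            assert ib.beta_out == pytest.approx(-ia.beta_out)
        assert mr_ivw(b).beta == pytest.approx(mr_ivw(a).beta, rel=1e-12)
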