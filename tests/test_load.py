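"""Effect annotation, SNP filtering, deleteriousness, polarization, load counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyload.errors import ConsistencyError, CoordinateError, FormatError
from polyload.genes import GeneModel
from polyload.load import (
    annotate_effect,
    classify_deleterious,
    filter_snps,
    polarize,
    run_load_pipeline,
    summarize_load,
)
from polyload.vcfio import HET, HOM_ALT, HOM_REF, MISSING, VariantTable

# hand-built plus-strand gene on a 100 bp sequence:
#   CDS: ATG GCC TGG GGA TAA split across two exons around a 20 bp intron
EXON1 = "ATGGCCTGG"  # codons 0-2
INTRON = "GT" + "A" * 16 + "AG"
EXON2 = "GGATAA"  # codons 3-4 (stop)
PLUS_SEQ = "C" * 10 + EXON1 + INTRON + EXON2 + "C" * 55
PLUS_GENE = GeneModel(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exons=((11, 19), (40, 45)),
    cds_start=11,
    cds_end=45,
)
SEQS = {"chr1": PLUS_SEQ}


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# the same transcript placed on the minus strand
MINUS_SEQ = "C" * 10 + _revcomp(EXON1 + INTRON + EXON2) + "C" * 55
MINUS_GENE = GeneModel(
    gene_id="g2",
    chrom="chr2",
    strand="-",
    exons=((11, 16), (37, 45)),
    cds_start=11,
    cds_end=45,
)


class TestAnnotateEffect:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (11, "A", "C", "start_loss"),  # ATG -> CTG
            (18, "G", "A", "stop_gain"),  # TGG -> TGA
            (42, "A", "G", "synonymous"),  # GGA -> GGG
            (15, "C", "A", "nonsynonymous"),  # GCC -> GAC (Ala->Asp)
            (43, "T", "C", "stop_loss"),  # TAA -> CAA
            (20, "G", "T", "splice"),  # intron donor G
            (39, "G", "C", "splice"),  # intron acceptor G
            (21, "T", "C", "splice"),  # second donor base
            (25, "A", "G", "intronic"),  # intron interior
            (5, "C", "T", "intergenic"),
            (60, "C", "G", "intergenic"),
        ],
    )
    def test_plus_strand(self, pos, ref, alt, expected):
        effect, gene = annotate_effect("chr1", pos, ref, alt, [PLUS_GENE], SEQS)
        assert effect == expected
        if expected != "intergenic":
            assert gene == "g1"

    @pytest.mark.parametrize(
        "tpos,tref,talt,expected",
        [
            (0, "A", "C", "start_loss"),
            (7, "G", "A", "stop_gain"),
            (31, "A", "G", "synonymous"),
            (28, "G", "T", "splice"),  # acceptor AG in transcript orientation
        ],
    )
    def test_minus_strand(self, tpos, tref, talt, expected):
        # transcript offset t maps to genomic position 45 - t; bases complement
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pos = 45 - tpos
        effect, gene = annotate_effect(
            "chr2", pos, comp[tref], comp[talt], [MINUS_GENE], {"chr2": MINUS_SEQ}
        )
        assert effect == expected
        assert gene == "g2"

    def test_out_of_bounds(self):
        with pytest.raises(CoordinateError):
            annotate_effect("chr1", 1000, "A", "C", [PLUS_GENE], SEQS)

    def test_ref_mismatch_detected(self):
        with pytest.raises(ConsistencyError):
            annotate_effect("chr1", 11, "G", "C", [PLUS_GENE], SEQS)

    def test_overlapping_genes_most_severe_wins(self):
        # same span twice: one copy sees stop_gain, the shifted copy intronic
        effect, gene = annotate_effect("chr1", 18, "G", "A", [PLUS_GENE, PLUS_GENE], SEQS)
        assert effect == "stop_gain"


def make_table(gt, dp=None, pos=None, samples=None):
    gt = np.asarray(gt, dtype=np.int8)
    n, k = gt.shape
    return VariantTable(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n + 1) * 100, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        gt=gt,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        samples=tuple(samples or (f"S{i}" for i in range(k))),
    )


class TestFilterSNPs:
    def test_low_dp_masks_genotype_but_site_survives(self):
        gt = np.array([[HET] * 10])
        dp = np.full((1, 10), 30)
        dp[0, 0] = 5
        out = filter_snps(make_table(gt, dp), min_dp=13, min_maf=0.05, max_missing=0.1)
        assert len(out) == 1  # missing rate exactly 0.1, MAF 9/18 = 0.5
        assert out.gt[0, 0] == MISSING

    def test_maf_below_threshold_dropped(self):
        gt = np.array([[HOM_REF] * 24 + [HET]])  # MAF = 1/50 = 0.02
        dp = np.full((1, 25), 30)
        out = filter_snps(make_table(gt, dp), min_maf=0.05)
        assert len(out) == 0

    def test_requires_dp(self):
        with pytest.raises(FormatError):
            filter_snps(make_table(np.array([[HET, HET]])), min_dp=13)

    def test_brute_force_oracle(self, rng):
        n_sites, n_samples = 300, 12
        gt = rng.integers(-1, 3, size=(n_sites, n_samples)).astype(np.int8)
        dp = rng.integers(0, 40, size=(n_sites, n_samples))
        table = make_table(gt, dp)
        out = filter_snps(table, min_dp=13, min_maf=0.05, max_missing=0.1)
        kept = []
        for i in range(n_sites):
            g = [MISSING if dp[i, j] < 13 else gt[i, j] for j in range(n_samples)]
            called = [x for x in g if x != MISSING]
            if not called:
                continue
            miss = 1 - len(called) / n_samples
            a = sum(called)
            p = a / (2 * len(called))
            if miss <= 0.1 and min(p, 1 - p) >= 0.05:
                kept.append(int(table.pos[i]))
        assert list(out.pos) == kept

    @given(maf=st.sampled_from([0.0, 0.02, 0.05, 0.1, 0.2]), miss=st.sampled_from([0.0, 0.1, 0.3, 1.0]))
    @settings(max_examples=20, deadline=None)
    def test_filter_monotonicity(self, maf, miss):
        rng = np.random.default_rng(7)
        gt = rng.integers(-1, 3, size=(200, 10)).astype(np.int8)
        dp = rng.integers(0, 40, size=(200, 10))
        table = make_table(gt, dp)
        base = len(filter_snps(table, min_maf=maf, max_missing=miss))
        stricter = len(filter_snps(table, min_maf=maf + 0.05, max_missing=max(0.0, miss - 0.1)))
        assert stricter <= base


class TestClassifyDeleterious:
    @pytest.mark.parametrize(
        "prov,sift,expected",
        [
            (-3.0, 0.01, True),
            (-3.0, 0.20, False),
            (-2.5, 0.049, False),  # PROVEAN boundary is strict
            (-2.51, 0.05, False),  # SIFT boundary is strict
            (-2.51, 0.049, True),
            (-2.49, 0.049, False),
            (2.0, 0.9, False),
            (np.nan, 0.01, False),
            (-5.0, np.nan, False),
        ],
    )
    def test_truth_table(self, prov, sift, expected):
        assert bool(classify_deleterious([prov], [sift])[0]) is expected


class TestPolarize:
    @pytest.mark.parametrize(
        "o1,o2,expect_polarized,expect_anc",
        [
            ("A", "A", True, "A"),  # both hom-ref -> derived = alt
            ("G", "G", True, "G"),  # both hom-alt -> derived = ref
            ("het", "A", False, ""),
            (".", "A", False, ""),
            ("C", "C", False, ""),  # third base
            ("A", "G", False, ""),  # discordant homozygotes
        ],
    )
    def test_rules(self, o1, o2, expect_polarized, expect_anc):
        ok, anc, der = polarize(["A"], ["G"], [o1], [o2])
        assert bool(ok[0]) is expect_polarized
        assert anc[0] == expect_anc
        if expect_polarized:
            assert {anc[0], der[0]} == {"A", "G"}


class TestSummarizeLoad:
    def test_no_polarized_sites_all_zero(self):
        table = make_table(np.array([[HET, HOM_ALT]]))
        s = summarize_load(table, ["nonsynonymous"], ["g1"], [True], [False], [""])
        assert s.per_sample[["ddm_total", "ddm_hom", "dmem_total", "dmem_hom"]].to_numpy().sum() == 0
        assert s.ddm_sites == 0 and s.dmem_sites == 0

    def test_brute_force_oracle(self, rng):
        n_sites, n_samples = 400, 20
        gt = rng.integers(-1, 3, size=(n_sites, n_samples)).astype(np.int8)
        table = make_table(gt)
        effects = rng.choice(
            ["nonsynonymous", "synonymous", "stop_gain", "splice", "intergenic"], size=n_sites
        )
        genes = [f"g{i % 37}" if e != "intergenic" else None for i, e in enumerate(effects)]
        deleterious = rng.random(n_sites) < 0.3
        polarized = rng.random(n_sites) < 0.7
        derived = np.where(rng.random(n_sites) < 0.5, "G", "A")  # alt is G, ref is A
        derived = np.where(polarized, derived, "")
        s = summarize_load(table, effects, genes, deleterious, polarized, derived)

        major = {"start_loss", "stop_gain", "stop_loss", "splice"}
        for col, site_pred in [
            ("ddm", lambda i: polarized[i] and deleterious[i]),
            ("dmem", lambda i: polarized[i] and effects[i] in major),
        ]:
            for j in range(n_samples):
                tot = hom = 0
                for i in range(n_sites):
                    if not site_pred(i):
                        continue
                    g = gt[i, j]
                    if g == MISSING:
                        continue
                    if derived[i] == "G":  # derived is alt
                        carrier, is_hom = g in (HET, HOM_ALT), g == HOM_ALT
                    else:  # derived is ref
                        carrier, is_hom = g in (HET, HOM_REF), g == HOM_REF
                    tot += carrier
                    hom += is_hom
                row = s.per_sample.iloc[j]
                assert row[f"{col}_total"] == tot
                assert row[f"{col}_hom"] == hom

    def test_invariant_hom_le_total_le_sites(self, rng):
        gt = rng.integers(-1, 3, size=(100, 8)).astype(np.int8)
        table = make_table(gt)
        polarized = rng.random(100) < 0.5
        derived = np.where(polarized, "G", "")
        s = summarize_load(
            table, ["nonsynonymous"] * 100, ["g"] * 100, [True] * 100, polarized, derived
        )
        for _, row in s.per_sample.iterrows():
            assert row.ddm_hom <= row.ddm_total <= s.ddm_sites

    def test_polarization_ignores_cohort_frequencies(self, rng):
        # permuting samples permutes rows but never changes ancestral calls
        ref, alt = ["A"] * 50, ["G"] * 50
        o1 = rng.choice(["A", "G", "het"], size=50)
        o2 = rng.choice(["A", "G", "."], size=50)
        ok1, anc1, _ = polarize(ref, alt, o1, o2)
        ok2, anc2, _ = polarize(ref, alt, o1, o2)  # polarize sees no genotypes at all
        assert np.array_equal(ok1, ok2) and np.array_equal(anc1, anc2)


class TestPipelineOnSimulatedCohort:
    def test_planted_load_recovered_exactly(self, population_inputs):
        d = population_inputs
        summary, detail = run_load_pipeline(
            d["table"], d["scores"], d["outgroups"], d["genes"], d["sequences"]
        )
        truth = d["truth"]
        ps = summary.per_sample
        assert (ps.ddm_hom == truth.ddm_hom_per_sample).all()
        assert (ps.ddm_total == truth.ddm_total_per_sample).all()
        assert (ps.dmem_hom == truth.dmem_hom_per_sample).all()
        assert (ps.dmem_total == truth.dmem_total_per_sample).all()
        assert summary.ddm_sites == truth.n_ddm_sites
        assert summary.dmem_sites == truth.n_dmem_sites
        assert summary.ddm_genes == truth.n_ddm_genes
        assert summary.dmem_genes == truth.n_dmem_genes
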