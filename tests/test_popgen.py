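"""Windowed nucleotide diversity and ROH scanning."""

from fractions import Fraction

import numpy as np
import pytest

from polyload.errors import InvalidParameterError, OrderingError
from polyload.popgen import (
    ROHSegment,
    roh_summary,
    scan_roh,
    site_diversity,
    windowed_pi,
)
from polyload.vcfio import HET, HOM_ALT, HOM_REF, MISSING, VariantTable


def make_table(gt, pos, samples=None, chrom="chr1"):
    gt = np.asarray(gt, dtype=np.int8)
    n, k = gt.shape
    return VariantTable(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        gt=gt,
        samples=tuple(samples or (f"S{i}" for i in range(k))),
    )


def brute_site_h(gt_row):
    """Exact average pairwise difference among allele copies, as a Fraction."""
    alleles = []
    for g in gt_row:
        if g == HOM_REF:
            alleles += [0, 0]
        elif g == HET:
            alleles += [0, 1]
        elif g == HOM_ALT:
            alleles += [1, 1]
    n = len(alleles)
    if n < 2:
        return Fraction(0)
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if alleles[i] != alleles[j]
    )
    return Fraction(diff, n * (n - 1) // 2)


def brute_roh(pos, g, window_snps=20, min_length=5000, min_snps=10):
    """O(n) enumeration of maximal homozygous stretches with post-filters."""
    segs = []
    n = len(g)
    i = 0
    while i < n:
        if g[i] not in (HOM_REF, HOM_ALT):
            i += 1
            continue
        j = i
        while j + 1 < n and g[j + 1] in (HOM_REF, HOM_ALT):
            j += 1
        cnt = j - i + 1
        span = int(pos[j] - pos[i] + 1)
        if cnt >= window_snps and cnt >= min_snps and span > min_length:
            segs.append((int(pos[i]), int(pos[j]), cnt))
        i = j + 1
    return segs


class TestWindowedPi:
    def test_hand_case_two_hets(self):
        # one SNP, genotypes 0/1 and 0/1: alleles (0,1,0,1), n=4, a=2:
        # 4 of the 6 allele pairs differ -> h = 2*2*2/(4*3) = 2/3
        table = make_table([[HET, HET]], pos=[500])
        out = windowed_pi(table, window_size=10_000, seq_lengths={"chr1": 10_000})
        assert len(out) == 1
        assert out.pi[0] == pytest.approx((2 / 3) / 10_000)
        assert brute_site_h(table.gt[0]) == Fraction(2, 3)

    def test_empty_window_zero(self):
        table = make_table([[HET, HET]], pos=[500])
        out = windowed_pi(table, window_size=10_000, seq_lengths={"chr1": 30_000})
        assert list(out.pi[1:]) == [0.0, 0.0]

    def test_monomorphic_contributes_zero(self):
        table = make_table([[HOM_REF, HOM_REF]], pos=[500])
        out = windowed_pi(table, window_size=10_000)
        assert out.pi.sum() == 0.0

    def test_single_callable_sample_skipped(self):
        # one called het sample: its two allele copies differ -> h = 1
        table = make_table([[HET, MISSING]], pos=[500])
        assert site_diversity(table.gt)[0] == pytest.approx(1.0)
        table = make_table([[MISSING, MISSING]], pos=[500])
        assert site_diversity(table.gt)[0] == 0.0

    def test_doubling_window_halves_pi(self, rng):
        gt = rng.integers(-1, 3, size=(50, 6)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_001), size=50, replace=False))
        table = make_table(gt, pos)
        small = windowed_pi(table, window_size=10_000, seq_lengths={"chr1": 10_000})
        big = windowed_pi(table, window_size=20_000, seq_lengths={"chr1": 10_000})
        assert big.pi[0] == pytest.approx(small.pi[0] / 2)

    def test_sample_order_invariance(self, rng):
        gt = rng.integers(-1, 3, size=(40, 8)).astype(np.int8)
        pos = np.arange(1, 41) * 100
        perm = rng.permutation(8)
        a = windowed_pi(make_table(gt, pos), window_size=5000)
        b = windowed_pi(make_table(gt[:, perm], pos), window_size=5000)
        assert np.allclose(a.pi, b.pi)

    @pytest.mark.parametrize("n_samples", [2, 5, 8])
    def test_exact_rational_oracle(self, n_samples, rng):
        for _ in range(30):
            gt = rng.integers(-1, 3, size=(1, n_samples)).astype(np.int8)
            h = site_diversity(gt)[0]
            row = gt[0]
            called = int(np.sum(row != MISSING))
            n = 2 * called
            a = int(np.where(row > 0, row, 0).sum())
            exact = Fraction(2 * a * (n - a), n * (n - 1)) if n >= 2 else Fraction(0)
            assert exact == brute_site_h(row)
            assert h == pytest.approx(float(exact), abs=1e-15)


class TestScanROH:
    def test_long_hom_run_emitted(self):
        pos = np.arange(25) * 250 + 1  # 25 SNPs spanning 6001 bp
        gt = np.full((25, 1), HOM_REF, dtype=np.int8)
        segs = scan_roh(make_table(gt, pos))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end, seg.n_snps) == (1, 6001, 25)
        assert seg.span == 6001

    def test_few_snps_not_emitted(self):
        pos = np.linspace(1, 6001, 9).astype(int)  # 9 hom SNPs over 6 kb
        gt = np.full((9, 1), HOM_ALT, dtype=np.int8)
        assert scan_roh(make_table(gt, pos)) == []

    def test_het_terminates_runs(self):
        pos = np.arange(50) * 300 + 1  # generous spacing: each half spans > 5 kb
        gt = np.full((50, 1), HOM_REF, dtype=np.int8)
        gt[24, 0] = HET
        segs = scan_roh(make_table(gt, pos))
        assert [s.n_snps for s in segs] == [24, 25]

    def test_missing_terminates_runs(self):
        pos = np.arange(30) * 300 + 1
        gt = np.full((30, 1), HOM_REF, dtype=np.int8)
        gt[5, 0] = MISSING
        segs = scan_roh(make_table(gt, pos))
        assert [s.n_snps for s in segs] == [24]

    def test_unsorted_raises(self):
        gt = np.full((3, 1), HOM_REF, dtype=np.int8)
        with pytest.raises(OrderingError):
            scan_roh(make_table(gt, [10, 5, 20]))

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = 1000
        pos = np.cumsum(rng.integers(50, 500, size=n))
        gt = rng.choice(
            [HOM_REF, HET, HOM_ALT, MISSING], size=(n, 2), p=[0.55, 0.2, 0.2, 0.05]
        ).astype(np.int8)
        table = make_table(gt, pos)
        segs = scan_roh(table)
        for j, sample in enumerate(table.samples):
            got = [(s.start, s.end, s.n_snps) for s in segs if s.sample == sample]
            assert got == brute_roh(pos, gt[:, j])

    def test_planted_tracts_recovered_exactly(self, population_sim):
        segs = scan_roh(population_sim.table)
        found = {(s.sample, s.start, s.end, s.n_snps) for s in segs}
        planted = {
            (r.sample, r.start, r.end, r.n_snps)
            for r in population_sim.truth.roh
            if r.n_snps >= 20 and (r.end - r.start + 1) > 5000
        }
        assert planted <= found


class TestROHSummary:
    def test_binning(self):
        segs = [
            ROHSegment("S1", "c", 1, 6_000, 30),
            ROHSegment("S1", "c", 10_000, 50_000, 200),
        ]
        out = roh_summary(segs)
        got = dict(zip(out["bin"].astype(str), out["count"]))
        assert got == {"5000-10000": 1, ">30000": 1}

    def test_empty(self):
        assert len(roh_summary([])) == 0

    def test_unsorted_edges_raise(self):
        with pytest.raises(InvalidParameterError):
            roh_summary([], bin_edges=(10_000, 5_000))

    def test_brute_force_tally(self, rng):
        spans = rng.integers(5_001, 60_000, size=200)
        segs = [
            ROHSegment(f"S{int(i % 3)}", "c", 1, int(span), 50)
            for i, span in enumerate(spans)
        ]
        out = roh_summary(segs)
        for sample in {s.sample for s in segs}:
            for lab, lo, hi in [
                ("5000-10000", 5_000, 10_000),
                ("10000-30000", 10_000, 30_000),
                (">30000", 30_000, 10**12),
            ]:
                expect = [s.span for s in segs if s.sample == sample and lo < s.span <= hi]
                row = out[(out["sample"] == sample) & (out["bin"].astype(str) == lab)]
                if expect:
                    assert int(row["count"].iloc[0]) == len(expect)
                    assert int(row["total_bp"].iloc[0]) == sum(expect)
                else:
                    assert len(row) == 0
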