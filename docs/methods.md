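# Methods

This note records the models, rules and numerical choices behind each stage,
what the synthetic-data generators do and do not emulate, and the design
decisions taken where more than one reasonable convention exists.

## k-mer spectrum ploidy calling (`polyload.kmer`)

A whole-genome-read k-mer spectrum from a p-ploid individual is modelled as
a mixture of count distributions centred at j·c for j = 1..p, where
c is the per-copy depth: k-mers shared by all homologous copies appear at
the homozygous depth p·c, k-mers private to j copies at j·c, and sequencing
errors pile up at multiplicities 1–3.

Procedure: the spectrum is smoothed with a centred moving average
(`smooth_width`, default 3 — the smallest width that suppresses
single-bin noise without shifting peak positions). The **error cutoff** is
the first local minimum of the smoothed spectrum (the valley between error
decay and signal), the convention jellyfish/GenomeScope users apply by eye.
Peaks are local maxima above the cutoff with prominence at least
`min_prominence_fraction` (default 0.05) of the global maximum above the
cutoff; on flat plateaus the lower multiplicity wins. The **ploidy call** is
round(hom/het) where hom is the highest-multiplicity prominent peak (repeat
shoulders can out-count the homozygous peak but never out-run it to the
right) and het is the leftmost prominent peak. One-peak spectra return an
indeterminate call rather than guessing between haploid and fully
homozygous polyploid. **Genome size** is Σ m·count(m) above the cutoff
divided by the homozygous peak depth; for a tetraploid spectrum this is the
whole (4n) size, matching how whole-genome estimates are quoted for
autotetraploids while diploids are quoted as monoploid sizes.

A property of mixture spectra worth knowing: the 3c sub-peak of a
tetraploid rides the rising flank of the much larger homozygous peak and
only becomes a distinct local maximum when the heterozygous k-mer fraction
exceeds roughly 0.4 — far above what nucleotide diversity of a few per
mille produces (~0.15 of 17-mer loci). The ploidy rule is insensitive to
this because it only needs the leftmost and homozygous peaks.

## Collapse accounting (`polyload.collapse`)

Reads mapped back to an assembly cover a region at m times the baseline
depth when m near-identical homologous copies were merged (collapsed) into
one sequence. Per 10 kb window (trailing partial windows kept iff at least
half a window long, to avoid length bias at contig ends), the ratio of
window depth to baseline maps to a collapse class: class 1 below 1.5, then
left-closed bins [1.5, 2.5) → 2, [2.5, 3.5) → 3, [3.5, ∞) → 4. The
touching printed ranges do not resolve the boundary points; half-open on
the left is the deterministic choice here, and a ratio of exactly 2.5 is
class 3. Near-zero dropout windows also map to class 1 — no sub-haploid
class is defined.

The **baseline** ("overall coverage depth") is the median of window mean
depths: robust against the very collapsed regions being measured inflating
the reference level, which a mean would absorb. When the cohort's overall
depth is known externally, an explicit `baseline=`/`--baseline` override
bypasses the median. Note that under heavy collapse (≳ 45% of windows
above 1×) the median itself sits a few percent above the single-copy depth;
class assignment tolerates this because classes are 50% of baseline apart.

Hidden homologous length: O = L₂ + 2·L₃ + 3·L₄, because a window
representing m merged copies hides m−1 copies of sequence. Reconciliation
(A + O)/E compares assembled size plus hidden length with the k-mer
estimated size; values near 1 mean collapse explains the assembly/estimate
gap.

## 4D divergence, 4DTv and mutation rate (`polyload.molevol`)

A third codon position is fourfold degenerate when its codon's first two
bases determine the amino acid (prefixes CT, GT, TC, CC, AC, GC, CG, GG in
the standard code). A site is eligible only if **both** sequences are
gap-free and unambiguous at the codon and share the same first-two-base
prefix — otherwise the site's degeneracy class is ambiguous between the
sequences. D is the raw observed fraction of eligible sites that differ
(no multiple-hit correction by default, since at divergences of a few
percent the correction is negligible; a Jukes–Cantor flag exists). 4DTv
counts only purine↔pyrimidine differences, so 4DTv ≤ D always.

μ = D·g/(2T) per site per generation: the divergence D accumulates along
two lineages for T years, i.e. 2T/g generations. T is taken in years; the
CLI accepts millions of years only with an explicit `--t-mya` flag to avoid
silent 10⁶ errors. The default generation-time panel is {15, 20, 30} years,
the bracketing used for slow-maturing tropical trees whose earliest
reproduction is around 10–12 years.

Multi-ortholog input can be aggregated `pooled` (concatenate sites) or
`mean` (each pair weighted equally); both are exposed because either
convention is defensible and they differ when ortholog lengths vary.

Distance-distribution modes (for Ks or 4DTv samples across paralog pairs,
where secondary modes mark whole-genome duplications) are read from a
histogram (default bin 0.01) smoothed with a width-3 moving average; local
maxima with ≥ 5% of the maximum's prominence count as modes — a
deterministic stand-in for reading peaks off a plot.

## Genetic load (`polyload.load`)

Pipeline order: depth-filter genotypes, then sites; annotate effects;
intersect deleteriousness scores; polarize; count.

- **Filter.** DP < 13 masks the genotype (per-genotype semantics, as in
  `vcftools --minDP`; the phrase "minimum depth" is ambiguous between
  per-site and per-genotype, and per-genotype is the stricter, standard
  reading). Sites are kept iff missing fraction ≤ 0.1 and MAF ≥ 0.05
  computed over non-missing alleles. Only bi-allelic SNPs are handled.
- **Effects.** Gene models are exon spans + CDS range + strand; the variant
  codon is translated strand-aware with the standard code. Disrupted
  initial ATG → start_loss; sense→stop → stop_gain; stop→sense →
  stop_loss; intronic positions within 2 bp of an exon boundary (the
  canonical GT–AG dinucleotides) → splice; otherwise synonymous /
  nonsynonymous / intronic / intergenic. For overlapping genes the most
  severe effect wins, in the order stop_gain > start_loss > stop_loss >
  splice > nonsynonymous > synonymous > intronic > intergenic.
- **Deleteriousness.** A nonsynonymous SNP is deleterious iff
  PROVEAN-like < −2.5 **and** SIFT-like < 0.05, both strict; a missing
  score means unsupported. The scoring engines themselves are not
  reimplemented — scores are an input table, because the contribution
  here is the intersection-and-polarization procedure, not the scorers.
- **Polarization.** A site polarizes iff both outgroup species are
  homozygous for the same base and that base is ref or alt; the other
  allele is derived. Outgroups homozygous for a third base leave the site
  unpolarized (conservative). Polarization never looks at focal-cohort
  genotype frequencies.
- **Counting.** DDM = polarized + deleterious; DMEM = polarized + effect in
  {start_loss, stop_gain, stop_loss, splice}. Per individual a site counts
  toward the total if the sample carries ≥ 1 derived allele and toward the
  homozygous column if both alleles are derived. Both columns are reported
  because published per-individual averages do not always say which is
  meant; cohort-level site and distinct-gene counts are also emitted.

## Diversity and ROH (`polyload.popgen`)

Per-site diversity is h = 2a(n−a)/(n(n−1)) over the n non-missing allele
copies with alt count a — exactly the average pairwise difference among
the sampled allele copies. Window π divides Σh by the window length in bp
(the `vcftools --window-pi` convention), not by the SNP count, so windows
without SNPs have π = 0. Sites with fewer than two called allele copies are
skipped.

ROH: candidate runs are maximal stretches of consecutive homozygous,
non-missing genotypes of one sample (heterozygous **or missing** genotypes
terminate runs — a zero-heterozygote rule). A run is emitted iff it
contains at least one full scan window of 20 consecutive homozygous SNPs
(equivalently ≥ 20 SNPs in the run), spans strictly more than 5,000 bp
(first SNP to last SNP inclusive, not padded to flanking midpoints) and has
≥ 10 SNPs. This is deliberately simpler than PLINK's heuristic, whose
heterozygote allowance, density and gap parameters are rarely reported;
with the zero-het rule the output is exactly reproducible and equals a
brute-force enumeration, at the cost of fragmenting runs at genotyping
errors. A `max_het`-style relaxation is deliberately not on by default.
Length bins for summaries are (5, 10], (10, 30], (30, ∞) kb.

## Synthetic data (`polyload.simulate`)

Every generator is a pure function of its parameters and a seed and stores
its planted truth alongside the data.

- **Spectra.** Counts per multiplicity are Poisson draws around the
  analytic mixture expectation (components at j·c), which has the same law
  at histogram level as per-k-mer simulation but costs O(max multiplicity).
  A heterozygous locus contributes k-mers at j·c *and* (p−j)·c, so its
  total mass equals one locus at the homozygous depth and genome-size
  recovery is unbiased. Default heterozygous-locus fraction 0.15: the
  probability that a 17-mer window segregates among four homologous copies
  at per-site diversity of a few per mille. Errors decay geometrically
  over multiplicities 1–3 (ratio 0.25) scaled by `error_rate`.
- **Depth tracks.** Exact window counts per planted class (rounded
  fractions), lognormal depth around m·base_depth at the requested CV —
  lognormal because depth is strictly positive and right-skewed; the real
  noise law behind published depth tracks is not stated anywhere, so this
  is this package's choice.
- **Codon alignments.** ~70% of codons from fourfold families; third
  positions flip with probability d4 (≤ 0.5: single-substitution regime),
  transversions with probability `tv_fraction`; realized counts go into the
  truth, so recovery tests are exact rather than statistical.
- **Cohorts.** One chromosome; a gene region at the start hosts all planted
  coding sites, neutral background SNPs (frequency chosen so that expected
  π matches `pi_target`) fill the rest. Planted load sites use a balanced
  rotation design: each of S sites has k heterozygous and n−k
  homozygous-derived samples, with k the smallest value whose MAF k/(2n)
  clears the filter threshold and S·(n−k) = H·n, so **every** sample is
  homozygous-derived at exactly H sites (default H = 85 DDMs, 73 DMEMs —
  the per-individual load magnitudes reported for wild autotetraploid
  *Hopea* populations) and a carrier at all S. Planted scores are drawn
  clear of the thresholds by more than the 4-decimal file precision.
  Major-effect sites are physically planted in two-exon genes (alternating
  strands) so the annotation stage genuinely re-derives start_loss /
  stop_gain / stop_loss / splice from sequence. Outgroup rows at planted
  sites are always concordant-ancestral (otherwise the planted truth would
  be unrecoverable by construction); the `outgroup_concordance` probability
  applies to neutral and decoy sites. ROH tracts are carved into the
  neutral region per sample, forcing homozygosity inside and a heterozygote
  at the flanking SNP on each side so recovered boundaries are exact.

What the generators do **not** emulate: read-level data (FASTQ/BAM),
linkage disequilibrium and realistic site-frequency spectra (neutral
genotypes are i.i.d. binomial), tetraploid dosage genotypes (cohorts are
diploid-coded, mirroring how tetraploid cohorts are mapped onto monoploid
references and genotyped as diploids), GC-biased or mapping-biased depth,
negative-binomial overdispersion of k-mer counts, multi-allelic sites,
UTRs and alternative splicing. Passing tests therefore demonstrate the
correctness of the accounting rules on clean inputs, not robustness to
these real-data complications.

## Problem sizes and tolerances in the test suite

The suite exercises: 20 replicate 5,000-window tracks (overlap within 5%,
classification ≥ 99%); 100 spectra per ploidy in {2,3,4} (≥ 95 correct,
size within 5%); 100,000-codon alignments at d4 ∈ {0.005, 0.02, 0.1}
(D within 3 binomial SE, exact oracle equality on 300-codon alignments);
a 30-sample cohort with ~10,400 sites (planted load recovered exactly and
equal to a per-site/per-sample loop); 200 random 1,000-SNP chromosomes
(ROH equal to the enumeration oracle); exact rational comparison of h
against the exhaustive pairwise average for ≤ 8 samples; and byte-identical
reruns of every generator under a fixed seed. These sizes keep the full
suite around ten seconds while leaving the statistical tolerances
comfortably non-trivial.

## Known limitations

- The effect annotator assumes clean gene models (CDS length divisible by
  3, no trans-splicing, no overlapping exons within a gene); UTR exon
  positions fall back to the non-coding background class.
- `find_4d_sites` requires identical codon prefixes, which slightly
  undercounts 4D sites between highly diverged sequences; at the few-percent
  divergences used for mutation-rate calibration the effect is negligible.
- The ROH rule is not PLINK-compatible by design; comparisons against
  PLINK output should expect fragmentation differences around isolated
  heterozygotes.
- The median baseline depth is biased upward when more than ~45% of the
  genome is collapsed; supply an external baseline in that regime.
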