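"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and returns
the generated object together with a truth record from which every planted
quantity can be recovered: k-mer spectra with peaks at c, 2c, ..., p*c;
depth tracks with windows collapsed 2x/3x/4x; codon alignments with a chosen
4D-site divergence and transversion share; and cohort VCFs with planted
derived deleterious/major-effect mutations, outgroup tables, deleteriousness
scores, gene models, a reference sequence and runs of homozygosity.

Planted load sites are built so that they survive the cohort SNP filter: at
each planted site k samples are heterozygous and n-k homozygous for the
derived allele, with k chosen so the minor allele frequency clears the MAF
threshold and the heterozygous set rotating across sites so that every
sample is homozygous-derived at exactly the requested number of sites.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import ceil, sqrt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import poisson

from .collapse import DepthTrack
from .errors import InvalidParameterError
from .genes import GeneModel, revcomp, write_gene_table
from .kmer import KmerHistogram
from .vcfio import HET, HOM_ALT, VariantTable, write_vcf

__all__ = [
    "KmerTruth",
    "DepthTruth",
    "AlignmentTruth",
    "LoadSpec",
    "PopulationTruth",
    "PopulationSim",
    "simulate_kmer_histogram",
    "simulate_depth_track",
    "simulate_codon_alignment",
    "simulate_population_vcf",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

FOURFOLD_PREFIX_LIST = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
_NON4D_CODONS = ("ATG", "TGG", "AAT", "GAT", "TTT", "CAT", "AAA", "GAA", "TAT", "ATT")


# ---------------------------------------------------------------------------
# k-mer spectra


@dataclass(frozen=True)
class KmerTruth:
    seed: int
    ploidy: int
    hom_depth: float
    genome_size: int
    het_fraction: float
    error_rate: float


def simulate_kmer_histogram(
    ploidy: int,
    hom_depth: float,
    genome_size: int,
    het_fraction: float = 0.15,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[KmerHistogram, KmerTruth]:
    """Tetraploid-style k-mer spectrum with peaks at c, 2c, ..., ploidy*c.

    A fraction ``het_fraction`` of k-mer loci segregate among the homologous
    copies: such a locus splits into one k-mer present in j copies and one in
    ploidy-j copies (j uniform), so its two variants appear at depths j*c and
    (ploidy-j)*c and its total mass still equals one locus at the homozygous
    depth.  Counts per multiplicity are Poisson around the analytic mixture
    expectation; sequencing errors add a geometric tail over multiplicities
    1-3 scaled by ``error_rate``.
    """
    if ploidy < 1:
        raise InvalidParameterError("ploidy must be >= 1")
    if hom_depth <= 0 or genome_size <= 0:
        raise InvalidParameterError("hom_depth and genome_size must be positive")
    if genome_size < 10_000:
        raise InvalidParameterError("genome_size must be >= 1e4 for a stable spectrum")
    if not 0 <= het_fraction < 1:
        raise InvalidParameterError("het_fraction must lie in [0, 1)")
    if not 0 <= error_rate < 1:
        raise InvalidParameterError("error_rate must lie in [0, 1)")
    c = hom_depth / ploidy
    if c < 5:
        raise InvalidParameterError("hom_depth/ploidy must be >= 5 so peaks are separable")

    rng = np.random.default_rng(seed)
    n_var = int(round(het_fraction * genome_size)) if ploidy > 1 else 0
    n_hom = genome_size - n_var

    # distinct-k-mer mass per copy-number class
    mass = np.zeros(ploidy + 1)
    mass[ploidy] += n_hom
    if n_var:
        js = rng.integers(1, ploidy, size=n_var)
        for j in range(1, ploidy):
            nj = int(np.sum(js == j))
            mass[j] += nj  # variant in j copies...
            mass[ploidy - j] += nj  # ...and its counterpart in the rest

    max_m = int(ceil(hom_depth + 6 * sqrt(hom_depth))) + 3
    m = np.arange(1, max_m + 1)
    expected = np.zeros(max_m)
    for j in range(1, ploidy + 1):
        if mass[j]:
            expected += mass[j] * poisson.pmf(m, j * c)
    if error_rate > 0:
        w = np.array([1.0, 0.25, 0.0625])
        err_mass = error_rate * genome_size
        expected[:3] += err_mass * w / w.sum()

    counts = rng.poisson(expected)
    keep = counts > 0
    hist = KmerHistogram(m[keep], counts[keep])
    truth = KmerTruth(seed, ploidy, hom_depth, genome_size, het_fraction, error_rate)
    return hist, truth


# ---------------------------------------------------------------------------
# depth tracks


@dataclass(frozen=True)
class DepthTruth:
    seed: int
    base_depth: float
    window_size: int
    class_lengths: dict[int, int]  # bp per multiplicity class 1..4
    classes: tuple[int, ...]  # true class per window
    overlap: int  # true hidden length L2 + 2*L3 + 3*L4


def simulate_depth_track(
    n_windows: int,
    window_size: int = 10_000,
    base_depth: float = 50.0,
    collapse_spec: Optional[dict[int, float]] = None,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[DepthTrack, DepthTruth]:
    """Windowed depth track with planted collapsed regions.

    ``collapse_spec`` maps multiplicity in {2,3,4} to the fraction of windows
    collapsed at that multiplicity (exact window counts, rounded); the rest
    are single-copy.  Depth per window is lognormal around m*base_depth with
    coefficient of variation ``noise_cv`` (exact when 0).
    """
    spec = dict(collapse_spec or {})
    if n_windows < 1 or window_size <= 0 or base_depth <= 0:
        raise InvalidParameterError("n_windows, window_size and base_depth must be positive")
    if any(k not in (2, 3, 4) for k in spec):
        raise InvalidParameterError("collapse_spec keys must be in {2, 3, 4}")
    if any(v < 0 for v in spec.values()) or sum(spec.values()) > 1:
        raise InvalidParameterError("collapse fractions must be >= 0 and sum to <= 1")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    classes = np.ones(n_windows, dtype=np.int64)
    cursor = 0
    for mult in sorted(spec):
        k = int(round(spec[mult] * n_windows))
        classes[cursor : cursor + k] = mult
        cursor += k
    rng.shuffle(classes)

    mean = classes * base_depth
    if noise_cv == 0:
        depth = mean.astype(float)
    else:
        sigma2 = np.log1p(noise_cv**2)
        mu = np.log(mean) - sigma2 / 2
        depth = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))

    starts = np.arange(n_windows, dtype=np.int64) * window_size
    track = DepthTrack(
        chrom=np.array(["chr1"] * n_windows, dtype=object),
        start=starts,
        end=starts + window_size,
        depth=depth,
        window_size=window_size,
    )
    lengths = {k: int(np.sum(classes == k)) * window_size for k in (1, 2, 3, 4)}
    overlap = lengths[2] + 2 * lengths[3] + 3 * lengths[4]
    truth = DepthTruth(
        seed, base_depth, window_size, lengths, tuple(int(x) for x in classes), overlap
    )
    return track, truth


# ---------------------------------------------------------------------------
# codon alignments


@dataclass(frozen=True)
class AlignmentTruth:
    seed: int
    n_codons: int
    n_4d: int
    n_diff: int
    n_tv: int

    @property
    def realized_d4(self) -> float:
        return self.n_diff / self.n_4d

    @property
    def realized_tv_fraction(self) -> float:
        return self.n_tv / self.n_diff if self.n_diff else 0.0


def simulate_codon_alignment(
    n_codons: int,
    d4: float = 0.02,
    tv_fraction: float = 0.5,
    seed: int = 0,
    fourfold_codon_fraction: float = 0.7,
) -> tuple[tuple[str, str], AlignmentTruth]:
    """Gap-free in-frame sequence pair diverged only at 4D third positions.

    Each codon is drawn from a fourfold-degenerate family with probability
    ``fourfold_codon_fraction`` (others are identical non-4D codons); each 4D
    third position differs with probability ``d4``, and a difference is a
    transversion with probability ``tv_fraction`` (transition otherwise).
    The realized difference and transversion counts are stored in the truth.
    """
    if n_codons < 100:
        raise InvalidParameterError("n_codons must be >= 100")
    if not 0 <= d4 <= 0.5:
        raise InvalidParameterError("d4 must lie in [0, 0.5] (single-substitution regime)")
    if not 0 <= tv_fraction <= 1:
        raise InvalidParameterError("tv_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    is4d = rng.random(n_codons) < fourfold_codon_fraction
    codons1 = []
    codons2 = []
    n_diff = 0
    n_tv = 0
    prefixes = rng.integers(0, len(FOURFOLD_PREFIX_LIST), size=n_codons)
    thirds = rng.integers(0, 4, size=n_codons)
    others = rng.integers(0, len(_NON4D_CODONS), size=n_codons)
    flip = rng.random(n_codons) < d4
    is_tv = rng.random(n_codons) < tv_fraction
    pick = rng.integers(0, 2, size=n_codons)
    for i in range(n_codons):
        if not is4d[i]:
            codon = _NON4D_CODONS[others[i]]
            codons1.append(codon)
            codons2.append(codon)
            continue
        base = str(_BASES[thirds[i]])
        codon1 = FOURFOLD_PREFIX_LIST[prefixes[i]] + base
        if flip[i]:
            if is_tv[i]:
                new = _TRANSVERSIONS[base][pick[i]]
                n_tv += 1
            else:
                new = _TRANSITION[base]
            n_diff += 1
            codons2.append(codon1[:2] + new)
        else:
            codons2.append(codon1)
        codons1.append(codon1)
    truth = AlignmentTruth(seed, n_codons, int(is4d.sum()), n_diff, n_tv)
    return ("".join(codons1), "".join(codons2)), truth


# ---------------------------------------------------------------------------
# population cohort with planted load and ROH


@dataclass(frozen=True)
class LoadSpec:
    """Planted per-individual homozygous-derived load counts."""

    ddm_hom: int = 85
    dmem_hom: int = 73


@dataclass(frozen=True)
class PlantedROH:
    sample: str
    chrom: str
    start: int  # first SNP inside the tract, 1-based
    end: int  # last SNP inside the tract
    n_snps: int
    nominal_start: int  # planted interval, 1-based inclusive
    nominal_end: int


@dataclass(frozen=True)
class PopulationTruth:
    seed: int
    samples: tuple[str, ...]
    pi_target: float
    ddm_hom_per_sample: int
    ddm_total_per_sample: int
    dmem_hom_per_sample: int
    dmem_total_per_sample: int
    n_ddm_sites: int
    n_ddm_genes: int
    n_dmem_sites: int
    n_dmem_genes: int
    roh: tuple[PlantedROH, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass(frozen=True)
class PopulationSim:
    """Paths of the generated scenario plus in-memory table and truth."""

    out_dir: Path
    vcf: Path
    scores: Path
    outgroups: Path
    genes: Path
    fasta: Path
    truth_json: Path
    table: VariantTable
    truth: PopulationTruth


def _balanced_design(n_samples: int, hom_count: int, min_maf: float = 0.05) -> tuple[int, int]:
    """Number of sites S and per-site het count k so that rotating the k
    heterozygous samples across sites makes every sample homozygous-derived
    at exactly ``hom_count`` sites, with per-site MAF = k/(2n) >= min_maf."""
    if hom_count == 0:
        return 0, 0
    k_min = max(1, ceil(2 * n_samples * min_maf))
    for k in range(k_min, n_samples):
        if (hom_count * n_samples) % (n_samples - k) == 0:
            return hom_count * n_samples // (n_samples - k), k
    raise InvalidParameterError(
        f"no balanced design for n={n_samples}, hom={hom_count}, maf={min_maf}"
    )


def _rotation_genotypes(n_sites: int, n_samples: int, k_het: int) -> np.ndarray:
    """(n_sites, n_samples) genotypes: k het per site, rest hom-alt, het set
    sweeping the samples so per-sample counts are exactly balanced."""
    gt = np.full((n_sites, n_samples), HOM_ALT, dtype=np.int8)
    for j in range(n_sites):
        for t in range(k_het):
            gt[j, (j * k_het + t) % n_samples] = HET
    return gt


# per-gene layout: two equal exons of 11 codons (ATG ... / ... stop) around a
# 120 bp intron; 8 mutable codon slots at fixed in-frame offsets
_EXON_CODONS = 11
_INTRON_LEN = 120
_EXON_BP = 3 * _EXON_CODONS
_GENE_LEN = 2 * _EXON_BP + _INTRON_LEN
_CODON_SLOTS = (2, 4, 6, 8, 13, 15, 17, 19)  # CDS codon indices
_SLOT_CODON = {"nonsyn": "GCC", "syn": "GGA", "stop_gain": "TGG"}
_SLOT_EDIT = {  # (offset in codon, ref base, alt base) in transcript orientation
    "nonsyn": (1, "C", "A"),  # GCC(Ala) -> GAC(Asp)
    "syn": (2, "A", "G"),  # GGA(Gly) -> GGG(Gly)
    "stop_gain": (1, "G", "A"),  # TGG(Trp) -> TAG(stop)
}


def _build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    gstart: int,
    codon_slot_types: Sequence[str],
    specials: set[str],
    rng: np.random.Generator,
) -> tuple[str, GeneModel, list[tuple[int, str, str, str, str]]]:
    """Construct one two-exon gene and its planted variant sites.

    Returns (genomic sequence, model, planted) where planted entries are
    (genomic pos, ref, alt, effect, slot type).  ``specials`` may contain
    'start_loss', 'stop_loss', 'donor', 'acceptor'.
    """
    codons = ["GAA"] * (2 * _EXON_CODONS)
    codons[0] = "ATG"
    codons[-1] = "TAA"
    edits: list[tuple[int, str, str, str, str]] = []  # (t, ref, alt, effect, kind)

    def codon_t(ci: int, off: int) -> int:
        base = 3 * ci + off
        return base if ci < _EXON_CODONS else base + _INTRON_LEN

    for ci, kind in zip(_CODON_SLOTS, codon_slot_types):
        codons[ci] = _SLOT_CODON[kind]
        off, ref, alt = _SLOT_EDIT[kind]
        effect = {"nonsyn": "nonsynonymous", "syn": "synonymous", "stop_gain": "stop_gain"}[kind]
        edits.append((codon_t(ci, off), ref, alt, effect, kind))
    if "start_loss" in specials:
        edits.append((codon_t(0, 0), "A", "G", "start_loss", "start_loss"))
    if "stop_loss" in specials:
        edits.append((codon_t(2 * _EXON_CODONS - 1, 0), "T", "C", "stop_loss", "stop_loss"))
    if "donor" in specials:
        edits.append((_EXON_BP, "G", "A", "splice", "donor"))
    if "acceptor" in specials:
        edits.append((_EXON_BP + _INTRON_LEN - 1, "G", "C", "splice", "acceptor"))

    intron = "GT" + "".join(rng.choice(list("ACT"), size=_INTRON_LEN - 4)) + "AG"
    transcript = "".join(codons[:_EXON_CODONS]) + intron + "".join(codons[_EXON_CODONS:])
    assert len(transcript) == _GENE_LEN

    exons = (
        (gstart, gstart + _EXON_BP - 1),
        (gstart + _EXON_BP + _INTRON_LEN, gstart + _GENE_LEN - 1),
    )
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=gstart,
        cds_end=gstart + _GENE_LEN - 1,
    )
    if strand == "+":
        gseq = transcript
        planted = [(gstart + t, ref, alt, eff, kind) for t, ref, alt, eff, kind in edits]
    else:
        gseq = revcomp(transcript)
        planted = [
            (gstart + _GENE_LEN - 1 - t, _COMP[ref], _COMP[alt], eff, kind)
            for t, ref, alt, eff, kind in edits
        ]
    return gseq, model, planted


def simulate_population_vcf(
    out_dir: str | Path,
    n_samples: int = 30,
    n_sites: int = 10_000,
    chrom_length: int = 1_200_000,
    pi_target: float = 3.3e-3,
    load_spec: Optional[LoadSpec] = None,
    roh_spec: Optional[Sequence[int] | Sequence[Sequence[int]]] = None,
    outgroup_concordance: float = 0.9,
    seed: int = 0,
    min_maf: float = 0.05,
) -> PopulationSim:
    """Cohort VCF + score/outgroup/gene tables + reference with planted truth.

    Writes into ``out_dir``: ``cohort.vcf`` (diploid-coded GT:DP),
    ``scores.tsv``, ``outgroups.tsv``, ``genes.tsv``, ``reference.fasta`` and
    ``truth.json``.  ``n_sites`` is the number of neutral background SNPs;
    planted load sites come on top.  ``roh_spec`` is a list of tract lengths
    planted in every sample (or one list per sample; default one 6 kb and one
    25 kb tract each; pass ``[]`` for none).  Outgroup rows at non-planted
    sites are concordant-homozygous with probability ``outgroup_concordance``;
    planted load sites always carry concordant ancestral outgroups so the
    planted truth is recoverable.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    if n_sites < 1:
        raise InvalidParameterError("n_sites must be >= 1")
    if not 0 <= outgroup_concordance <= 1:
        raise InvalidParameterError("outgroup_concordance must lie in [0, 1]")
    spec = load_spec or LoadSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    samples = tuple(f"S{i + 1:03d}" for i in range(n_samples))

    # --- per-sample ROH tract lengths
    if roh_spec is None:
        per_sample_tracts: list[list[int]] = [[6_000, 25_000] for _ in samples]
    elif len(roh_spec) and isinstance(roh_spec[0], (list, tuple)):
        if len(roh_spec) != n_samples:
            raise InvalidParameterError("per-sample roh_spec must list one entry per sample")
        per_sample_tracts = [list(x) for x in roh_spec]  # type: ignore[union-attr]
    else:
        per_sample_tracts = [list(roh_spec) for _ in samples]  # type: ignore[arg-type]
    for tracts in per_sample_tracts:
        for L in tracts:
            if L > chrom_length:
                raise InvalidParameterError(f"ROH tract of {L} bp exceeds chromosome length")

    # --- balanced designs for planted load
    S_ddm, k_ddm = _balanced_design(n_samples, spec.ddm_hom, min_maf)
    S_dmem, k_dmem = _balanced_design(n_samples, spec.dmem_hom, min_maf)
    n_benign = max(20, S_ddm // 4)
    n_syn = 30

    # --- DMEM class cycling
    dmem_kinds: list[str] = []
    splice_toggle = 0
    for i in range(S_dmem):
        cls = ("stop_gain", "splice", "stop_loss", "start_loss")[i % 4]
        if cls == "splice":
            cls = ("donor", "acceptor")[splice_toggle % 2]
            splice_toggle += 1
        dmem_kinds.append(cls)
    n_specials = {
        kind: dmem_kinds.count(kind) for kind in ("start_loss", "stop_loss", "donor", "acceptor")
    }
    codon_requests = (
        ["stop_gain"] * dmem_kinds.count("stop_gain")
        + ["nonsyn"] * S_ddm
        + ["benign"] * n_benign
        + ["syn"] * n_syn
    )
    rng.shuffle(codon_requests)
    n_genes = max(
        ceil(len(codon_requests) / len(_CODON_SLOTS)), max(n_specials.values(), default=0), 1
    )

    # --- reference scaffold and genes
    gene_gap = 150
    gene_region_start = 1_000
    ref = rng.choice(_BASES, size=chrom_length)
    genes: list[GeneModel] = []
    planted: dict[str, list[tuple[int, str, str, str, str]]] = {
        k: [] for k in ("nonsyn", "benign", "syn", "stop_gain", "start_loss", "stop_loss", "donor", "acceptor")
    }
    gene_of_site: dict[int, str] = {}
    spent = dict.fromkeys(n_specials, 0)
    for g in range(n_genes):
        gstart = gene_region_start + 1 + g * (_GENE_LEN + gene_gap)
        if gstart + _GENE_LEN >= chrom_length:
            raise InvalidParameterError("chrom_length too small for the planted gene region")
        slots = codon_requests[g * len(_CODON_SLOTS) : (g + 1) * len(_CODON_SLOTS)]
        slots = slots + ["syn"] * (len(_CODON_SLOTS) - len(slots))
        specials = {k for k in n_specials if spent[k] < n_specials[k]}
        for k in specials:
            spent[k] += 1
        slot_types = ["nonsyn" if s == "benign" else s for s in slots]
        strand = "+" if g % 2 == 0 else "-"
        gseq, model, sites = _build_gene(f"gene{g + 1:04d}", chrom, strand, gstart, slot_types, specials, rng)
        ref[gstart - 1 : gstart - 1 + _GENE_LEN] = list(gseq)
        genes.append(model)
        benign_slots = [i for i, s in enumerate(slots) if s == "benign"]
        codon_count = 0
        for pos, rbase, abase, effect, kind in sites:
            bucket = kind
            if kind == "nonsyn":
                bucket = "benign" if codon_count in benign_slots else "nonsyn"
            if kind in ("nonsyn", "syn", "stop_gain"):
                codon_count += 1
            planted[bucket].append((pos, rbase, abase, effect, kind))
            gene_of_site[pos] = model.gene_id
    gene_region_end = gene_region_start + n_genes * (_GENE_LEN + gene_gap) + 500

    # trim surplus slots (the last gene may over-provide specials/codons)
    planted["nonsyn"] = planted["nonsyn"][:S_ddm]
    planted["benign"] = planted["benign"][:n_benign]
    for kind in n_specials:
        planted[kind] = planted[kind][: n_specials[kind]]
    planted["stop_gain"] = planted["stop_gain"][: dmem_kinds.count("stop_gain")]

    ddm_sites = planted["nonsyn"]
    dmem_sites = planted["stop_gain"] + planted["donor"] + planted["acceptor"] + planted["stop_loss"] + planted["start_loss"]
    decoy_sites = planted["benign"] + planted["syn"]
    if len(ddm_sites) != S_ddm or len(dmem_sites) != S_dmem:
        raise InvalidParameterError("internal: slot allocation failed")

    # --- neutral background sites
    neutral_start = gene_region_end
    region = chrom_length - neutral_start
    spacing = region // n_sites
    if spacing < 2:
        raise InvalidParameterError("chrom_length too small for n_sites neutral SNPs")
    jitter = rng.integers(0, max(1, spacing // 2), size=n_sites)
    neutral_pos = neutral_start + np.arange(n_sites, dtype=np.int64) * spacing + jitter + 1
    h_bar = pi_target * chrom_length / n_sites
    if h_bar > 0.5:
        raise InvalidParameterError("pi_target unreachable: raise n_sites or shrink chrom_length")
    p_alt = (1 - sqrt(1 - 2 * h_bar)) / 2
    neutral_gt = rng.binomial(2, p_alt, size=(n_sites, n_samples)).astype(np.int8)

    # --- plant ROH tracts in the neutral region; force flanking heterozygotes
    tract_gap = 2_000
    cursor = int(neutral_pos[2])  # leave flanking sites at the region edge
    roh_truth: list[PlantedROH] = []
    order = [(s_idx, L) for s_idx, tracts in enumerate(per_sample_tracts) for L in tracts]
    for s_idx, L in order:
        start = cursor + tract_gap
        end = start + L - 1
        if end >= chrom_length - 2 * spacing:
            raise InvalidParameterError("chromosome too short for the requested ROH tracts")
        inside = np.nonzero((neutral_pos >= start) & (neutral_pos <= end))[0]
        if inside.size:
            hom_draw = rng.integers(0, 2, size=inside.size).astype(np.int8) * 2
            current = neutral_gt[inside, s_idx]
            forced = np.where(current == HET, hom_draw, current)
            neutral_gt[inside, s_idx] = forced
            before = inside[0] - 1
            after = inside[-1] + 1
            if before >= 0:
                neutral_gt[before, s_idx] = HET
            if after < n_sites:
                neutral_gt[after, s_idx] = HET
            roh_truth.append(
                PlantedROH(
                    sample=samples[s_idx],
                    chrom=chrom,
                    start=int(neutral_pos[inside[0]]),
                    end=int(neutral_pos[inside[-1]]),
                    n_snps=int(inside.size),
                    nominal_start=start,
                    nominal_end=end,
                )
            )
        cursor = end

    # neutral ref/alt from the reference sequence
    neutral_ref = ref[neutral_pos - 1]
    shift = rng.integers(1, 4, size=n_sites)
    base_idx = np.searchsorted(_BASES, neutral_ref)
    neutral_alt = _BASES[(base_idx + shift) % 4]

    # neutral DP: mostly comfortable, a small fraction below the depth filter
    neutral_dp = rng.integers(14, 61, size=(n_sites, n_samples)).astype(np.int32)
    low = rng.random((n_sites, n_samples)) < 0.02
    neutral_dp[low] = rng.integers(5, 13, size=int(low.sum()))
    for rec in roh_truth:
        s_idx = samples.index(rec.sample)
        inside = np.nonzero((neutral_pos >= rec.start - 1) & (neutral_pos <= rec.end + 1))[0]
        lo = max(0, inside[0] - 1) if inside.size else 0
        hi = min(n_sites - 1, inside[-1] + 1) if inside.size else -1
        if hi >= lo:
            neutral_dp[lo : hi + 1, s_idx] = np.maximum(neutral_dp[lo : hi + 1, s_idx], 20)

    # --- assemble all sites
    def planted_arrays(sites, gt_matrix):
        pos = np.array([p for p, *_ in sites], dtype=np.int64)
        rb = np.array([r for _, r, *_ in sites], dtype=object)
        ab = np.array([a for _, _, a, *_ in sites], dtype=object)
        dp = rng.integers(25, 61, size=gt_matrix.shape).astype(np.int32)
        return pos, rb, ab, gt_matrix, dp

    ddm_gt = _rotation_genotypes(S_ddm, n_samples, k_ddm)
    dmem_gt = _rotation_genotypes(S_dmem, n_samples, k_dmem)
    decoy_p = rng.uniform(0.1, 0.4, size=len(decoy_sites))
    decoy_gt = rng.binomial(2, decoy_p[:, None], size=(len(decoy_sites), n_samples)).astype(np.int8)

    blocks = [
        planted_arrays(ddm_sites, ddm_gt),
        planted_arrays(dmem_sites, dmem_gt),
        planted_arrays(decoy_sites, decoy_gt),
        (neutral_pos, neutral_ref.astype(object), neutral_alt.astype(object), neutral_gt, neutral_dp),
    ]
    pos_all = np.concatenate([b[0] for b in blocks])
    ref_all = np.concatenate([b[1] for b in blocks])
    alt_all = np.concatenate([b[2] for b in blocks])
    gt_all = np.vstack([b[3] for b in blocks])
    dp_all = np.vstack([b[4] for b in blocks])
    order_idx = np.argsort(pos_all, kind="stable")
    table = VariantTable(
        chrom=np.array([chrom] * len(pos_all), dtype=object),
        pos=pos_all[order_idx],
        ref=ref_all[order_idx],
        alt=alt_all[order_idx],
        gt=gt_all[order_idx],
        dp=dp_all[order_idx],
        samples=samples,
    )

    # --- outgroup states
    keys = table.keys()
    planted_pos = {p for p, *_ in ddm_sites} | {p for p, *_ in dmem_sites}
    o1 = np.empty(len(table), dtype=object)
    o2 = np.empty(len(table), dtype=object)
    conc_draw = rng.random(len(table))
    anc_is_ref = rng.random(len(table)) < 0.75
    disc_kind = rng.integers(0, 3, size=len(table))
    third = rng.integers(0, 4, size=len(table))
    for i in range(len(table)):
        p = int(table.pos[i])
        r, a = str(table.ref[i]), str(table.alt[i])
        if p in planted_pos:
            o1[i] = o2[i] = r  # ancestral = reference allele
        elif conc_draw[i] < outgroup_concordance:
            o1[i] = o2[i] = r if anc_is_ref[i] else a
        else:
            kind = int(disc_kind[i])
            if kind == 0:
                o1[i], o2[i] = "het", r
            elif kind == 1:
                o1[i], o2[i] = r, "."
            else:
                b = str(_BASES[third[i]])
                o1[i] = o2[i] = b if b not in (r, a) else "het"

    # --- scores for nonsynonymous sites
    nonsyn_pos = [p for p, *_ in ddm_sites]
    benign_pos = [p for p, *_ in planted["benign"]]
    score_rows = []
    # stay clear of the thresholds by more than the 4-decimal print precision
    for p, rbase, abase, _, _ in ddm_sites:
        score_rows.append(
            (f"{chrom}:{p}:{rbase}:{abase}", rng.uniform(-8.0, -2.505), rng.uniform(0.0, 0.0495))
        )
    for p, rbase, abase, _, _ in planted["benign"]:
        which = rng.integers(0, 3)
        prov = rng.uniform(-2.4, 2.0) if which in (0, 2) else rng.uniform(-8.0, -2.6)
        sift = rng.uniform(0.06, 1.0) if which in (1, 2) else rng.uniform(0.0, 0.04)
        score_rows.append((f"{chrom}:{p}:{rbase}:{abase}", prov, sift))
    score_rows.sort()

    # --- write everything
    vcf_path = out_dir / "cohort.vcf"
    scores_path = out_dir / "scores.tsv"
    outgroups_path = out_dir / "outgroups.tsv"
    genes_path = out_dir / "genes.tsv"
    fasta_path = out_dir / "reference.fasta"
    truth_path = out_dir / "truth.json"

    write_vcf(table, vcf_path, contig_lengths={chrom: chrom_length})
    with open(scores_path, "w") as fh:
        fh.write("key\tprovean_score\tsift_score\n")
        for key, prov, sift in score_rows:
            fh.write(f"{key}\t{prov:.4f}\t{sift:.4f}\n")
    with open(outgroups_path, "w") as fh:
        fh.write("key\toutgroup1\toutgroup2\n")
        for i in range(len(table)):
            fh.write(f"{keys[i]}\t{o1[i]}\t{o2[i]}\n")
    write_gene_table(genes, genes_path)
    seq = "".join(ref.tolist())
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    ddm_genes = {gene_of_site[p] for p, *_ in ddm_sites}
    dmem_genes = {gene_of_site[p] for p, *_ in dmem_sites}
    truth = PopulationTruth(
        seed=seed,
        samples=samples,
        pi_target=pi_target,
        ddm_hom_per_sample=spec.ddm_hom,
        ddm_total_per_sample=S_ddm,
        dmem_hom_per_sample=spec.dmem_hom,
        dmem_total_per_sample=S_dmem,
        n_ddm_sites=S_ddm,
        n_ddm_genes=len(ddm_genes),
        n_dmem_sites=S_dmem,
        n_dmem_genes=len(dmem_genes),
        roh=tuple(roh_truth),
    )
    truth.to_json(truth_path)
    return PopulationSim(
        out_dir=out_dir,
        vcf=vcf_path,
        scores=scores_path,
        outgroups=outgroups_path,
        genes=genes_path,
        fasta=fasta_path,
        truth_json=truth_path,
        table=table,
        truth=truth,
    )
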