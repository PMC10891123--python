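"""Derived deleterious and major-effect mutation (DDM/DMEM) load accounting.

The procedure: (1) filter cohort SNPs (per-genotype depth, minor allele
frequency, missing rate); (2) annotate each SNP's coding effect against gene
models; (3) flag nonsynonymous SNPs deleterious when both a PROVEAN-like
score (< -2.5) and a SIFT-like score (< 0.05) say so; (4) polarize each SNP
into ancestral/derived using two outgroup species, accepting only sites where
both outgroups are homozygous for the same base and that base is one of the
two alleles; (5) count, per individual, sites carrying at least one derived
allele (total) and sites homozygous for the derived allele, separately for
deleterious (DDM) and major-effect (DMEM) sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, CoordinateError, FormatError
from .genes import GeneModel, revcomp
from .vcfio import HET, HOM_ALT, HOM_REF, MISSING, VariantTable

__all__ = [
    "EFFECT_SEVERITY",
    "MAJOR_EFFECTS",
    "PROVEAN_THRESHOLD",
    "SIFT_THRESHOLD",
    "LoadSummary",
    "filter_snps",
    "annotate_effect",
    "classify_deleterious",
    "polarize",
    "summarize_load",
    "run_load_pipeline",
    "read_score_table",
    "read_outgroup_table",
]

PROVEAN_THRESHOLD = -2.5
SIFT_THRESHOLD = 0.05
SPLICE_MARGIN = 2  # bp at each intron end (canonical GT-AG region)

MAJOR_EFFECTS = frozenset({"start_loss", "stop_gain", "stop_loss", "splice"})

# most severe first; used when a variant falls in overlapping genes
EFFECT_SEVERITY = (
    "stop_gain",
    "start_loss",
    "stop_loss",
    "splice",
    "nonsynonymous",
    "synonymous",
    "intronic",
    "intergenic",
)

_CODON_TABLE = {}


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon.upper(), "X")


def filter_snps(
    table: VariantTable,
    min_dp: int = 13,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
) -> VariantTable:
    """Apply the cohort SNP filter: DP, MAF and missing-rate thresholds.

    Genotypes with per-genotype depth below ``min_dp`` are set missing first
    (per-genotype semantics, as in ``vcftools --minDP``); sites are then kept
    iff the missing fraction is <= ``max_missing`` and the minor allele
    frequency over non-missing alleles is >= ``min_maf``.
    """
    if min_dp > 0 and table.dp is None:
        raise FormatError("depth filtering requested but the table has no DP")
    gt = table.gt.copy()
    if min_dp > 0:
        gt[table.dp < min_dp] = MISSING
    missing = gt == MISSING
    n_called = (~missing).sum(axis=1)
    miss_frac = missing.mean(axis=1) if table.n_samples else np.zeros(len(table))
    alt_count = np.where(gt > 0, gt, 0).sum(axis=1)
    n_alleles = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p_alt, 1 - p_alt)
    keep = (miss_frac <= max_missing) & (maf >= min_maf) & (n_alleles > 0)
    out = table.take(np.nonzero(keep)[0])
    return VariantTable(
        chrom=out.chrom,
        pos=out.pos,
        ref=out.ref,
        alt=out.alt,
        gt=gt[keep],
        dp=out.dp,
        samples=out.samples,
    )


def _effect_in_gene(pos: int, ref: str, alt: str, gene: GeneModel, chrom_seq: str) -> str:
    for a, b in gene.introns():
        if a <= pos <= b:
            if pos - a < SPLICE_MARGIN or b - pos < SPLICE_MARGIN:
                return "splice"
            return "intronic"
    idx = gene.cds_index(pos)
    if idx is None:
        # inside the gene span but neither intron nor CDS (UTR exon): treat
        # as non-coding background
        return "intergenic"
    cds = gene.cds_sequence(chrom_seq)
    if chrom_seq[pos - 1].upper() != ref.upper():
        raise ConsistencyError(
            f"reference base at {gene.chrom}:{pos} is {chrom_seq[pos - 1]!r}, VCF says {ref!r}"
        )
    alt_base = alt.upper() if gene.strand == "+" else revcomp(alt.upper())
    codon_i = idx // 3
    off = idx % 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:
        return "intergenic"  # trailing partial codon in a malformed model
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_loss"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def annotate_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
) -> tuple[str, Optional[str]]:
    """Classify one SNP's effect; returns (effect class, gene id or None).

    Coding changes are translated strand-aware with the standard code:
    disrupted initial ATG -> start_loss, sense->stop -> stop_gain,
    stop->sense -> stop_loss, same amino acid -> synonymous, otherwise
    nonsynonymous.  Intronic positions within 2 bp of an exon/intron boundary
    (the canonical GT-AG dinucleotides) -> splice.  For overlapping genes the
    most severe effect wins.
    """
    if chrom not in sequences:
        raise CoordinateError(f"unknown sequence {chrom!r}")
    seq = sequences[chrom]
    if not 1 <= pos <= len(seq):
        raise CoordinateError(f"position {pos} outside {chrom} (length {len(seq)})")
    best: tuple[int, str, Optional[str]] = (EFFECT_SEVERITY.index("intergenic"), "intergenic", None)
    for gene in genes:
        if gene.chrom != chrom or not gene.contains(pos):
            continue
        eff = _effect_in_gene(pos, ref, alt, gene, seq)
        rank = EFFECT_SEVERITY.index(eff)
        if rank < best[0]:
            best = (rank, eff, gene.gene_id if eff != "intergenic" else None)
    return best[1], best[2]


def classify_deleterious(provean_score, sift_score) -> np.ndarray:
    """True iff PROVEAN-like score < -2.5 AND SIFT-like score < 0.05 (both strict).

    A mutation must be supported by both scorers; a missing (NaN) score
    counts as unsupported.
    """
    p = np.asarray(provean_score, dtype=float)
    s = np.asarray(sift_score, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p < PROVEAN_THRESHOLD) & (s < SIFT_THRESHOLD)


def polarize(
    ref,
    alt,
    outgroup1,
    outgroup2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign ancestral/derived alleles from two outgroup states.

    Outgroup states are single bases when homozygous, ``"het"`` or ``"."``
    otherwise.  A site polarizes iff both outgroups are homozygous for the
    same base and that base equals ref or alt; the other allele is derived.
    Returns (polarized mask, ancestral array, derived array); unpolarized
    entries hold empty strings.
    """
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    o1 = np.array([str(x).upper() for x in outgroup1], dtype=object)
    o2 = np.array([str(x).upper() for x in outgroup2], dtype=object)
    bases = {"A", "C", "G", "T"}
    n = len(ref)
    anc = np.full(n, "", dtype=object)
    der = np.full(n, "", dtype=object)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        if o1[i] == o2[i] and o1[i] in bases:
            if o1[i] == ref[i]:
                ok[i], anc[i], der[i] = True, ref[i], alt[i]
            elif o1[i] == alt[i]:
                ok[i], anc[i], der[i] = True, alt[i], ref[i]
    return ok, anc, der


@dataclass(frozen=True)
class LoadSummary:
    """Per-individual and cohort-level DDM/DMEM accounting."""

    per_sample: pd.DataFrame  # sample, ddm_total, ddm_hom, dmem_total, dmem_hom
    ddm_sites: int
    ddm_genes: int
    dmem_sites: int
    dmem_genes: int

    def to_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "cohort": {
                "ddm_sites": self.ddm_sites,
                "ddm_genes": self.ddm_genes,
                "dmem_sites": self.dmem_sites,
                "dmem_genes": self.dmem_genes,
            },
        }


def _per_sample_counts(gt: np.ndarray, derived_is_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(carrier counts, homozygous-derived counts) per sample for one site class."""
    if gt.shape[0] == 0:
        z = np.zeros(gt.shape[1], dtype=np.int64)
        return z, z.copy()
    # derived allele = alt: carriers are het/hom-alt; derived = ref: het/hom-ref
    da = derived_is_alt[:, None]
    carrier = np.where(da, (gt == HET) | (gt == HOM_ALT), (gt == HET) | (gt == HOM_REF))
    hom = np.where(da, gt == HOM_ALT, gt == HOM_REF)
    return carrier.sum(axis=0).astype(np.int64), hom.sum(axis=0).astype(np.int64)


def summarize_load(
    table: VariantTable,
    effects: Sequence[str],
    gene_ids: Sequence[Optional[str]],
    deleterious: Sequence[bool],
    polarized: Sequence[bool],
    derived: Sequence[str],
) -> LoadSummary:
    """Per-individual DDM/DMEM counts and cohort site/gene totals.

    A site is a DDM when it is polarized and flagged deleterious, a DMEM when
    it is polarized with a major effect (start_loss, stop_gain, stop_loss,
    splice).  Per individual, a site counts toward the total when the sample
    carries at least one derived allele and toward the homozygous column when
    both alleles are derived; missing genotypes never count.
    """
    n = len(table)
    effects = np.asarray(effects, dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    deleterious = np.asarray(deleterious, dtype=bool)
    polarized = np.asarray(polarized, dtype=bool)
    derived = np.asarray(derived, dtype=object)
    if not (len(effects) == len(deleterious) == len(polarized) == len(derived) == n):
        raise ConsistencyError("per-variant annotations must match the variant table")

    is_ddm = polarized & deleterious
    is_dmem = polarized & np.isin(effects, sorted(MAJOR_EFFECTS))
    derived_is_alt = derived == np.asarray(table.alt, dtype=object)

    ddm_tot, ddm_hom = _per_sample_counts(table.gt[is_ddm], derived_is_alt[is_ddm])
    dmem_tot, dmem_hom = _per_sample_counts(table.gt[is_dmem], derived_is_alt[is_dmem])

    per_sample = pd.DataFrame(
        {
            "sample": list(table.samples),
            "ddm_total": ddm_tot,
            "ddm_hom": ddm_hom,
            "dmem_total": dmem_tot,
            "dmem_hom": dmem_hom,
        }
    )

    def _genes(mask: np.ndarray) -> int:
        ids = {g for g in gene_ids[mask] if g not in (None, "")}
        return len(ids)

    return LoadSummary(
        per_sample=per_sample,
        ddm_sites=int(is_ddm.sum()),
        ddm_genes=_genes(is_ddm),
        dmem_sites=int(is_dmem.sum()),
        dmem_genes=_genes(is_dmem),
    )


def read_score_table(path: str | Path) -> pd.DataFrame:
    """TSV keyed CHROM:POS:REF:ALT with provean_score and sift_score columns."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str})
    for col in ("key", "provean_score", "sift_score"):
        if col not in df.columns:
            raise FormatError(f"score table {path} lacks column {col!r}")
    return df


def read_outgroup_table(path: str | Path) -> pd.DataFrame:
    """TSV keyed CHROM:POS:REF:ALT with outgroup1/outgroup2 state columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("key", "outgroup1", "outgroup2"):
        if col not in df.columns:
            raise FormatError(f"outgroup table {path} lacks column {col!r}")
    return df


def run_load_pipeline(
    table: VariantTable,
    scores: pd.DataFrame,
    outgroups: pd.DataFrame,
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    min_dp: int = 13,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
) -> tuple[LoadSummary, pd.DataFrame]:
    """Filter -> annotate -> score-intersect -> polarize -> summarize.

    Returns the :class:`LoadSummary` and a per-variant annotation frame
    (key, effect, gene, deleterious, polarized, ancestral, derived).
    """
    filtered = filter_snps(table, min_dp=min_dp, min_maf=min_maf, max_missing=max_missing)
    keys = filtered.keys()

    eff_gene = [
        annotate_effect(c, int(p), r, a, genes, sequences)
        for c, p, r, a in zip(filtered.chrom, filtered.pos, filtered.ref, filtered.alt)
    ]
    effects = [e for e, _ in eff_gene]
    gene_ids = [g for _, g in eff_gene]

    score_map = scores.set_index("key")
    prov = np.full(len(filtered), np.nan)
    sift = np.full(len(filtered), np.nan)
    hit = np.isin(keys, score_map.index.to_numpy())
    if hit.any():
        sub = score_map.loc[keys[hit]]
        prov[hit] = sub["provean_score"].to_numpy(dtype=float)
        sift[hit] = sub["sift_score"].to_numpy(dtype=float)
    deleterious = classify_deleterious(prov, sift) & (np.asarray(effects, dtype=object) == "nonsynonymous")

    og = outgroups.set_index("key")
    o1 = np.full(len(filtered), ".", dtype=object)
    o2 = np.full(len(filtered), ".", dtype=object)
    oh = np.isin(keys, og.index.to_numpy())
    if oh.any():
        sub = og.loc[keys[oh]]
        o1[oh] = sub["outgroup1"].to_numpy(dtype=object)
        o2[oh] = sub["outgroup2"].to_numpy(dtype=object)
    polarized, anc, der = polarize(filtered.ref, filtered.alt, o1, o2)

    summary = summarize_load(filtered, effects, gene_ids, deleterious, polarized, der)
    detail = pd.DataFrame(
        {
            "key": keys,
            "effect": effects,
            "gene": gene_ids,
            "provean_score": prov,
            "sift_score": sift,
            "deleterious": deleterious,
            "polarized": polarized,
            "ancestral": anc,
            "derived": der,
        }
    )
    return summary, detail
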