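"""Cohort variant table: in-memory container and VCF round-trip.

Genotypes are diploid-coded integers per (site, sample): 0 hom-ref, 1 het,
2 hom-alt, -1 missing.  Reading goes through cyvcf2; writing emits a minimal
deterministic VCF v4.2 with GT:DP so that identical inputs give byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, InvalidParameterError

__all__ = ["VariantTable", "read_vcf", "write_vcf", "variant_keys"]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class VariantTable:
    """Bi-allelic SNP cohort: site arrays plus (n_sites, n_samples) GT/DP matrices."""

    chrom: np.ndarray  # str
    pos: np.ndarray  # int, 1-based
    ref: np.ndarray  # str single base
    alt: np.ndarray  # str single base
    gt: np.ndarray  # int8 matrix, coding above
    samples: tuple[str, ...]
    dp: Optional[np.ndarray] = None  # int matrix or None

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.gt.shape != (n, len(self.samples)):
            raise InvalidParameterError("gt matrix shape must be (n_sites, n_samples)")
        if self.dp is not None and self.dp.shape != self.gt.shape:
            raise InvalidParameterError("dp matrix shape must match gt")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def keys(self) -> np.ndarray:
        return variant_keys(self.chrom, self.pos, self.ref, self.alt)


def variant_keys(chrom, pos, ref, alt) -> np.ndarray:
    """CHROM:POS:REF:ALT string keys used across score/outgroup tables."""
    return np.array(
        [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref, alt)], dtype=object
    )


def read_vcf(path: str | Path, require_dp: bool = True) -> VariantTable:
    """Load bi-allelic SNPs from a VCF into a :class:`VariantTable`.

    Multi-allelic records and non-SNP records are skipped.  Missing DP with
    ``require_dp=True`` raises :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = tuple(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    gts, dps = [], []
    has_dp = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=np.int8)
        coded = np.where(gt == 0, HOM_REF, np.where(gt == 1, HET, np.where(gt == 3, HOM_ALT, MISSING)))
        gts.append(coded.astype(np.int8))
        dp = var.format("DP")
        if dp is None:
            has_dp = False
            dps.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dps.append(np.clip(dp.reshape(-1).astype(np.int64), 0, None).astype(np.int32))
    vcf.close()
    if require_dp and not has_dp and len(chroms):
        raise FormatError(f"{path} lacks per-genotype DP, required for depth filtering")
    n = len(chroms)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=np.array(gts, dtype=np.int8) if n else np.zeros((0, len(samples)), dtype=np.int8),
        dp=np.array(dps, dtype=np.int32) if (has_dp and n) else None,
        samples=samples,
    )


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a minimal deterministic VCF v4.2 with GT:DP per genotype."""
    lines = ["##fileformat=VCFv4.2", "##source=polyload"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples)
    )
    dp = table.dp
    for i in range(len(table)):
        fields = [
            str(table.chrom[i]),
            str(int(table.pos[i])),
            ".",
            str(table.ref[i]),
            str(table.alt[i]),
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        row_dp = dp[i] if dp is not None else None
        for j in range(table.n_samples):
            g = _GT_STRINGS[int(table.gt[i, j])]
            d = int(row_dp[j]) if row_dp is not None else 0
            fields.append(f"{g}:{d}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
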