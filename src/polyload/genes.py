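"""Simplified gene models for variant-effect annotation.

A gene model is a strand-aware set of exon spans plus a CDS range on one
sequence; coding intervals are the exon pieces inside the CDS range, and the
concatenated coding sequence (reverse-complemented on the minus strand) is
translated in frame from its first base.  Models round-trip through a small
TSV (one gene per row) and can be imported from GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .errors import InvalidParameterError

__all__ = ["GeneModel", "read_gene_table", "write_gene_table", "genes_from_gff3"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene: exon spans and CDS range, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 1-based inclusive
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvalidParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if a > b:
                raise InvalidParameterError(f"exon {a}-{b} of {self.gene_id} is inverted")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise InvalidParameterError(f"overlapping exons in {self.gene_id}")
        if self.cds_start > self.cds_end:
            raise InvalidParameterError(f"CDS range inverted in {self.gene_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces inside the CDS range (1-based inclusive), sorted."""
        out = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (1-based inclusive), sorted."""
        return [
            (b0 + 1, a1 - 1)
            for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])
            if a1 - b0 > 1
        ]

    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.coding_intervals())

    def cds_index(self, pos: int) -> Optional[int]:
        """0-based index of a genomic position within the stranded CDS, or None."""
        offset = 0
        for a, b in self.coding_intervals():
            if a <= pos <= b:
                plus_index = offset + (pos - a)
                if self.strand == "+":
                    return plus_index
                return self.cds_length() - 1 - plus_index
            offset += b - a + 1
        return None

    def cds_sequence(self, chrom_seq: str) -> str:
        """Concatenated coding sequence in reading orientation.

        ``chrom_seq`` is the full sequence of ``self.chrom`` (0-based string).
        """
        parts = [chrom_seq[a - 1 : b] for a, b in self.coding_intervals()]
        cds = "".join(parts).upper()
        return revcomp(cds) if self.strand == "-" else cds


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as TSV: gene_id, chrom, strand, exons, cds_start, cds_end."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texons\tcds_start\tcds_end\n")
        for g in genes:
            spans = ",".join(f"{a}-{b}" for a, b in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{spans}\t{g.cds_start}\t{g.cds_end}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise InvalidParameterError(f"{path} is not a gene-model table")
        for line in fh:
            if not line.strip():
                continue
            gene_id, chrom, strand, spans, cs, ce = line.rstrip("\n").split("\t")
            exons = tuple(
                (int(a), int(b)) for a, b in (s.split("-") for s in spans.split(","))
            )
            genes.append(GeneModel(gene_id, chrom, strand, exons, int(cs), int(ce)))
    return genes


def genes_from_gff3(path: str | Path) -> list[GeneModel]:
    """Import gene models from GFF3 (one transcript per gene; exon + CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons:
            exons = cds
        if not exons:
            continue
        cds_start = min(a for a, _ in cds) if cds else min(a for a, _ in exons)
        cds_end = max(b for _, b in cds) if cds else max(b for _, b in exons)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(sorted(exons)),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes
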