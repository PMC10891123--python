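"""Windowed nucleotide diversity and runs of homozygosity.

Nucleotide diversity pi is computed per fixed window as the sum over SNPs of
the per-site average pairwise difference among sampled allele copies,

    h_i = 2 * a_i * (n_i - a_i) / (n_i * (n_i - 1)),

divided by the window length in bp (``vcftools --window-pi`` behaviour),
where n_i is the number of non-missing allele copies and a_i the alternate
allele count.

A run of homozygosity (ROH) is a maximal stretch of consecutive homozygous,
non-missing genotypes of one sample along a sequence (heterozygous or missing
genotypes terminate runs).  A run is reported when it contains at least one
complete scan window of consecutive homozygous SNPs (default 20), spans more
than a minimum length (default 5 kb, strict) and holds a minimum number of
SNPs (default 10); span is measured first SNP to last SNP, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, OrderingError
from .vcfio import HOM_ALT, HOM_REF, MISSING, VariantTable

__all__ = [
    "ROHSegment",
    "windowed_pi",
    "site_diversity",
    "scan_roh",
    "roh_summary",
    "DEFAULT_ROH_BINS",
]

DEFAULT_ROH_BINS = (5_000, 10_000, 30_000)  # bp edges: (5,10], (10,30], (30,inf)


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous tract: first->last SNP, 1-based inclusive."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def site_diversity(gt: np.ndarray) -> np.ndarray:
    """Per-site average pairwise difference h over diploid-coded genotypes.

    Sites with fewer than two called allele copies get h = 0 (skipped).
    """
    called = gt != MISSING
    n = 2 * called.sum(axis=1)
    a = np.where(gt > 0, gt, 0).sum(axis=1)
    h = np.zeros(len(gt), dtype=float)
    ok = n >= 2
    h[ok] = 2.0 * a[ok] * (n[ok] - a[ok]) / (n[ok] * (n[ok] - 1.0))
    return h


def windowed_pi(
    table: VariantTable,
    window_size: int = 10_000,
    seq_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Nucleotide diversity in fixed non-overlapping windows.

    Returns a frame (chrom, start, end, n_sites, pi) with 0-based half-open
    windows tiling each sequence up to ``seq_lengths`` (or the last SNP when
    lengths are not given); windows without SNPs have pi = 0.
    """
    if window_size <= 0:
        raise InvalidParameterError("window_size must be positive")
    h = site_diversity(table.gt)
    rows = []
    chroms = pd.unique(pd.Series(table.chrom, dtype=object)) if len(table) else []
    lengths = dict(seq_lengths or {})
    for name in set(lengths) - set(chroms):
        chroms = list(chroms) + [name]
    for chrom in chroms:
        mask = np.asarray(table.chrom, dtype=object) == chrom
        pos = table.pos[mask]
        hv = h[mask]
        if pos.size and np.any(np.diff(pos) < 0):
            order = np.argsort(pos, kind="stable")
            pos, hv = pos[order], hv[order]
        length = lengths.get(chrom, int(pos.max()) if pos.size else 0)
        n_win = max(1, int(np.ceil(length / window_size))) if length else 0
        win_idx = (pos - 1) // window_size
        for w in range(n_win):
            sel = win_idx == w
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window_size,
                    "end": min((w + 1) * window_size, length) if length else (w + 1) * window_size,
                    "n_sites": int(sel.sum()),
                    "pi": float(hv[sel].sum()) / window_size,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


def scan_roh(
    table: VariantTable,
    window_snps: int = 20,
    min_length: int = 5_000,
    min_snps: int = 10,
    samples: Optional[Sequence[str]] = None,
) -> list[ROHSegment]:
    """Scan every sample for runs of homozygosity.

    Candidate runs are maximal stretches of consecutive homozygous
    non-missing genotypes; a run is emitted iff it holds at least one full
    window of ``window_snps`` consecutive homozygous SNPs (i.e. its SNP count
    is >= ``window_snps``), spans strictly more than ``min_length`` bp and
    contains at least ``min_snps`` SNPs.
    """
    if window_snps < 1 or min_snps < 1:
        raise InvalidParameterError("window_snps and min_snps must be >= 1")
    wanted = list(table.samples) if samples is None else list(samples)
    idx = {s: i for i, s in enumerate(table.samples)}
    segments: list[ROHSegment] = []
    chrom_arr = np.asarray(table.chrom, dtype=object)
    for chrom in pd.unique(pd.Series(chrom_arr, dtype=object)) if len(table) else []:
        mask = chrom_arr == chrom
        pos = table.pos[mask]
        if np.any(np.diff(pos) <= 0):
            raise OrderingError(f"positions not strictly increasing on {chrom}")
        gts = table.gt[mask]
        for sample in wanted:
            g = gts[:, idx[sample]]
            hom = (g == HOM_REF) | (g == HOM_ALT)
            # maximal homozygous stretches
            boundaries = np.nonzero(np.diff(hom.astype(np.int8)))[0] + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(hom)]])
            for s, e in zip(starts, ends):
                if not hom[s]:
                    continue
                n = e - s
                span = int(pos[e - 1] - pos[s] + 1)
                if n >= window_snps and n >= min_snps and span > min_length:
                    segments.append(
                        ROHSegment(
                            sample=sample,
                            chrom=str(chrom),
                            start=int(pos[s]),
                            end=int(pos[e - 1]),
                            n_snps=int(n),
                        )
                    )
    return segments


def roh_summary(
    segments: Iterable[ROHSegment],
    bin_edges: Sequence[int] = DEFAULT_ROH_BINS,
) -> pd.DataFrame:
    """Per-sample segment counts and total bp per span length bin.

    ``bin_edges`` (ascending) define left-open bins (e0, e1], ..., (ek, inf);
    with the defaults: 5-10 kb, 10-30 kb, >30 kb.  Segments at or below the
    first edge are not counted (they would not have been emitted anyway).
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise InvalidParameterError("bin edges must be strictly ascending")
    labels = [f"{a}-{b}" for a, b in zip(edges, edges[1:])] + [f">{edges[-1]}"]

    def _bin(span: int) -> Optional[str]:
        if span <= edges[0]:
            return None
        for i in range(1, len(edges)):
            if span <= edges[i]:
                return labels[i - 1]
        return labels[-1]

    rows: dict[tuple[str, str], dict] = {}
    for seg in segments:
        lab = _bin(seg.span)
        if lab is None:
            continue
        key = (seg.sample, lab)
        rec = rows.setdefault(key, {"sample": seg.sample, "bin": lab, "count": 0, "total_bp": 0})
        rec["count"] += 1
        rec["total_bp"] += seg.span
    frame = pd.DataFrame(list(rows.values()), columns=["sample", "bin", "count", "total_bp"])
    if len(frame):
        frame["bin"] = pd.Categorical(frame["bin"], categories=labels, ordered=True)
        frame = frame.sort_values(["sample", "bin"]).reset_index(drop=True)
    return frame
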