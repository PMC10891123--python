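"""Fourfold-degenerate-site divergence, 4DTv, mutation rates and WGD mode detection.

Fourfold-degenerate (4D) sites are third codon positions at which any base
encodes the same amino acid; they evolve approximately neutrally, so the
observed per-site difference fraction D between two aligned coding sequences
calibrates the per-generation mutation rate

    mu = D * g / (2 * T)

given a generation time g (years) and a divergence time T (years) — the
factor 2 accounts for the two lineages separating the sequences.  4DTv, the
fraction of 4D sites differing by a transversion, saturates more slowly than
D and its frequency distribution across paralog pairs shows whole-genome
duplications as distinct modes; the same mode detection applies to Ks value
distributions computed elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .errors import EmptyInputError, FrameError, InvalidParameterError

__all__ = [
    "FOURFOLD_PREFIXES",
    "DivergenceResult",
    "MutationRateEstimate",
    "find_4d_sites",
    "pairwise_divergence_4d",
    "aggregate_divergence",
    "mutation_rate",
    "mutation_rates",
    "detect_distance_modes",
    "read_alignment_fasta",
]

# 2-base codon prefixes whose third position is fourfold degenerate
# (standard genetic code): Leu(CT), Val(GT), Ser(TC), Pro(CC), Thr(AC),
# Ala(GC), Arg(CG), Gly(GG).
FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")

DEFAULT_GENERATION_TIMES = (15.0, 20.0, 30.0)  # years


@dataclass(frozen=True)
class DivergenceResult:
    """Pairwise 4D-site divergence between two aligned coding sequences."""

    n4d: int  # number of eligible 4D alignment columns
    ndiff: int  # columns where the two sequences differ
    ntv: int  # differing columns where the change is a transversion
    jukes_cantor: bool = False  # whether D carries the JC69 correction

    @property
    def D(self) -> float:
        p = self.ndiff / self.n4d
        if not self.jukes_cantor:
            return p
        if p >= 0.75:
            raise InvalidParameterError("divergence too high for Jukes-Cantor correction")
        return -0.75 * log(1 - 4 * p / 3)

    @property
    def four_d_tv(self) -> float:
        return self.ntv / self.n4d


@dataclass(frozen=True)
class MutationRateEstimate:
    """mu = D*g/(2T), per site per generation."""

    D: float
    generation_time: float  # years
    divergence_time: float  # years
    mu: float


def _codon_view(seq: str) -> np.ndarray:
    if len(seq) % 3 != 0:
        raise FrameError(f"alignment length {len(seq)} not divisible by 3")
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1").reshape(-1, 3)


def find_4d_sites(seq1: str, seq2: str) -> np.ndarray:
    """0-based alignment columns that are fourfold degenerate in both sequences.

    A third codon position qualifies iff both codons are gap-free with
    unambiguous bases, the first two bases are identical between the two
    sequences, and that shared 2-base prefix heads a fourfold-degenerate
    codon family.  Requiring an identical prefix avoids columns whose
    degeneracy class differs between the sequences.
    """
    if len(seq1) != len(seq2):
        raise FrameError("aligned sequences must have equal length")
    c1, c2 = _codon_view(seq1), _codon_view(seq2)

    valid = np.frombuffer("ACGT".encode(), dtype="S1")
    ok = np.isin(c1, valid).all(axis=1) & np.isin(c2, valid).all(axis=1)
    prefix_same = (c1[:, 0] == c2[:, 0]) & (c1[:, 1] == c2[:, 1])

    code = c1[:, 0].view(np.uint8).astype(np.uint16) * 256 + c1[:, 1].view(np.uint8)
    fourfold_codes = np.array(
        sorted(ord(p[0]) * 256 + ord(p[1]) for p in FOURFOLD_PREFIXES), dtype=np.uint16
    )
    is4d = np.isin(code, fourfold_codes)

    codons = np.nonzero(ok & prefix_same & is4d)[0]
    return codons * 3 + 2


def pairwise_divergence_4d(
    seq1: str,
    seq2: str,
    jukes_cantor: bool = False,
) -> DivergenceResult:
    """Observed 4D-site difference fraction D and transversion fraction 4DTv.

    D is the raw observed frequency of differing 4D sites (set
    ``jukes_cantor=True`` for a JC69 multiple-hit correction of D; the raw
    count fields are unchanged).  Transversions are purine <-> pyrimidine
    changes, so 4DTv <= D always.
    """
    sites = find_4d_sites(seq1, seq2)
    if sites.size == 0:
        raise EmptyInputError("no fourfold-degenerate sites in the alignment")
    b1 = np.frombuffer(seq1.upper().encode("ascii"), dtype="S1")[sites]
    b2 = np.frombuffer(seq2.upper().encode("ascii"), dtype="S1")[sites]
    diff = b1 != b2
    purine = np.frombuffer(b"AG", dtype="S1")
    tv = diff & (np.isin(b1, purine) != np.isin(b2, purine))
    return DivergenceResult(
        n4d=int(sites.size),
        ndiff=int(diff.sum()),
        ntv=int(tv.sum()),
        jukes_cantor=jukes_cantor,
    )


def aggregate_divergence(
    results: Sequence[DivergenceResult],
    aggregate: str = "pooled",
) -> DivergenceResult:
    """Combine per-ortholog divergence results.

    ``pooled`` concatenates sites (sums counts); ``mean`` weighs each
    ortholog pair equally by averaging D and 4DTv and rescaling onto the
    total site count (counts are then rounded to the nearest site).
    """
    if not results:
        raise EmptyInputError("no divergence results to aggregate")
    n = sum(r.n4d for r in results)
    if aggregate == "pooled":
        return DivergenceResult(
            n4d=n,
            ndiff=sum(r.ndiff for r in results),
            ntv=sum(r.ntv for r in results),
        )
    if aggregate == "mean":
        d = float(np.mean([r.ndiff / r.n4d for r in results]))
        tv = float(np.mean([r.ntv / r.n4d for r in results]))
        return DivergenceResult(n4d=n, ndiff=round(d * n), ntv=round(tv * n))
    raise InvalidParameterError(f"unknown aggregate mode {aggregate!r}")


def mutation_rate(D: float, g: float, T: float) -> MutationRateEstimate:
    """Per-site per-generation mutation rate mu = D*g/(2T).

    Parameters
    ----------
    D : observed 4D-site divergence (frequency, in [0, 1])
    g : generation time in years
    T : divergence time in years
    """
    if T <= 0:
        raise InvalidParameterError("divergence time T must be positive")
    if g <= 0:
        raise InvalidParameterError("generation time g must be positive")
    if not 0 <= D <= 1:
        raise InvalidParameterError("D must lie in [0, 1]")
    return MutationRateEstimate(D=D, generation_time=g, divergence_time=T, mu=D * g / (2 * T))


def mutation_rates(
    D: float,
    T: float,
    generation_times: Iterable[float] = DEFAULT_GENERATION_TIMES,
) -> list[MutationRateEstimate]:
    """One mutation-rate estimate per generation-time scenario (default 15/20/30 y)."""
    return [mutation_rate(D, g, T) for g in generation_times]


def detect_distance_modes(
    values: Sequence[float],
    bin_width: float = 0.01,
    smooth_width: int = 3,
    min_prominence_fraction: float = 0.05,
) -> list[float]:
    """Modes of a distance (Ks or 4DTv) distribution, as histogram bin centers.

    The sample is histogrammed at ``bin_width``, smoothed with a centered
    moving average, and local maxima with prominence of at least
    ``min_prominence_fraction`` of the global maximum are returned in
    ascending order.  Secondary modes in paralog distance distributions mark
    whole-genome duplications.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise EmptyInputError("empty distance sample")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    if np.any(vals < 0):
        raise InvalidParameterError("distances must be non-negative")
    nbins = max(1, int(np.ceil((vals.max() + bin_width) / bin_width)))
    counts, edges = np.histogram(vals, bins=nbins, range=(0.0, nbins * bin_width))
    centers = (edges[:-1] + edges[1:]) / 2
    s = uniform_filter1d(counts.astype(float), size=smooth_width, mode="nearest")
    idx, props = find_peaks(s, plateau_size=(1, None))
    if idx.size == 0:
        return [float(centers[int(np.argmax(s))])]
    prom = peak_prominences(s, idx)[0]
    keep = prom >= min_prominence_fraction * float(s.max())
    if not np.any(keep):
        keep = prom == prom.max()
    positions = props.get("left_edges", idx)[keep]
    return [float(centers[int(p)]) for p in positions]


def read_alignment_fasta(path: str | Path) -> tuple[str, str]:
    """Read a pairwise codon alignment (exactly two records) from FASTA."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise InvalidParameterError(f"expected exactly 2 records in {path}, got {len(records)}")
    return str(records[0].seq), str(records[1].seq)
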