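"""k-mer-spectrum ploidy calling and genome-size estimation.

A k-mer spectrum (multiplicity -> number of distinct k-mers observed at that
multiplicity, the ``jellyfish histo`` output) of whole-genome reads from a
p-ploid individual shows peaks near c, 2c, ..., p*c where c is the per-copy
sequencing depth: k-mers shared by all p homologous copies pile up at the
homozygous depth p*c, while k-mers private to a subset of copies form the
lower peaks.  The ploidy call used here is the ratio of the homozygous
(highest-multiplicity) peak depth to the leftmost heterozygous peak depth,
rounded to the nearest integer; genome size is total k-mer mass above the
error cutoff divided by the homozygous peak depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .errors import EmptyInputError, InvalidParameterError, InvalidStateError, NoSignalError

__all__ = [
    "KmerHistogram",
    "PeakSet",
    "PloidyCall",
    "detect_peaks",
    "call_ploidy",
    "estimate_genome_size",
    "analyze_spectrum",
    "count_kmers",
]


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer multiplicity spectrum.

    Parameters
    ----------
    multiplicity : strictly increasing positive ints
    count : non-negative number of distinct k-mers per multiplicity
    """

    multiplicity: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.multiplicity, dtype=np.int64)
        c = np.asarray(self.count, dtype=np.int64)
        if m.shape != c.shape or m.ndim != 1:
            raise InvalidParameterError("multiplicity and count must be 1-D and equal length")
        if m.size and (np.any(np.diff(m) <= 0) or m[0] < 1):
            raise InvalidParameterError("multiplicities must be strictly increasing and >= 1")
        if np.any(c < 0):
            raise InvalidParameterError("counts must be non-negative")
        object.__setattr__(self, "multiplicity", m)
        object.__setattr__(self, "count", c)

    def __len__(self) -> int:
        return int(self.multiplicity.size)

    def dense(self) -> tuple[int, np.ndarray]:
        """Return (offset, counts) with counts indexed by multiplicity - offset,
        zero-filled at multiplicities absent from the file."""
        if not len(self):
            raise EmptyInputError("empty histogram")
        lo = int(self.multiplicity[0])
        hi = int(self.multiplicity[-1])
        dense = np.zeros(hi - lo + 1, dtype=np.int64)
        dense[self.multiplicity - lo] = self.count
        return lo, dense

    @classmethod
    def from_file(cls, path: str | Path) -> "KmerHistogram":
        """Read a two-column whitespace-separated histogram (``jellyfish histo``)."""
        data = np.loadtxt(path, dtype=np.int64, ndmin=2)
        if data.size == 0:
            raise EmptyInputError(f"no rows in {path}")
        order = np.argsort(data[:, 0], kind="stable")
        return cls(data[order, 0], data[order, 1])

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.multiplicity, self.count]), fmt="%d")


@dataclass(frozen=True)
class PeakSet:
    """Prominent peaks of a smoothed spectrum above the error cutoff."""

    error_cutoff: int
    peaks: tuple[tuple[int, float], ...]  # (multiplicity, smoothed count), ascending

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(m for m, _ in self.peaks)


@dataclass(frozen=True)
class PloidyCall:
    """Ploidy and genome size read off a peak set.

    ``ploidy`` is None (indeterminate) when only one peak exists: a single
    peak cannot distinguish a haploid from a fully homozygous higher ploidy.
    """

    ploidy: Optional[int]
    hom_peak_depth: int
    het_peak_depth: Optional[int] = None
    ratio: Optional[float] = None
    genome_size_estimate: Optional[int] = None

    @property
    def determinate(self) -> bool:
        return self.ploidy is not None


def _smooth(dense: np.ndarray, smooth_width: int) -> np.ndarray:
    if smooth_width < 1 or smooth_width % 2 == 0:
        raise InvalidParameterError("smooth_width must be a positive odd integer")
    return uniform_filter1d(dense.astype(float), size=smooth_width, mode="nearest")


def detect_peaks(
    hist: KmerHistogram,
    smooth_width: int = 3,
    min_prominence_fraction: float = 0.05,
) -> PeakSet:
    """Locate the error cutoff and the prominent peaks of a spectrum.

    The spectrum is smoothed with a centered moving average of ``smooth_width``
    bins.  The error cutoff is the first local minimum of the smoothed
    spectrum (the valley between the sequencing-error decay and the first
    real peak); peaks are local maxima above the cutoff whose prominence is
    at least ``min_prominence_fraction`` of the global maximum above the
    cutoff.  Ties across a flat plateau resolve to the lowest multiplicity.

    Raises
    ------
    EmptyInputError
        for an empty histogram.
    NoSignalError
        when the smoothed spectrum is monotone non-increasing (pure error
        decay, no interior minimum).
    """
    if not len(hist):
        raise EmptyInputError("empty histogram")
    lo, dense = hist.dense()
    s = _smooth(dense, smooth_width)

    # first index where the smoothed spectrum turns upward = first local minimum
    rises = np.nonzero(np.diff(s) > 0)[0]
    if rises.size == 0:
        raise NoSignalError("spectrum is monotone non-increasing; no peak beyond the error decay")
    cut_idx = int(rises[0])
    error_cutoff = lo + cut_idx

    region = s[cut_idx:]
    idx, props = find_peaks(region, plateau_size=(1, None))
    positions = props.get("left_edges", idx)  # lower multiplicity wins on plateaus
    if idx.size == 0:
        # monotone-increasing tail: the boundary maximum is the only peak
        best = int(np.argmax(region))
        return PeakSet(error_cutoff, ((lo + cut_idx + best, float(region[best])),))
    prominences = peak_prominences(region, idx)[0]
    threshold = min_prominence_fraction * float(region.max())
    keep = prominences >= threshold
    if not np.any(keep):
        best = int(idx[np.argmax(region[idx])])
        keep = idx == best
    peaks = tuple(
        (int(lo + cut_idx + p), float(region[i]))
        for p, i in zip(positions[keep], idx[keep])
    )
    return PeakSet(error_cutoff, peaks)


def call_ploidy(peaks: PeakSet) -> PloidyCall:
    """Call ploidy as round(hom peak depth / leftmost heterozygous peak depth).

    The homozygous peak is the highest-multiplicity prominent peak (repeat
    shoulders can out-count it, but never out-run it to the right); the
    leftmost prominent peak is the lowest heterozygous peak.  With a single
    peak the call is indeterminate.
    """
    if not peaks.peaks:
        raise InvalidStateError("peak set is empty")
    ms = peaks.multiplicities
    hom = ms[-1]
    if len(ms) == 1:
        return PloidyCall(ploidy=None, hom_peak_depth=hom)
    het = ms[0]
    ratio = hom / het
    ploidy = max(1, int(round(ratio)))
    return PloidyCall(ploidy=ploidy, hom_peak_depth=hom, het_peak_depth=het, ratio=ratio)


def estimate_genome_size(hist: KmerHistogram, peaks: PeakSet) -> int:
    """Genome size = total k-mer mass above the error cutoff / homozygous depth.

    Mass is sum(multiplicity * count); dividing by the homozygous peak depth
    converts it to a count of genomic positions.  For a tetraploid spectrum
    this is the whole (4n) genome size, matching the convention of reporting
    whole-genome estimates for autotetraploids.
    """
    if not peaks.peaks:
        raise InvalidStateError("cannot size a genome without a homozygous peak")
    hom = peaks.multiplicities[-1]
    mask = hist.multiplicity > peaks.error_cutoff
    mass = float(np.sum(hist.multiplicity[mask] * hist.count[mask]))
    return int(round(mass / hom))


def analyze_spectrum(
    hist: KmerHistogram,
    smooth_width: int = 3,
    min_prominence_fraction: float = 0.05,
) -> PloidyCall:
    """detect_peaks + call_ploidy + estimate_genome_size in one step."""
    peaks = detect_peaks(hist, smooth_width, min_prominence_fraction)
    call = call_ploidy(peaks)
    size = estimate_genome_size(hist, peaks)
    return PloidyCall(
        ploidy=call.ploidy,
        hom_peak_depth=call.hom_peak_depth,
        het_peak_depth=call.het_peak_depth,
        ratio=call.ratio,
        genome_size_estimate=size,
    )


def count_kmers(sequences: Iterable[str], k: int = 17) -> KmerHistogram:
    """Naive k-mer counter for small synthetic sequences (testing aid only).

    Counts canonical-strand k-mers verbatim (no reverse-complement folding)
    and returns their multiplicity spectrum.  Not intended for read data.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    spectrum = Counter(counts.values())
    ms = np.array(sorted(spectrum), dtype=np.int64)
    return KmerHistogram(ms, np.array([spectrum[int(m)] for m in ms], dtype=np.int64))
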