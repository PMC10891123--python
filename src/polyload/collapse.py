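"""Depth-ratio accounting of collapsed homologous regions in polyploid assemblies.

When homologous chromosome copies of an autopolyploid are nearly identical,
assemblers merge them into a single sequence; reads from all copies then map
onto the merged copy, which shows up as elevated coverage.  Classifying fixed
windows by the ratio of window depth to the overall (baseline) depth gives a
per-window collapse multiplicity: ratio < 1.5 -> 1 copy (no collapse),
[1.5, 2.5) -> 2 copies, [2.5, 3.5) -> 3 copies, >= 3.5 -> 4 copies.  The total
overlapping (assembly-absent) length is then

    O = L2 + 2*L3 + 3*L4

because a window representing m collapsed copies hides m-1 copies' worth of
sequence.  The reconciliation fraction (A + O)/E compares assembled size A
plus hidden length O against the k-mer estimated genome size E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError, OrderingError

__all__ = [
    "DepthTrack",
    "CollapseClassification",
    "CollapseReport",
    "window_depths",
    "read_depth_tsv",
    "baseline_depth",
    "classify_windows",
    "total_overlap",
    "reconcile",
    "collapse_report",
]

RATIO_BIN_EDGES = (1.5, 2.5, 3.5)  # left-closed bins for classes 2, 3, 4


@dataclass(frozen=True)
class DepthTrack:
    """Non-overlapping fixed windows with mean depth (0-based half-open coords)."""

    chrom: np.ndarray  # str per window
    start: np.ndarray  # int, 0-based inclusive
    end: np.ndarray  # int, exclusive
    depth: np.ndarray  # float mean depth
    window_size: int = 10_000

    def __post_init__(self) -> None:
        n = len(self.depth)
        if not (len(self.chrom) == len(self.start) == len(self.end) == n):
            raise InvalidParameterError("track arrays must have equal length")
        if n and np.any(np.asarray(self.end) - np.asarray(self.start) <= 0):
            raise InvalidParameterError("windows must have positive length")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.end) - np.asarray(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "depth": self.depth}
        )


@dataclass(frozen=True)
class CollapseClassification:
    """Per-window depth ratios and collapse classes for a track."""

    ratio: np.ndarray
    cls: np.ndarray  # int in {1,2,3,4}
    baseline: float


@dataclass(frozen=True)
class CollapseReport:
    """Class length totals, overlap length and genome-size reconciliation (bp)."""

    L1: int
    L2: int
    L3: int
    L4: int
    overlap: int
    assembled_size: Optional[int] = None
    estimated_size: Optional[int] = None
    reconciliation: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_depth_tsv(path: str | Path) -> Iterator[Tuple[str, int, float]]:
    """Stream (sequence, 1-based position, depth) rows from a ``samtools depth`` TSV."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seq, pos, depth = line.split()[:3]
            yield seq, int(pos), float(depth)


def window_depths(
    per_base_depth: Iterable[Tuple[str, int, float]],
    window_size: int = 10_000,
) -> DepthTrack:
    """Aggregate a sorted per-base depth stream into fixed non-overlapping windows.

    Positions are 1-based (``samtools depth`` dialect).  A trailing partial
    window is retained iff its covered extent is at least half the window
    size, to avoid biasing contig ends.  Unsorted positions within a sequence
    raise :class:`OrderingError`.
    """
    if window_size <= 0:
        raise InvalidParameterError("window_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    means: list[float] = []

    cur_seq: Optional[str] = None
    cur_win = -1
    acc_sum = 0.0
    acc_n = 0
    last_pos = 0
    max_pos = 0

    def flush(final: bool) -> None:
        nonlocal acc_sum, acc_n
        if cur_seq is None or acc_n == 0:
            return
        wstart = cur_win * window_size
        wend = min((cur_win + 1) * window_size, max_pos)
        if final and (wend - wstart) < window_size and (wend - wstart) < window_size / 2:
            acc_sum, acc_n = 0.0, 0
            return
        chroms.append(cur_seq)
        starts.append(wstart)
        ends.append(wend)
        means.append(acc_sum / acc_n)
        acc_sum, acc_n = 0.0, 0

    for seq, pos, depth in per_base_depth:
        if seq != cur_seq:
            flush(final=True)
            cur_seq, cur_win, last_pos, max_pos = seq, (pos - 1) // window_size, 0, 0
        if pos <= last_pos:
            raise OrderingError(f"positions not strictly increasing in {seq} at {pos}")
        win = (pos - 1) // window_size
        if win != cur_win:
            max_pos = last_pos
            flush(final=False)
            cur_win = win
        last_pos = pos
        max_pos = pos
        acc_sum += depth
        acc_n += 1
    flush(final=True)

    return DepthTrack(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        depth=np.array(means, dtype=float),
        window_size=window_size,
    )


def baseline_depth(track: DepthTrack) -> float:
    """Overall coverage depth of a genome, taken as the median of window means.

    The median is robust to the inflated depth of collapsed regions, which a
    mean would absorb.
    """
    if not len(track):
        raise EmptyInputError("empty depth track")
    return float(np.median(track.depth))


def classify_windows(track: DepthTrack, baseline: float) -> CollapseClassification:
    """Map each window's depth/baseline ratio to a collapse class in {1,2,3,4}.

    Bins are left-closed: class 2 on [1.5, 2.5), class 3 on [2.5, 3.5),
    class 4 on [3.5, inf); everything below 1.5 (including dropout) is class 1.
    """
    if baseline <= 0:
        raise InvalidParameterError("baseline depth must be positive")
    ratio = np.asarray(track.depth, dtype=float) / baseline
    cls = 1 + np.digitize(ratio, RATIO_BIN_EDGES, right=False)
    return CollapseClassification(ratio=ratio, cls=cls.astype(np.int64), baseline=float(baseline))


def total_overlap(classification: CollapseClassification, lengths: np.ndarray) -> CollapseReport:
    """Total bp per collapse class and the hidden overlap length O = L2 + 2*L3 + 3*L4."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.shape != classification.cls.shape:
        raise InvalidParameterError("lengths must match classification")
    L = [int(lengths[classification.cls == k].sum()) for k in (1, 2, 3, 4)]
    O = L[1] + 2 * L[2] + 3 * L[3]
    return CollapseReport(L1=L[0], L2=L[1], L3=L[2], L4=L[3], overlap=O)


def reconcile(assembled_size: float, overlap: float, estimated_size: float) -> float:
    """Fraction of the estimated genome size explained by assembly + hidden overlap."""
    if estimated_size <= 0:
        raise InvalidParameterError("estimated genome size must be positive")
    return (assembled_size + overlap) / estimated_size


def collapse_report(
    track: DepthTrack,
    assembled_size: Optional[int] = None,
    estimated_size: Optional[int] = None,
    baseline: Optional[float] = None,
) -> CollapseReport:
    """Classify a track end to end and assemble the full report.

    ``baseline`` overrides the median-of-windows baseline when the overall
    coverage depth is known externally.
    """
    base = baseline_depth(track) if baseline is None else float(baseline)
    cc = classify_windows(track, base)
    rep = total_overlap(cc, track.lengths)
    rec = None
    if assembled_size is not None and estimated_size is not None:
        rec = reconcile(assembled_size, rep.overlap, estimated_size)
    return CollapseReport(
        L1=rep.L1,
        L2=rep.L2,
        L3=rep.L3,
        L4=rep.L4,
        overlap=rep.overlap,
        assembled_size=assembled_size,
        estimated_size=estimated_size,
        reconciliation=rec,
    )
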