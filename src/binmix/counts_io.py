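"""Count-vector containers and genomic-interval I/O.

Observations are read counts per fixed-width genomic bin.  Reads are treated
as points (their start positions); a chromosome is tiled with equal-width
bins, and any bin touching an excluded (e.g. telomeric/centromeric) region is
dropped outright rather than truncated, so every retained bin has the same
width.  Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger("binmix")

__all__ = [
    "CountVector",
    "RegionSet",
    "bin_reads",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
]


@dataclass(frozen=True)
class CountVector:
    """Non-negative integer read counts, one per genomic bin.

    Parameters
    ----------
    counts
        Reads per bin; non-negative integers.
    bin_width
        Bin width in bp, if the counts carry genomic coordinates.
    chrom
        Chromosome name, if known.
    bin_starts
        Start coordinate (bp) of each retained bin, parallel to ``counts``.
        Strictly increasing; each start is offset from the first by a whole
        number of bin widths (bins may be missing where regions were
        excluded, but never shifted off the grid).
    """

    counts: np.ndarray
    bin_width: int | None = None
    chrom: str | None = None
    bin_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_float = counts.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                raise ValueError("counts must be integer-valued")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if self.bin_starts is not None:
            starts = np.asarray(self.bin_starts).astype(np.int64)
            if starts.shape != counts.shape:
                raise ValueError("bin_starts must parallel counts")
            if starts.size > 1 and np.any(np.diff(starts) <= 0):
                raise ValueError("bin_starts must be strictly increasing")
            if self.bin_width is not None and starts.size:
                if np.any((starts - starts[0]) % int(self.bin_width) != 0):
                    raise ValueError("bin_starts must sit on the bin_width grid")
            object.__setattr__(self, "bin_starts", starts)

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class RegionSet:
    """A set of genomic intervals, (chrom, start, end), 0-based half-open.

    Intervals are normalized on construction: sorted, and overlapping or
    bookended intervals on the same chromosome are merged.
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {(chrom, start, end)}: need 0 <= start < end")
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, int(start), int(end)))
        object.__setattr__(self, "intervals", tuple(merged))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)

    def for_chrom(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == chrom]


def bin_reads(
    read_positions: Sequence[tuple[str, int]],
    chrom_length: int,
    bin_width: int,
    excluded: RegionSet | None = None,
) -> CountVector:
    """Bin read start positions into fixed-width bins tiling one chromosome.

    The chromosome is tiled with ``chrom_length // bin_width`` full bins
    starting at 0; a trailing partial bin is dropped.  A read falls in the
    bin containing its position.  Any bin overlapping an excluded interval
    by at least 1 bp is removed from the output entirely (not zero-filled).
    Duplicate positions are retained.

    Raises
    ------
    ValueError
        If ``bin_width < 1`` or any position lies outside ``[0, chrom_length)``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    chroms = {c for c, _ in read_positions}
    if len(chroms) > 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else None
    pos = np.asarray([p for _, p in read_positions], dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= chrom_length):
        bad = pos[(pos < 0) | (pos >= chrom_length)][0]
        raise ValueError(f"read position {bad} outside chromosome [0, {chrom_length})")

    n_bins = chrom_length // bin_width
    idx = pos // bin_width
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins)[:n_bins]

    keep = np.ones(n_bins, dtype=bool)
    if excluded is not None and len(excluded):
        known = {c for c, _, _ in excluded.intervals}
        if chrom is not None:
            for other in known - {chrom}:
                logger.warning("excluded intervals on unknown chromosome %r ignored", other)
            spans = excluded.for_chrom(chrom)
        else:
            # reads carried no chromosome label; apply all exclusions
            spans = [(s, e) for _, s, e in excluded.intervals]
        for start, end in spans:
            lo = start // bin_width
            hi = -(-end // bin_width)  # ceil
            keep[max(lo, 0) : min(hi, n_bins)] = False

    starts = np.arange(n_bins, dtype=np.int64) * bin_width
    return CountVector(
        counts=counts[keep],
        bin_width=bin_width,
        chrom=chrom,
        bin_starts=starts[keep],
    )


# ---------------------------------------------------------------------------
# BED and count-table I/O


def read_bed(path: str | Path) -> RegionSet:
    """Read a 3-column BED file (0-based half-open) into a RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {lineno}: need 0 <= start < end")
            intervals.append((parts[0], start, end))
    return RegionSet(tuple(intervals))


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_counts(path: str | Path) -> CountVector:
    """Read a count table written by :func:`write_counts`.

    Accepts headered TSV with either a single ``count`` column or
    ``(chrom, start, count)`` columns.  Metadata lines ``# key=value``
    before the header carry ``bin_width`` and (coordinate-free) ``chrom``.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [h.strip() for h in line.split("\t")]
                continue
            rows.append((lineno, line.split("\t")))
    if header is None:
        return CountVector(counts=np.empty(0, dtype=np.int64))
    if "count" not in header:
        raise ValueError(f"{path}: header must contain a 'count' column")
    ci = header.index("count")
    with_coords = "chrom" in header and "start" in header
    counts: list[int] = []
    starts: list[int] = []
    chroms: set[str] = set()
    for lineno, parts in rows:
        if len(parts) != len(header):
            raise ValueError(f"{path}: line {lineno}: expected {len(header)} fields")
        try:
            c = int(parts[ci])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer count") from exc
        if c < 0:
            raise ValueError(f"{path}: line {lineno}: negative count")
        counts.append(c)
        if with_coords:
            chroms.add(parts[header.index("chrom")])
            try:
                starts.append(int(parts[header.index("start")]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer start") from exc
    if with_coords and len(chroms) > 1:
        raise ValueError(f"{path}: multiple chromosomes in one count table")
    chrom = chroms.pop() if chroms else meta.get("chrom")
    if chrom == ".":
        chrom = None
    bin_width = int(meta["bin_width"]) if "bin_width" in meta else None
    return CountVector(
        counts=np.asarray(counts, dtype=np.int64),
        bin_width=bin_width,
        chrom=chrom,
        bin_starts=np.asarray(starts, dtype=np.int64) if with_coords else None,
    )


def write_counts(cv: CountVector, path: str | Path) -> None:
    """Write a CountVector as headered TSV (round-trips with read_counts)."""
    with open(path, "w") as fh:
        if cv.bin_width is not None:
            fh.write(f"# bin_width={cv.bin_width}\n")
        if cv.bin_starts is not None:
            chrom = cv.chrom if cv.chrom is not None else "."
            fh.write("chrom\tstart\tcount\n")
            for start, count in zip(cv.bin_starts, cv.counts):
                fh.write(f"{chrom}\t{start}\t{count}\n")
        else:
            if cv.chrom is not None:
                fh.write(f"# chrom={cv.chrom}\n")
            fh.write("count\n")
            for count in cv.counts:
                fh.write(f"{count}\n")
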