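"""TF-binding regions: BED reading, overlap merging, positional sorting.

Coordinates are BED-standard 0-based half-open throughout. Peaks are
strandless; any strand column in the input is ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Binding regions for one TF in one cell line under one condition."""

    cell_line: str = ""
    tf: str = ""
    condition_id: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


_SKIP = re.compile(r"^(#|track\b|browser\b)")


def read_bed(
    path: str | Path,
    *,
    cell_line: str = "",
    tf: str = "",
    condition_id: str = "",
) -> PeakSet:
    """Parse a BED3+ file into a PeakSet.

    Track/browser/comment lines and blank lines are skipped; columns past
    the third are ignored. Malformed coordinates raise :class:`BedParseError`
    naming the offending line. An empty file yields an empty PeakSet.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or _SKIP.match(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise BedParseError(
                    f"{path.name}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from None
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise BedParseError(f"{path.name}:{lineno}: {exc}") from None
    return PeakSet(cell_line=cell_line, tf=tf, condition_id=condition_id,
                   intervals=intervals)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < chr10 < chrX.

    Numeric runs inside the name compare numerically, other runs
    lexicographically; purely presentational downstream.
    """
    parts = re.split(r"(\d+)", chrom)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


def sort_peaks(peaks: PeakSet) -> PeakSet:
    """Return a new PeakSet ordered by (chrom natural order, start, end)."""
    ordered = sorted(peaks.intervals,
                     key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))
    return replace(peaks, intervals=ordered)


def merge_overlapping(peaks: PeakSet) -> PeakSet:
    """Merge overlapping and abutting intervals per chromosome.

    Abutting intervals ([a,b) and [b,c)) are merged, matching the
    bedtools-merge default at distance 0. The output is sorted and covers
    exactly the same genomic bases as the input.
    """
    ordered = sort_peaks(peaks).intervals
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return replace(peaks, intervals=merged)


def pool_peaks(peak_sets: Iterable[PeakSet], *, cell_line: str = "",
               tf: str = "", condition_id: str = "") -> PeakSet:
    """Concatenate several PeakSets (e.g. experiments from one cell line).

    TF identity is kept per input PeakSet; pooling across TFs or experiments
    is an explicit caller choice made here. The result is not merged --
    call :func:`merge_overlapping` afterwards.
    """
    all_iv: list[GenomicInterval] = []
    for ps in peak_sets:
        all_iv.extend(ps.intervals)
    return PeakSet(cell_line=cell_line, tf=tf, condition_id=condition_id,
                   intervals=all_iv)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED3, one interval per line, in the PeakSet's current order."""
    with Path(path).open("w") as fh:
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
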