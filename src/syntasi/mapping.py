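"""Exact-match mapping to the precursor (+) strand and positional profiling.

The mapping universe is a single short precursor, so alignment reduces to
exact substring search: a collapsed read maps wherever it occurs verbatim
on the forward strand, with no mismatches or gaps.  Profiles count 5' ends
per (position, read length) cell and normalise to RPM (reads per million
mapped reads); by default the RPM denominator is the reads mapped to this
precursor within the profiled size range, not the library size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Sequence

from .design import PrecursorDesign
from .errors import EmptyProfileError
from .sread_io import CollapsedRead

logger = logging.getLogger(__name__)

DEFAULT_SIZE_RANGE = (19, 24)


@dataclasses.dataclass(frozen=True)
class MappingHit:
    """One exact occurrence of a read on the precursor (+) strand."""

    sequence: str
    count: int
    start: int  # 0-based 5'-most coordinate
    length: int
    multi: bool = False  # read occurs more than once on the precursor

    @property
    def end(self) -> int:
        return self.start + self.length


def find_all_occurrences(haystack: str, needle: str) -> list[int]:
    """All start offsets (including overlapping) of needle in haystack."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_exact(collapsed: Iterable[CollapsedRead],
              precursor: PrecursorDesign | str) -> list[MappingHit]:
    """Map collapsed reads to the precursor forward strand, exact match only.

    A read with no occurrence is unmapped and silently skipped; a read with
    several occurrences yields one hit per occurrence, each flagged
    ``multi`` and carrying the read's full count (a warning is logged —
    this cannot happen for default designs, which forbid duplicate guides).
    """
    seq = precursor.sequence if isinstance(precursor, PrecursorDesign) else precursor
    if not seq:
        raise ValueError("precursor sequence is empty")
    hits: list[MappingHit] = []
    for read in collapsed:
        starts = find_all_occurrences(seq, read.sequence)
        if not starts:
            continue
        multi = len(starts) > 1
        if multi:
            logger.warning(
                "read %s maps at %d positions; counting full weight at each",
                read.sequence, len(starts),
            )
        for s in starts:
            hits.append(MappingHit(sequence=read.sequence, count=read.count,
                                   start=s, length=len(read.sequence),
                                   multi=multi))
    return hits


@dataclasses.dataclass(frozen=True)
class PositionProfile:
    """Per-(position, length) 5'-end counts and RPM over the precursor."""

    precursor_length: int
    size_range: tuple[int, int]
    counts: dict[tuple[int, int], int]  # (0-based position, length) -> count
    total_mapped: int
    rpm_denominator: int  # equals total_mapped in per-precursor mode

    def rpm(self, position: int, length: int) -> float:
        if self.rpm_denominator == 0:
            raise EmptyProfileError("no mapped reads; RPM undefined")
        return self.counts.get((position, length), 0) / self.rpm_denominator * 1e6

    def rpm_cells(self) -> dict[tuple[int, int], float]:
        if self.rpm_denominator == 0:
            raise EmptyProfileError("no mapped reads; RPM undefined")
        return {k: c / self.rpm_denominator * 1e6 for k, c in self.counts.items()}

    def position_totals(self) -> dict[int, int]:
        """Counts summed over read lengths, keyed by 0-based 5' position."""
        out: dict[int, int] = {}
        for (pos, _length), c in self.counts.items():
            out[pos] = out.get(pos, 0) + c
        return out


def build_profile(hits: Iterable[MappingHit], precursor_length: int,
                  size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
                  library_size: int | None = None) -> PositionProfile:
    """Aggregate hits into a positional profile restricted to a size range.

    Hits outside ``size_range`` (default 19–24 nt) are excluded from both
    the cells and ``total_mapped``.  ``library_size`` switches the RPM
    denominator to the whole library for cross-sample comparisons; the
    default denominator is the per-precursor mapped total.
    """
    lo, hi = size_range
    counts: dict[tuple[int, int], int] = {}
    total = 0
    for h in hits:
        if h.end > precursor_length:
            raise ValueError(
                f"hit at {h.start}+{h.length} exceeds precursor length "
                f"{precursor_length}"
            )
        if not lo <= h.length <= hi:
            continue
        key = (h.start, h.length)
        counts[key] = counts.get(key, 0) + h.count
        total += h.count
    denom = library_size if library_size is not None else total
    return PositionProfile(precursor_length=precursor_length,
                           size_range=(lo, hi), counts=counts,
                           total_mapped=total, rpm_denominator=denom)


def write_profile_tsv(profile: PositionProfile, path) -> None:
    """TSV with 1-based positions: position, read_length, count, rpm."""
    with open(path, "w") as fh:
        fh.write("position\tread_length\tcount\trpm\n")
        for (pos, length), c in sorted(profile.counts.items()):
            rpm = (c / profile.rpm_denominator * 1e6
                   if profile.rpm_denominator else float("nan"))
            fh.write(f"{pos + 1}\t{length}\t{c}\t{rpm:.4f}\n")


def write_profile_summary(profile: PositionProfile, path, *,
                          precursor_name: str = "precursor") -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "precursor": precursor_name,
                "precursor_length": profile.precursor_length,
                "size_range": list(profile.size_range),
                "total_mapped": profile.total_mapped,
                "rpm_denominator": profile.rpm_denominator,
            },
            fh, indent=2,
        )
        fh.write("\n")


def stacked_profile(profile: PositionProfile) -> list[dict]:
    """Per-position rows (1-based) with per-length counts, for plotting."""
    lo, hi = profile.size_range
    rows = []
    for pos in range(profile.precursor_length):
        row = {"position": pos + 1}
        any_count = 0
        for length in range(lo, hi + 1):
            c = profile.counts.get((pos, length), 0)
            row[f"len{length}"] = c
            any_count += c
        row["total"] = any_count
        rows.append(row)
    return rows
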