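"""Processing-accuracy and 21-register phasing statistics.

Two headline statistics describe how faithfully a syn-tasiRNA precursor is
diced downstream of the trigger cleavage site:

* **Processing accuracy** (per guide): among 19–24-nt (+) reads whose 5'
  end lies within ±4 nt of the guide's 5' end, the fraction that are the
  authentic mature guide — length exactly 21 with the 5' end exactly at the
  guide start (under exact mapping this is precisely the guide sequence).

* **Phasing table**: 21-nt (+) reads with 5' ends at or downstream of the
  cleavage site are binned by phasing register.  With the first nucleotide
  after the cut as position 1, a read at 1-based distance d falls in
  register ((d−1) mod 21) + 1; register 1 is the in-phase class and every
  guide 5' end sits there by construction.

All proportions weight unique reads by their collapsed counts.  Undefined
fractions (zero denominators) are reported as null, never coerced to 0.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

from .design import GUIDE_LENGTH, PrecursorDesign
from .errors import EmptyTableError, NoWindowReadsError
from .mapping import MappingHit, PositionProfile

N_REGISTERS = 21
DEFAULT_WINDOW = 4
DEFAULT_SIZE_RANGE = (19, 24)


@dataclasses.dataclass(frozen=True)
class GuideAccuracy:
    """Processing-accuracy entry for one guide."""

    guide_name: str
    guide_index: int  # 1-based
    guide_offset: int  # 0-based 5' offset on the precursor
    window: int
    size_range: tuple[int, int]
    window_count: int
    authentic_count: int

    @property
    def fraction(self) -> float:
        if self.window_count == 0:
            raise NoWindowReadsError(
                f"no reads within ±{self.window} nt of guide "
                f"{self.guide_name!r}; accuracy undefined"
            )
        return self.authentic_count / self.window_count


@dataclasses.dataclass(frozen=True)
class ProcessingReport:
    """Per-guide accuracy entries plus a pooled (all-guide) summary."""

    entries: tuple[GuideAccuracy, ...]
    window: int
    size_range: tuple[int, int]

    @property
    def pooled_window_count(self) -> int:
        return sum(e.window_count for e in self.entries)

    @property
    def pooled_authentic_count(self) -> int:
        return sum(e.authentic_count for e in self.entries)

    @property
    def pooled_fraction(self) -> float:
        if self.pooled_window_count == 0:
            raise NoWindowReadsError("no reads in any guide window")
        return self.pooled_authentic_count / self.pooled_window_count


@dataclasses.dataclass(frozen=True)
class PhasingTable:
    """Count-weighted proportions over the 21 phasing registers."""

    register_counts: tuple[int, ...]  # registers 1..21
    n_reads: int
    cleavage_offset: int

    @property
    def register_proportion(self) -> tuple[float, ...]:
        if self.n_reads == 0:
            raise EmptyTableError("no qualifying 21-nt reads; table undefined")
        return tuple(c / self.n_reads for c in self.register_counts)


def register_of(offset: int, cleavage_offset: int) -> int:
    """Phasing register (1..21) of a 5' end at 0-based ``offset``.

    Position 1 is the first nucleotide after the cleavage site, so the
    1-based phase distance is d = offset − cleavage_offset + 1 and the
    register is ((d − 1) mod 21) + 1.
    """
    d = offset - cleavage_offset + 1
    return (d - 1) % N_REGISTERS + 1


def processing_accuracy(hits: Iterable[MappingHit], design: PrecursorDesign,
                        guide_index: int, window: int = DEFAULT_WINDOW,
                        size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
                        authentic_any_length: bool = False) -> GuideAccuracy:
    """Accuracy of one guide: authentic / (reads in the ±window nt window).

    The window is inclusive at both ends: 5' ends in
    [guide_5' − window, guide_5' + window], sizes restricted to
    ``size_range``.  ``authentic_any_length`` relaxes the numerator to any
    read whose 5' end matches the guide start regardless of length.
    Raises :class:`NoWindowReadsError` via ``.fraction`` when the window is
    empty — an undefined fraction is never reported as 0.
    """
    guide = design.guides[guide_index - 1]
    g5 = design.guide_offset(guide_index)
    lo, hi = size_range
    window_count = 0
    authentic_count = 0
    for h in hits:
        if not lo <= h.length <= hi:
            continue
        if abs(h.start - g5) > window:
            continue
        window_count += h.count
        if h.start == g5 and (authentic_any_length or h.length == GUIDE_LENGTH):
            authentic_count += h.count
    entry = GuideAccuracy(
        guide_name=guide.name, guide_index=guide_index, guide_offset=g5,
        window=window, size_range=(lo, hi),
        window_count=window_count, authentic_count=authentic_count,
    )
    if window_count == 0:
        # surface the error eagerly; callers that tolerate empty windows
        # catch this and record a null fraction
        raise NoWindowReadsError(
            f"no {lo}-{hi} nt reads within ±{window} nt of guide "
            f"{guide.name!r}"
        )
    return entry


def processing_report(hits: Sequence[MappingHit], design: PrecursorDesign,
                      window: int = DEFAULT_WINDOW,
                      size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
                      authentic_any_length: bool = False) -> ProcessingReport:
    """Accuracy entries for every guide; empty windows yield zero-count
    entries whose ``.fraction`` raises (serialised as null)."""
    entries = []
    for k in range(1, len(design.guides) + 1):
        try:
            entries.append(
                processing_accuracy(hits, design, k, window, size_range,
                                    authentic_any_length)
            )
        except NoWindowReadsError:
            entries.append(
                GuideAccuracy(
                    guide_name=design.guides[k - 1].name, guide_index=k,
                    guide_offset=design.guide_offset(k), window=window,
                    size_range=size_range, window_count=0, authentic_count=0,
                )
            )
    return ProcessingReport(entries=tuple(entries), window=window,
                            size_range=size_range)


def phasing_table(hits: Iterable[MappingHit],
                  design: PrecursorDesign) -> PhasingTable:
    """Bin 21-nt (+) reads downstream of the cleavage site by register.

    Reads whose 5' end lies upstream of the cleavage site span the cut and
    are excluded: the register statistic is defined only over positions
    downstream of it.
    """
    cut = design.cleavage_offset
    counts = [0] * N_REGISTERS
    total = 0
    for h in hits:
        if h.length != GUIDE_LENGTH or h.start < cut:
            continue
        counts[register_of(h.start, cut) - 1] += h.count
        total += h.count
    if total == 0:
        raise EmptyTableError(
            "no 21-nt reads at or downstream of the cleavage site"
        )
    return PhasingTable(register_counts=tuple(counts), n_reads=total,
                        cleavage_offset=cut)


# ---------------------------------------------------------------------------
# report document

def build_report(design: PrecursorDesign, profile: PositionProfile,
                 accuracy: ProcessingReport, phasing: PhasingTable, *,
                 provenance: dict | None = None) -> dict:
    """Assemble the machine-readable report (JSON-serialisable dict).

    Positions are reported 1-based; undefined fractions are null.
    """
    entries = []
    for e in accuracy.entries:
        entries.append({
            "guide": e.guide_name,
            "guide_index": e.guide_index,
            "guide_position": e.guide_offset + 1,
            "window_count": e.window_count,
            "authentic_count": e.authentic_count,
            "fraction": (e.authentic_count / e.window_count
                         if e.window_count else None),
        })
    pooled_fraction = (accuracy.pooled_authentic_count
                       / accuracy.pooled_window_count
                       if accuracy.pooled_window_count else None)
    props = list(phasing.register_proportion)
    return {
        "design": {
            "name": design.name,
            "length": len(design.sequence),
            "n_guides": len(design.guides),
            "cleavage_position": design.cleavage_offset,  # point after pos 12
        },
        "profile": {
            "size_range": list(profile.size_range),
            "total_mapped": profile.total_mapped,
            "rpm_denominator": profile.rpm_denominator,
        },
        "processing_accuracy": {
            "window": accuracy.window,
            "per_guide": entries,
            "pooled": {
                "window_count": accuracy.pooled_window_count,
                "authentic_count": accuracy.pooled_authentic_count,
                "fraction": pooled_fraction,
            },
        },
        "phasing": {
            "n_reads": phasing.n_reads,
            "register_counts": list(phasing.register_counts),
            "register_proportion": props,
        },
        "provenance": provenance or {},
    }


_REQUIRED = {
    "design": ["name", "length", "n_guides", "cleavage_position"],
    "profile": ["size_range", "total_mapped", "rpm_denominator"],
    "processing_accuracy": ["window", "per_guide", "pooled"],
    "phasing": ["n_reads", "register_counts", "register_proportion"],
    "provenance": [],
}


def validate_report(doc: dict) -> None:
    """Structural validation against the shipped schema's constraints."""
    for section, keys in _REQUIRED.items():
        if section not in doc:
            raise ValueError(f"report missing section {section!r}")
        for k in keys:
            if k not in doc[section]:
                raise ValueError(f"report section {section!r} missing {k!r}")
    ph = doc["phasing"]
    if len(ph["register_counts"]) != N_REGISTERS:
        raise ValueError("phasing table must have exactly 21 registers")
    if len(ph["register_proportion"]) != N_REGISTERS:
        raise ValueError("phasing table must have exactly 21 proportions")
    if ph["n_reads"] > 0:
        s = sum(ph["register_proportion"])
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"register proportions sum to {s}, not 1")
    for entry in doc["processing_accuracy"]["per_guide"]:
        if entry["window_count"] == 0 and entry["fraction"] is not None:
            raise ValueError("empty window must report a null fraction")


def write_report(doc: dict, path) -> None:
    validate_report(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    validate_report(doc)
    return doc


def write_register_tsv(phasing: PhasingTable, path) -> None:
    props = phasing.register_proportion
    with open(path, "w") as fh:
        fh.write("register\tcount\tproportion\n")
        for i, (c, p) in enumerate(zip(phasing.register_counts, props), 1):
            fh.write(f"{i}\t{c}\t{p:.6f}\n")


def write_accuracy_tsv(report: ProcessingReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("guide\twindow_count\tauthentic_count\tfraction\n")
        for e in report.entries:
            frac = (f"{e.authentic_count / e.window_count:.6f}"
                    if e.window_count else "NA")
            fh.write(f"{e.guide_name}\t{e.window_count}\t"
                     f"{e.authentic_count}\t{frac}\n")
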