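"""Reading adapter-trimmed small-RNA libraries and collapsing identical reads.

Inputs are assumed to be clean reads: quality-trimmed and adapter-removed
upstream.  Collapsing merges identical sequences into one record while
keeping the read count, mirroring the fastx_collapser convention.  No
length filtering happens here — size gating (19–24 nt) belongs to the
profiling and metrics steps so that I/O stays lossless.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")


@dataclasses.dataclass(frozen=True)
class RawRead:
    sequence: str
    id: str | None = None


@dataclasses.dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


def read_library(path, format: str = "fasta") -> Iterator[RawRead]:
    """Yield reads from a FASTA or FASTQ file in file order.

    Quality strings are ignored.  Sequences are uppercased with U→T so RNA-
    and DNA-alphabet libraries collapse together; ambiguity codes are kept
    here and dealt with at collapse time.
    """
    if format not in ("fasta", "fastq"):
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        for rec in SeqIO.parse(str(path), format):
            yield RawRead(sequence=str(rec.seq).upper().replace("U", "T"),
                          id=rec.id)
    except ValueError as exc:  # biopython signals malformed records this way
        raise FormatError(f"malformed {format} in {path}: {exc}") from exc


def collapse(reads: Iterable[RawRead | str],
             drop_ambiguous: bool = True) -> list[CollapsedRead]:
    """Collapse identical reads into unique sequences with counts.

    Reads containing non-ACGT characters (N and friends) are dropped when
    ``drop_ambiguous`` is set — they can never exact-map — and the dropped
    total is logged.  Returns records ordered by descending count then
    sequence, so output is deterministic.
    """
    counts: Counter[str] = Counter()
    dropped = 0
    for r in reads:
        seq = r.sequence if isinstance(r, RawRead) else str(r)
        if drop_ambiguous and (set(seq) - _DNA):
            dropped += 1
            continue
        counts[seq] += 1
    if dropped:
        logger.info("collapse: dropped %d read(s) with ambiguous bases", dropped)
    return [
        CollapsedRead(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path) -> None:
    """fastx_collapser dialect: headers ``>seq{i}_x{count}``."""
    with open(path, "w") as fh:
        for i, rec in enumerate(collapsed, start=1):
            fh.write(f">seq{i}_x{rec.count}\n{rec.sequence}\n")


def write_collapsed_tsv(collapsed: Iterable[CollapsedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for rec in collapsed:
            fh.write(f"{rec.sequence}\t{rec.count}\n")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    """Parse the ``>seq{i}_x{count}`` dialect back into collapsed reads."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"header {rec.id!r} is not in seqN_xCOUNT form"
            ) from exc
        out.append(CollapsedRead(sequence=str(rec.seq).upper(), count=count))
    return out
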