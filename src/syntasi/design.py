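"""Assembly and annotation of minimal syn-tasiRNA precursors.

A minimal precursor is the concatenation of three parts:

* a 22-nt target site (TS) recognised by a 22-nt trigger miRNA,
* an 11-nt spacer,
* one or more 21-nt syn-tasiRNA guide sequences in tandem.

Trigger-guided cleavage falls between TS positions 12 and 13 (1-based),
opposite miRNA positions 10/11, leaving 10 TS nucleotides on the 3'
fragment.  Those 10 nt plus the 11-nt spacer form exactly one 21-nt phase,
so the first guide occupies the second phase interval downstream of the
cut (position label ``3'D2[+]``) and every guide 5' end sits in phasing
register 1.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    AmbiguousSiteError,
    DuplicateGuideError,
    EmptyCassetteError,
    LengthError,
    NotFoundError,
)

#: 0-based offset, within the TS, of the first nucleotide of the 3'
#: cleavage fragment.  Cleavage opposite miRNA positions 10/11 of a 22-nt
#: trigger leaves 10 TS nucleotides downstream, i.e. the cut sits between
#: TS positions 12 and 13 (1-based).  Only this value places the first
#: guide in phasing register 1 at 3'D2[+].
CLEAVAGE_OFFSET = 12

TS_LENGTH = 22
SPACER_LENGTH = 11
GUIDE_LENGTH = 21
PHASE = 21

#: TS of Arabidopsis miR173a and the AtTAS1c 3'D1[+] spacer, the components
#: the minimal-precursor architecture was established with.
ATMIR173A_TS = "GTGATTTTTCTCTACAAGCGAA"
ATTAS1C_SPACER = "TAGACCATTTA"

_DNA = frozenset("ACGT")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`AlphabetError` if anything but A/C/G/T remains.
    """
    norm = seq.strip().upper().replace("U", "T")
    bad = set(norm) - _DNA
    if bad:
        raise AlphabetError(
            f"non-nucleotide characters {sorted(bad)} in sequence {seq!r}"
        )
    return norm


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclasses.dataclass(frozen=True)
class MiRNATrigger:
    """A 22-nt miRNA target site with its inferred cleavage position."""

    name: str
    ts_sequence: str
    cleavage_offset: int = CLEAVAGE_OFFSET

    def __post_init__(self) -> None:
        if len(self.ts_sequence) != TS_LENGTH:
            raise LengthError(
                f"trigger TS must be {TS_LENGTH} nt, got {len(self.ts_sequence)}"
            )
        if set(self.ts_sequence) - _DNA:
            raise AlphabetError(f"TS {self.ts_sequence!r} is not normalized DNA")


@dataclasses.dataclass(frozen=True)
class GuideRNA:
    """A 21-nt syn-tasiRNA guide and its ordinal in the cassette.

    ``position_index`` k = 1 places the guide at TAS1c-style position
    3'D2[+], k = 2 at 3'D3[+], and so on.
    """

    name: str
    sequence: str
    position_index: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) != GUIDE_LENGTH:
            raise LengthError(
                f"guide {self.name!r} must be {GUIDE_LENGTH} nt, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - _DNA:
            raise AlphabetError(f"guide {self.name!r} is not normalized DNA")


@dataclasses.dataclass(frozen=True)
class FeatureAnnotation:
    """Half-open 0-based interval on the precursor; zero-width = point."""

    kind: str  # TS | spacer | guide | cleavage_site | phase_position
    start: int
    end: int
    label: str


@dataclasses.dataclass(frozen=True)
class PrecursorDesign:
    """An assembled minimal precursor with its feature annotations."""

    name: str
    trigger: MiRNATrigger
    spacer: str
    guides: tuple[GuideRNA, ...]
    sequence: str
    features: tuple[FeatureAnnotation, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cleavage_offset(self) -> int:
        return self.trigger.cleavage_offset

    def guide_offset(self, k: int) -> int:
        """0-based 5' offset of guide k (1-based) on the precursor."""
        if not 1 <= k <= len(self.guides):
            raise IndexError(f"guide index {k} out of range 1..{len(self.guides)}")
        return TS_LENGTH + SPACER_LENGTH + GUIDE_LENGTH * (k - 1)

    @property
    def phase_offsets(self) -> tuple[int, ...]:
        """All in-phase 5' offsets 12 + 21m that lie within the sequence."""
        return tuple(
            range(self.cleavage_offset, len(self.sequence), PHASE)
        )


@dataclasses.dataclass(frozen=True)
class OligoPair:
    """Complementary cloning oligos with 4-nt single-stranded overhangs."""

    sense: str
    antisense: str
    overhang_5: str
    overhang_3: str


def validate_trigger(name: str, ts: str) -> MiRNATrigger:
    """Normalize a TS string and build a trigger.

    Rejects any length other than 22 nt: shorter triggers (e.g. a 21-nt
    miRNA) do not license tasiRNA biogenesis, so the architecture requires
    a genuine 22-mer.
    """
    if not ts or not ts.strip():
        raise LengthError("empty target-site sequence")
    norm = normalize_sequence(ts)
    if len(norm) != TS_LENGTH:
        raise LengthError(
            f"target site must be {TS_LENGTH} nt (22-nt miRNA TS), got {len(norm)}"
        )
    return MiRNATrigger(name=name, ts_sequence=norm)


def _annotate(trigger: MiRNATrigger, spacer: str, guides: Sequence[GuideRNA],
              sequence: str) -> tuple[FeatureAnnotation, ...]:
    feats = [
        FeatureAnnotation("TS", 0, TS_LENGTH, trigger.name),
        FeatureAnnotation("cleavage_site", trigger.cleavage_offset,
                          trigger.cleavage_offset, "cleavage"),
        FeatureAnnotation("spacer", TS_LENGTH, TS_LENGTH + SPACER_LENGTH,
                          "spacer"),
    ]
    for k, g in enumerate(guides, start=1):
        start = TS_LENGTH + SPACER_LENGTH + GUIDE_LENGTH * (k - 1)
        feats.append(
            FeatureAnnotation("guide", start, start + GUIDE_LENGTH,
                              f"{g.name}|3'D{k + 1}[+]")
        )
    off = trigger.cleavage_offset
    m = 0
    while off + PHASE * m < len(sequence):
        pos = off + PHASE * m
        feats.append(
            FeatureAnnotation("phase_position", pos, pos, f"phase_{m + 1}")
        )
        m += 1
    return tuple(feats)


def assemble_minimal(trigger: MiRNATrigger, spacer: str,
                     guides: Iterable[GuideRNA | str], *,
                     name: str = "minimal_precursor",
                     allow_duplicate_guides: bool = False) -> PrecursorDesign:
    """Assemble TS + spacer + tandem guides into an annotated precursor.

    Guides may be given as :class:`GuideRNA` or plain strings.  The result
    has length 33 + 21·G for G guides.  Duplicate guide sequences are
    rejected by default because exact-match mapping of the shared mature
    sequence would become ambiguous.
    """
    spacer_norm = normalize_sequence(spacer)
    if len(spacer_norm) != SPACER_LENGTH:
        raise LengthError(
            f"spacer must be {SPACER_LENGTH} nt, got {len(spacer_norm)}"
        )
    guide_objs: list[GuideRNA] = []
    for k, g in enumerate(list(guides), start=1):
        if isinstance(g, GuideRNA):
            guide_objs.append(dataclasses.replace(g, position_index=k))
        else:
            guide_objs.append(
                GuideRNA(name=f"guide{k}", sequence=normalize_sequence(g),
                         position_index=k)
            )
    if not guide_objs:
        raise EmptyCassetteError("a precursor needs at least one guide")
    seqs = [g.sequence for g in guide_objs]
    if not allow_duplicate_guides and len(set(seqs)) != len(seqs):
        raise DuplicateGuideError(
            "duplicate guide sequences in one cassette (pass "
            "allow_duplicate_guides=True to permit)"
        )
    sequence = trigger.ts_sequence + spacer_norm + "".join(seqs)
    features = _annotate(trigger, spacer_norm, guide_objs, sequence)
    return PrecursorDesign(
        name=name, trigger=trigger, spacer=spacer_norm,
        guides=tuple(guide_objs), sequence=sequence, features=features,
    )


def swap_trigger_site(full_precursor: str, old_ts: str,
                      new_trigger: MiRNATrigger) -> str:
    """Replace the single occurrence of ``old_ts`` with the new trigger TS.

    This is how a TAS1c-style full-length precursor is retargeted to a
    different endogenous trigger miRNA (e.g. AtmiR173a TS swapped for
    NbmiR482a or NbmiR6019a/b TSs): everything but the 22-nt site is kept.
    """
    precursor = normalize_sequence(full_precursor)
    old = normalize_sequence(old_ts)
    n = precursor.count(old)
    if n == 0:
        raise NotFoundError(f"target site {old!r} not found in precursor")
    if n > 1:
        raise AmbiguousSiteError(
            f"target site {old!r} occurs {n} times; replacement is ambiguous"
        )
    return precursor.replace(old, new_trigger.ts_sequence)


def guide_layout(design: PrecursorDesign) -> list[tuple[str, int, str]]:
    """Per-guide (name, 0-based 5' offset, TAS1c position label).

    Guide k starts at 33 + 21(k−1) and carries label ``3'D{k+1}[+]``: the
    first 21-nt phase after cleavage (10 TS nt + 11-nt spacer) is 3'D1[+],
    so the guide cassette begins at 3'D2[+].
    """
    return [
        (g.name, design.guide_offset(k), f"3'D{k + 1}[+]")
        for k, g in enumerate(design.guides, start=1)
    ]


def cloning_oligos(design: PrecursorDesign, overhang_5: str,
                   overhang_3: str) -> OligoPair:
    """Sense/antisense oligo pair reconstituting the insert when annealed.

    Each overhang is a 4-nt 5' extension (sense strand gets ``overhang_5``,
    antisense gets ``overhang_3``); the cores are exact reverse complements,
    leaving 4-nt single-stranded ends for directional ligation.  Overhang
    sequences are vector-specific and must be supplied by the caller.
    """
    for tag, oh in (("5'", overhang_5), ("3'", overhang_3)):
        if len(oh) != 4:
            raise LengthError(f"{tag} overhang must be 4 nt, got {len(oh)}")
    return OligoPair(
        sense=normalize_sequence(overhang_5) + design.sequence,
        antisense=normalize_sequence(overhang_3)
        + reverse_complement(design.sequence),
        overhang_5=normalize_sequence(overhang_5),
        overhang_3=normalize_sequence(overhang_3),
    )


# ---------------------------------------------------------------------------
# writers

def write_fasta(design: PrecursorDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{design.name}\n{design.sequence}\n")


def write_bed(design: PrecursorDesign, path) -> None:
    """Interval features as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for f in design.features:
            fh.write(
                f"{design.name}\t{f.start}\t{f.end}\t{f.kind}:{f.label}\n"
            )


def write_feature_table(design: PrecursorDesign, path) -> None:
    """GFF3-like TSV with 1-based inclusive coordinates for human readers."""
    with open(path, "w") as fh:
        fh.write("seqid\tkind\tstart\tend\tlabel\n")
        for f in design.features:
            # 1-based inclusive; a zero-width point reports start == end
            start1 = f.start + 1 if f.end > f.start else f.start
            fh.write(f"{design.name}\t{f.kind}\t{start1}\t{f.end}\t{f.label}\n")


def write_oligos(design: PrecursorDesign, pair: OligoPair, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\tlength\n")
        fh.write(f"{design.name}_F\t{pair.sense}\t{len(pair.sense)}\n")
        fh.write(f"{design.name}_R\t{pair.antisense}\t{len(pair.antisense)}\n")
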