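"""Synthetic small-RNA libraries with known ground truth.

The simulator emulates the read population that accumulates downstream of
a trigger-cleaved minimal precursor, so every pipeline statistic can be
tested against an analytic expectation without sequencing data.  Each read
is one of three disjoint populations:

* **phased** — a perfect 21-mer starting exactly at a guide 5' end
  (probability ``phasing_fidelity`` among precursor-derived reads; the
  guide is drawn by ``guide_weights``);
* **jittered** — a mis-processed precursor read whose 5' end is a guide 5'
  end plus a uniform non-zero jitter in ±``jitter_max`` nt and whose
  length is drawn from ``length_distribution`` over 19–24 nt (jitter and
  length are drawn jointly, conditioned on the read fitting inside the
  precursor);
* **background** — a uniform random sequence (probability
  ``background_fraction``), unmappable with overwhelming probability for
  read lengths ≥ 19.

A single RNG stream (numpy default_rng) is consumed in a fixed per-read
order — population coin(s), then origin, then jitter/length or random
bases — so a given seed reproduces the library byte for byte.
``expected_metrics`` enumerates the same finite outcome space (guides ×
jitter offsets × lengths) to give exact expected register proportions and
processing accuracy, with no sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .design import GUIDE_LENGTH, PrecursorDesign
from .errors import ConfigError
from .phasing import N_REGISTERS, register_of
from .sread_io import RawRead

#: Unphased/background read-length distribution over 19-24 nt: a 21-nt
#: dominated profile with shoulders, the shape typical of plant AGO-bound
#: sRNA libraries.
DEFAULT_LENGTH_DISTRIBUTION = {
    19: 0.08, 20: 0.12, 21: 0.35, 22: 0.20, 23: 0.15, 24: 0.10,
}

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    design: PrecursorDesign
    n_reads: int = 20000
    phasing_fidelity: float = 0.75
    guide_weights: tuple[float, ...] | None = None  # per guide, uniform if None
    jitter_max: int = 4
    length_distribution: dict[int, float] | None = None
    background_fraction: float = 0.2
    seed: int = 1

    def resolved_weights(self) -> np.ndarray:
        g = len(self.design.guides)
        w = (np.full(g, 1.0 / g) if self.guide_weights is None
             else np.asarray(self.guide_weights, dtype=float))
        if len(w) != g:
            raise ConfigError(
                f"guide_weights has {len(w)} entries for {g} guides"
            )
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigError("guide_weights must be non-negative, sum > 0")
        return w / w.sum()

    def resolved_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        dist = self.length_distribution or DEFAULT_LENGTH_DISTRIBUTION
        lengths = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[int(l)] for l in lengths], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("length_distribution must be a probability vector")
        return lengths, probs

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if not 0.0 <= self.phasing_fidelity <= 1.0:
            raise ConfigError("phasing_fidelity must be in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction must be in [0, 1]")
        if self.jitter_max < 1:
            raise ConfigError("jitter_max must be >= 1")
        self.resolved_weights()
        self.resolved_lengths()


@dataclasses.dataclass(frozen=True)
class ReadTruth:
    read_id: str
    label: str  # phased | jittered | background
    origin_offset: int  # 0-based 5' offset on the precursor; -1 for background
    length: int


@dataclasses.dataclass(frozen=True)
class SimulatedLibrary:
    reads: tuple[RawRead, ...]
    truth: tuple[ReadTruth, ...]
    params: SimulationParams


def _jitter_support(design: PrecursorDesign, guide_offset: int,
                    jitter_max: int, lengths: np.ndarray,
                    length_probs: np.ndarray):
    """Valid (delta, length) combos for one guide with renormalised probs.

    The unconditioned joint is uniform over non-zero deltas times the
    length distribution; combos whose read would overrun either precursor
    end are removed and the rest renormalised.
    """
    n = len(design.sequence)
    combos, probs = [], []
    for delta in range(-jitter_max, jitter_max + 1):
        if delta == 0:
            continue
        start = guide_offset + delta
        if start < 0:
            continue
        for length, q in zip(lengths, length_probs):
            if start + int(length) <= n and q > 0:
                combos.append((delta, int(length)))
                probs.append(q / (2 * jitter_max))
    if not combos:
        raise ConfigError(
            f"no valid jittered read fits the precursor at offset "
            f"{guide_offset}"
        )
    p = np.array(probs)
    return combos, p / p.sum()


def _draw(rng: np.random.Generator, cum: np.ndarray) -> int:
    return int(np.searchsorted(cum, rng.random(), side="right"))


def simulate(params: SimulationParams) -> SimulatedLibrary:
    """Generate a library; reproducible byte-for-byte given the seed."""
    params.validate()
    design = params.design
    rng = np.random.default_rng(params.seed)
    w = params.resolved_weights()
    lengths, length_probs = params.resolved_lengths()
    cum_w = np.cumsum(w)
    cum_len = np.cumsum(length_probs)
    supports = [
        _jitter_support(design, design.guide_offset(k), params.jitter_max,
                        lengths, length_probs)
        for k in range(1, len(design.guides) + 1)
    ]
    cum_support = [np.cumsum(p) for _, p in supports]

    reads: list[RawRead] = []
    truth: list[ReadTruth] = []
    for i in range(params.n_reads):
        rid = f"read{i}"
        if rng.random() < params.background_fraction:
            length = int(lengths[_draw(rng, cum_len)])
            seq = "".join(_BASES[rng.integers(0, 4, size=length)])
            reads.append(RawRead(sequence=seq, id=rid))
            truth.append(ReadTruth(rid, "background", -1, length))
        elif rng.random() < params.phasing_fidelity:
            g = _draw(rng, cum_w)
            off = design.guide_offset(g + 1)
            seq = design.sequence[off:off + GUIDE_LENGTH]
            reads.append(RawRead(sequence=seq, id=rid))
            truth.append(ReadTruth(rid, "phased", off, GUIDE_LENGTH))
        else:
            g = _draw(rng, cum_w)
            combos, _ = supports[g]
            delta, length = combos[_draw(rng, cum_support[g])]
            off = design.guide_offset(g + 1) + delta
            seq = design.sequence[off:off + length]
            reads.append(RawRead(sequence=seq, id=rid))
            truth.append(ReadTruth(rid, "jittered", off, length))
    return SimulatedLibrary(reads=tuple(reads), truth=tuple(truth),
                            params=params)


@dataclasses.dataclass(frozen=True)
class ExpectedMetrics:
    """Analytic expectations from exhaustive outcome-space enumeration."""

    register_proportion: tuple[float, ...]  # expected phasing-table entries
    accuracy_fraction: float | None  # expected pooled processing accuracy
    mapped_fraction: float  # expected fraction of reads mapping exactly

    @property
    def register1(self) -> float:
        return self.register_proportion[0]


def expected_metrics(params: SimulationParams,
                     window: int = 4,
                     size_range: tuple[int, int] = (19, 24)) -> ExpectedMetrics:
    """Exact expectations for the pipeline's statistics under the model.

    Enumerates guides × valid (jitter, length) combos — no sampling.  The
    phasing-table expectation is conditioned the same way the pipeline
    conditions: 21-nt reads with 5' ends at or downstream of the cleavage
    site.  Background reads are treated as unmappable (the chance a random
    19-mer hits a ≤ few-hundred-nt precursor is ~10⁻⁹).
    """
    params.validate()
    design = params.design
    p = params.phasing_fidelity
    b = params.background_fraction
    w = params.resolved_weights()
    lengths, length_probs = params.resolved_lengths()
    cut = design.cleavage_offset
    guide_offsets = [design.guide_offset(k)
                     for k in range(1, len(design.guides) + 1)]

    reg_mass = np.zeros(N_REGISTERS)
    window_mass = 0.0
    authentic_mass = 0.0
    lo, hi = size_range

    # phased component: 21-mers exactly at guide 5' ends
    for g, off in enumerate(guide_offsets):
        mass = (1 - b) * p * w[g]
        reg_mass[register_of(off, cut) - 1] += mass
        if lo <= GUIDE_LENGTH <= hi:
            window_mass += mass
            authentic_mass += mass

    # jittered component
    for g, off in enumerate(guide_offsets):
        combos, probs = _jitter_support(design, off, params.jitter_max,
                                        lengths, length_probs)
        for (delta, length), q in zip(combos, probs):
            mass = (1 - b) * (1 - p) * w[g] * q
            start = off + delta
            if length == GUIDE_LENGTH and start >= cut:
                reg_mass[register_of(start, cut) - 1] += mass
            if lo <= length <= hi and any(
                abs(start - go) <= window for go in guide_offsets
            ):
                window_mass += mass
                # authentic only if jitter carries the read onto another
                # guide's 5' end (needs jitter_max >= 21; impossible at the
                # default ±4)
                if length == GUIDE_LENGTH and start in guide_offsets:
                    authentic_mass += mass

    total_reg = reg_mass.sum()
    register = (tuple(reg_mass / total_reg) if total_reg > 0
                else tuple([0.0] * N_REGISTERS))
    accuracy = (authentic_mass / window_mass) if window_mass > 0 else None
    return ExpectedMetrics(register_proportion=register,
                           accuracy_fraction=accuracy,
                           mapped_fraction=1 - b)


# ---------------------------------------------------------------------------
# writers

def write_library_fasta(lib: SimulatedLibrary, path) -> None:
    with open(path, "w") as fh:
        for r in lib.reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_library_fastq(lib: SimulatedLibrary, path) -> None:
    with open(path, "w") as fh:
        for r in lib.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(lib: SimulatedLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\torigin_offset\tlength\n")
        for t in lib.truth:
            fh.write(f"{t.read_id}\t{t.label}\t{t.origin_offset}\t{t.length}\n")
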