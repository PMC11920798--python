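# Methods

## The minimal-precursor model

A minimal syn-tasiRNA precursor is the string concatenation

```
precursor = TS (22 nt) + spacer (11 nt) + guide_1 (21 nt) + … + guide_G (21 nt)
```

so `len = 33 + 21·G`. The geometry that makes this work is the cleavage
coordinate: a 22-nt trigger miRNA directs cleavage opposite its positions
10/11, which places the cut between TS positions 12 and 13 (1-based). The
package fixes this as `CLEAVAGE_OFFSET = 12` (0-based index of the first
nucleotide of the 3′ fragment). Ten TS nucleotides then remain upstream of
the spacer, and 10 + 11 = 21 — exactly one phase — so guide *k* starts at
offset `33 + 21(k−1) = 12 + 21k` and is labelled `3′D{k+1}[+]` in TAS1c
position nomenclature. Every guide 5′ end therefore satisfies
`(offset − 12) mod 21 = 0`: phasing register 1. The cleavage offset is a
named constant rather than a free parameter of the public API because any
other value breaks this arithmetic; it can still be overridden by
constructing `MiRNATrigger` directly for exploratory work.

Coordinates are 0-based half-open internally and 1-based inclusive in all
human-readable output. Sequences are DNA internally; RNA input (U) is
silently normalised to T and case is folded. Triggers that are not exactly
22 nt are rejected (`LengthError`) — a shorter miRNA does not license
tasiRNA biogenesis, so treating it as a valid trigger would be a design
error, not a warning. Duplicate guides in one cassette are rejected by
default because their shared mature sequence would exact-map ambiguously
(`allow_duplicate_guides=True` overrides). Cloning-oligo overhangs are
vector-specific 4-mers and must be supplied by the caller; the package
ships no default overhangs.

## Read handling and mapping

Input libraries are assumed adapter-trimmed and quality-filtered ("clean
reads"). Collapsing merges identical sequences keeping counts; reads with
ambiguity codes are dropped by default (they can never exact-map) and the
drop count is logged. No length filter is applied at I/O time — size
gating belongs to the metrics, keeping I/O lossless.

Mapping is exact substring search on the precursor forward strand: no
mismatches, no gaps, no reverse strand. With a mapping universe of one
short precursor this is both the correct model and the fastest
implementation; genome-scale aligners and SAM/BAM output are deliberately
out of scope. A read occurring at several positions yields one hit per
occurrence, each carrying the read's full count and a `multi` flag plus a
logged warning; with duplicate guides forbidden this arises only on
adversarial input. All mapping output is verified in the test suite
against a naive all-substrings scan on randomized instances.

The positional profile counts 5′ ends per (position, read length) cell,
restricted to 19–24 nt by default. RPM is `count / total_mapped × 10⁶`
where `total_mapped` is the per-precursor mapped total within the size
range; a `library_size` argument switches the denominator to the whole
library for cross-sample comparisons. An empty profile raises rather than
reporting RPM of 0/0.

## Phasing and processing statistics

**Processing accuracy** (per guide, window ±4 nt inclusive, sizes
19–24 nt): the numerator counts reads of length exactly 21 whose 5′ end
equals the guide 5′ end — under exact mapping these are precisely the
mature guide sequence; a flag relaxes the numerator to any length with a
matching 5′ end. The denominator is the reads inside the window only, not
all precursor-mapped reads (a whole-precursor denominator would conflate
accuracy with expression at other positions; it remains available through
the profile for sensitivity analysis). Zero denominators raise
`NoWindowReadsError` and serialise as `null`, never as 0 — an empty window
carries no evidence of perfect or absent accuracy. A pooled (all-guide)
summary is reported alongside the per-guide entries, both labelled.

**Phasing table**: 21-nt forward-strand reads whose 5′ end is at or
downstream of the cleavage site are binned by register
`((d−1) mod 21) + 1` with `d = offset − 12 + 1`; reads spanning the cut
are excluded. The table has exactly 21 entries and count-weighted
proportions sum to 1. Both statistics weight unique reads by their
collapsed counts.

No inferential statistics (phasing p-values, Fisher-style phase scores)
are computed: the statistics here are descriptive proportions.

## The synthetic library generator

The simulator emulates the read population downstream of a trigger-cleaved
minimal precursor with three disjoint, ground-truth-labelled populations:

| parameter | default | meaning |
|---|---|---|
| `n_reads` | 20 000 | library size, a typical per-precursor mapped depth |
| `phasing_fidelity` p | 0.75 | probability a precursor-derived read is a perfect 21-mer at a guide 5′ end |
| `guide_weights` | uniform over guides | relative phased/jittered mass per guide position |
| `jitter_max` | 4 | mis-processed 5′ ends drawn uniformly from ±4 nt, excluding 0 |
| `length_distribution` | 19:0.08, 20:0.12, 21:0.35, 22:0.20, 23:0.15, 24:0.10 | unphased/background read lengths; a 21-nt-dominated profile with shoulders, the shape typical of plant sRNA libraries |
| `background_fraction` b | 0.2 | reads that are uniform random sequence |

Jitter excludes offset 0 so the phased and jittered populations are
disjoint and truth labels are unambiguous. Jitter and length are drawn
jointly, conditioned on the read fitting inside the precursor (the
unconditioned joint is uniform-over-deltas × length distribution,
renormalised over the valid set); `expected_metrics` enumerates exactly
the same support, so expectation and simulation share one definition.
Background reads are uniform random strings — the simplest model that is
unmappable with probability ≈ 1 − L/4^ℓ ≥ 1 − 10⁻⁹ for ℓ ≥ 19. Phased
mass defaults to the guide positions only; the first phase interval
(spacer + TS remnant, offset 12) receives no phased reads because no
mature guide resides there, though reads jittered into it are handled like
any other.

A single numpy `default_rng(seed)` stream is consumed in a fixed per-read
order (population coin(s) → origin → jitter/length or random bases), so a
seed reproduces a library byte for byte within this implementation;
cross-implementation portability is claimed only at the level of summary
statistics.

`expected_metrics` computes, by exhaustive enumeration of
guides × valid (jitter, length) pairs and with no sampling: the expected
phasing-table proportions (conditioned exactly as the pipeline conditions,
on 21-nt reads downstream of the cut) and the expected pooled processing
accuracy. Two consequences worth noting: with `jitter_max ≤ 4 < 21` a
jittered 21-mer can never land in register 1, so the expected register-1
proportion is `p / (p + (1−p)·q21)` with `q21` the 21-nt mass of the
jittered component — larger than p itself; and because every jittered read
stays inside the ±4 window, the expected pooled accuracy equals p exactly.

**What passing tests show — and don't.** The simulator reproduces the
*positional* statistics the pipeline measures (phase-locked 5′ ends,
bounded jitter, a size distribution, unmappable mass). It does not model
sequencing error, quality scores, ligation bias, viral siRNA or degradome
background composition, or expression differences between positions.
Agreement between measured and expected metrics therefore validates the
pipeline's arithmetic and conditioning, not any claim about real
libraries.

## Numerical and testing choices

* Proportion sums are checked to 1e-9; accuracy and register values are
  exact rational counts, so most assertions are exact.
* Parameter-recovery tests compare the measured register-1 proportion to
  the enumerated expectation within 3 binomial standard errors
  (`√(e(1−e)/n)` with n the qualifying-read count), requiring ≥ 9/10 seeds
  to pass per fidelity — a deliberate allowance for the expected ~1%
  two-sided tail at 3 SE.
* Problem sizes: simulations use 20 000-read libraries (4 fidelities × 10
  seeds in the acceptance suite); oracle-equivalence checks run 1 000
  randomized instances with precursors ≤ 160 nt. These sizes give
  sub-percent Monte-Carlo error on every proportion while keeping the full
  suite under a minute of simulation time.
* Degenerate inputs fail loudly and specifically: empty cassettes, missing
  or ambiguous TS during swapping, empty profiles/windows/tables each have
  their own exception, and the CLI maps them to distinct exit codes
  (2 config, 3 I/O, 4 empty result).

## Known limitations

* Only forward-strand, mismatch-free mapping: a single sequencing error
  makes a read invisible, so measured "accuracy" on real data conflates
  processing fidelity with sequencing fidelity (exactly as in the
  fastx-collapser–based protocols this mirrors).
* The RPM denominator question (per-precursor vs per-library) is resolved
  per-precursor by default with the alternative exposed; cross-study RPM
  comparisons must pick one convention.
* No guide design against targets: guide sequences are taken as given.
* No thermodynamics, off-target prediction, or vector biology.
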