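"""Processing-accuracy window statistic and 21-register phasing table."""

import numpy as np
import pytest

import syntasi as st
from syntasi.phasing import (
    build_report,
    phasing_table,
    processing_accuracy,
    processing_report,
    read_report,
    register_of,
    write_report,
)


def hit(start, length=21, count=1, seq=None):
    return st.MappingHit(sequence=seq or "N/A", count=count, start=start,
                         length=length)


def brute_force_accuracy(hits, g5, window=4, size_range=(19, 24)):
    """Oracle: explicit membership test at every offset in −w..+w."""
    window_offsets = {g5 + d for d in range(-window, window + 1)}
    win = sum(h.count for h in hits
              if size_range[0] <= h.length <= size_range[1]
              and h.start in window_offsets)
    auth = sum(h.count for h in hits
               if h.length == 21 and h.start == g5)
    return auth, win


def brute_force_registers(hits, cut=12):
    counts = [0] * 21
    for h in hits:
        if h.length == 21 and h.start >= cut:
            d = h.start - cut + 1
            counts[(d - 1) % 21] += h.count
    return counts


class TestProcessingAccuracy:
    def test_pure_authentic_reads(self, design1):
        hits = [hit(33, 21, 100)]
        e = processing_accuracy(hits, design1, 1)
        assert e.fraction == 1.0

    def test_half_shifted_half_authentic(self, design1):
        hits = [hit(33, 21, 50), hit(35, 21, 50)]
        e = processing_accuracy(hits, design1, 1)
        assert (e.authentic_count, e.window_count) == (50, 100)
        assert e.fraction == 0.5
        assert brute_force_accuracy(hits, 33) == (50, 100)

    @pytest.mark.parametrize("delta,inside", [(-5, False), (-4, True),
                                              (4, True), (5, False)])
    def test_window_inclusive_at_plus_minus_four(self, design1, delta, inside):
        hits = [hit(33 + delta, 21, 10), hit(33, 21, 1)]
        e = processing_accuracy(hits, design1, 1)
        assert e.window_count == (11 if inside else 1)

    def test_empty_window_raises_not_zero(self, design1):
        with pytest.raises(st.NoWindowReadsError):
            processing_accuracy([hit(33 + 5, 21, 10)], design1, 1)

    def test_shifted_21mers_count_as_other(self, design1):
        # misprocessed 21-nt reads inside the window dilute the fraction
        hits = [hit(33, 21, 10), hit(32, 21, 10), hit(34, 21, 20)]
        e = processing_accuracy(hits, design1, 1)
        assert e.fraction == pytest.approx(0.25)

    def test_length_filter_excludes_18_and_25(self, design1):
        hits = [hit(33, 21, 1), hit(33, 18, 99), hit(33, 25, 99)]
        e = processing_accuracy(hits, design1, 1)
        assert e.window_count == 1

    def test_authentic_requires_length_21_by_default(self, design1):
        hits = [hit(33, 20, 10), hit(33, 21, 10)]
        e = processing_accuracy(hits, design1, 1)
        assert e.fraction == 0.5
        e2 = processing_accuracy(hits, design1, 1, authentic_any_length=True)
        assert e2.fraction == 1.0

    def test_monotonicity(self, design1):
        base = [hit(33, 21, 10), hit(35, 22, 10)]
        f0 = processing_accuracy(base, design1, 1).fraction
        more_auth = processing_accuracy(base + [hit(33, 21, 5)],
                                        design1, 1).fraction
        more_other = processing_accuracy(base + [hit(31, 20, 5)],
                                         design1, 1).fraction
        assert more_auth >= f0 >= more_other

    def test_brute_force_agreement_randomized(self, design4):
        rng = np.random.default_rng(5)
        for _ in range(200):
            hits = [hit(int(rng.integers(0, 96)), int(rng.integers(18, 26)),
                        int(rng.integers(1, 20))) for _ in range(30)]
            for k in range(1, 5):
                g5 = design4.guide_offset(k)
                auth, win = brute_force_accuracy(hits, g5)
                try:
                    e = processing_accuracy(hits, design4, k)
                    assert (e.authentic_count, e.window_count) == (auth, win)
                except st.NoWindowReadsError:
                    assert win == 0


class TestPhasingTable:
    def test_first_position_after_cut_is_register_1(self, design1):
        t = phasing_table([hit(12)], design1)
        assert t.register_proportion[0] == 1.0

    def test_guide_5prime_ends_all_register_1(self, design4):
        t = phasing_table([hit(off) for off in (33, 54, 75, 96)], design4)
        assert t.register_proportion[0] == 1.0
        # via the 1-based phase distance: d = 22, 43, 64, 85 all reduce to 1
        for off in (33, 54, 75, 96):
            d = off - 12 + 1
            assert (d - 1) % 21 + 1 == 1

    def test_21_consecutive_offsets_hit_every_register_once(self, design4):
        t = phasing_table([hit(off) for off in range(12, 33)], design4)
        assert t.register_proportion == tuple([1 / 21] * 21)

    def test_register_bijection_any_window(self, design4):
        # any 21 consecutive downstream offsets cover registers 1..21 once
        for start in range(12, 70):
            regs = sorted(register_of(o, 12) for o in range(start, start + 21))
            assert regs == list(range(1, 22))

    def test_upstream_and_non21_reads_excluded(self, design1):
        t = phasing_table([hit(11), hit(13, 20), hit(12)], design1)
        assert t.n_reads == 1
        assert t.register_proportion[0] == 1.0

    def test_empty_table_raises(self, design1):
        with pytest.raises(st.EmptyTableError):
            phasing_table([hit(5), hit(20, 22)], design1)

    def test_brute_force_agreement_randomized(self, design4):
        rng = np.random.default_rng(6)
        for _ in range(200):
            hits = [hit(int(rng.integers(0, 96)), int(rng.integers(19, 25)),
                        int(rng.integers(1, 30))) for _ in range(25)]
            oracle = brute_force_registers(hits)
            try:
                t = phasing_table(hits, design4)
                assert list(t.register_counts) == oracle
                assert sum(t.register_proportion) == pytest.approx(1.0)
            except st.EmptyTableError:
                assert sum(oracle) == 0


class TestReport:
    def _full_report(self, design):
        hits = [hit(33, 21, 90, seq=design.guides[0].sequence),
                hit(31, 22, 10)]
        profile = st.build_profile(hits, len(design.sequence))
        acc = processing_report(hits, design)
        table = phasing_table(hits, design)
        return build_report(design, profile, acc, table,
                            provenance={"seed": 1})

    def test_schema_conformance_and_round_trip(self, design1, tmp_path):
        doc = self._full_report(design1)
        st.validate_report(doc)
        p = tmp_path / "report.json"
        write_report(doc, p)
        assert read_report(p) == doc

    def test_proportions_sum_to_one(self, design1):
        doc = self._full_report(design1)
        assert sum(doc["phasing"]["register_proportion"]) == \
            pytest.approx(1.0, abs=1e-9)

    def test_empty_window_serialized_as_null(self, design4):
        hits = [hit(33, 21, 10, seq=design4.guides[0].sequence)]
        profile = st.build_profile(hits, len(design4.sequence))
        acc = processing_report(hits, design4)
        table = phasing_table(hits, design4)
        doc = build_report(design4, profile, acc, table)
        fractions = [e["fraction"]
                     for e in doc["processing_accuracy"]["per_guide"]]
        assert fractions[0] == 1.0
        assert fractions[1:] == [None, None, None]
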