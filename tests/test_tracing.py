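"""Read tracing: trimming, size selection, exact mapping, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import snstrace as st
from snstrace.tracing import SRnaRead

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def brute_force_hits(read_seq: str, reference: str):
    """Independent all-positions scan oracle for exact mapping."""
    hits = []
    L = len(read_seq)
    rc = st.revcomp(read_seq)
    for i in range(len(reference) - L + 1):
        window = reference[i : i + L]
        if window == read_seq:
            hits.append((i + 1, "+"))
        if window == rc:
            hits.append((i + 1, "-"))
    return sorted(hits)


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        read = SRnaRead("r", "ACGTACGTACGTACGTACGTA" + ADAPTER)
        assert st.trim_adapter(read, ADAPTER).sequence == "ACGTACGTACGTACGTACGTA"

    def test_no_adapter_untouched(self):
        read = SRnaRead("r", "ACGTACGTACGTACGTACGTA")
        assert st.trim_adapter(read, ADAPTER).sequence == read.sequence

    def test_partial_adapter_prefix_removed(self):
        insert = "CCCCCCCCCCCCCCCCCCCCC"
        read = SRnaRead("r", insert + ADAPTER[:5])
        assert st.trim_adapter(read, ADAPTER, min_overlap=5).sequence == insert
        # below the overlap floor the fragment is not trusted as adapter
        assert st.trim_adapter(read, ADAPTER, min_overlap=6).sequence == insert + ADAPTER[:5]

    def test_leftmost_match_wins(self):
        read = SRnaRead("r", "AAAA" + ADAPTER + "TTTT" + ADAPTER)
        assert st.trim_adapter(read, ADAPTER).sequence == "AAAA"


class TestSizeSelect:
    def test_bounds_21_to_24(self):
        reads = [SRnaRead(str(L), "A" * L) for L in (20, 21, 24, 25)]
        kept, dropped = st.size_select(reads)
        assert sorted(r.length for r in kept) == [21, 24]
        assert dropped == {20: 1, 25: 1}

    def test_empty_input(self):
        kept, dropped = st.size_select([])
        assert kept == [] and not dropped

    def test_uniform_length_all_kept(self):
        reads = [SRnaRead(str(i), "ACGT" * 5 + "AC") for i in range(10)]
        kept, _ = st.size_select(reads)
        assert len(kept) == 10

    def test_u_normalized_and_non_acgt_dropped(self):
        kept, dropped = st.size_select(
            [SRnaRead("u", "U" * 22), SRnaRead("n", "N" * 22)]
        )
        assert [r.sequence for r in kept] == ["T" * 22]
        assert dropped["non_acgt"] == 1

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            st.size_select([], min_len=24, max_len=21)


class TestMapPerfect:
    def test_constructed_plus_hit(self, locus_fixture):
        locus, _ = locus_fixture
        read = SRnaRead("r", locus[10:31])
        hits = st.map_perfect(read, locus)
        assert (11, "+") in {(h.start, h.strand) for h in hits}

    def test_constructed_minus_hit(self, locus_fixture):
        locus, _ = locus_fixture
        read = SRnaRead("r", st.revcomp(locus[40:61]))
        hits = st.map_perfect(read, locus)
        assert (41, "-") in {(h.start, h.strand) for h in hits}

    def test_repeat_reference_yields_two_hits(self):
        unit = "ACGTGCATTGCA"
        ref = unit + "TTTTTTTTTTTT" + unit
        hits = st.map_perfect(SRnaRead("r", unit), ref)
        assert sorted((h.start, h.strand) for h in hits) == brute_force_hits(unit, ref)

    @settings(derandomize=True, max_examples=40)
    @given(data=hs.data())
    def test_agrees_with_brute_force_oracle(self, data):
        rng_seq = data.draw(hs.text(alphabet="ACGT", min_size=30, max_size=300))
        L = data.draw(hs.integers(5, 24))
        start = data.draw(hs.integers(0, max(0, len(rng_seq) - L)))
        read_seq = rng_seq[start : start + L]
        if len(read_seq) < L:
            return
        flip = data.draw(hs.booleans())
        if flip:
            read_seq = st.revcomp(read_seq)
        hits = st.map_perfect(SRnaRead("r", read_seq), rng_seq)
        assert sorted((h.start, h.strand) for h in hits) == brute_force_hits(read_seq, rng_seq)


class TestClassify:
    def test_reference_length_mismatch(self):
        with pytest.raises(ValueError):
            st.classify_read(SRnaRead("r", "ACGT"), "A" * 50, "A" * 49)

    def test_variant_copy_is_primary(self, locus_fixture, trigger10, variant_locus):
        locus, windows = locus_fixture
        w0, _ = windows["promoter"]
        # 21-mer from the variant covering SNSs (spacing 10 guarantees >=2)
        read = SRnaRead("r", variant_locus[w0 - 1 : w0 + 20])
        assert st.classify_read(read, locus, variant_locus).origin == "primary"

    def test_wt_copy_is_secondary(self, locus_fixture, trigger10, variant_locus):
        locus, windows = locus_fixture
        w0, _ = windows["promoter"]
        read = SRnaRead("r", locus[w0 - 1 : w0 + 20])
        assert st.classify_read(read, locus, variant_locus).origin == "secondary"

    def test_sns_free_window_is_ambiguous(self):
        """Under spacing 40 a 21-nt read can sit between two SNSs."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        frag = st.TargetFragment(id="f", sequence=seq)
        trig = st.design_marked_trigger(frag, st.SNSDesign(spacing=40, offset=20))
        var = trig.variant_sequence
        # SNSs at 20, 60, 100; positions 21..59 (0-based 20..58) are SNS-free
        read = SRnaRead("r", seq[21:42])
        cr = st.classify_read(read, seq, var)
        assert cr.origin == "ambiguous"

    def test_unmapped(self, locus_fixture, variant_locus):
        locus, _ = locus_fixture
        read = SRnaRead("r", "A" * 21)
        assert st.classify_read(read, locus, variant_locus).origin == "unmapped"


class TestReport:
    def _classified(self, reads, locus, variant_locus):
        return [st.classify_read(r, locus, variant_locus) for r in reads]

    def test_all_secondary_inside_window_zero_transitivity(
        self, locus_fixture, variant_locus
    ):
        locus, windows = locus_fixture
        w0, w1 = windows["promoter"]
        reads = [SRnaRead(f"r{i}", locus[w0 - 1 + i : w0 + 20 + i]) for i in range(5)]
        report = st.build_report(
            self._classified(reads, locus, variant_locus),
            {"wt": len(locus)},
            trigger_window=(w0, w1),
        )
        assert report.transitivity == 0.0

    def test_half_coverage_outside_gives_half(self, locus_fixture, variant_locus):
        locus, windows = locus_fixture
        w0, w1 = windows["promoter"]
        inside = SRnaRead("in", locus[w0 - 1 : w0 + 20])
        outside = SRnaRead("out", locus[w1 + 50 : w1 + 71])
        report = st.build_report(
            self._classified([inside, outside], locus, variant_locus),
            {"wt": len(locus)},
            trigger_window=(w0, w1),
        )
        assert report.transitivity == pytest.approx(0.5)

    def test_empty_input(self, locus_fixture):
        locus, windows = locus_fixture
        report = st.build_report([], {"wt": len(locus)}, windows["promoter"])
        assert report.transitivity == 0.0
        assert report.counts.empty

    def test_window_outside_reference_rejected(self, locus_fixture):
        locus, _ = locus_fixture
        with pytest.raises(ValueError):
            st.build_report([], {"wt": len(locus)}, (0, 10))
        with pytest.raises(ValueError):
            st.build_report([], {"wt": len(locus)}, (1, len(locus) + 1))

    def test_partition_counts_conserved(self, locus_fixture, trigger10, variant_locus):
        """Every size-selected read lands in exactly one class; totals conserved."""
        locus, windows = locus_fixture
        w0, w1 = windows["promoter"]
        cfg = st.SimConfig(seed=11, n_reads=400)
        prim = st.simulate_primary_reads(trigger10, variant_locus, cfg)
        sec = st.simulate_secondary_reads(
            locus, (w0, w1), st.SimConfig(seed=12, n_reads=400, transitivity_fraction=0.3)
        )
        junk = [SRnaRead("junk", "ACGT" * 8)]  # 32 nt, dropped by size selection
        report, classified, dropped = st.trace_library(
            prim + sec + junk, locus, variant_locus, trigger_window=(w0, w1)
        )
        assert report.n_reads == 800
        assert dropped == {32: 1}
        assert report.counts["count"].sum() == pytest.approx(800)
        totals = report.class_totals()
        assert sum(totals.values()) == pytest.approx(800)

    def test_strand_symmetry(self, locus_fixture, trigger10, variant_locus):
        """Reverse-complementing the reads swaps +/- counts, preserving totals."""
        locus, windows = locus_fixture
        cfg = st.SimConfig(seed=13, n_reads=200, strand_fraction_plus=0.7)
        reads = st.simulate_primary_reads(trigger10, variant_locus, cfg)

        def strand_totals(reads):
            classified = [st.classify_read(r, locus, variant_locus) for r in reads]
            rep = st.build_report(classified, {"wt": len(locus)})
            by = rep.counts.groupby("strand")["count"].sum()
            return float(by.get("+", 0)), float(by.get("-", 0))

        p1, m1 = strand_totals(reads)
        rc_reads = [SRnaRead(r.id, st.revcomp(r.sequence)) for r in reads]
        p2, m2 = strand_totals(rc_reads)
        assert (p1, m1) == pytest.approx((m2, p2))
        assert p1 + m1 == pytest.approx(p2 + m2)
        assert p1 > m1  # strand bias present, so the swap is non-trivial

    def test_multimapper_fractional_weight(self):
        """A read hitting a two-copy repeat contributes one unit in total."""
        unit = "ACGTGCATTGCAGGATCCATG"  # 21 nt
        wt = unit + "T" * 30 + unit
        var = wt[:-1] + ("A" if wt[-1] != "A" else "C")
        cr = st.classify_read(SRnaRead("r", unit), wt, var)
        report = st.build_report([cr], {"wt": len(wt)})
        assert report.counts["count"].sum() == pytest.approx(1.0)
        starts = report.profiles[report.profiles["starts"] > 0]
        wt_starts = starts[starts["ref_id"] == "wt"]
        assert wt_starts["starts"].sum() == pytest.approx(1.0)
        assert len(wt_starts) == 2
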