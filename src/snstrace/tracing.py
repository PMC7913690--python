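"""Origin tracing of small RNA reads by SNS content.

Reads are adapter-trimmed, size-selected to the 21-24 nt small-RNA range, and
mapped with zero mismatches against two same-length references: the wild-type
locus and the SNS-variant locus (the wild-type with the trigger's marker
alleles substituted in).  Because the two references differ only at the marker
positions, exact matching sorts every read into one of four origin classes:

primary
    matches only the variant reference — the read carries at least one marker
    allele, so it was processed directly from the trigger.
secondary
    matches only the wild-type reference — the read covers at least one marker
    position but carries the wild-type allele, so it was produced from the
    unmarked target by RDR-dependent amplification.
ambiguous
    matches both references — the read covers no marker position (possible
    when the marker spacing exceeds the read length, or the read lies outside
    the trigger window) and its origin cannot be decided.
unmapped
    matches neither reference.

The report aggregates class x length x strand counts, per-position read-start
and coverage profiles, and a transitivity score: the fraction of
secondary-read aligned bases falling outside the trigger window, i.e. how far
amplification has spread beyond the originally targeted region.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq import revcomp, normalize_rna, is_dna

ORIGINS = ("primary", "secondary", "ambiguous", "unmapped")


@dataclass(frozen=True)
class SRnaRead:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """An exact occurrence of a read on a reference.

    ``start`` is the 1-based plus-strand position of the leftmost aligned
    base, for both strands; a minus-strand hit means the reverse complement
    of the read matches the reference there.
    """

    ref_id: str
    start: int
    strand: str


@dataclass(frozen=True)
class ClassifiedRead:
    read: SRnaRead
    wt_hits: tuple[AlignmentHit, ...]
    variant_hits: tuple[AlignmentHit, ...]

    @property
    def origin(self) -> str:
        if self.variant_hits and not self.wt_hits:
            return "primary"
        if self.wt_hits and not self.variant_hits:
            return "secondary"
        if self.wt_hits and self.variant_hits:
            return "ambiguous"
        return "unmapped"


def trim_adapter(read: SRnaRead, adapter: str, min_overlap: int = 8) -> SRnaRead:
    """Remove a 3' adapter by exact prefix match.

    The insert ends at the leftmost position where a prefix of the adapter of
    length >= ``min_overlap`` (or the remaining read, whichever is shorter)
    matches exactly.  Reads without a detectable adapter are returned
    untouched — a valid outcome for inserts longer than the sequenced length.
    """
    if not adapter:
        raise ValueError("adapter is empty")
    seq = read.sequence
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        probe = adapter[: min(len(adapter), len(tail))]
        if len(probe) >= min_overlap and tail.startswith(probe):
            return SRnaRead(id=read.id, sequence=seq[:i])
    return read


def size_select(
    reads: list[SRnaRead], min_len: int = 21, max_len: int = 24
) -> tuple[list[SRnaRead], Counter]:
    """Keep reads in the [min_len, max_len] size range, in DNA space.

    Returns the retained reads and a Counter of dropped reads keyed by length
    (reads with non-ACGT symbols are dropped under the key ``"non_acgt"``).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept: list[SRnaRead] = []
    dropped: Counter = Counter()
    for read in reads:
        seq = normalize_rna(read.sequence)
        if not is_dna(seq):
            dropped["non_acgt"] += 1
        elif min_len <= len(seq) <= max_len:
            kept.append(SRnaRead(id=read.id, sequence=seq))
        else:
            dropped[len(seq)] += 1
    return kept, dropped


def map_perfect(read: SRnaRead, reference: str, ref_id: str = "ref") -> list[AlignmentHit]:
    """Every exact occurrence of the read on either strand of the reference.

    Overlapping occurrences are all reported.  Minus-strand hits are
    occurrences of the read's reverse complement, reported with the
    plus-strand coordinate of their leftmost base.
    """
    if read.length > len(reference):
        return []
    hits = [
        AlignmentHit(ref_id=ref_id, start=i + 1, strand="+")
        for i in _find_all(reference, read.sequence)
    ]
    rc = revcomp(read.sequence)
    hits += [
        AlignmentHit(ref_id=ref_id, start=i + 1, strand="-")
        for i in _find_all(reference, rc)
    ]
    return hits


def classify_read(
    read: SRnaRead,
    wt_reference: str,
    variant_reference: str,
    wt_id: str = "wt",
    variant_id: str = "variant",
) -> ClassifiedRead:
    """Assign a read its origin class by exact mapping to both references."""
    if len(wt_reference) != len(variant_reference):
        raise ValueError(
            "wild-type and variant references differ in length "
            f"({len(wt_reference)} vs {len(variant_reference)})"
        )
    return ClassifiedRead(
        read=read,
        wt_hits=tuple(map_perfect(read, wt_reference, wt_id)),
        variant_hits=tuple(map_perfect(read, variant_reference, variant_id)),
    )


@dataclass
class TracingReport:
    """Count tables, per-position profiles and transitivity for one library.

    ``counts``: DataFrame with columns origin, length, strand, count.  Reads
    hitting multiple positions contribute fractionally (1/n_hits per hit) so
    the count total always equals the number of size-selected reads;
    unmapped reads are tallied under strand ``"."``.

    ``profiles``: DataFrame with columns ref_id, position, length, strand,
    starts, coverage — fractional read-start and per-base coverage counts.

    ``transitivity``: fraction of aligned bases of mapped non-primary reads
    (secondary plus ambiguous) falling outside the trigger window (0 when
    there are none).  Ambiguous reads are included because a read lying
    entirely outside the window necessarily matches both references.
    """

    counts: pd.DataFrame
    profiles: pd.DataFrame
    transitivity: float
    n_reads: int

    def class_totals(self) -> dict[str, float]:
        by = self.counts.groupby("origin")["count"].sum()
        return {o: float(by.get(o, 0.0)) for o in ORIGINS}


def _counting_hits(cr: ClassifiedRead) -> tuple[AlignmentHit, ...]:
    # The hits that define where a read is counted: its discriminating
    # reference for primary/secondary, the wild-type for ambiguous (both
    # references give the same coordinates there by construction).
    if cr.origin == "primary":
        return cr.variant_hits
    if cr.origin in ("secondary", "ambiguous"):
        return cr.wt_hits
    return ()


def build_report(
    classified_reads: list[ClassifiedRead],
    reference_lengths: dict[str, int],
    trigger_window: tuple[int, int] | None = None,
) -> TracingReport:
    """Aggregate classified reads into counts, profiles and transitivity.

    ``trigger_window`` is the 1-based inclusive (start, end) span of the
    trigger on the wild-type reference coordinate system; it bounds the
    transitivity computation.  ``reference_lengths`` maps ref_id to length
    and is used to validate the window and shape the profile table.
    """
    if trigger_window is not None:
        w0, w1 = trigger_window
        max_len = max(reference_lengths.values(), default=0)
        if w0 < 1 or w1 > max_len or w0 > w1:
            raise ValueError(f"trigger_window {trigger_window} outside reference")

    count_acc: defaultdict[tuple[str, int, str], float] = defaultdict(float)
    starts_acc: defaultdict[tuple[str, int, int, str], float] = defaultdict(float)
    cover_acc: defaultdict[tuple[str, int, int, str], float] = defaultdict(float)
    sec_inside = sec_outside = 0.0

    for cr in classified_reads:
        L = cr.read.length
        hits = _counting_hits(cr)
        if not hits:
            count_acc[("unmapped", L, ".")] += 1.0
            continue
        w = 1.0 / len(hits)
        for hit in hits:
            count_acc[(cr.origin, L, hit.strand)] += w
        # Profiles pool every hit on every reference, weighted per reference
        # so each read contributes one unit of starts per reference it maps to.
        for hit_group in (cr.wt_hits, cr.variant_hits):
            by_ref: defaultdict[str, list[AlignmentHit]] = defaultdict(list)
            for hit in hit_group:
                by_ref[hit.ref_id].append(hit)
            for ref_id, ref_hits in by_ref.items():
                wr = 1.0 / len(ref_hits)
                for hit in ref_hits:
                    starts_acc[(ref_id, hit.start, L, hit.strand)] += wr
                    for pos in range(hit.start, hit.start + L):
                        cover_acc[(ref_id, pos, L, hit.strand)] += wr
        # Transitivity pools all mapped reads lacking SNS evidence: strictly
        # secondary reads plus ambiguous ones.  A read mapping entirely
        # outside the trigger window matches both references (they are
        # identical there) and is classed ambiguous, yet it is precisely the
        # transitive, target-amplified signal the score must capture — the
        # trigger itself spans only the window, so nothing outside it can be
        # trigger-derived.
        if cr.origin in ("secondary", "ambiguous") and trigger_window is not None:
            w0, w1 = trigger_window
            for hit in hits:
                wr = 1.0 / len(hits)
                for pos in range(hit.start, hit.start + L):
                    if w0 <= pos <= w1:
                        sec_inside += wr
                    else:
                        sec_outside += wr

    counts = pd.DataFrame(
        [(o, L, s, c) for (o, L, s), c in sorted(count_acc.items())],
        columns=["origin", "length", "strand", "count"],
    )
    rows = [
        (ref, pos, L, s, starts_acc.get((ref, pos, L, s), 0.0), cov)
        for (ref, pos, L, s), cov in sorted(cover_acc.items())
    ]
    profiles = pd.DataFrame(
        rows, columns=["ref_id", "position", "length", "strand", "starts", "coverage"]
    )
    total_sec = sec_inside + sec_outside
    transitivity = sec_outside / total_sec if total_sec > 0 else 0.0
    return TracingReport(
        counts=counts,
        profiles=profiles,
        transitivity=float(transitivity),
        n_reads=len(classified_reads),
    )


def trace_library(
    reads: list[SRnaRead],
    wt_reference: str,
    variant_reference: str,
    trigger_window: tuple[int, int] | None = None,
    adapter: str | None = None,
    min_overlap: int = 8,
    min_len: int = 21,
    max_len: int = 24,
) -> tuple[TracingReport, list[ClassifiedRead], Counter]:
    """End-to-end pipeline: trim, size-select, classify, report."""
    if adapter:
        reads = [trim_adapter(r, adapter, min_overlap) for r in reads]
    kept, dropped = size_select(reads, min_len=min_len, max_len=max_len)
    classified = [classify_read(r, wt_reference, variant_reference) for r in kept]
    report = build_report(
        classified,
        {"wt": len(wt_reference), "variant": len(variant_reference)},
        trigger_window,
    )
    return report, classified, dropped


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
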