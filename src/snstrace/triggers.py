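"""Design of silencing triggers carrying regularly interspaced single-nucleotide
substitutions (SNSs).

An SNS-marked trigger is a variant of a target fragment in which every
``spacing``-th base, starting at ``offset``, is substituted by a deterministic
involutive base map.  Two schemes are supported:

``transition_guw``
    Transitions A<->G and C<->T.  A small RNA carrying such a substitution can
    still pair with its target transcript through a G:U wobble pair on exactly
    one polarity, so silencing activity is largely preserved while the
    substitution remains a sequencing-detectable marker.

``transversion``
    Transversions A<->T and G<->C.  No wobble rescue on either polarity; the
    mismatch is fully disruptive to base pairing.

Because both maps are involutions, applying a scheme twice restores the
original sequence — a property used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .seq import revcomp, complement, validate_dna

Scheme = Literal["transition_guw", "transversion"]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "T", "T": "A", "G": "C", "C": "G"}

BASE_MAPS: dict[str, dict[str, str]] = {
    "transition_guw": _TRANSITION,
    "transversion": _TRANSVERSION,
}


def fragment_length(locus_start: int, locus_end: int) -> int:
    """Inclusive length of a coordinate interval on a locus.

    Promoter coordinates are signed relative to the transcription start site
    and have no position 0, so an interval spanning negative to positive
    coordinates is one shorter than plain inclusive arithmetic suggests.

    >>> fragment_length(-208, -89)
    120
    >>> fragment_length(364, 483)
    120
    >>> fragment_length(-1, 1)
    2
    """
    if locus_start > locus_end:
        raise ValueError(
            f"reversed interval: start {locus_start} > end {locus_end}"
        )
    length = locus_end - locus_start + 1
    if locus_start < 0 < locus_end:
        length -= 1  # signed promoter coordinates skip position 0
    return length


@dataclass(frozen=True)
class TargetFragment:
    """A target subsequence with its locus coordinates and strand."""

    id: str
    sequence: str
    locus_id: str = ""
    locus_start: int = 1
    locus_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        validate_dna(self.sequence, what=f"fragment {self.id!r}")
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r} is empty")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        end = self.locus_end
        if end == 0:
            # coordinates optional: default to a 1-based span of the sequence
            end = len(self.sequence)
            object.__setattr__(self, "locus_end", end)
        if fragment_length(self.locus_start, end) != len(self.sequence):
            raise ValueError(
                f"fragment {self.id!r}: sequence length {len(self.sequence)} "
                f"does not match coordinates {self.locus_start}..{end} "
                f"({fragment_length(self.locus_start, end)} nt)"
            )


@dataclass(frozen=True)
class SNSDesign:
    """A regular-interval substitution plan.

    spacing : distance in nt between consecutive substitutions (>= 1)
    offset  : 1-based position of the first substitution; must be <= spacing
    scheme  : ``transition_guw`` or ``transversion``
    """

    spacing: int
    offset: int | None = None
    scheme: Scheme = "transition_guw"

    def __post_init__(self) -> None:
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1")
        if self.offset is None:
            # First marker sits mid-interval when the spacing is even,
            # at one full spacing otherwise.
            default = round(self.spacing / 2) if self.spacing % 2 == 0 else self.spacing
            object.__setattr__(self, "offset", default)
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        if self.offset > self.spacing:
            raise ValueError(
                f"offset {self.offset} exceeds spacing {self.spacing}"
            )
        if self.scheme not in BASE_MAPS:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class SNSRecord:
    """One substitution: where, what, and its wobble behaviour.

    ``wobble_polarity`` names the sRNA polarity (sense/antisense relative to
    the fragment) whose pairing against the target transcript forms a G:U
    wobble, or ``none`` when neither does (all transversions).
    """

    position: int  # 1-based within the fragment
    ref_base: str
    alt_base: str
    substitution_class: str = field(default="")
    wobble_polarity: str = field(default="")

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")
        if not self.substitution_class:
            cls = "transition" if _TRANSITION[self.ref_base] == self.alt_base else "transversion"
            object.__setattr__(self, "substitution_class", cls)


def annotate_wobble(record: SNSRecord) -> SNSRecord:
    """Fill in which sRNA polarity pairs with the target through G:U.

    A sense sRNA carries the substituted base (read as RNA, T->U) and pairs
    against the complement of the reference base on the antisense transcript;
    an antisense sRNA carries the complement of the substituted base and pairs
    against the reference base on the sense transcript.  Whichever pairing is
    {G, U} is the wobble polarity; transversions never form one.
    """

    def as_rna(b: str) -> str:
        return "U" if b == "T" else b

    sense_pair = {as_rna(record.alt_base), as_rna(complement(record.ref_base))}
    anti_pair = {as_rna(complement(record.alt_base)), as_rna(record.ref_base)}
    gu = {"G", "U"}
    if sense_pair == gu:
        polarity = "sense"
    elif anti_pair == gu:
        polarity = "antisense"
    else:
        polarity = "none"
    return replace(record, wobble_polarity=polarity)


@dataclass(frozen=True)
class MarkedTrigger:
    """An SNS-variant trigger sequence with its per-substitution records."""

    fragment: TargetFragment
    design: SNSDesign
    variant_sequence: str
    sns: tuple[SNSRecord, ...]

    def sns_positions(self) -> tuple[int, ...]:
        return tuple(r.position for r in self.sns)


def design_marked_trigger(fragment: TargetFragment, design: SNSDesign) -> MarkedTrigger:
    """Introduce substitutions at ``offset, offset+spacing, ...`` into the fragment.

    Raises ``ValueError`` when the offset lies beyond the fragment (no marker
    could be placed, so the design is unusable).
    """
    n = len(fragment.sequence)
    if design.offset > n:
        raise ValueError(
            f"offset {design.offset} beyond fragment length {n}: no SNS placeable"
        )
    base_map = BASE_MAPS[design.scheme]
    positions = range(design.offset, n + 1, design.spacing)
    seq = list(fragment.sequence)
    records = []
    for pos in positions:
        ref = seq[pos - 1]
        alt = base_map[ref]
        seq[pos - 1] = alt
        records.append(annotate_wobble(SNSRecord(position=pos, ref_base=ref, alt_base=alt)))
    return MarkedTrigger(
        fragment=fragment,
        design=design,
        variant_sequence="".join(seq),
        sns=tuple(records),
    )


def min_mismatches_per_read(trigger: MarkedTrigger, read_lengths: set[int]) -> int:
    """Minimum number of SNSs covered by any fully-internal sRNA window.

    Every sRNA of a length in ``read_lengths`` processed from the trigger
    corresponds to a window of that length inside the fragment; the value
    returned is the worst case over all such windows — the guaranteed number
    of mismatches each trigger-derived sRNA carries against the unmarked
    target.
    """
    if not read_lengths:
        raise ValueError("read_lengths is empty")
    n = len(trigger.fragment.sequence)
    positions = trigger.sns_positions()
    best = None
    for length in sorted(read_lengths):
        if length > n:
            raise ValueError(f"read length {length} exceeds fragment length {n}")
        for start in range(1, n - length + 2):
            count = sum(1 for p in positions if start <= p <= start + length - 1)
            if best is None or count < best:
                best = count
    return best


def project_sns_onto_locus(locus_sequence: str, trigger: MarkedTrigger) -> str:
    """Substitute the trigger's SNS alleles into a full-length locus.

    The fragment must occur exactly once in the locus, on either strand; on the
    minus strand the alleles are applied reverse-complemented.  The result is
    the "variant reference" against which primary (marker-carrying) sRNAs map
    perfectly while secondary sRNAs do not.
    """
    validate_dna(locus_sequence, what="locus")
    frag = trigger.fragment.sequence
    fwd = _find_all(locus_sequence, frag)
    rev = _find_all(locus_sequence, revcomp(frag))
    total = len(fwd) + len(rev)
    if total == 0:
        raise ValueError("fragment does not occur in the locus")
    if total > 1:
        raise ValueError(
            f"fragment occurs {total} times in the locus; projection is ambiguous"
        )
    seq = list(locus_sequence)
    L = len(frag)
    if fwd:
        start = fwd[0]  # 0-based
        for rec in trigger.sns:
            seq[start + rec.position - 1] = rec.alt_base
    else:
        start = rev[0]
        for rec in trigger.sns:
            # fragment position p maps to locus index start + (L - p)
            seq[start + L - rec.position] = complement(rec.alt_base)
    return "".join(seq)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
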