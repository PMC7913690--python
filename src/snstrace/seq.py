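"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")


def complement(base_or_seq: str) -> str:
    return base_or_seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, what: str = "sequence") -> None:
    """Reject anything outside uppercase A/C/G/T (no IUPAC ambiguity codes)."""
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def is_dna(seq: str) -> bool:
    return not set(seq) - _DNA


def normalize_rna(seq: str) -> str:
    """Map RNA input into DNA space (U -> T), uppercase."""
    return seq.upper().replace("U", "T")
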