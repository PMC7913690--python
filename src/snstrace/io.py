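"""FASTA/FASTQ input and output, via Bio.SeqIO.

Reads may arrive as FASTA or FASTQ, optionally gzip-compressed; format is
inferred from the filename (.fq/.fastq vs everything else).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tracing import SRnaRead


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fmt(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    return "fastq" if name.endswith((".fq", ".fastq")) else "fasta"


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence for every record in a FASTA file."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_reads(path: str | Path) -> list[SRnaRead]:
    """Load sRNA reads from FASTA or FASTQ (optionally gzipped)."""
    with _open_text(path) as fh:
        return [
            SRnaRead(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, _fmt(path))
        ]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    recs = []
    for rid, seq in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")
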