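"""Cytosine methylation calling from bisulfite-converted clone sequences.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine resists conversion and stays C.  Aligning a
Sanger-sequenced clone of the converted amplicon back to the untreated
reference therefore reads out the methylation state of every C on the assayed
strand: C means methylated, T means converted (unmethylated), anything else —
including gaps — is uninformative.

Contexts follow the plant convention: CG if the next base is G, else CHG if
the base after next is G, else CHH (H = A, C or T), with CG taking priority
over CHG.  The three contexts are maintained by distinct pathways (MET1,
CMT3, and DRM2/CMT2 respectively), so summaries are reported per context with
Wilson 95% score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as sps

from .seq import revcomp, validate_dna
from .stats import wilson_interval

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class CytosineSite:
    position: int  # 1-based on the assayed strand
    context: str
    strand: str = "+"


@dataclass(frozen=True)
class MethylationCall:
    clone_id: str
    site: CytosineSite
    state: str  # methylated | unmethylated | missing


def assign_contexts(
    reference: str, strand: str = "+", flank3: str = ""
) -> list[CytosineSite]:
    """One site per cytosine on the assayed strand, with its context.

    Context priority is CG > CHG > CHH.  Cytosines lacking two downstream
    bases are excluded unless ``flank3`` supplies 3' flanking sequence beyond
    the amplicon end (positions remain within the amplicon).
    """
    validate_dna(reference)
    if strand == "-":
        seq = revcomp(reference)
    elif strand == "+":
        seq = reference
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    extended = seq + flank3
    sites = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i + 2 >= len(extended):
            continue  # cannot resolve context at the amplicon edge
        if extended[i + 1] == "G":
            ctx = "CG"
        elif extended[i + 2] == "G":
            ctx = "CHG"
        else:
            ctx = "CHH"
        sites.append(CytosineSite(position=i + 1, context=ctx, strand=strand))
    return sites


def _bisulfite_aligner() -> Align.PairwiseAligner:
    # Asymmetric scoring: reference C aligned to clone T is a full match,
    # because conversion of unmethylated C is the expected chemistry, not an
    # error. Everything else scores as plain match/mismatch.
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = 1.0 if a == b else -1.0
    mat["C", "T"] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    # do not penalize terminal gaps (truncated Sanger reads, overhangs)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


class CloneRejected(ValueError):
    """Raised when a clone aligns below the identity floor."""


def align_clone(
    clone: str,
    reference: str,
    strand: str = "+",
    min_identity: float = 0.8,
) -> tuple[dict[int, str], str]:
    """Globally align a bisulfite clone to the assayed reference strand.

    Orientation is auto-detected by aligning both the clone and its reverse
    complement and keeping the higher score.  Returns a mapping of 1-based
    reference position -> clone base (positions deleted in the clone are
    absent from the mapping) and the detected orientation ("+" if the clone
    was supplied in the assayed strand's orientation).

    Raises :class:`CloneRejected` when bisulfite-aware identity — matches over
    all reference bases, counting reference-C/clone-T as a match — falls below
    ``min_identity``.  The reference-length denominator folds coverage into the
    floor, so clones spanning too little of the amplicon are rejected along
    with divergent ones.
    """
    validate_dna(reference)
    ref = revcomp(reference) if strand == "-" else reference
    clone = clone.upper().replace("U", "T")
    aligner = _bisulfite_aligner()
    candidates = [(clone, "+"), (revcomp(clone), "-")]
    best = None
    for seq, orient in candidates:
        aln = aligner.align(ref, seq)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, seq, orient)
    aln, oriented, orientation = best

    by_pos: dict[int, str] = {}
    matches = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            rb, cb = ref[t0 + k], oriented[q0 + k]
            by_pos[t0 + k + 1] = cb
            if rb == cb or (rb == "C" and cb == "T"):
                matches += 1
    identity = matches / len(ref) if ref else 0.0
    if identity < min_identity:
        raise CloneRejected(
            f"clone identity {identity:.2f} below floor {min_identity:.2f}"
        )
    return by_pos, orientation


def call_clone(
    clone_id: str, by_pos: dict[int, str], sites: list[CytosineSite]
) -> list[MethylationCall]:
    """Methylation state at each site from the aligned clone bases."""
    calls = []
    for site in sites:
        base = by_pos.get(site.position)
        if base == "C":
            state = "methylated"
        elif base == "T":
            state = "unmethylated"
        else:
            state = "missing"
        calls.append(MethylationCall(clone_id=clone_id, site=site, state=state))
    return calls


def summarize(calls: list[MethylationCall], level: float = 0.95) -> pd.DataFrame:
    """Per-context and total methylation proportions with Wilson intervals.

    Rows: CG, CHG, CHH, total.  Columns: m (methylated), n (informative =
    methylated + unmethylated; missing excluded), proportion, wilson_low,
    wilson_high.  A context with no informative calls has NaN proportion and
    bounds — undefined, not zero.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    rows = []
    groups: dict[str, list[MethylationCall]] = {ctx: [] for ctx in CONTEXTS}
    for c in calls:
        groups[c.site.context].append(c)
    groups["total"] = list(calls)
    for name in (*CONTEXTS, "total"):
        grp = groups[name]
        m = sum(c.state == "methylated" for c in grp)
        n = m + sum(c.state == "unmethylated" for c in grp)
        if n == 0:
            rows.append((name, 0, 0, np.nan, np.nan, np.nan))
        else:
            ci = wilson_interval(m, n, level)
            rows.append((name, m, n, m / n, ci.low, ci.high))
    return pd.DataFrame(
        rows, columns=["context", "m", "n", "proportion", "wilson_low", "wilson_high"]
    ).set_index("context")


def call_sample(
    reference: str,
    clones: dict[str, str],
    strand: str = "+",
    min_identity: float = 0.8,
    flank3: str = "",
    max_unconverted_chh: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Call every clone of a sample against one amplicon reference.

    Returns (call matrix, summary, rejected clone ids).  The call matrix is
    clone x site (columns labelled ``pos<position>_<context>``) with values
    C/T/. for methylated/unmethylated/missing — the per-clone methylation
    pattern layout familiar from Sanger bisulfite analyses.

    ``max_unconverted_chh``, when set, rejects clones whose count of
    unconverted (C) calls at CHH sites exceeds the threshold — an optional
    conversion-efficiency filter, off by default.
    """
    sites = assign_contexts(reference, strand=strand, flank3=flank3)
    all_calls: list[MethylationCall] = []
    matrix_rows: dict[str, list[str]] = {}
    rejected: list[str] = []
    for clone_id, seq in clones.items():
        try:
            by_pos, _ = align_clone(seq, reference, strand=strand, min_identity=min_identity)
        except CloneRejected:
            rejected.append(clone_id)
            continue
        calls = call_clone(clone_id, by_pos, sites)
        if max_unconverted_chh is not None:
            chh_unconv = sum(
                c.state == "methylated" for c in calls if c.site.context == "CHH"
            )
            if chh_unconv > max_unconverted_chh:
                rejected.append(clone_id)
                continue
        all_calls.extend(calls)
        symbol = {"methylated": "C", "unmethylated": "T", "missing": "."}
        matrix_rows[clone_id] = [symbol[c.state] for c in calls]
    if not all_calls:
        raise ValueError("every clone was rejected; nothing to summarize")
    columns = [f"pos{s.position}_{s.context}" for s in sites]
    matrix = pd.DataFrame.from_dict(matrix_rows, orient="index", columns=columns)
    return matrix, summarize(all_calls), rejected


def compare_samples(
    replicate_proportions_a: list[float], replicate_proportions_b: list[float]
) -> tuple[float, float]:
    """Two-sample two-sided t-test on replicate-level methylation proportions.

    Equal-variance (Student's) by default, matching the convention of testing
    total-methylation differences across three biological replicates.
    Returns (t statistic, p value).
    """
    if len(replicate_proportions_a) < 2 or len(replicate_proportions_b) < 2:
        raise ValueError("need >= 2 biological replicates per sample")
    t, p = sps.ttest_ind(
        replicate_proportions_a, replicate_proportions_b, equal_var=True
    )
    return float(t), float(p)
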