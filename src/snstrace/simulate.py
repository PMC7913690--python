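"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a TRV-based VIGS
experiment read out by small-RNA sequencing and Sanger bisulfite sequencing:

* a synthetic locus with designated promoter and coding-sequence windows
  standing in for a 35S:GFP transgene locus;
* primary sRNA reads (21-24 nt, both strands, unevenly distributed along the
  trigger) sampled from an SNS-marked trigger embedded in a carrier sequence;
* secondary sRNA reads sampled from the unmarked target, with a configurable
  fraction drawn from outside the trigger window (transitivity);
* bisulfite clones with per-context methylation probabilities and an
  incomplete-conversion noise rate.

Every generator is a pure function of (seed, config): outputs are
byte-identical across runs.  Ground-truth origin labels are embedded in the
read identifiers so downstream classification accuracy can be computed
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import revcomp
from .methylation import assign_contexts
from .tracing import SRnaRead
from .triggers import MarkedTrigger

READ_LENGTHS = (21, 22, 23, 24)


@dataclass(frozen=True)
class BisulfiteConfig:
    """Per-context methylation probabilities and conversion noise."""

    p_cg: float = 0.8
    p_chg: float = 0.6
    p_chh: float = 0.3
    conversion_failure_rate: float = 0.01
    n_clones: int = 12  # 8-16 Sanger clones per sample is typical

    def __post_init__(self) -> None:
        for name in ("p_cg", "p_chg", "p_chh", "conversion_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def p_for(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation settings.

    length_weights are over 21/22/23/24 nt, defaulting to a 21/22-nt-heavy
    profile typical of DCL4/DCL2-dominated viral sRNA populations with a
    smaller 24-nt class.  hotspot_peaks shapes the lumpy positional abundance
    (viral sRNAs are not evenly distributed along their source); it lists
    (relative_position, weight, width) mixture components over the sampled
    window.
    """

    seed: int = 0
    n_reads: int = 1000
    length_weights: tuple[float, ...] = (0.4, 0.3, 0.1, 0.2)
    strand_fraction_plus: float = 0.5
    hotspot_peaks: tuple[tuple[float, float, float], ...] = (
        (0.2, 3.0, 0.05),
        (0.55, 1.5, 0.08),
        (0.85, 2.0, 0.04),
    )
    transitivity_fraction: float = 0.0
    adapter: str | None = None

    def __post_init__(self) -> None:
        if len(self.length_weights) != len(READ_LENGTHS):
            raise ValueError("length_weights must cover lengths 21-24")
        if any(w < 0 for w in self.length_weights) or sum(self.length_weights) <= 0:
            raise ValueError("length_weights must be non-negative and sum > 0")
        if not 0.0 <= self.strand_fraction_plus <= 1.0:
            raise ValueError("strand_fraction_plus must be in [0, 1]")
        if not 0.0 <= self.transitivity_fraction <= 1.0:
            raise ValueError("transitivity_fraction must be in [0, 1]")

    def normalized_length_weights(self) -> np.ndarray:
        w = np.asarray(self.length_weights, dtype=float)
        return w / w.sum()


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_locus_fixture(
    seed: int, promoter_len: int = 800, cds_len: int = 720, window_len: int = 120
) -> tuple[str, dict[str, tuple[int, int]]]:
    """A random uniform-composition locus with promoter and CDS trigger windows.

    Returns (locus sequence, windows) where windows maps ``"promoter"`` and
    ``"cds"`` to 1-based inclusive (start, end) spans of length ``window_len``.
    The promoter window sits just upstream of the promoter/CDS boundary and
    the CDS window mid-CDS, mimicking a promoter fragment close to the
    transcription start site and an internal coding-sequence fragment.
    """
    if window_len > promoter_len or window_len > cds_len:
        raise ValueError("window_len exceeds promoter or CDS length")
    rng = np.random.default_rng(seed)
    locus = _random_dna(rng, promoter_len + cds_len)
    prom_end = promoter_len - 80 if promoter_len - 80 >= window_len else promoter_len
    prom_start = prom_end - window_len + 1
    cds_start = promoter_len + max(1, (cds_len - window_len) // 2)
    windows = {
        "promoter": (prom_start, prom_end),
        "cds": (cds_start, cds_start + window_len - 1),
    }
    return locus, windows


def _position_weights(cfg: SimConfig, n_starts: int) -> np.ndarray:
    """Lumpy start-position distribution from the hotspot mixture."""
    x = np.linspace(0.0, 1.0, n_starts)
    w = np.full(n_starts, 0.2)  # uniform floor so every position is reachable
    for center, height, width in cfg.hotspot_peaks:
        w += height * np.exp(-0.5 * ((x - center) / width) ** 2)
    return w / w.sum()


def _sample_reads(
    rng: np.random.Generator,
    source: str,
    region: tuple[int, int],
    n: int,
    cfg: SimConfig,
    label: str,
) -> list[SRnaRead]:
    """Sample exact-substring reads from a region of ``source`` (1-based span)."""
    lw = cfg.normalized_length_weights()
    lengths = rng.choice(READ_LENGTHS, size=n, p=lw)
    plus = rng.random(n) < cfg.strand_fraction_plus
    r0, r1 = region
    reads = []
    for i in range(n):
        L = int(lengths[i])
        lo, hi = r0, r1 - L + 1  # 1-based valid starts keeping the read inside
        if hi < lo:
            raise ValueError(f"region {region} shorter than read length {L}")
        weights = _position_weights(cfg, hi - lo + 1)
        start = lo + int(rng.choice(hi - lo + 1, p=weights))
        seq = source[start - 1 : start - 1 + L]
        strand = "+" if plus[i] else "-"
        if strand == "-":
            seq = revcomp(seq)
        if cfg.adapter:
            seq = seq + cfg.adapter
        reads.append(
            SRnaRead(id=f"{label}|{i}|start={start}|strand={strand}|len={L}", sequence=seq)
        )
    return reads


def simulate_primary_reads(
    trigger: MarkedTrigger, carrier: str, cfg: SimConfig
) -> list[SRnaRead]:
    """Primary sRNAs: exact copies of the marked trigger inside its carrier.

    The variant trigger must be embedded in the carrier (as in a recombinant
    viral RNA); reads are drawn from within the trigger window with the
    configured length/strand/position distributions, so each read carries the
    marker alleles its window covers.  Ground-truth origin is recorded in the
    read id.
    """
    idx = carrier.find(trigger.variant_sequence)
    if idx == -1:
        raise ValueError("variant trigger sequence not embedded in carrier")
    rng = np.random.default_rng(cfg.seed)
    region = (idx + 1, idx + len(trigger.variant_sequence))
    return _sample_reads(rng, carrier, region, cfg.n_reads, cfg, "primary")


def simulate_secondary_reads(
    wt_locus: str, trigger_window: tuple[int, int], cfg: SimConfig
) -> list[SRnaRead]:
    """Secondary sRNAs: unmarked target copies, optionally spread beyond the window.

    A fraction ``transitivity_fraction`` of reads is drawn from outside the
    trigger window (entirely, so base-level and read-level transitivity
    coincide); the remainder from inside.  With fraction 0 this emulates the
    TGS-like situation of amplification confined to the targeted region; a
    large fraction emulates PTGS-style transitive spreading.
    """
    w0, w1 = trigger_window
    if w0 < 1 or w1 > len(wt_locus) or w0 > w1:
        raise ValueError(f"trigger_window {trigger_window} outside locus")
    rng = np.random.default_rng(cfg.seed + 1)
    n_out = int(np.round(cfg.n_reads * cfg.transitivity_fraction))
    n_in = cfg.n_reads - n_out
    reads = _sample_reads(rng, wt_locus, (w0, w1), n_in, cfg, "secondary_in")
    max_len = max(READ_LENGTHS)
    left = (1, w0 - 1)
    right = (w1 + 1, len(wt_locus))
    outside = [r for r in (left, right) if r[1] - r[0] + 1 >= max_len]
    if n_out > 0:
        if not outside:
            raise ValueError("no room outside the trigger window for transitive reads")
        sizes = np.array([r[1] - r[0] + 1 for r in outside], dtype=float)
        picks = rng.choice(len(outside), size=n_out, p=sizes / sizes.sum())
        for j, region_idx in enumerate(picks):
            reads += _sample_reads(
                rng, wt_locus, outside[region_idx], 1, cfg, f"secondary_out{j}"
            )
    return reads


def simulate_bisulfite_clones(
    reference: str,
    bis: BisulfiteConfig,
    seed: int,
    strand: str = "+",
) -> tuple[dict[str, str], dict[str, dict[int, bool]]]:
    """Bisulfite-converted Sanger clones of one amplicon.

    Per clone, each cytosine on the assayed strand is methylated with its
    context probability (and then stays C); unmethylated cytosines convert to
    T except with probability ``conversion_failure_rate`` (incomplete
    conversion, which mimics methylation).  Non-C bases are copied unchanged.

    Returns (clones, truth): clone id -> sequence, and clone id -> {site
    position -> truly methylated} for exact downstream accuracy checks.
    """
    rng = np.random.default_rng(seed)
    assayed = revcomp(reference) if strand == "-" else reference
    sites = assign_contexts(reference, strand=strand)
    site_by_pos = {s.position: s for s in sites}
    clones: dict[str, str] = {}
    truth: dict[str, dict[int, bool]] = {}
    for k in range(bis.n_clones):
        seq = list(assayed)
        states: dict[int, bool] = {}
        for i, base in enumerate(assayed):
            if base != "C":
                continue
            pos = i + 1
            site = site_by_pos.get(pos)
            if site is not None:
                methylated = rng.random() < bis.p_for(site.context)
                states[pos] = bool(methylated)
            else:
                # terminal C with unresolvable context: never called downstream;
                # simulated with the CHH probability
                methylated = rng.random() < bis.p_chh
            if not methylated and rng.random() >= bis.conversion_failure_rate:
                seq[i] = "T"
        clone_id = f"clone{k}|meth={sum(states.values())}"
        clones[clone_id] = "".join(seq)
        truth[clone_id] = states
    return clones, truth
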