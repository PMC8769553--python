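"""Quality filters for long-read transcript models and end validation.

Five artifact filters are implemented: poly(A) intrapriming (unreliable 3'
ends), short-read junction support, noncanonical splice sites, RT-switch
direct repeats, and intron retention.  Which filters gate which structural
category is set by the per-category policy in :func:`apply_filter_policy`:
reference-matching isoforms (FSM) pass unconditionally, truncations (ISM)
must only have reliable 3' ends, and the novel categories carry
progressively more filters, with NNC and the remaining categories also
required to use exclusively canonical, non-RT-switch junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import StructuralCall, StructuralCategory
from .core import Genome, PeakIndex, ReferenceIndex, SpliceJunction, TranscriptModel

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
POLYA_MOTIFS = ("AATAAA", "ATTAAA")


@dataclass
class QcConfig:
    tts_distance: int = 100  # bp from an annotated TTS before a 3' end is "far"
    a_fraction: float = 0.80  # strict > threshold on downstream adenine content
    a_window: int = 20  # nt of genomic sequence downstream of the 3' end
    polya_slack: int = 10  # +/- bp tolerance for poly(A)-site catalog overlap
    min_coverage: int = 5  # short reads per junction
    min_lr_samples: int = 3  # alternative long-read support clause
    rt_switch_k: int = 8  # direct-repeat length
    end_window: int = 50  # CAGE/ATAC and 3'-seq peak window for end validation
    motif_window: int = 50  # transcript 3' nt scanned for poly(A) motifs


@dataclass
class QcFlags:
    transcript_id: str
    far_from_tts: bool = False
    a_rich_downstream: bool = False
    no_polyA_db_overlap: bool = False
    noncanonical_junctions: List[SpliceJunction] = field(default_factory=list)
    rt_switch_junctions: List[SpliceJunction] = field(default_factory=list)
    junction_short_read_coverage: Dict[Tuple[int, int], int] = field(default_factory=dict)
    lr_sample_count: int = 0
    intron_retention_code: Optional[str] = None

    @property
    def unreliable_3prime(self) -> bool:
        return self.far_from_tts and self.a_rich_downstream and self.no_polyA_db_overlap


@dataclass
class FilterDecision:
    transcript_id: str
    category: StructuralCategory
    keep: bool
    reasons: List[str] = field(default_factory=list)


# --- individual filters -------------------------------------------------


def detect_intrapriming(
    tx: TranscriptModel,
    genome: Genome,
    polyA_db: PeakIndex,
    ref: ReferenceIndex,
    config: QcConfig = QcConfig(),
) -> Tuple[bool, bool, bool]:
    """Poly(A) intrapriming sub-flags for the transcript 3' end.

    Returns (far_from_tts, a_rich_downstream, no_polyA_db_overlap); the 3'
    end is unreliable only when all three hold.
    """
    if tx.chrom not in genome:
        raise KeyError(f"genome does not cover {tx.chrom}")
    tts = tx.tts
    dist = ref.nearest_tts_distance(tx.chrom, tx.strand, tts)
    far = dist is None or dist > config.tts_distance

    w = config.a_window
    if tx.strand == "+":
        window = genome.fetch(tx.chrom, tts + 1, tts + 1 + w, "+")
    else:
        window = genome.fetch(tx.chrom, tts - w, tts, "-")
    a_rich = bool(window) and window.count("A") / len(window) > config.a_fraction

    no_db = not polyA_db.overlaps(tx.chrom, tts, slack=config.polya_slack)
    return far, a_rich, no_db


def junction_support_filter(
    tx: TranscriptModel,
    coverage_table: Dict[Tuple[int, int], int],
    lr_sample_count: int,
    config: QcConfig = QcConfig(),
) -> bool:
    """Pass iff every junction has >= 5 short reads, or the transcript was
    seen in >= 3 long-read samples.  Junctions absent from the coverage
    table count as zero."""
    if lr_sample_count >= config.min_lr_samples:
        return True
    chain = tx.junction_chain()
    if not chain:
        return True
    return min(coverage_table.get(j, 0) for j in chain) >= config.min_coverage


def canonical_status(junction: SpliceJunction, genome: Genome) -> str:
    """'canonical' iff the sense intron dinucleotides are GT-AG, GC-AG or AT-AC."""
    d, a = junction.donor_pos, junction.acceptor_pos
    if d < 0 or a > genome.chrom_len(junction.chrom):
        raise ValueError("junction outside contig")
    if junction.strand == "+":
        first2 = genome.fetch(junction.chrom, d, d + 2)
        last2 = genome.fetch(junction.chrom, a - 2, a)
    else:
        first2 = genome.fetch(junction.chrom, a - 2, a, "-")
        last2 = genome.fetch(junction.chrom, d, d + 2, "-")
    return "canonical" if (first2, last2) in CANONICAL_PAIRS else "noncanonical"


def _has_common_kmer(w1: str, w2: str, k: int) -> bool:
    if len(w1) < k or len(w2) < k:
        return False
    kmers = {w1[i : i + k] for i in range(len(w1) - k + 1)}
    return any(w2[i : i + k] in kmers for i in range(len(w2) - k + 1))


def detect_rt_switch(junction: SpliceJunction, genome: Genome, k: int = 8) -> bool:
    """Direct-repeat test for RT template switching.

    Compares the 2k-nt window spanning the donor exon/intron boundary with
    the 2k-nt window spanning the acceptor boundary (both in sense
    orientation); flags the junction when they share an exact repeat of
    length >= k.  Windows running off the contig are truncated.
    """
    d, a = junction.donor_pos, junction.acceptor_pos
    if junction.strand == "+":
        donor_w = genome.fetch(junction.chrom, d - k, d + k)
        accept_w = genome.fetch(junction.chrom, a - k, a + k)
    else:
        donor_w = genome.fetch(junction.chrom, a - k, a + k, "-")
        accept_w = genome.fetch(junction.chrom, d - k, d + k, "-")
    return _has_common_kmer(donor_w, accept_w, k)


def detect_intron_retention(
    query: TranscriptModel, ref: ReferenceIndex
) -> Optional[str]:
    """Intron-retention class code (m, n, i, y) or None.

    Codes follow gffcompare semantics: ``m`` - the query retains reference
    intron(s) and its own junctions are otherwise consistent with that
    reference transcript; ``n`` - retention with a partially matching
    chain; ``i`` - query fully inside a reference intron with no exonic
    overlap; ``y`` - a reference transcript is fully contained within a
    query intron.
    """
    best: Optional[str] = None
    rank = {"m": 4, "n": 3, "y": 2, "i": 1}
    qjx = set(query.junction_chain())
    qintrons = [(i.start, i.end) for i in query.introns()]
    for t in ref.transcripts.values():
        if t.chrom != query.chrom or t.strand != query.strand:
            continue
        if t.end <= query.start or query.end <= t.start:
            continue
        tjx = set(t.junction_chain())
        exonic = any(
            qe.overlap_len(te) > 0 for qe in query.exons for te in t.exons
        )
        code: Optional[str] = None
        if exonic:
            retained = [
                (i.start, i.end)
                for i in t.introns()
                if any(e.start < i.start and i.end < e.end for e in query.exons)
            ]
            if retained:
                other = [
                    (i.start, i.end)
                    for i in t.introns()
                    if (i.start, i.end) not in retained
                    and query.start < i.start
                    and i.end < query.end
                ]
                code = "m" if all(j in qjx for j in other) else "n"
        else:
            if any(
                i.start <= query.start and query.end <= i.end for i in t.introns()
            ):
                code = "i"
        if code is None and any(
            s <= t.start and t.end <= e for s, e in qintrons
        ):
            code = "y"
        if code and (best is None or rank[code] > rank[best]):
            best = code
    return best


# --- flag assembly and policy ------------------------------------------


def compute_qc_flags(
    tx: TranscriptModel,
    genome: Genome,
    ref: ReferenceIndex,
    polyA_db: PeakIndex,
    coverage_table: Dict[Tuple[int, int], int],
    lr_sample_count: int = 1,
    config: QcConfig = QcConfig(),
) -> QcFlags:
    far, a_rich, no_db = detect_intrapriming(tx, genome, polyA_db, ref, config)
    flags = QcFlags(
        transcript_id=tx.transcript_id,
        far_from_tts=far,
        a_rich_downstream=a_rich,
        no_polyA_db_overlap=no_db,
        lr_sample_count=lr_sample_count,
        junction_short_read_coverage={
            j: coverage_table.get(j, 0) for j in tx.junction_chain()
        },
        intron_retention_code=detect_intron_retention(tx, ref),
    )
    for jx in tx.junctions():
        if canonical_status(jx, genome) == "noncanonical":
            flags.noncanonical_junctions.append(jx)
        if detect_rt_switch(jx, genome, k=config.rt_switch_k):
            flags.rt_switch_junctions.append(jx)
    return flags


#: filters gating each structural category (FSM intentionally empty)
POLICY: Dict[StructuralCategory, Tuple[str, ...]] = {
    StructuralCategory.FSM: (),
    StructuralCategory.ISM: ("unreliable_3prime",),
    StructuralCategory.NIC: ("unreliable_3prime", "coverage", "intron_retention"),
    StructuralCategory.NNC: (
        "unreliable_3prime",
        "coverage",
        "intron_retention",
        "rt_switch",
        "noncanonical",
    ),
    StructuralCategory.ANTISENSE: ("coverage", "intron_retention", "rt_switch", "noncanonical"),
    StructuralCategory.INTERGENIC: ("coverage", "intron_retention", "rt_switch", "noncanonical"),
    StructuralCategory.FUSION: ("coverage", "intron_retention", "rt_switch", "noncanonical"),
    StructuralCategory.GENIC: ("coverage", "intron_retention", "rt_switch", "noncanonical"),
}


def apply_filter_policy(
    call: StructuralCall, flags: QcFlags, config: QcConfig = QcConfig()
) -> FilterDecision:
    """Apply the per-category keep policy; reasons list the failing filters."""
    if call.category not in POLICY:
        raise ValueError(f"unknown category {call.category!r}")
    checks = {
        "unreliable_3prime": lambda: flags.unreliable_3prime,
        "coverage": lambda: not _coverage_pass(flags, config),
        "intron_retention": lambda: flags.intron_retention_code is not None,
        "rt_switch": lambda: bool(flags.rt_switch_junctions),
        "noncanonical": lambda: bool(flags.noncanonical_junctions),
    }
    reasons = [name for name in POLICY[call.category] if checks[name]()]
    return FilterDecision(call.transcript_id, call.category, not reasons, reasons)


def _coverage_pass(flags: QcFlags, config: QcConfig) -> bool:
    if flags.lr_sample_count >= config.min_lr_samples:
        return True
    cov = flags.junction_short_read_coverage
    if not cov:
        return True
    return min(cov.values()) >= config.min_coverage


# --- orthogonal end support (CAGE/ATAC/3'-seq, poly(A) motif) -----------


@dataclass
class EndSupport:
    transcript_id: str
    tss_supported: bool
    tts_supported: bool

    @property
    def supported(self) -> bool:
        return self.tss_supported and self.tts_supported


def validate_ends(
    tx: TranscriptModel,
    cage: Optional[PeakIndex],
    atac: Optional[PeakIndex],
    threeprime: Optional[PeakIndex],
    genome: Genome,
    config: QcConfig = QcConfig(),
) -> EndSupport:
    """TSS support from CAGE/ATAC peaks; TTS support from 3'-seq peaks or a
    poly(A) motif (AATAAA/ATTAAA) in the last 50 nt of the transcript."""
    w = config.end_window
    tss_ok = any(
        idx.overlaps(tx.chrom, tx.tss, slack=w)
        for idx in (cage, atac)
        if idx is not None
    )
    tts_ok = threeprime is not None and threeprime.overlaps(tx.chrom, tx.tts, slack=w)
    if not tts_ok:
        tail = tx.sequence(genome)[-config.motif_window :]
        tts_ok = any(m in tail for m in POLYA_MOTIFS)
    return EndSupport(tx.transcript_id, tss_ok, tts_ok)


def support_rate_report(
    calls: Sequence[StructuralCall],
    supports: Sequence[EndSupport],
    decisions: Optional[Sequence[FilterDecision]] = None,
) -> pd.DataFrame:
    """Per-category end-support fractions.

    Returns a frame indexed by category with columns n, tss_rate, tts_rate
    and supported_rate (both ends).  Categories with zero members are
    absent (missing, not zero).  When ``decisions`` is given, only kept
    transcripts are counted.
    """
    sup = {s.transcript_id: s for s in supports}
    kept = (
        None
        if decisions is None
        else {d.transcript_id for d in decisions if d.keep}
    )
    rows = {}
    for call in calls:
        if call.transcript_id not in sup:
            continue
        if kept is not None and call.transcript_id not in kept:
            continue
        s = sup[call.transcript_id]
        r = rows.setdefault(call.category.value, [0, 0, 0, 0])
        r[0] += 1
        r[1] += s.tss_supported
        r[2] += s.tts_supported
        r[3] += s.supported
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n", "tss", "tts", "both"]
    )
    if out.empty:
        return pd.DataFrame(columns=["n", "tss_rate", "tts_rate", "supported_rate"])
    out["tss_rate"] = out["tss"] / out["n"]
    out["tts_rate"] = out["tts"] / out["n"]
    out["supported_rate"] = out["both"] / out["n"]
    return out[["n", "tss_rate", "tts_rate", "supported_rate"]].sort_index()
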