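"""ORF selection, proteome comparison, NMD prediction, peptide classes and
ribosome-occupancy translation cutoffs.

Candidate coding regions are enumerated on the sense transcript sequence in
the three forward frames (reverse-strand frames are never read: the
transcript orientation is known).  A single best ORF per transcript is then
chosen by significant homology to a reference proteome, domain conservation,
length, and finally 5'-most start, in that order.

The NMD rule is the canonical exon-junction-complex heuristic: a transcript
is NMD-sensitive when its stop codon falls in a non-terminal exon more than
55 nt upstream of the last splice junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core import Genome, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}
HOMOLOGY_EVALUE = 1e-5


@dataclass(frozen=True)
class OrfCandidate:
    start: int  # transcript coordinate, 0-based
    stop: int  # exclusive; includes the stop codon when has_stop
    has_start: bool  # begins with ATG (False: 5'-incomplete, open at nt 0)
    has_stop: bool
    protein: str

    @property
    def key(self) -> str:
        return f"{self.start}-{self.stop}"

    @property
    def aa_len(self) -> int:
        return len(self.protein)


@dataclass
class OrfRecord:
    transcript_id: str
    orf_start: int
    orf_stop: int
    protein_seq: str
    has_start: bool = True
    has_stop: bool = True
    best_reference_hit: Optional[str] = None
    identity_pct: Optional[float] = None
    domain_set: Set[str] = field(default_factory=set)
    tm_region_count: int = 0
    localization: Optional[str] = None
    nmd_sensitive: bool = False


def _translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate()).rstrip("*")


def enumerate_orfs(tx_seq: str, min_aa: int = 100) -> List[OrfCandidate]:
    """Enumerate candidate ORFs of >= ``min_aa`` residues in the 3 forward frames.

    Every ATG is paired with its next in-frame stop (or the sequence end,
    yielding a 3'-incomplete candidate); additionally each frame open at the
    transcript start contributes a 5'-incomplete candidate when it does not
    begin with ATG.
    """
    seq = tx_seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("transcript sequence contains non-ACGTN characters")
    out: List[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops = [i for i in codon_starts if seq[i : i + 3] in STOP_CODONS]
        atgs = [i for i in codon_starts if seq[i : i + 3] == "ATG"]

        def next_stop(pos: int) -> Optional[int]:
            for s in stops:
                if s >= pos:
                    return s
            return None

        for a in atgs:
            s = next_stop(a)
            if s is None:
                cand = OrfCandidate(a, a + (n - a) // 3 * 3, True, False, _translate(seq[a:]))
            else:
                cand = OrfCandidate(a, s + 3, True, True, _translate(seq[a:s]))
            if cand.aa_len >= min_aa:
                out.append(cand)
        if frame < n and seq[frame : frame + 3] != "ATG":
            s = next_stop(frame)
            if s is None:
                cand = OrfCandidate(
                    frame, frame + (n - frame) // 3 * 3, False, False, _translate(seq[frame:])
                )
            else:
                cand = OrfCandidate(frame, s + 3, False, True, _translate(seq[frame:s]))
            if cand.aa_len >= min_aa:
                out.append(cand)
    return sorted(out, key=lambda c: (c.start, c.stop))


@dataclass(frozen=True)
class HomologyHit:
    hit: str
    bitscore: float
    evalue: float


def select_best_orf(
    transcript_id: str,
    candidates: Sequence[OrfCandidate],
    homology_hits: Optional[Dict[str, HomologyHit]] = None,
    domain_hits: Optional[Dict[str, Set[str]]] = None,
) -> Optional[OrfRecord]:
    """Pick the single best ORF, or None when the transcript is non-coding.

    Ranking: significant homology (e <= 1e-5), then bitscore, then domain
    conservation, then ORF length, then 5'-most start.  Deterministic under
    permutation of the candidate list.
    """
    if not candidates:
        return None
    homology_hits = homology_hits or {}
    domain_hits = domain_hits or {}

    def rank(c: OrfCandidate):
        h = homology_hits.get(c.key)
        sig = h is not None and h.evalue <= HOMOLOGY_EVALUE
        bit = h.bitscore if sig else 0.0
        return (-int(sig), -bit, -int(bool(domain_hits.get(c.key))), -c.aa_len, c.start)

    best = min(candidates, key=rank)
    h = homology_hits.get(best.key)
    return OrfRecord(
        transcript_id=transcript_id,
        orf_start=best.start,
        orf_stop=best.stop,
        protein_seq=best.protein,
        has_start=best.has_start,
        has_stop=best.has_stop,
        best_reference_hit=h.hit if h and h.evalue <= HOMOLOGY_EVALUE else None,
        domain_set=set(domain_hits.get(best.key, set())),
    )


_aligner: Optional[PairwiseAligner] = None


def _get_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = PairwiseAligner()
        _aligner.mode = "global"
        _aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    _aligner.open_gap_score = -gap_open
    _aligner.extend_gap_score = -gap_extend
    return _aligner


def global_identity(
    query_protein: str,
    reference_protein: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Needleman-Wunsch global percent identity (matches / alignment length).

    BLOSUM62 scoring with affine gaps (open 10, extend 0.5) over the full
    lengths of both sequences.
    """
    if not query_protein or not reference_protein:
        raise ValueError("empty protein sequence")
    aligner = _get_aligner(gap_open, gap_extend)
    aln = aligner.align(query_protein, reference_protein)[0]
    c = aln.counts()
    return 100.0 * c.identities / (c.gaps + c.identities + c.mismatches)


@dataclass
class ProteinDelta:
    transcript_id: str
    novel_protein: bool
    domains_gained: Set[str] = field(default_factory=set)
    domains_lost: Set[str] = field(default_factory=set)
    tm_gained: int = 0
    tm_lost: int = 0
    localization_switch: bool = False


def compare_to_reference(
    orf: OrfRecord,
    reference_proteome: Dict[str, str],
    reference_domains: Optional[Dict[str, Set[str]]] = None,
    reference_tm: Optional[Dict[str, int]] = None,
    reference_localization: Optional[Dict[str, str]] = None,
    novel_identity_threshold: float = 99.0,
) -> ProteinDelta:
    """Protein-level deltas against the closest reference proteome entry.

    An ORF is "novel" when its global identity to the closest hit is below
    99% (or when it has no reference hit at all, in which case the deltas
    are undefined and left empty).
    """
    hit = orf.best_reference_hit
    if hit is None or hit not in reference_proteome:
        return ProteinDelta(orf.transcript_id, novel_protein=True)
    ident = orf.identity_pct
    if ident is None:
        ident = global_identity(orf.protein_seq, reference_proteome[hit])
        orf.identity_pct = ident
    ref_dom = (reference_domains or {}).get(hit, set())
    ref_tm = (reference_tm or {}).get(hit, 0)
    ref_loc = (reference_localization or {}).get(hit)
    return ProteinDelta(
        transcript_id=orf.transcript_id,
        novel_protein=ident < novel_identity_threshold,
        domains_gained=orf.domain_set - ref_dom,
        domains_lost=ref_dom - orf.domain_set,
        tm_gained=max(0, orf.tm_region_count - ref_tm),
        tm_lost=max(0, ref_tm - orf.tm_region_count),
        localization_switch=(
            orf.localization is not None
            and ref_loc is not None
            and orf.localization != ref_loc
        ),
    )


def predict_nmd(orf: OrfRecord, tx: TranscriptModel, min_distance: int = 55) -> bool:
    """Exon-junction-complex NMD rule.

    True iff the first base of the stop codon lies in a non-terminal exon
    and more than ``min_distance`` nt upstream of the last splice junction
    (both in transcript coordinates).  Mono-exon transcripts and ORFs
    without a stop codon are never NMD-sensitive.
    """
    if orf.orf_stop > tx.length:
        raise ValueError("ORF extends past transcript end")
    if tx.n_exons < 2 or not orf.has_stop:
        return False
    stop_pos = orf.orf_stop - 3
    exon_lengths = [len(e) for e in tx.exons]
    if tx.strand == "-":
        exon_lengths = exon_lengths[::-1]
    last_junction_pos = sum(exon_lengths[:-1])
    if stop_pos >= last_junction_pos:  # stop in the terminal exon
        return False
    return last_junction_pos - stop_pos > min_distance


class PeptideClass:
    UNIQUE_PACBIO = "unique_PacBio"
    NON_UNIQUE_PACBIO = "non_unique_PacBio"
    NONUNIQUE_PACBIO_UNIPROT = "nonunique_PacBio_UniProt"
    MULTIGENE = "multigene"


def classify_peptide(
    peptide: str,
    orf_db: Sequence[Tuple[str, str, str]],
    reference_proteome: Iterable[str],
    min_len: int = 6,
) -> Optional[str]:
    """Assign a peptide-spectrum match to one of the four evidence classes.

    ``orf_db`` holds (orf_id, gene_id, protein_seq) for the long-read ORFs.
    Exact substring matching; ``multigene`` takes precedence when matches
    span more than one gene.  Peptides matching no long-read ORF return
    None (they carry no isoform evidence).
    """
    if len(peptide) < min_len:
        raise ValueError(f"peptide shorter than {min_len} aa")
    fl_hits = [(oid, gid) for oid, gid, seq in orf_db if peptide in seq]
    ref_hits = sum(1 for seq in reference_proteome if peptide in seq)
    if not fl_hits:
        return None
    genes = {gid for _, gid in fl_hits}
    if len(genes) > 1:
        return PeptideClass.MULTIGENE
    if ref_hits > 0:
        return PeptideClass.NONUNIQUE_PACBIO_UNIPROT
    if len(fl_hits) == 1:
        return PeptideClass.UNIQUE_PACBIO
    return PeptideClass.NON_UNIQUE_PACBIO


@dataclass
class TranslationCutoffs:
    f1_cutoff: float
    pme_cutoff: float
    min_reads: int = 10


def derive_translation_cutoffs(
    metrics: pd.DataFrame,
    housekeeping_ids: Set[str],
    target_frac: float = 0.8,
    min_reads: int = 10,
) -> TranslationCutoffs:
    """Largest (f1, pme) cutoff pair keeping >= ``target_frac`` of
    housekeeping ORFs classified as translated.

    ``metrics`` has columns orf_id, f1, pme, reads.  The search grid is the
    set of observed housekeeping metric values (rows with sufficient
    reads); among feasible pairs the one maximizing f1 + pme is chosen,
    ties broken by larger f1.
    """
    if not housekeeping_ids:
        raise ValueError("empty housekeeping set")
    hk = metrics[metrics["orf_id"].isin(housekeeping_ids)]
    if hk.empty:
        raise ValueError("no housekeeping ids present in metrics")
    n = len(hk)
    ok_reads = hk["reads"] >= min_reads
    f1_grid = sorted(set(hk.loc[ok_reads, "f1"]))
    pme_grid = sorted(set(hk.loc[ok_reads, "pme"]))
    best: Optional[Tuple[float, float]] = None
    f1v = hk["f1"].to_numpy()
    pmev = hk["pme"].to_numpy()
    okr = ok_reads.to_numpy()
    for a in f1_grid:
        for b in pme_grid:
            frac = ((f1v >= a) & (pmev >= b) & okr).sum() / n
            if frac >= target_frac:
                if best is None or (a + b, a) > (best[0] + best[1], best[0]):
                    best = (a, b)
    if best is None:
        raise ValueError(
            "no feasible cutoffs: fewer than target_frac housekeeping ORFs "
            f"have >= {min_reads} reads"
        )
    return TranslationCutoffs(best[0], best[1], min_reads)


def classify_translated(metrics: pd.DataFrame, cutoffs: TranslationCutoffs) -> pd.Series:
    """Per-ORF translated call: f1 and pme above the cutoffs and >= 10 reads."""
    return (
        (metrics["f1"] >= cutoffs.f1_cutoff)
        & (metrics["pme"] >= cutoffs.pme_cutoff)
        & (metrics["reads"] >= cutoffs.min_reads)
    )


def annotate_transcript(
    tx: TranscriptModel,
    genome: Genome,
    homology_hits: Optional[Dict[str, HomologyHit]] = None,
    domain_hits: Optional[Dict[str, Set[str]]] = None,
    min_aa: int = 100,
) -> Optional[OrfRecord]:
    """Enumerate, select and NMD-annotate the best ORF of one transcript."""
    cands = enumerate_orfs(tx.sequence(genome), min_aa=min_aa)
    rec = select_best_orf(tx.transcript_id, cands, homology_hits, domain_hits)
    if rec is not None:
        rec.nmd_sensitive = predict_nmd(rec, tx)
    return rec
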