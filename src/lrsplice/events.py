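"""Local alternative-splicing event extraction and PSI quantification.

Seven event types are extracted from a transcript annotation, following the
local-event conventions of SUPPA-style generators: skipped exon (SE),
mutually exclusive exons (MX), alternative 5'/3' splice site (A5SS/A3SS),
retained intron (RI), and alternative first/last exon (AF/AL).  Each event
carries disjoint inclusion and exclusion transcript sets within one gene,
and PSI per sample is the inclusion fraction of event-relevant abundance:

    PSI = sum TPM(inclusion) / (sum TPM(inclusion) + sum TPM(exclusion))

masked as missing when the denominator falls below ``min_total_tpm``.

Overlap thresholds mirror the cited event-generator flags: first/last exons
whose genomic spans overlap by more than ``af_al_threshold`` (default 250
bp) are treated as one variant rather than alternative, and for local
events alternative boundaries closer than ``local_threshold`` (default 10
bp) are merged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import TranscriptModel

EVENT_TYPES = ("SE", "MX", "A5SS", "A3SS", "RI", "AF", "AL")


@dataclass
class AsEvent:
    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    coordinates: Tuple[int, ...]
    inclusion_transcripts: Set[str] = field(default_factory=set)
    exclusion_transcripts: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: inclusion/exclusion sets overlap")


def _txs_with_junction(txs: Sequence[TranscriptModel], j: Tuple[int, int]) -> Set[str]:
    return {t.transcript_id for t in txs if j in set(t.junction_chain())}


def _txs_with_exon(txs: Sequence[TranscriptModel], exon: Tuple[int, int]) -> Set[str]:
    return {
        t.transcript_id
        for t in txs
        if any(e.start == exon[0] and e.end == exon[1] for e in t.exons)
    }


def extract_events(
    transcripts: Sequence[TranscriptModel],
    af_al_threshold: int = 250,
    local_threshold: int = 10,
) -> List[AsEvent]:
    """Extract all seven local AS event types, deduplicated genome-wide by
    (gene, type, coordinates).  Single-transcript genes yield no events."""
    by_gene: Dict[str, List[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id or t.transcript_id].append(t)
    events: Dict[Tuple[str, str, Tuple[int, ...]], AsEvent] = {}

    def emit(
        gene: str,
        etype: str,
        chrom: str,
        strand: str,
        coords: Tuple[int, ...],
        inclusion: Set[str],
        exclusion: Set[str],
    ) -> None:
        exclusion = exclusion - inclusion
        if not inclusion or not exclusion:
            return
        key = (gene, etype, coords)
        ev = events.get(key)
        if ev is None:
            eid = f"{gene};{etype}:{chrom}:" + "-".join(map(str, coords)) + f":{strand}"
            events[key] = AsEvent(
                eid, gene, etype, chrom, strand, coords, set(inclusion), set(exclusion)
            )
        else:
            ev.inclusion_transcripts |= inclusion
            ev.exclusion_transcripts |= exclusion - ev.inclusion_transcripts

    for gene in sorted(by_gene):
        txs = sorted(by_gene[gene], key=lambda t: t.transcript_id)
        if len(txs) < 2:
            continue
        chrom, strand = txs[0].chrom, txs[0].strand
        junctions: Set[Tuple[int, int]] = set()
        for t in txs:
            junctions.update(t.junction_chain())

        _se_events(txs, junctions, gene, chrom, strand, emit)
        _mx_events(txs, gene, chrom, strand, local_threshold, emit)
        _altss_events(txs, junctions, gene, chrom, strand, local_threshold, emit)
        _ri_events(txs, junctions, gene, chrom, strand, emit)
        _afal_events(txs, gene, chrom, strand, af_al_threshold, emit)

    return sorted(events.values(), key=lambda e: e.event_id)


def _se_events(txs, junctions, gene, chrom, strand, emit) -> None:
    # exon bounded by shared flanking junctions, present vs skipped
    for t in txs:
        ch = t.junction_chain()
        for i, exon in enumerate(t.exons[1:-1], start=1):
            j1, j2 = ch[i - 1], ch[i]
            skip = (j1[0], j2[1])
            if skip in junctions:
                inc = _txs_with_junction(txs, j1) & _txs_with_junction(txs, j2)
                exc = _txs_with_junction(txs, skip)
                emit(gene, "SE", chrom, strand, (j1[0], j1[1], j2[0], j2[1]), inc, exc)


def _mx_events(txs, gene, chrom, strand, local_threshold, emit) -> None:
    # two internal exons sharing outer flanks, each excluding the other
    cassettes = []  # (flank_left, exon, flank_right, transcript)
    for t in txs:
        ch = t.junction_chain()
        for i, exon in enumerate(t.exons[1:-1], start=1):
            cassettes.append((ch[i - 1][0], (exon.start, exon.end), ch[i][1], t))
    for a in range(len(cassettes)):
        for b in range(a + 1, len(cassettes)):
            c1, e1, d1, _ = cassettes[a]
            c2, e2, d2, _ = cassettes[b]
            if c1 != c2 or d1 != d2 or e1 == e2:
                continue
            first, second = sorted([e1, e2])
            if first[1] + local_threshold > second[0]:  # overlapping/near variants
                continue
            inc_first = _txs_with_junction(txs, (c1, first[0])) & _txs_with_junction(
                txs, (first[1], d1)
            )
            inc_second = _txs_with_junction(txs, (c1, second[0])) & _txs_with_junction(
                txs, (second[1], d1)
            )
            if not inc_first or not inc_second or (inc_first & inc_second):
                continue
            # inclusion = the 5'-proximal exon in transcript orientation
            inc, exc = (
                (inc_first, inc_second) if strand == "+" else (inc_second, inc_first)
            )
            coords = (c1, first[0], first[1], second[0], second[1], d1)
            emit(gene, "MX", chrom, strand, coords, inc, exc)


def _altss_events(txs, junctions, gene, chrom, strand, local_threshold, emit) -> None:
    # junction pairs sharing one boundary; the varying side must belong to
    # overlapping exon variants and differ by more than the merge threshold
    by_right: Dict[int, Set[int]] = defaultdict(set)
    by_left: Dict[int, Set[int]] = defaultdict(set)
    for d, a in junctions:
        by_right[a].add(d)
        by_left[d].add(a)

    def exon_before(t: TranscriptModel, donor: int):
        for e in t.exons:
            if e.end == donor:
                return (e.start, e.end)
        return None

    def exon_after(t: TranscriptModel, acceptor: int):
        for e in t.exons:
            if e.start == acceptor:
                return (e.start, e.end)
        return None

    def variants_overlap(ex1, ex2) -> bool:
        # the alternative-boundary exons must be variants of the same exon
        return any(
            min(a[1], b[1]) - max(a[0], b[0]) > 0 for a in ex1 for b in ex2 if a and b
        )

    for a, donors in sorted(by_right.items()):
        ds = sorted(donors)
        for i in range(len(ds)):
            for jx in range(i + 1, len(ds)):
                d1, d2 = ds[i], ds[jx]
                if d2 - d1 <= local_threshold:
                    continue
                t1 = {t.transcript_id for t in txs if (d1, a) in t.junction_chain()}
                t2 = {t.transcript_id for t in txs if (d2, a) in t.junction_chain()}
                if not t1 or not t2:
                    continue
                ex1 = [exon_before(t, d1) for t in txs if t.transcript_id in t1]
                ex2 = [exon_before(t, d2) for t in txs if t.transcript_id in t2]
                if not variants_overlap(ex1, ex2):
                    continue
                # longer exon (shorter intron) is the inclusion form
                etype = "A5SS" if strand == "+" else "A3SS"
                emit(gene, etype, chrom, strand, (d1, a, d2, a), t2, t1)
    for d, accs in sorted(by_left.items()):
        as_ = sorted(accs)
        for i in range(len(as_)):
            for jx in range(i + 1, len(as_)):
                a1, a2 = as_[i], as_[jx]
                if a2 - a1 <= local_threshold:
                    continue
                t1 = {t.transcript_id for t in txs if (d, a1) in t.junction_chain()}
                t2 = {t.transcript_id for t in txs if (d, a2) in t.junction_chain()}
                if not t1 or not t2:
                    continue
                ex1 = [exon_after(t, a1) for t in txs if t.transcript_id in t1]
                ex2 = [exon_after(t, a2) for t in txs if t.transcript_id in t2]
                if not variants_overlap(ex1, ex2):
                    continue
                etype = "A3SS" if strand == "+" else "A5SS"
                emit(gene, etype, chrom, strand, (d, a1, d, a2), t1, t2)


def _ri_events(txs, junctions, gene, chrom, strand, emit) -> None:
    # retained form: a single exon exactly spanning spliced flanking exons
    for t in txs:
        exons = t.exons
        for i, (d, a) in enumerate(t.junction_chain()):
            fs, fe = exons[i].start, exons[i + 1].end
            retainers = _txs_with_exon(txs, (fs, fe))
            if retainers:
                spliced = {
                    u.transcript_id
                    for u in txs
                    if (d, a) in u.junction_chain()
                    and any(e.start == fs and e.end == d for e in u.exons)
                    and any(e.start == a and e.end == fe for e in u.exons)
                }
                emit(gene, "RI", chrom, strand, (fs, d, a, fe), retainers, spliced)


def _afal_events(txs, gene, chrom, strand, threshold, emit) -> None:
    multi = [t for t in txs if t.n_exons >= 2]
    # first exons in transcript orientation
    firsts, lasts = [], []
    for t in multi:
        ch = t.junction_chain()
        if strand == "+":
            firsts.append((t, (t.exons[0].start, t.exons[0].end), ch[0]))
            lasts.append((t, (t.exons[-1].start, t.exons[-1].end), ch[-1]))
        else:
            firsts.append((t, (t.exons[-1].start, t.exons[-1].end), ch[-1]))
            lasts.append((t, (t.exons[0].start, t.exons[0].end), ch[0]))

    def alt_end_events(entries, etype):
        for i in range(len(entries)):
            for jx in range(i + 1, len(entries)):
                t1, e1, j1 = entries[i]
                t2, e2, j2 = entries[jx]
                if e1 == e2:
                    continue
                # shared junction boundary on the gene-internal side
                if etype == "AF":
                    shared = (j1[1] == j2[1]) if strand == "+" else (j1[0] == j2[0])
                else:
                    shared = (j1[0] == j2[0]) if strand == "+" else (j1[1] == j2[1])
                if not shared:
                    continue
                # variants must actually differ at the distal (TSS/TTS) end
                if etype == "AF":
                    distal_differs = (e1[0] != e2[0]) if strand == "+" else (e1[1] != e2[1])
                else:
                    distal_differs = (e1[1] != e2[1]) if strand == "+" else (e1[0] != e2[0])
                if not distal_differs:
                    continue
                overlap = min(e1[1], e2[1]) - max(e1[0], e2[0])
                if overlap > threshold:  # merged into one variant
                    continue
                a, b = sorted([e1, e2])
                set_a = {
                    t.transcript_id
                    for t, e, _ in entries
                    if e == a
                }
                set_b = {
                    t.transcript_id
                    for t, e, _ in entries
                    if e == b
                }
                if set_a & set_b:
                    continue
                # inclusion = the distal variant (5'-most for AF, 3'-most for AL)
                if etype == "AF":
                    inc, exc = (set_a, set_b) if strand == "+" else (set_b, set_a)
                else:
                    inc, exc = (set_b, set_a) if strand == "+" else (set_a, set_b)
                emit(gene, etype, chrom, strand, (a[0], a[1], b[0], b[1]), inc, exc)

    alt_end_events(firsts, "AF")
    alt_end_events(lasts, "AL")


# --- PSI ---------------------------------------------------------------


@dataclass
class PsiMatrix:
    psi: pd.DataFrame  # events x samples, NaN = missing
    total: pd.DataFrame  # companion event-relevant total abundance

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("PSI outside [0, 1]")


def compute_psi(
    events: Sequence[AsEvent],
    tpm: pd.DataFrame,
    min_total_tpm: float = 1.0,
) -> PsiMatrix:
    """PSI per event and sample from a transcripts x samples TPM matrix.

    PSI = inclusion / (inclusion + exclusion); missing (NaN) when the
    denominator is below ``min_total_tpm``.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative TPM")
    psi_rows, tot_rows, index = [], [], []
    for ev in events:
        missing = (ev.inclusion_transcripts | ev.exclusion_transcripts) - set(tpm.index)
        if missing:
            raise KeyError(f"{ev.event_id}: transcripts absent from TPM: {sorted(missing)}")
        inc = tpm.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        exc = tpm.loc[sorted(ev.exclusion_transcripts)].sum(axis=0)
        total = inc + exc
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(total >= max(min_total_tpm, 1e-300), inc / total, np.nan)
        psi_rows.append(psi)
        tot_rows.append(total.to_numpy())
        index.append(ev.event_id)
    psi_df = pd.DataFrame(psi_rows, index=index, columns=tpm.columns)
    tot_df = pd.DataFrame(tot_rows, index=index, columns=tpm.columns)
    return PsiMatrix(psi_df, tot_df)


def write_ioe(events: Sequence[AsEvent], path: str) -> None:
    """Write events as an ioe-style TSV."""
    with open(path, "w") as fh:
        fh.write("seqname\tgene_id\tevent_id\tinclusion_transcripts\ttotal_transcripts\n")
        for ev in events:
            total = sorted(ev.inclusion_transcripts | ev.exclusion_transcripts)
            fh.write(
                f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t"
                f"{','.join(sorted(ev.inclusion_transcripts))}\t{','.join(total)}\n"
            )


def read_ioe(path: str) -> List[AsEvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        eid = row["event_id"]
        gene, rest = eid.split(";", 1)
        etype, chrom, coords, strand = rest.split(":")
        inc = set(str(row["inclusion_transcripts"]).split(","))
        total = set(str(row["total_transcripts"]).split(","))
        out.append(
            AsEvent(
                eid,
                gene,
                etype,
                chrom,
                strand,
                tuple(int(c) for c in coords.split("-")),
                inc,
                total - inc,
            )
        )
    return out
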