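"""Domain types, coordinate conventions and standard-format I/O.

Internal coordinates are 0-based, half-open (``start`` inclusive, ``end``
exclusive) on an explicit strand.  All conversion to and from 1-based
inclusive formats (GTF) happens at the I/O boundary and nowhere else.

A splice junction is identified by ``(chrom, donor_pos, acceptor_pos,
strand)`` where ``donor_pos`` is the first intronic base (0-based) and
``acceptor_pos`` is one past the last intronic base; exon boundaries are
matched at exact (+/- 0 bp) coordinates.  On the minus strand the
biological donor is the right-hand side of the intron, but the genomic
(left, right) pair identifies the junction unambiguously either way.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

STRANDS = ("+", "-")


class GtfError(ValueError):
    """Malformed GTF input (message carries the offending line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class SpliceJunction:
    chrom: str
    donor_pos: int  # first intronic base, 0-based (genomic left edge)
    acceptor_pos: int  # last intronic base + 1 (genomic right edge)
    strand: str

    def __post_init__(self) -> None:
        if not self.donor_pos < self.acceptor_pos:
            raise ValueError("donor_pos must be < acceptor_pos")

    @property
    def coords(self) -> Tuple[int, int]:
        return (self.donor_pos, self.acceptor_pos)


@dataclass
class TranscriptModel:
    """A stranded exon-chain transcript model in genomic coordinates.

    ``exons`` are sorted by start, non-overlapping, separated by introns of
    at least 1 bp, and all on one chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    exons: List[GenomicInterval]
    cds: Optional[List[GenomicInterval]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or touch "
                    f"({a.start}-{a.end}, {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (0-based position of first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination (0-based last base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def junctions(self) -> List[SpliceJunction]:
        return [
            SpliceJunction(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def junction_chain(self) -> Tuple[Tuple[int, int], ...]:
        """Ordered (genomic left-to-right) chain of junction coordinates."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    def introns(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def sequence(self, genome: "Genome") -> str:
        """Spliced transcript sequence in 5'->3' sense orientation."""
        s = "".join(genome.fetch(self.chrom, e.start, e.end) for e in self.exons)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (0-based, on an exon) to transcript coordinates."""
        off = 0
        for e in self.exons:
            if e.start <= pos < e.end:
                t = off + (pos - e.start)
                return t if self.strand == "+" else self.length - 1 - t
            off += len(e)
        raise ValueError(f"position {pos} not exonic in {self.transcript_id}")


class Genome:
    """In-memory genome with strand-aware sequence fetch."""

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        recs = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
        if not recs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(recs)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._seqs):
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_len(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Fetch [start, end); minus strand returns the reverse complement.

        Coordinates are clamped to the contig (windows near contig ends are
        truncated rather than erroring).
        """
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not seq:
            raise ValueError(f"empty genome record {chrom!r}")
        s = seq[max(0, start) : max(0, end)]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


class PeakIndex:
    """Interval index over BED-style peaks with overlap and nearest queries."""

    def __init__(self, intervals: Iterable[Tuple[str, int, int, Optional[str]]] = ()):
        self._trees: Dict[str, IntervalTree] = {}
        self._edges: Dict[str, List[Tuple[int, int]]] = {}
        self._sorted: Dict[str, Tuple[List[int], List[int]]] = {}
        self._n = 0
        for chrom, start, end, _strand in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._edges.setdefault(chrom, []).append((start, end))
        self._sorted.pop(chrom, None)
        self._n += 1

    def _arrays(self, chrom: str) -> Tuple[List[int], List[int]]:
        """Sorted starts and running maximum of ends (handles nesting)."""
        if chrom not in self._sorted:
            ivs = sorted(self._edges[chrom])
            starts = [s for s, _ in ivs]
            maxend: List[int] = []
            cur = -1
            for _, e in ivs:
                cur = max(cur, e)
                maxend.append(cur)
            self._sorted[chrom] = (starts, maxend)
        return self._sorted[chrom]

    def __len__(self) -> int:
        return self._n

    def overlaps(self, chrom: str, pos: int, slack: int = 0) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos - slack, pos + slack + 1))

    def nearest_distance(self, chrom: str, pos: int) -> Optional[int]:
        """Distance from ``pos`` to the closest peak (0 when inside one).

        The gap to a half-open peak [s, e) is ``s - pos`` on the left and
        ``pos - e`` on the right.
        """
        if chrom not in self._edges:
            return None
        starts, maxend = self._arrays(chrom)
        i = bisect.bisect_right(starts, pos)
        best = None
        if i > 0:
            if maxend[i - 1] > pos:
                return 0
            best = pos - maxend[i - 1]
        if i < len(starts):
            d = starts[i] - pos
            best = d if best is None else min(best, d)
        return best


ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> Dict[str, str]:
    return dict(ATTR_RE.findall(field9))


def read_gtf(path: str, attribute_keys: Sequence[str] = ()) -> List[TranscriptModel]:
    """Read exon (and CDS) features from a GTF into transcript models.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open at this boundary.  Exons are grouped by ``transcript_id``.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    genes: Dict[str, str] = {}
    order: List[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise GtfError(f"{path}:{ln}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfError(f"{path}:{ln}: non-integer coordinates") from exc
            attrd = _parse_attributes(attrs)
            tid = attrd.get("transcript_id")
            if not tid:
                raise GtfError(f"{path}:{ln}: {feature} without transcript_id")
            if strand not in STRANDS:
                raise GtfError(f"{path}:{ln}: invalid strand {strand!r}")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            target = exons if feature == "exon" else cds
            if tid not in exons and tid not in cds:
                order.append(tid)
            target.setdefault(tid, []).append(iv)
            if "gene_id" in attrd:
                genes.setdefault(tid, attrd["gene_id"])
    out = []
    for tid in order:
        if tid not in exons:
            raise GtfError(f"{path}: transcript {tid} has CDS but no exon features")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes.get(tid, ""),
                exons=exons[tid],
                cds=cds.get(tid),
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write transcripts as GTF exon/CDS features, deterministically ordered."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        key = lambda t: (t.chrom, t.start, t.transcript_id)
        for tx in sorted(transcripts, key=key):
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for e in tx.exons:
                fh.write(
                    f"{e.chrom}\tlrsplice\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
            for c in tx.cds or ():
                fh.write(
                    f"{c.chrom}\tlrsplice\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t.\t{attrs}\n"
                )


def read_bed_peaks(path: str) -> PeakIndex:
    """Read a BED3+ peak track into a queryable index (strand-agnostic)."""
    idx = PeakIndex()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            idx.add(parts[0], start, end)
    return idx


def write_bed(intervals: Iterable[Tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: List[str] = field(default_factory=list)
    junctions: Set[Tuple[int, int]] = field(default_factory=set)
    left_sites: Set[int] = field(default_factory=set)  # donor on '+', acceptor on '-'
    right_sites: Set[int] = field(default_factory=set)
    chains: Set[Tuple[Tuple[int, int], ...]] = field(default_factory=set)
    exons: Set[Tuple[int, int]] = field(default_factory=set)


class ReferenceIndex:
    """Indexed view of a reference annotation.

    Exposes per-gene donor/acceptor/junction/chain sets, a genome-wide
    interval index of gene bodies per strand, and strand-aware TSS/TTS sets.
    """

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.genes: Dict[str, GeneRecord] = {}
        self._chains: Dict[Tuple[str, str], List[Tuple[Tuple[Tuple[int, int], ...], str]]] = {}
        self._gene_trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._tts: Dict[Tuple[str, str], List[int]] = {}
        self._tss: Dict[Tuple[str, str], List[int]] = {}
        self.tss_set: Set[Tuple[str, str, int]] = set()
        self.tts_set: Set[Tuple[str, str, int]] = set()

        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {tx.transcript_id!r}")
            self.transcripts[tx.transcript_id] = tx
            gid = tx.gene_id or tx.transcript_id
            g = self.genes.get(gid)
            if g is None:
                g = self.genes[gid] = GeneRecord(
                    gid, tx.chrom, tx.strand, tx.start, tx.end
                )
            g.start = min(g.start, tx.start)
            g.end = max(g.end, tx.end)
            g.transcript_ids.append(tx.transcript_id)
            chain = tx.junction_chain()
            g.chains.add(chain)
            for d, a in chain:
                g.junctions.add((d, a))
                g.left_sites.add(d)
                g.right_sites.add(a)
            for e in tx.exons:
                g.exons.add((e.start, e.end))
            key = (tx.chrom, tx.strand)
            if chain:
                self._chains.setdefault(key, []).append((chain, tx.transcript_id))
            self._tss.setdefault(key, []).append(tx.tss)
            self._tts.setdefault(key, []).append(tx.tts)
            self.tss_set.add((tx.chrom, tx.strand, tx.tss))
            self.tts_set.add((tx.chrom, tx.strand, tx.tts))

        for g in self.genes.values():
            self._gene_trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
        for key in self._tts:
            self._tts[key] = sorted(set(self._tts[key]))
        for key in self._tss:
            self._tss[key] = sorted(set(self._tss[key]))

    # --- queries -------------------------------------------------------

    def chains_on(self, chrom: str, strand: str):
        return self._chains.get((chrom, strand), [])

    def genes_overlapping(self, chrom: str, strand: str, start: int, end: int) -> List[GeneRecord]:
        tree = self._gene_trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end)),
            key=lambda g: g.gene_id,
        )

    def nearest_tts_distance(self, chrom: str, strand: str, pos: int) -> Optional[int]:
        sites = self._tts.get((chrom, strand))
        if not sites:
            return None
        i = bisect.bisect_left(sites, pos)
        cand = []
        if i < len(sites):
            cand.append(abs(sites[i] - pos))
        if i > 0:
            cand.append(abs(sites[i - 1] - pos))
        return min(cand)

    def junction_annotated(self, jx: SpliceJunction) -> bool:
        for g in self.genes_overlapping(jx.chrom, jx.strand, jx.donor_pos, jx.acceptor_pos):
            if jx.coords in g.junctions:
                return True
        return False

    def all_left_sites(self, chrom: str, strand: str) -> Set[int]:
        out: Set[int] = set()
        for g in self.genes.values():
            if g.chrom == chrom and g.strand == strand:
                out |= g.left_sites
        return out

    def all_right_sites(self, chrom: str, strand: str) -> Set[int]:
        out: Set[int] = set()
        for g in self.genes.values():
            if g.chrom == chrom and g.strand == strand:
                out |= g.right_sites
        return out


def build_reference_index(transcripts: Sequence[TranscriptModel]) -> ReferenceIndex:
    """Build the reference index; gene ids are taken verbatim from the GTF."""
    return ReferenceIndex(transcripts)


# --- clinical sample table ---------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "group", "subtype", "survival_time", "event_observed"]


def read_samples(path: str) -> pd.DataFrame:
    """Read the per-sample clinical table.

    Columns: sample_id, group (tumor/control), optional subtype,
    survival_time (days) and event_observed (0/1).  Survival fields are
    required to be present only for tumor samples; controls never enter
    survival analysis.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_samples(df)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "sample_id" not in df or "group" not in df:
        raise ValueError("sample table needs sample_id and group columns")
    bad = set(df["group"]) - {"tumor", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    for col in ("subtype", "survival_time", "event_observed"):
        if col not in df:
            df[col] = pd.NA
    ctrl = df["group"] == "control"
    df.loc[ctrl, ["survival_time", "event_observed"]] = pd.NA
    st = pd.to_numeric(df["survival_time"], errors="coerce")
    if (st.dropna() < 0).any():
        raise ValueError("negative survival_time")
    df["survival_time"] = st
    df["event_observed"] = pd.to_numeric(df["event_observed"], errors="coerce")
    return df
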