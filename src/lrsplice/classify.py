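"""SQANTI-style structural classification of query transcripts.

Each query transcript receives exactly one structural category relative to
a reference annotation, decided on its ordered splice-junction chain:

* ``FSM``  - the chain equals a reference transcript's full chain;
* ``ISM``  - the chain equals a *consecutive* sub-chain of a reference
  transcript (a truncated model);
* ``NIC``  - only annotated donors/acceptors of the assigned gene are used
  (or every junction is individually annotated) but the chain itself is new;
* ``NNC``  - at least one splice site is absent from the assigned gene's
  annotated site sets;
* ``FUSION`` - the query's junctions span two or more non-overlapping
  annotated genes on the same strand;
* ``ANTISENSE`` / ``INTERGENIC`` - overlap only on the opposite strand /
  no gene-body overlap at all;
* ``GENIC`` - mono-exon query inside a same-strand gene without any of the
  mono-exon match rules applying.

Junction matching is exact (+/- 0 bp); transcript *end* positions are not
part of the FSM/ISM test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from sklearn.base import BaseEstimator

from .core import (
    GeneRecord,
    ReferenceIndex,
    SpliceJunction,
    TranscriptModel,
    build_reference_index,
)


class StructuralCategory(str, Enum):
    FSM = "FSM"
    ISM = "ISM"
    NIC = "NIC"
    NNC = "NNC"
    ANTISENSE = "ANTISENSE"
    INTERGENIC = "INTERGENIC"
    FUSION = "FUSION"
    GENIC = "GENIC"


NOVEL_CATEGORIES = {StructuralCategory.NIC, StructuralCategory.NNC}


@dataclass
class StructuralCall:
    transcript_id: str
    category: StructuralCategory
    assigned_gene: Optional[str] = None
    matched_reference_transcript: Optional[str] = None
    novel_junctions: List[SpliceJunction] = field(default_factory=list)
    novel_splice_sites: List[int] = field(default_factory=list)


def _is_consecutive_subchain(
    sub: Tuple[Tuple[int, int], ...], chain: Tuple[Tuple[int, int], ...]
) -> bool:
    n, m = len(sub), len(chain)
    if n == 0 or n > m:
        return False
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def _exonic_overlap(query: TranscriptModel, gene: GeneRecord) -> int:
    total = 0
    for qs, qe in ((e.start, e.end) for e in query.exons):
        for gs, ge in gene.exons:
            total += max(0, min(qe, ge) - max(qs, gs))
    return total


def _gene_body_overlap(query: TranscriptModel, gene: GeneRecord) -> int:
    return max(0, min(query.end, gene.end) - max(query.start, gene.start))


class IsoformClassifier(BaseEstimator):
    """Classify query transcripts against a reference annotation.

    Parameters
    ----------
    monoexon_end_tolerance : int
        Mono-exon queries are FSM when both boundaries match a mono-exon
        reference transcript within this many bases.
    genomewide_sites : bool
        Evaluate donor/acceptor membership for the NIC/NNC decision against
        all same-strand sites genome-wide instead of the assigned gene's
        sites only.
    """

    def __init__(self, monoexon_end_tolerance: int = 50, genomewide_sites: bool = False):
        self.monoexon_end_tolerance = monoexon_end_tolerance
        self.genomewide_sites = genomewide_sites

    # -- sklearn plumbing ------------------------------------------------

    def fit(self, reference, y=None):
        """Index the reference annotation (a ReferenceIndex or transcript list)."""
        if isinstance(reference, ReferenceIndex):
            self.reference_index_ = reference
        else:
            self.reference_index_ = build_reference_index(list(reference))
        return self

    def predict(self, queries: Sequence[TranscriptModel]) -> List[str]:
        return [call.category.value for call in self.classify(queries)]

    # -- classification --------------------------------------------------

    def classify(self, queries: Sequence[TranscriptModel]) -> List[StructuralCall]:
        if not hasattr(self, "reference_index_"):
            raise RuntimeError("classifier is not fitted")
        return [self.classify_one(q) for q in queries]

    def classify_one(self, query: TranscriptModel) -> StructuralCall:
        if query.n_exons == 0:  # defensive; TranscriptModel enforces >=1
            raise ValueError("query with zero exons")
        ref = self.reference_index_
        if query.n_exons == 1:
            return self._classify_monoexon(query, ref)
        return self._classify_multiexon(query, ref)

    # -- multi-exon ------------------------------------------------------

    def _classify_multiexon(self, query: TranscriptModel, ref: ReferenceIndex) -> StructuralCall:
        chain = query.junction_chain()
        key_chains = ref.chains_on(query.chrom, query.strand)

        fsm = sorted(tid for c, tid in key_chains if c == chain)
        if fsm:
            tid = fsm[0]
            return StructuralCall(
                query.transcript_id,
                StructuralCategory.FSM,
                assigned_gene=ref.transcripts[tid].gene_id,
                matched_reference_transcript=tid,
            )

        ism = sorted(tid for c, tid in key_chains if _is_consecutive_subchain(chain, c))
        if ism:
            tid = ism[0]
            return StructuralCall(
                query.transcript_id,
                StructuralCategory.ISM,
                assigned_gene=ref.transcripts[tid].gene_id,
                matched_reference_transcript=tid,
            )

        same = ref.genes_overlapping(query.chrom, query.strand, query.start, query.end)
        same = [g for g in same if _gene_body_overlap(query, g) > 0]
        if not same:
            return self._no_same_strand(query, ref)

        # FUSION: junctions spanning >=2 annotated genes whose bodies do not
        # overlap each other ("fusion of adjacent loci").
        hit = [g for g in same if _exonic_overlap(query, g) > 0] or same
        if len(hit) >= 2:
            disjoint = all(
                a.end <= b.start or b.end <= a.start
                for i, a in enumerate(hit)
                for b in hit[i + 1 :]
            )
            if disjoint:
                return StructuralCall(
                    query.transcript_id,
                    StructuralCategory.FUSION,
                    assigned_gene="+".join(sorted(g.gene_id for g in hit)),
                )

        gene = max(hit, key=lambda g: (_exonic_overlap(query, g), g.gene_id))

        if self.genomewide_sites:
            left = ref.all_left_sites(query.chrom, query.strand)
            right = ref.all_right_sites(query.chrom, query.strand)
            annotated_jx = lambda j: ref.junction_annotated(
                SpliceJunction(query.chrom, j[0], j[1], query.strand)
            )
        else:
            left, right = gene.left_sites, gene.right_sites
            annotated_jx = lambda j: j in gene.junctions

        novel_sites = [d for d, _ in chain if d not in left]
        novel_sites += [a for _, a in chain if a not in right]
        if novel_sites:
            return StructuralCall(
                query.transcript_id,
                StructuralCategory.NNC,
                assigned_gene=gene.gene_id,
                novel_junctions=[
                    SpliceJunction(query.chrom, d, a, query.strand)
                    for d, a in chain
                    if not annotated_jx((d, a))
                ],
                novel_splice_sites=sorted(set(novel_sites)),
            )

        return StructuralCall(
            query.transcript_id,
            StructuralCategory.NIC,
            assigned_gene=gene.gene_id,
            novel_junctions=[
                SpliceJunction(query.chrom, d, a, query.strand)
                for d, a in chain
                if not annotated_jx((d, a))
            ],
        )

    # -- mono-exon -------------------------------------------------------

    def _classify_monoexon(self, query: TranscriptModel, ref: ReferenceIndex) -> StructuralCall:
        tol = self.monoexon_end_tolerance
        # FSM: boundary match to a mono-exon reference transcript
        for tid in sorted(ref.transcripts):
            t = ref.transcripts[tid]
            if (
                t.n_exons == 1
                and t.chrom == query.chrom
                and t.strand == query.strand
                and abs(t.start - query.start) <= tol
                and abs(t.end - query.end) <= tol
            ):
                return StructuralCall(
                    query.transcript_id,
                    StructuralCategory.FSM,
                    assigned_gene=t.gene_id,
                    matched_reference_transcript=tid,
                )
        # ISM: fully contained in a reference exon (same strand)
        same = ref.genes_overlapping(query.chrom, query.strand, query.start, query.end)
        for g in same:
            for gs, ge in sorted(g.exons):
                if gs <= query.start and query.end <= ge:
                    tid = sorted(
                        tid
                        for tid in g.transcript_ids
                        if any(
                            e.start == gs and e.end == ge
                            for e in ref.transcripts[tid].exons
                        )
                    )[0]
                    return StructuralCall(
                        query.transcript_id,
                        StructuralCategory.ISM,
                        assigned_gene=g.gene_id,
                        matched_reference_transcript=tid,
                    )
        if same:
            gene = max(same, key=lambda g: (_exonic_overlap(query, g), g.gene_id))
            return StructuralCall(
                query.transcript_id, StructuralCategory.GENIC, assigned_gene=gene.gene_id
            )
        return self._no_same_strand(query, ref)

    def _no_same_strand(self, query: TranscriptModel, ref: ReferenceIndex) -> StructuralCall:
        opposite = "-" if query.strand == "+" else "+"
        anti = ref.genes_overlapping(query.chrom, opposite, query.start, query.end)
        if anti:
            return StructuralCall(
                query.transcript_id,
                StructuralCategory.ANTISENSE,
                assigned_gene=anti[0].gene_id,
            )
        return StructuralCall(query.transcript_id, StructuralCategory.INTERGENIC)


def classify_transcript(query: TranscriptModel, ref: ReferenceIndex, **params) -> StructuralCall:
    return IsoformClassifier(**params).fit(ref).classify_one(query)


def classify_catalog(
    queries: Sequence[TranscriptModel], ref: ReferenceIndex, **params
) -> Tuple[List[StructuralCall], Dict[str, int]]:
    """Classify a catalog; returns calls plus a per-category count summary."""
    calls = IsoformClassifier(**params).fit(ref).classify(queries)
    summary = {c.value: 0 for c in StructuralCategory}
    summary.update(Counter(call.category.value for call in calls))
    return calls, summary
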