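"""Synthetic genomes, annotations, isoform catalogs and cohorts with
planted ground truth.

Everything here is generated programmatically and deterministically from a
seed, at toy scale, so that every pipeline stage can be scored against a
truth table without any external download:

* a random genome whose genes have canonical GT-AG introns by construction
  (CT..AC on the forward strand for minus-strand genes);
* a query catalog with planted structural categories (reference copies,
  truncations, exon skips over annotated sites, shifted splice sites,
  antisense and intergenic transcripts) and planted artifacts (A-rich
  genomic 3' extensions emulating oligo-dT intrapriming, direct repeats at
  junctions emulating RT template switching, noncanonical splice
  dinucleotides, low junction read support, retained introns);
* a tumor/control cohort with per-event Gaussian PSI subpopulations
  (truncated to [0, 1]) and exponential survival with subpopulation
  hazards.

The generator actively removes *accidental* artifact signatures (e.g.
chance direct repeats at junctions that were not planted), so planted
truth tables are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, Genome, PeakIndex, TranscriptModel
from .qc import QcConfig, _has_common_kmer

BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (5, 8)
    exon_len: Tuple[int, int] = (100, 300)
    intron_len: Tuple[int, int] = (120, 250)
    intergenic_gap: int = 2000
    category_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "FSM": 10,
            "ISM": 10,
            "NIC": 10,
            "NNC": 10,
            "ANTISENSE": 5,
            "INTERGENIC": 5,
        }
    )
    artifact_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "intrapriming": 5,
            "rt_switch": 5,
            "noncanonical": 5,
            "low_coverage": 5,
            "intron_retention": 5,
        }
    )


# --- genome + annotation -----------------------------------------------


def make_genome_and_annotation(
    spec: FixtureSpec,
) -> Tuple[Genome, List[TranscriptModel]]:
    """Random single-chromosome genome with one reference transcript per gene.

    Strands alternate (+, -, +, ...).  Introns are canonical on their
    strand by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    seq: List[str] = []
    transcripts: List[TranscriptModel] = []
    pos = spec.intergenic_gap
    seq.append("".join(rng.choice(BASES, size=pos)))
    for gi in range(spec.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exons = []
        cur = pos
        for ei in range(n_exons):
            elen = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
            exons.append(GenomicInterval("chr1", cur, cur + elen, strand))
            cur += elen
            if ei < n_exons - 1:
                ilen = int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
                cur += ilen
        seq.append("".join(rng.choice(BASES, size=cur - pos)))
        transcripts.append(
            TranscriptModel(f"g{gi:03d}.t1", f"g{gi:03d}", exons)
        )
        gap = spec.intergenic_gap
        seq.append("".join(rng.choice(BASES, size=gap)))
        pos = cur + gap
    genome_list = list("".join(seq))
    for tx in transcripts:
        for iv in tx.introns():
            _set_canonical(genome_list, iv.start, iv.end, tx.strand, canonical=True)
    return Genome({"chr1": "".join(genome_list)}), transcripts


def _set_canonical(seq: List[str], d: int, a: int, strand: str, canonical: bool) -> None:
    if strand == "+":
        seq[d], seq[d + 1] = "G", "T"
        seq[a - 2], seq[a - 1] = ("A", "G") if canonical else ("T", "G")
    else:
        seq[d], seq[d + 1] = ("C", "T") if canonical else ("C", "A")
        seq[a - 2], seq[a - 1] = "A", "C"


# --- planted catalog ----------------------------------------------------


@dataclass
class PlantedCatalog:
    genome: Genome
    reference: List[TranscriptModel]
    queries: List[TranscriptModel]
    truth: pd.DataFrame
    coverage: Dict[Tuple[int, int], int]
    lr_sample_counts: Dict[str, int]
    polya_db: PeakIndex


def plant_query_isoforms(
    spec: FixtureSpec, genome: Genome, reference: Sequence[TranscriptModel]
) -> PlantedCatalog:
    """Plant labeled query isoforms and artifact variants on a reference."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    seq = list(genome.fetch("chr1", 0, genome.chrom_len("chr1")))
    ref = list(reference)
    plus_genes = [t for t in ref if t.strand == "+"]
    qc = QcConfig()
    k = qc.rt_switch_k

    queries: List[TranscriptModel] = []
    rows: List[Dict] = []
    coverage: Dict[Tuple[int, int], int] = {}
    lr_counts: Dict[str, int] = {}
    protected: Set[int] = set()
    counter = [0]
    used_skips: Dict[str, Set[int]] = {}
    used_shifts: Dict[str, Set[int]] = {}

    for tx in ref:
        for d, a in tx.junction_chain():
            protected.update((d, d + 1, a - 2, a - 1))

    def new_id() -> str:
        counter[0] += 1
        return f"q{counter[0]:04d}"

    def record(tx: TranscriptModel, category: str, artifact: str = "none", **flags):
        queries.append(tx)
        lr_counts.setdefault(tx.transcript_id, 1)
        row = {
            "transcript_id": tx.transcript_id,
            "gene_id": tx.gene_id,
            "category": category,
            "artifact": artifact,
            "is_intrapriming": False,
            "is_rt_switch": False,
            "is_noncanonical": False,
            "is_low_coverage": False,
            "is_intron_retention": False,
        }
        row.update(flags)
        rows.append(row)

    def pick_gene(pool: Sequence[TranscriptModel], i: int) -> TranscriptModel:
        return pool[i % len(pool)]

    def skip_exon(tx: TranscriptModel, registry: Dict[str, Set[int]]) -> Optional[TranscriptModel]:
        used = registry.setdefault(tx.gene_id, set())
        for i in range(1, tx.n_exons - 1):
            if i not in used:
                used.add(i)
                exons = [e for j, e in enumerate(tx.exons) if j != i]
                return TranscriptModel(new_id(), "", exons)
        return None

    def shift_acceptor(tx: TranscriptModel, canonical: bool) -> Optional[Tuple[TranscriptModel, Tuple[int, int]]]:
        # '+'-strand genes only: extend an intron 4 nt into the downstream exon
        used = used_shifts.setdefault(tx.gene_id, set())
        chain = tx.junction_chain()
        for i, (d, a) in enumerate(chain):
            if i in used:
                continue
            used.add(i)
            exons = list(tx.exons)
            e = exons[i + 1]
            exons[i + 1] = GenomicInterval(e.chrom, e.start + 4, e.end, e.strand)
            new_a = a + 4
            _set_canonical(seq, d, new_a, "+", canonical=canonical)
            protected.update((new_a - 2, new_a - 1))
            return TranscriptModel(new_id(), "", exons), (d, new_a)
        return None

    # -- structural categories ------------------------------------------
    for i in range(spec.category_counts.get("FSM", 0)):
        tx = pick_gene(ref, i)
        record(
            TranscriptModel(new_id(), "", list(tx.exons)), "FSM", gene_id=tx.gene_id
        )
    for i in range(spec.category_counts.get("ISM", 0)):
        tx = pick_gene([t for t in ref if t.n_exons >= 3], i)
        record(TranscriptModel(new_id(), "", list(tx.exons[1:])), "ISM", gene_id=tx.gene_id)
    for i in range(spec.category_counts.get("NIC", 0)):
        tx = pick_gene(ref, i)
        q = skip_exon(tx, used_skips)
        if q is None:
            continue
        record(q, "NIC", gene_id=tx.gene_id)
    for i in range(spec.category_counts.get("NNC", 0)):
        tx = pick_gene(plus_genes, i)
        got = shift_acceptor(tx, canonical=True)
        if got is None:
            continue
        q, _ = got
        record(q, "NNC", gene_id=tx.gene_id)
    chrom_len = len(seq)
    for i in range(spec.category_counts.get("ANTISENSE", 0)):
        tx = pick_gene(ref, 3 * i)
        opp = "-" if tx.strand == "+" else "+"
        e = tx.exons[0]
        record(
            TranscriptModel(new_id(), "", [GenomicInterval("chr1", e.start + 10, e.end - 10, opp)]),
            "ANTISENSE",
            gene_id=tx.gene_id,
        )
    for i in range(spec.category_counts.get("INTERGENIC", 0)):
        start = 100 + i * 300
        if start + 200 > spec.intergenic_gap - 200:
            start = 100 + (i % 5) * 300
        record(
            TranscriptModel(new_id(), "", [GenomicInterval("chr1", start, start + 200, "+")]),
            "INTERGENIC",
            gene_id="",
        )

    # -- artifacts -------------------------------------------------------
    n = spec.artifact_counts.get("intrapriming", 0)
    pool = [t for t in plus_genes if t.n_exons >= 3]
    for i in range(n):
        tx = pick_gene(pool, i)
        ext = 50
        e2 = tx.exons[1]
        exons = [tx.exons[0], GenomicInterval(e2.chrom, e2.start, e2.end + ext, e2.strand)]
        q = TranscriptModel(new_id(), "", exons)
        wstart = e2.end + ext
        for p in range(wstart, wstart + qc.a_window):
            seq[p] = "A"
            protected.add(p)
        record(q, "ISM", artifact="intrapriming", is_intrapriming=True, gene_id=tx.gene_id)

    n = spec.artifact_counts.get("rt_switch", 0)
    for i in range(n):
        tx = pick_gene(plus_genes, i + 3)
        got = shift_acceptor(tx, canonical=True)
        if got is None:
            continue
        q, (d, a) = got
        repeat = "".join(rng.choice(BASES, size=k))
        for off, base in enumerate(repeat):
            seq[d - k + off] = base
            seq[a + off] = base
            protected.update((d - k + off, a + off))
        record(q, "NNC", artifact="rt_switch", is_rt_switch=True, gene_id=tx.gene_id)

    n = spec.artifact_counts.get("noncanonical", 0)
    for i in range(n):
        tx = pick_gene(plus_genes, i + 1)
        got = shift_acceptor(tx, canonical=False)
        if got is None:
            continue
        q, _ = got
        record(q, "NNC", artifact="noncanonical", is_noncanonical=True, gene_id=tx.gene_id)

    n = spec.artifact_counts.get("low_coverage", 0)
    low_cov_jx: List[Tuple[int, int]] = []
    for i in range(n):
        tx = pick_gene(ref, 2 * i + 1)
        q = skip_exon(tx, used_skips)
        if q is None:
            continue
        novel = [j for j in q.junction_chain() if j not in set(tx.junction_chain())]
        low_cov_jx.extend(novel)
        record(q, "NIC", artifact="low_coverage", is_low_coverage=True, gene_id=tx.gene_id)

    n = spec.artifact_counts.get("intron_retention", 0)
    for i in range(n):
        tx = pick_gene(ref, 2 * i)
        used = used_skips.setdefault(tx.gene_id, set())
        merged = None
        # merge an internal junction only: removing a terminal junction
        # leaves a consecutive sub-chain (an ISM), not a novel chain
        for j in range(1, tx.n_exons - 2):
            if ("ri", j) not in used:
                used.add(("ri", j))
                exons = list(tx.exons)
                merged_exon = GenomicInterval(
                    exons[j].chrom, exons[j].start, exons[j + 1].end, exons[j].strand
                )
                merged = exons[:j] + [merged_exon] + exons[j + 2 :]
                break
        if merged is None:
            continue
        q = TranscriptModel(new_id(), "", merged)
        record(q, "NIC", artifact="intron_retention", is_intron_retention=True, gene_id=tx.gene_id)

    # -- coverage table and poly(A) catalog ------------------------------
    for q in queries:
        for j in q.junction_chain():
            coverage.setdefault(j, 10 + int(rng.integers(0, 40)))
    for j in low_cov_jx:
        coverage[j] = int(rng.integers(0, 5))

    polya = PeakIndex()
    for tx in ref:
        polya.add("chr1", tx.tts - 5, tx.tts + 6)

    # -- scrub accidental artifact signatures ----------------------------
    genome_obj = _scrub(seq, queries, rows, protected, k, rng)

    truth = pd.DataFrame(rows)
    return PlantedCatalog(
        genome=genome_obj,
        reference=ref,
        queries=queries,
        truth=truth,
        coverage=coverage,
        lr_sample_counts=lr_counts,
        polya_db=polya,
    )


def _scrub(
    seq: List[str],
    queries: Sequence[TranscriptModel],
    rows: Sequence[Dict],
    protected: Set[int],
    k: int,
    rng: np.random.Generator,
) -> Genome:
    """Remove chance direct repeats at junctions that were not planted."""
    planted_rt = {
        r["transcript_id"] for r in rows if r["is_rt_switch"]
    }
    letters = list("ACGT")
    for q in queries:
        if q.transcript_id in planted_rt:
            continue
        for d, a in q.junction_chain():
            for _ in range(100):
                donor_w = "".join(seq[d - k : d + k])
                accept_w = "".join(seq[a - k : a + k])
                if not _has_common_kmer(donor_w, accept_w, k):
                    break
                cands = [p for p in range(a - k, a + k) if p not in protected]
                if not cands:
                    break
                p = int(rng.choice(cands))
                seq[p] = letters[int(rng.integers(0, 4))]
    return Genome({"chr1": "".join(seq)})


def make_fixture(spec: Optional[FixtureSpec] = None) -> PlantedCatalog:
    """Genome + annotation + planted catalog in one call."""
    spec = spec or FixtureSpec()
    genome, ref = make_genome_and_annotation(spec)
    return plant_query_isoforms(spec, genome, ref)


# --- cohort simulation --------------------------------------------------


@dataclass
class PlantedEvent:
    name: str
    event_type: str = "SE"
    subpop_weight: float = 0.4  # fraction of tumors in the aberrant subpopulation
    subpop_mean: float = 0.2
    rest_mean: float = 0.7
    control_mean: float = 0.7
    sd: float = 0.05
    hazard_ratio: float = 1.0  # subpopulation-specific hazard multiplier


@dataclass
class CohortSpec:
    seed: int = 0
    n_tumor: int = 200
    n_control: int = 100
    n_null_events: int = 50
    planted: List[PlantedEvent] = field(default_factory=list)
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_rate: float = 0.3  # censoring hazard as fraction of baseline
    null_sd: float = 0.08


@dataclass
class SimulatedCohort:
    psi: pd.DataFrame  # events x samples
    samples: pd.DataFrame
    truth: pd.DataFrame  # per planted event: tumor-specific / survival flags
    memberships: Dict[str, np.ndarray]  # event -> tumor subpop indicator


def _truncnorm(rng, mean, sd, size) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate per-event PSI and survival for a tumor/control cohort.

    Tumors of each planted event are split into an aberrant subpopulation
    (weight ``subpop_weight``, PSI ~ N(subpop_mean, sd) truncated to [0,1])
    and the remainder at ``rest_mean``; controls sit at ``control_mean``.
    Null events draw every sample from a single Gaussian.  Survival is
    exponential with hazard ``baseline * hazard_ratio`` for members of a
    survival-planted subpopulation, censored by an independent exponential.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    tumors = [f"T{i:04d}" for i in range(spec.n_tumor)]
    controls = [f"C{i:04d}" for i in range(spec.n_control)]
    samples = tumors + controls

    psi_rows = {}
    memberships: Dict[str, np.ndarray] = {}
    truth_rows = []
    for pi, ev in enumerate(spec.planted):
        if not 0 < ev.subpop_weight < 1:
            raise ValueError(f"{ev.name}: infeasible subpopulation weight")
        eid = f"{ev.name};{ev.event_type}:chr1:{1000 + pi}-{2000 + pi}:+"
        member = rng.random(spec.n_tumor) < ev.subpop_weight
        vals = np.empty(len(samples))
        vals[: spec.n_tumor][member] = _truncnorm(rng, ev.subpop_mean, ev.sd, int(member.sum()))
        vals[: spec.n_tumor][~member] = _truncnorm(rng, ev.rest_mean, ev.sd, int((~member).sum()))
        vals[spec.n_tumor :] = _truncnorm(rng, ev.control_mean, ev.sd, spec.n_control)
        psi_rows[eid] = vals
        memberships[eid] = member
        truth_rows.append(
            {
                "event_id": eid,
                "planted_tumor_specific": True,
                "planted_survival": ev.hazard_ratio != 1.0,
                "planted_delta_psi": 100.0 * (ev.subpop_mean - ev.control_mean),
            }
        )
    for ni in range(spec.n_null_events):
        eid = f"null{ni:03d};SE:chr1:{5000 + ni}-{6000 + ni}:+"
        mean = rng.uniform(0.35, 0.65)
        psi_rows[eid] = _truncnorm(rng, mean, spec.null_sd, len(samples))
        truth_rows.append(
            {
                "event_id": eid,
                "planted_tumor_specific": False,
                "planted_survival": False,
                "planted_delta_psi": 0.0,
            }
        )

    psi = pd.DataFrame.from_dict(psi_rows, orient="index", columns=samples)

    hazard = np.full(spec.n_tumor, spec.baseline_hazard)
    for ev, eid in zip(spec.planted, list(psi_rows)[: len(spec.planted)]):
        if ev.hazard_ratio != 1.0:
            hazard[memberships[eid]] *= ev.hazard_ratio
    t_death = rng.exponential(1.0 / hazard)
    c_rate = max(spec.censoring_rate * spec.baseline_hazard, 1e-12)
    t_cens = rng.exponential(1.0 / c_rate, size=spec.n_tumor)
    time = np.minimum(t_death, t_cens)
    observed = t_death <= t_cens

    sdf = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["tumor"] * spec.n_tumor + ["control"] * spec.n_control,
            "subtype": pd.NA,
            "survival_time": list(np.round(time, 3)) + [pd.NA] * spec.n_control,
            "event_observed": list(observed.astype(int)) + [pd.NA] * spec.n_control,
        }
    )
    return SimulatedCohort(psi, sdf, pd.DataFrame(truth_rows), memberships)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Five planted tumor-specific events (one survival-associated, hazard
    ratio 3) among fifty null events; 200 tumors, 100 controls."""
    planted = [
        PlantedEvent(name=f"planted{i}", event_type=t, hazard_ratio=3.0 if i == 0 else 1.0)
        for i, t in enumerate(["SE", "RI", "A5SS", "AF", "MX"])
    ]
    return CohortSpec(seed=seed, planted=planted)
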