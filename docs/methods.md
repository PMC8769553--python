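# Methods

## Coordinates and junction identity

All internal coordinates are 0-based half-open on an explicit strand;
conversion to/from 1-based inclusive GTF happens only at the I/O boundary.
A splice junction is `(chrom, donor_pos, acceptor_pos, strand)` with
`donor_pos` the first intronic base and `acceptor_pos` one past the last;
junction and exon-boundary matching is exact (±0 bp). Reference gene
assignment is taken verbatim from the GTF `gene_id`; no re-clustering.

## Structural classification

Multi-exon queries are classified on their ordered junction chain: FSM when
the chain equals a reference transcript's full chain; ISM when it equals a
*consecutive* sub-chain (a non-consecutive subset is NIC); otherwise the
query is assigned to the same-strand gene with maximal exonic overlap and
called NNC if any donor/acceptor is absent from that gene's annotated site
sets (a `genomewide_sites` switch relaxes this to genome-wide sites), NIC
otherwise. FUSION requires exonic overlap with ≥2 annotated genes whose
bodies do not overlap each other. Queries with no same-strand overlap are
ANTISENSE (opposite-strand overlap) or INTERGENIC. Transcript end positions
deliberately do not enter the FSM/ISM test. Mono-exon rules (a design
choice, since junction chains are empty): FSM when both boundaries match a
mono-exon reference transcript within 50 bp; ISM when contained in a
reference exon; GENIC when overlapping a same-strand gene otherwise. Note
that a NIC made of individually annotated junctions in a novel order has,
by definition, no novel junctions — `novel_junctions` lists junctions absent
from the assigned gene's junction set and may be empty for such chains.

When several reference transcripts match (FSM/ISM), the lexicographically
smallest transcript id is reported, making classification deterministic.

## Quality filters

* **Intrapriming** (unreliable 3′ end): flagged only when all three hold —
  strand-aware distance from the query 3′ end to the nearest annotated TTS
  > 100 bp; adenine fraction of the 20-nt genomic window immediately
  downstream of the 3′ end (sense-corrected) strictly > 0.80; and no
  poly(A)-site catalog interval within ±10 bp of the 3′ end. The 20-nt
  window and ±10 bp slack are configurable defaults chosen to match common
  long-read QC practice; windows truncated at contig ends use the available
  bases.
* **Junction support**: pass iff min per-junction short-read coverage ≥ 5
  (missing junctions count as 0) OR the transcript was detected in ≥ 3
  long-read samples. The filter applies to *all* junctions of a transcript,
  not only novel ones. An alternative full-length-read-count reading of the
  long-read clause is exposed through the same `lr_sample_count` argument.
* **Canonical splice sites**: sense dinucleotides must be GT-AG, GC-AG or
  AT-AC.
* **RT switching**: the 2k-nt windows spanning the donor and acceptor
  exon/intron boundaries (sense orientation) are compared; a junction is
  flagged when they share an exact repeat of length ≥ k (default k = 8,
  found by k-mer set intersection). The repeat rule is parameterized
  because template-switch detection has no single canonical formula.
* **Intron retention**: gffcompare-style class codes. `m` — ≥1 reference
  intron fully contained in a query exon with the query's remaining
  junctions consistent with that reference transcript; `n` — retention with
  a partially matching chain; `i` — query fully inside a reference intron
  with no exonic overlap; `y` — a reference transcript fully inside a query
  intron. Priority m > n > y > i across overlapping references.

Per-category policy: FSM — no filtering; ISM — unreliable 3′ end only;
NIC — unreliable 3′ end, coverage, intron retention; NNC — those plus
RT-switch and canonical-only junctions; antisense/intergenic/fusion/genic —
coverage, intron retention, RT-switch, canonical-only. A transcript is kept
iff no gating filter fails; the failing filters are reported as reasons.

End validation: TSS supported when within 50 bp of a CAGE or ATAC peak;
TTS supported when within 50 bp of a 3′-seq peak or when AATAAA/ATTAAA
occurs in the last 50 nt of the transcript sequence.

## ORF annotation

Candidates are enumerated in the three forward frames of the sense
transcript sequence: every ATG paired with its next in-frame stop, plus a
5′-incomplete candidate per frame open at the transcript start; stop-less
3′-incomplete candidates are kept but never enter NMD calls. Default
minimum length 100 aa. The best ORF is chosen by (significant homology at
e ≤ 1e−5, bitscore, domain conservation, length, 5′-most start) — the
ordering of homology before domains and the 5′-most tie-break are
documented design choices. Homology and domain evidence arrive as
precomputed tables (running a search engine is out of scope).

Global identity uses Needleman–Wunsch with BLOSUM62, gap open 10 / extend
0.5, identity = matches / alignment length × 100 (alignment length, not
shorter-sequence length — a stated choice). NMD: sensitive iff the first
base of the stop codon lies in a non-terminal exon more than 55 nt upstream
of the last splice junction, both in transcript coordinates; mono-exon
transcripts are never NMD-sensitive. Peptides are classed as unique_PacBio /
non_unique_PacBio / nonunique_PacBio_UniProt / multigene by exact substring
matching, multigene taking precedence; peptides under 6 aa are rejected.
Ribo-seq cutoffs: the largest (f1, pme) pair on the grid of observed
housekeeping metric values such that ≥ 80% of housekeeping ORFs satisfy
f1 ≥ cutoff, pme ≥ cutoff and reads ≥ 10; among feasible pairs the one
maximizing f1 + pme wins, ties broken by larger f1 (the constraint admits
many solutions; this makes one canonical).

## AS events and PSI

Local events follow the conventions of ioe-style event generators. SE:
cassette exon with shared flanking junctions versus the skipping junction.
MX: two non-overlapping cassette exons sharing outer flanks with disjoint
inclusion sets; the 5′-proximal exon (transcript orientation) is the
inclusion form. A5SS/A3SS: junction pairs sharing one boundary whose
variant-side exons overlap; the longer exon (shorter intron) is the
inclusion form; boundaries closer than the 10-bp local threshold are merged
as one variant. RI: an exon exactly spanning two spliced flanking exons;
the retaining form is the inclusion. AF/AL: distinct first (last) exons
with a shared inner junction boundary and distinct TSS (TTS), called
alternative only when their spans overlap by at most 250 bp (the
first/last-exon threshold); the distal variant is the inclusion form.
Events are deduplicated genome-wide by (gene, type, coordinates) and ids are
deterministic strings `gene;TYPE:chrom:coords:strand`.

PSI per sample is inclusion / (inclusion + exclusion) transcript abundance,
reported missing when the denominator is below `min_total_tpm` (default
1.0 TPM; 0 reproduces raw behavior where PSI is missing only when neither
form is detected).

## GMM stratification

Per event, PSI values of all fitted samples (tumor + control, missing
removed, floor of 10 values) are modeled as a univariate Gaussian mixture
on the raw [0,1] scale. EM details: means initialized at the (1..k)/(k+1)
quantiles, pooled-variance start, equal weights, 5 restarts with means
jittered by N(0, sd/2) (best log-likelihood kept), tolerance 1e−6 on the
log-likelihood, ≤500 iterations, variance floor 1e−4 (PSI piles up at the
boundaries; the floor prevents degenerate spikes). BIC = −2·logLik +
(3k−1)·ln n (unequal-variance 1-D model, the least restrictive family);
k ∈ {1,2,3} minimizing BIC is selected and samples are hard-assigned by
maximum posterior. Components are labeled in increasing order of mean.

Subpopulations: per component, tumor/control counts, purity, ΔPSI =
100·(mean PSI of tumor members − mean PSI of *all* fitted controls)
(means, not medians; controls regardless of component membership), and a
two-sided Wilcoxon rank-sum test of tumor-member PSI against control PSI
(exact enumeration when both n ≤ 25 and no ties, otherwise the normal
approximation with tie correction). Tumor-specific: purity > 0.90, ≥ 50
tumor members, |ΔPSI| ≥ 20 points, and Wilcoxon p < 0.05 (the significance
gate is switchable since the specificity definition can be read with or
without it).

Survival: components with ≥ 30 tumor members carrying survival data are
eligible. A global log-rank test across eligible components (eligible ones
only — a documented choice) is followed by all pairwise log-rank tests with
Benjamini–Hochberg adjustment within the event; a pair is significant when
the global p and its adjusted p are both < 0.01. Kaplan–Meier and the
multi-group log-rank statistic are implemented from their defining formulas
(product-limit with right censoring; observed − expected deaths under the
hypergeometric law with the full covariance matrix) and are cross-checked
against lifelines in the test suite. Cross-event multiple-testing burden is
reported per event, not used as a gate, mirroring the per-event framing of
the procedure.

## Sample similarity

Jaccard(I_A, I_B) = |I_A ∩ I_B| / |I_A ∪ I_B| on per-sample isoform sets
(defined as 1 when both sets are empty); agglomerative clustering on
1 − Jaccard with average linkage by default (the linkage method is not
dictated by the procedure); samples are ordered lexicographically before
linkage so the dendrogram (and its newick serialization) is deterministic.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
toy scale, fully reproducible from a seed.

*Genome/annotation*: one random chromosome, 20 genes of 5–8 exons
(100–300 bp) and introns of 120–250 bp, alternating strands, canonical
GT-AG introns by construction (CT..AC on the forward strand for minus
genes), 2-kb intergenic gaps.

*Catalog*: planted FSM (copies), ISM (truncations), NIC (skips of annotated
exons), NNC (acceptors shifted +4 nt into the downstream exon, dinucleotides
reset to canonical), antisense and intergenic transcripts; artifact
variants add A-rich (20×A) genomic windows past extended 3′ ends
(intrapriming), planted 8-mer direct repeats at novel junctions
(RT-switch), noncanonical dinucleotides, junctions with <5 supporting reads
(low coverage), and merged internal exons (intron retention). The generator
*scrubs* chance direct repeats at all non-planted junctions so the truth
table is exact by construction — this is what makes precision = recall = 1
a meaningful end-to-end check rather than a statistical one.

*Cohort*: per planted event, tumors split into an aberrant subpopulation
(default weight 0.4, PSI ~ N(0.2, 0.05) truncated to [0,1] by rejection)
and a remainder at N(0.7, 0.05); controls at N(0.7, 0.05); null events draw
all samples from one Gaussian with mean U(0.35, 0.65) and sd 0.08. Survival
is exponential (baseline hazard 1/1000 per day, subpopulation hazard ratio
3 for the survival-planted event) with independent exponential censoring at
0.3× the baseline hazard (≈ 25–30% censoring). Defaults: 200 tumors, 100
controls, 5 planted events among 50 null events — large enough for the ≥50
patient and ≥30 patient gates to be exercised while keeping a full
stratification run under a minute. Truncation makes realized means deviate
slightly from the planted ones near the boundaries; truth tables record the
planted parameters and tests compare realized quantities with sampling
tolerances.

What the fixtures do *not* emulate: sequencing error and indels, alignment
ambiguity, expression-dependent detection, correlated events within genes,
non-Gaussian PSI shapes (e.g. Beta-like boundary masses beyond truncation),
covariate structure in survival. Passing tests therefore demonstrate
correctness of the implemented rules and statistical machinery, not
performance on real tumor data.

## Numerical choices and limitations

Ties in best-ORF selection fall back to the 5′-most start; classification
ties to the lexicographically smallest reference id; GMM component labels
are sorted by mean; BH adjustment uses statsmodels. Events with fewer than
10 non-missing PSI values, or with no fitted control samples, are skipped
with a logged reason. The log-rank covariance matrix is solved directly,
falling back to a pseudo-inverse for singular risk configurations. The
package does not run aligners, BLAST/HMMER/TMHMM/DeepLoc, mass-spec search
or Ribo-seq quantification — their outputs are consumed as tables; Cox
models, covariate adjustment and batch correction are out of scope.
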