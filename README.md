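# lrsplice

Long-read RNA-seq captures full-length transcript isoforms and therefore
reveals splice variants — many of them tumor-specific — that short-read
assembly cannot reconstruct. `lrsplice` implements the analysis layer of
such a platform for bulk and single-cell transcriptomics:

1. **Structural classification** of full-length transcript models against a
   reference annotation into the standard categories FSM, ISM, NIC, NNC,
   antisense, intergenic, fusion and genic, decided on exact splice-junction
   chain matching.
2. **Quality control** with five artifact filters — poly(A) intrapriming
   (3′ end >100 bp from an annotated TTS, downstream adenine fraction >80%,
   no poly(A)-site catalog overlap), short-read junction support (every
   junction ≥5 reads or the transcript seen in ≥3 long-read samples),
   noncanonical splice dinucleotides, RT-switch direct repeats at junctions,
   and intron retention — applied per structural category (FSM is never
   filtered), plus CAGE/ATAC/3′-seq end validation.
3. **Protein-level consequences**: ORF enumeration and best-ORF selection by
   homology and domain conservation, Needleman–Wunsch global identity to a
   reference proteome, domain/transmembrane/localization deltas, the 55-nt
   exon-junction NMD rule, peptide-evidence classes, and Ribo-seq
   translation cutoffs calibrated on housekeeping genes.
4. **Alternative-splicing events**: extraction of the seven local event
   types (SE, MX, A5SS, A3SS, RI, AF, AL) and PSI quantification from a
   transcript TPM matrix,
   `PSI = TPM(inclusion) / (TPM(inclusion) + TPM(exclusion))`.
5. **Patient stratification**: for every event, a univariate Gaussian
   mixture (k = 1..3, EM, BIC selection) fitted to pooled tumor + control
   PSI values; components with >90% tumor purity, ≥50 patients and
   |ΔPSI| ≥ 20 percentage points versus controls (Wilcoxon rank-sum) are
   tumor-specific subpopulations, compared for overall survival by global
   and pairwise log-rank tests (≥30 patients per subpopulation,
   Benjamini–Hochberg adjusted P < 0.01).
6. **Sample similarity**: Jaccard coefficient on per-sample isoform sets
   with average-linkage hierarchical clustering.

A synthetic-data module generates toy genomes, annotations, isoform
catalogs and tumor/control cohorts with planted ground truth, so the whole
pipeline is testable without any external download.

## Worked example

```bash
lrsplice simulate --out-dir demo --seed 3
lrsplice qc --query demo/queries.gtf --reference demo/reference.gtf \
    --genome demo/genome.fa --junction-cov demo/junction_coverage.tsv \
    --polya-db demo/polya.bed --out demo/qc.tsv
lrsplice stratify --psi demo/psi.tsv --samples demo/samples.tsv \
    --out-dir demo/strat --seed 3
```

On the seed-3 fixture the QC step keeps 50 of 75 transcripts and drops the
25 planted artifacts with their planted reasons:

```
{True: 50, False: 25}
{'unreliable_3prime': 5, 'intron_retention': 5, 'coverage': 5,
 'noncanonical': 5, 'rt_switch': 5}
```

and stratification of the simulated cohort (200 tumors, 100 controls, 5
planted tumor-specific events among 50 null events) reports

```
"n_tumor_specific_events": 5,
"n_survival_events": 1
```

i.e. all five planted events recovered with no false positives, and the one
subpopulation simulated with a 3-fold hazard flagged as survival-associated.

The same operations are available as library calls
(`IsoformClassifier`, `GmmStratifier`, `extract_events`, `compute_psi`, ...);
the estimator classes follow scikit-learn `fit`/`predict` conventions.

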