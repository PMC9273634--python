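# cleftdnm

Trio whole-genome **de novo mutation (DNM)** discovery and prioritization for
orofacial-cleft case-parent cohorts, exercised end-to-end on synthetic trio
cohorts with planted truth.

The package implements:

- **io_formats** — readers/writers for trio VCF (GT/GQ/DP, multi-allelic
  decomposition), PED, FASTA, transcript tables, frequency panels, score
  tables, evidence tables, GMT gene sets, expression matrices, and the
  pipeline's TSV outputs.
- **synthetic_cohort** — a desk-scale cohort simulator: mini-genome (22
  autosomes + X), transcript models (including a 50-exon gene), trio
  genotypes with Hardy-Weinberg background, planted DNMs, per-filter-stage
  decoys, and trios constructed to violate exactly one QC rule each. Every
  planted object is recorded in a `PlantedTruth` ledger.
- **trio_qc** — the cohort QC screen: missingness (> 10%), X-homozygosity
  sex check (inbreeding coefficient F), exact Hardy-Weinberg test
  (site-level screen at 1e-6), Mendelian-error excess (> mean + 3 SD),
  het/hom-ratio outliers (beyond 4 SD), and KING-style kinship with a
  parent-offspring window of [0.15, 0.35]. A trio is excluded iff any
  member fails any rule.
- **dnm_discovery** — the filtration funnel
  `raw -> quality_pass (GQ >= 20, DP >= 10, all members) -> denovo_config
  (parents hom-ref, child carries the alternate) -> protein_altering ->
  rare (max panel MAF <= 0.01)`, with a transcript-model consequence caller
  (stop_gained / start_lost / splice donor+acceptor / frameshift / missense
  / synonymous / intron, HGVS-like protein changes, reverse-strand aware).
- **prioritization** — CADD phred percentile bins (>= 30 top 0.1%, >= 20
  top 1%, >= 10 top 10%), SIFT/PolyPhen class labels, and the
  craniofacial-evidence join producing a Table-1-style prioritized list.
- **stability** — folding free-energy arithmetic
  (ddG = dG_folded - dG_unfolded), replicate mean/sample-SD, and the
  strict > 1 kcal/mol disease-likely rule.
- **enrichment_expression** — hypergeometric (Fisher) and EASE gene-set
  over-representation tests with nominal p < 0.05, tissue contrasts
  (maxillary vs mandibular ratios) and row-scaled heat values.
- **pipeline / cli** — orchestration, cohort cross-tabulation, Markdown
  report, and the `denovo-cleft` command line.

## CLI

```bash
denovo-cleft simulate --seed 1 --out cohort/            # synthetic cohort + truth ledger
denovo-cleft qc --cohort cohort/ --out qc/              # QC report, exclusions, retained PED
denovo-cleft discover --cohort cohort/ --ped qc/retained.ped --out disc/
denovo-cleft prioritize --cohort cohort/ --dnms disc/dnms.tsv --out prio/
denovo-cleft stability --replicates ddg_replicates.tsv --out stability.tsv
denovo-cleft enrich --genes genes.txt --gmt sets.gmt --out enrichment.tsv
denovo-cleft expression --matrix expr.tsv --genes genes.txt --out expr/
denovo-cleft run --seed 1 --out results/                # full pipeline + report.md
```

`simulate` accepts a YAML `--spec` file mirroring `CohortSpec` (number of
trios, planted QC failures, decoy counts, DNM rate, background site counts,
seed); `run` accepts a YAML `--config` with `cohort_spec`, `qc_thresholds`
and `filter_config` sections (CLI flags take precedence).

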