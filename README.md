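# pharmprio

Two-phase germline pharmacogenomic variant prioritization, implemented as a
tested, reusable pipeline:

1. **QC** — per-variant minor allele frequency, exact Hardy-Weinberg test,
   missingness filter cascade (MAF > 0.05, HWE p > 0.01, < 50% missing),
   genotype-group collapsing for sparse homozygote classes, and
   cross-platform non-reference discordance.
2. **Association** — Pearson chi-square of genotype group vs therapy
   response; Kaplan-Meier / log-rank disease-free survival with a 120-month
   study horizon; Monte-Carlo permutation-adjusted p-values (1000
   permutations for response, 100 for survival, optionally stratified by
   therapy arm); Cox (Efron ties) and logistic multivariate adjustment with
   likelihood-ratio tests; Bonferroni/Holm/Hochberg/Hommel/BH corrections.
3. **Gene-dosage gate** — variants whose heterozygote outcome is more
   extreme than both homozygotes (restricted mean survival time for DFS,
   responder proportion for response) are excluded.
4. **Prioritization** — class-appropriate in-silico deleteriousness
   consensus (strict four-tool consensus for missense; MaxEntScan/dbscSNV
   for splice sites; RegulomeDB/PINES/IW/miRNA signals for non-coding;
   CADD >= 19 upgrade), combined with PharmGKB/ClinVar evidence through a
   four-level decision matrix into a deterministic ranked validation panel.
5. **Validation phase** — panel variants re-tested with collapsing,
   permutation adjustment, multivariate adjustment, per-subtype log-rank,
   and the dosage gate.
6. **Synthetic cohorts** — HWE genotypes (with optional inbreeding
   departures), logistic planted response odds ratios, exponential
   proportional-hazards survival with censoring, CAR missingness, and
   clinical covariates, so the whole pipeline is testable with no external
   data.

## CLI

```bash
pharmprio simulate   --config sim.yaml --out cohort/          # synthetic cohort
pharmprio qc         --genotypes g.tsv --report qc.tsv        # filter cascade
pharmprio associate  --genotypes g.tsv --clinical c.tsv \
                     --test response --permutations 1000 --seed 1 --out assoc.tsv
pharmprio prioritize --assoc associations.tsv --evidence ev.tsv \
                     --max-size 58 --out panel.tsv
pharmprio run        --phase testing --config run.yaml        # full phase
```

`pharmprio run` reads a YAML config (see `pipeline.RunConfig`) naming the
genotype/clinical/evidence files, thresholds, permutation counts, covariate
lists and seed, and writes `associations.tsv`, `qc.tsv` and `panel.tsv`
(testing phase) or `validation.tsv` and `subtype_tests.tsv` (validation
phase).

## File formats

* **Genotypes**: TSV matrix (rows = variants, first column `variant_id`,
  cells `0/1/2/NA`) or VCF 4.x (GT subfield only, biallelic sites, `/` or
  `|` separators). Codes count non-reference alleles; sites where the
  non-reference allele is the cohort-major allele are flipped so code 0 is
  always the common homozygote.
* **Clinical**: TSV with columns `sample_id, arm, response, dfs_months,
  dfs_event, stage, grade, er, pr, her2, subtype, lost_to_followup`.
  Response is defined only for neoadjuvant samples; DFS fields are absent
  exactly for samples lost to follow-up.
* **Evidence**: TSV with database flags and per-tool in-silico outputs
  (see `variant_io.EVIDENCE_COLUMNS`); `.` marks a missing prediction.

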