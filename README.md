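# dispersalshare

Analysis toolkit for **shared-taxa bacterial dispersal** studies: given ASV
count tables for paired human (saliva / skin swab / feces) and doormat
samples, it computes the proportion of each human sample's ASVs that are also
present on the paired doormat — an indirect indicator of bacterial dispersal
within homes — and models that proportion against household and lifestyle
covariates.

## What it does

- **`asv_tables`** — typed data model and I/O for count tables (plain TSV and
  mothur `shared` dialects), taxonomy (semicolon lineages, bootstrap suffixes
  stripped), and sample/subject metadata with explicit missing-value handling.
- **`filtering`** — the fixed post-classification chain: lineage blacklist
  removal (Chloroplast / Mitochondria / unknown / Archaea / Eukaryota),
  whole-dataset singleton removal, strict negative-control ASV removal,
  replicate merging, and single-draw multivariate-hypergeometric rarefaction
  (fixed depth or per-sample-type minimum).
- **`shared`** — presence sets, human–mat pairing by subject and timepoint,
  the shared count / human richness statistic carried as exact (k, n) pairs,
  Table-style per-dataset summaries, and exact 2–4-set Venn partitions.
- **`distance`** — Bray-Curtis, Sørensen and Hellinger dissimilarities,
  classical PCoA, PERMANOVA (pseudo-F, free label permutation, `(1+hits)/(1+n)`
  p-values), pairwise contrasts with BH/Bonferroni adjustment, and PERMDISP
  with Weiszfeld spatial medians and the negative-eigenvalue correction.
- **`glmm`** — binomial-logit GLMM with a subject random intercept, fitted by
  Laplace-approximated maximum likelihood (adaptive Gauss-Hermite optional;
  cross-checked against lme4), plus the full forward-selection protocol:
  per-candidate interaction screening (LRT), a p-gated first entry, Δ-AIC ≥ 3
  additions, the staged missing-data rules, per-timepoint refits, and
  simulation-based (DHARMa-style) residual diagnostics.
- **`simulate`** — a generative study model (regional urban/rural taxon pools,
  subject core communities, covariate-driven dispersal on the logit scale,
  mat shedding, sequencing as multinomial draws, contaminated negative
  controls) with full ground truth for end-to-end validation.
- **`pipeline`** — orchestration of all stages with a JSON run manifest.

## CLI

```bash
dispersalshare simulate --seed 1 --out study/              # synthetic study
dispersalshare filter   --counts study/counts.tsv --taxonomy study/taxonomy.tsv \
                        --metadata study/metadata.tsv --depth auto --seed 1 --out filt/
dispersalshare shared   --rarefied filt/rarefied_counts.tsv \
                        --metadata filt/merged_metadata.tsv --out shared.tsv
dispersalshare ordinate --rarefied filt/rarefied_counts.tsv \
                        --metadata filt/merged_metadata.tsv \
                        --distance sorensen --nperm 999 --seed 1 --out ord/
dispersalshare model    --shared shared.tsv --metadata study/metadata.tsv \
                        --human-type saliva --nsim 250 --seed 1 --out models/
dispersalshare run      --config pipeline.yaml             # everything at once
```

`pipeline.yaml` keys mirror `dispersalshare.pipeline.PipelineConfig`
(`counts`, `metadata`, `taxonomy`, `out_dir`, plus seeds, `distances`,
`n_perm`, `candidates`, ...).

## Notes

- All stochastic steps (rarefaction, permutation tests, residual simulation,
  study generation) take explicit seeds; pipeline runs are bit-reproducible.
- Counts remain integers end-to-end; shared proportions are carried as
  integer (k, n) pairs into the binomial GLMM stage.
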