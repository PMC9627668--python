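# metaboline

QC, normalization and pathway-level statistics for replicate-structured
cell-line metabolomics.

The package implements an end-to-end analysis chain for a metabolite
intensity matrix measured over cell lines with biological and technical
replicates:

- **`synthetic`** — a seeded study generator (intensities, metadata,
  pathway sets, planted mutation effects, score/drug couplings) with a
  machine-readable ground-truth record, so every stage is testable offline.
- **`qc`** — replicate-ROC reproducibility metric (Euclidean distance AUC),
  per-feature Lowess injection-order correction, low-intensity injection
  removal, confluency correction, ANOVA-driven batch/plate feature filtering
  tuned by the replicate AUC, z-scoring and biological-replicate averaging.
- **`activity`** — rank-based pathway activity per cell line (rank-sum change
  vs the bulk ordering), minimum-hypergeometric (mHG) prefix statistics with
  permutation or Bonferroni calibration, doubling-time regression,
  hypergeometric over-representation (ORA) and Benjamini–Hochberg FDR.
- **`association`** — mutation–metabolite T-statistics from OLS fits with
  one-hot tissue covariates, tissue-specific fits, cross-tissue Spearman
  heterogeneity, two-group differential abundance, per-metabolite gene ranking.
- **`scorecorr`** — correlation of continuous per-line scores (program
  activity, drug ln IC50) with metabolites, |r|-ranked pathway enrichment
  with direction, drug×pathway signed profiles, drug-pair anticorrelation
  and overlay with known synergies (ZIP > 0).
- **`network`** — thresholded gene–metabolite Pearson correlation graph,
  size-filtered connected components, per-component ORA.
- **`subtype`** — driver/downstream differential-metabolite overlap,
  mutation-class (e.g. DNA-contact vs conformation) pathway association via
  Fisher's exact test, average-linkage pathway-similarity tree (Newick).
- **`permutation`** — label-adjacency clustering score with an exhaustive or
  Monte-Carlo permuted null, and cross-dataset per-metabolite concordance
  against a permuted-cell-line null.
- **`pipeline` / `cli`** — orchestration with deterministic artifacts and a
  reproducibility manifest; TSV/GMT/JSON I/O.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (replicate-ROC
ordering, drift removal, batch-filter recovery, mHG oracle equivalence and
calibration, association recovery/confounding control, OLS type-I error,
permutation exactness, network block recovery, drug-synergy construction,
closed-form checks).

## CLI

```sh
# simulate a full synthetic study
metaboline simulate --outdir run/sim --seed 1

# normalize it and compute QC metrics
metaboline qc --matrix run/sim/intensities.tsv --meta run/sim/metadata.tsv --outdir run/qc

# pathway activity on the cell-line averaged matrix
metaboline activity --matrix run/qc/cellline_avg.tsv --gmt run/sim/pathways.gmt \
    --meta run/sim/metadata.tsv --outdir run/act --seed 1

# mutation association on the z-scored matrix
metaboline associate --matrix run/qc/zscored.tsv --mutations run/sim/mutations.tsv \
    --meta run/sim/metadata.tsv --outdir run/assoc

# drug profiles + synergy overlay
metaboline drugs --matrix run/qc/zscored.tsv --drugs run/sim/drugs.tsv \
    --gmt run/sim/pathways.gmt --synergy run/sim/synergy.tsv --outdir run/drugs --seed 1

# everything at once (simulate -> qc -> activity -> association -> enrichment
# -> network -> subtype -> permutation), with a checksummed manifest
metaboline run --outdir run/full --seed 1
```

Other subcommands: `network`, `subtype`, `permtest`, `tree`. All stochastic
commands require an explicit `--seed`; identical seeds give bit-identical
outputs.

## File formats

TSV matrices (samples as rows, `#`-prefixed schema header), GMT pathway
sets (name, description, members), long-format mutation TSV
(cell_line, gene, status, protein_change, mutation_class), JSON ground
truth/manifests, Newick pathway trees.
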