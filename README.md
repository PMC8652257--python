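# modcaps

Interpretable multi-source classification with a capsule network. Each data
source (a feature group of a tabular dataset, or a gene set slicing an
expression matrix) is standardized by its own small encoder into a
"primary capsule"; a dynamic-routing capsule layer performs classification;
and the routing coupling coefficients — averaged per class — score how much
each source contributed to recognizing each class, as a co-product of
training rather than a post-hoc step.

The model is implemented in plain NumPy (float64 dense algebra) with
hand-derived, finite-difference-verified gradients; no deep-learning
framework is required.

## What it does

- **Sources**: define feature groups directly (`SourceSpec`), use the
  packaged 8-group / 71-feature variant-call layout
  (`build_variant_call_spec`), or decompose a samples × genes expression
  matrix with prior-knowledge gene sets (GMT or two-column TSV) into one
  block per TF-target set / PPI subnetwork / regulon
  (`parse_gene_sets`, `decompose_expression`). Genes missing from the
  matrix are zero-filled; overlapping sets copy their shared genes.
  `exclude_labeling_tf` removes each regulon's own TF from its target list.
- **Model**: per-source `tanh` encoders (primary capsule length `n=8`),
  prediction vectors, dynamic routing (`r=3` iterations, overwrite logits,
  L2-normalize the weighted sums on non-final iterations), squash
  nonlinearity with constant 0.5, class score = type-capsule length.
  Variant behaviors are exposed via `--normalize-every-iter` and
  `--accumulate-logits`.
- **Training**: margin loss (m+ = 0.9, m− = 0.1, λ = 0.5), Adam, stratified
  9:1 train/validation split, 9 seeded repeats by default. Evaluation:
  one-vs-rest AUC per class, accuracy, macro F1, confusion matrix. A
  permutation-importance baseline (per-feature AUC drop, groupable per
  source) and Pearson correlation of importance vectors support
  cross-model comparisons.
- **Interpretability**: per-class type-average coupling matrices, the
  overall heatmap of effective rows, repeat averaging, and top-k source
  rankings.
- **Synthetic data**: seeded generators with planted class-informative
  sources (modular layout or expression + gene sets) and ground truth, so
  the full pipeline is testable end to end without external downloads.

## CLI

```sh
# seeded synthetic dataset (presets: variant-call-like, regulon-like, planted)
modcaps simulate --preset planted --seed 7 --out sim/

# train 9 repeats; writes checkpoints, history, eval, per-repeat and
# averaged coupling heatmaps, and the top-k importance report
modcaps train --manifest sim/manifest.yaml --repeats 9 --seed 7 --out run/

# expression-matrix route with gene-set priors
modcaps train --expression expr.tsv --gene-sets sets.gmt --labels labels.tsv \
    --exclude-labeling-tf --repeats 9 --out run/

# recompute importance from checkpoints; --compare writes per-class top-k overlap
modcaps importance --checkpoint run/checkpoint_rep0.npz \
    --manifest sim/manifest.yaml --top-k 10 --out importance/

modcaps evaluate --checkpoint run/checkpoint_rep0.npz \
    --manifest sim/manifest.yaml --out eval.json
```

Run directories contain a frozen `config.yaml` (all resolved options plus
the seed) sufficient to reproduce the run exactly.

## Layout

- `src/modcaps/sources.py` — source specs, gene-set parsing, expression decomposition
- `src/modcaps/core.py` — encoders, routing, squash, model forward/backward, checkpoints
- `src/modcaps/train.py` — margin loss, Adam training loop, metrics, permutation importance
- `src/modcaps/interpret.py` — type-average couplings, overall heatmap, rankings
- `src/modcaps/simulate.py` — seeded synthetic data generators with ground truth
- `src/modcaps/io.py`, `src/modcaps/cli.py` — file formats and the `modcaps` CLI
- `tests/` — unit, property and acceptance tests; `tests/oracles.py` holds
  independent scalar-loop reference implementations
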