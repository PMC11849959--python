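# phylomix

Phylogeny-guided mixup data augmentation for microbiome abundance tables.

Synthetic training samples are generated by exchanging *probabilistic
phylogenetic profiles* between pairs of real samples: each sample is encoded
as its total abundance plus, at every internal node of a binary phylogeny,
the fraction of abundance falling into the left vs. right child subtree. A
Beta(α, α) mixing weight λ decides how many internal nodes are taken from
the partner sample (whole subtrees at a time, until roughly (1 − λ) of the
internal nodes are exchanged), abundances are rebuilt at the base sample's
sequencing depth, and labels are mixed as λ·yᵢ + (1 − λ)·yⱼ. Because the
exchange operates on branch probabilities rather than raw features, the
synthetic samples remain valid counts or compositions regardless of
sequencing-depth differences — the failure mode of naive feature mixing.

The package also ships:

- `phylomix.tree` — Newick reading, seeded polytomy resolution, pruning to
  a taxon subset, and pre-order indexing with cached subtree queries;
- `phylomix.profile` — profile construction (per-node left/right
  probabilities), path-product reconstruction of relative abundances, and
  total-abundance allocation with optional half-up rounding;
- `phylomix.augment` — the subtree-exchange augmenter plus a vanilla-mixup
  baseline sharing the same pairing and λ machinery;
- `phylomix.simdata` — a fully synthetic benchmark generator (random binary
  phylogeny, multinomial counts with variable depth, and a binary trait
  whose signal is concentrated in a few designated clades);
- `phylomix.evaluation` — CLR preprocessing and a repeated stratified
  cross-validation harness (AUROC/AUPRC on concatenated test-fold
  predictions, regression counterparts for continuous post-augmentation
  labels, pairwise one-tailed t-tests);
- `phylomix.cli` — `simulate` / `augment` / `evaluate` subcommands.

## CLI

```bash
# simulate a labeled dataset with clade-localized signal
phylomix simulate --p 200 --n 100 --effect-size 4 --seed 0 --out sim/

# augment it 3x with subtree exchange (or --method mixup)
phylomix augment --tree sim/tree.nwk --abundance sim/abundance.tsv \
    --labels sim/labels.tsv --alpha 2.0 --ratio 3.0 --seed 0 --out aug/

# compare augmentation methods under repeated 5-fold CV
phylomix evaluate --tree sim/tree.nwk --abundance sim/abundance.tsv \
    --labels sim/labels.tsv --model logistic --folds 5 --repeats 20 \
    --methods none,phylomix,vanilla_mixup --seed 0 --out eval/
```

Abundance tables are TSV/CSV with samples as rows, a `sample_id` first
column, and taxon IDs as the header; taxa must appear as leaves of the
Newick tree (the tree is pruned to the table's taxa, and any polytomies are
resolved deterministically).

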