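# Methods

`mdassoc` ranks candidate disease–metabolite associations with a gradient-boosted
classifier trained on features derived from a known-association matrix and two
side-information tables. This note defines every quantity the package computes,
states the default parameters, and records the numerical and protocol decisions
that matter for interpreting its output.

## Inputs

Three tab-separated tables:

1. **Associations** — one `(disease_id, metabolite_id)` pair per line. Read into
   a binary matrix `M` (`nd × nm`) with lexicographically sorted label
   registries; duplicate pairs collapse to one entry.
2. **Pathway membership** — `(metabolite_id, pathway_id)` pairs, read into a
   binary matrix `MP` (`np × nm`). Metabolites without any membership get an
   all-zero column.
3. **Symptom catalog** — `(disease_id, symptom_id[, count])` records with
   positive counts (default 1). `Tn` denotes the sum of all counts in the
   catalog.

## Similarity matrices

Four base matrices, two integrated ones. All are symmetric with values in
`[0, 1]`.

**Metabolite Hamming similarity (MHS).** For metabolites *i*, *j* with pathway
membership columns of `MP`:

    MHS(i, j) = 1 − (# pathways where the columns differ) / np

**Disease functional similarity (DNF).** A normalised-mutual-information-style
score over symptom sets. The entropy of a symptom set S uses *global* symptom
frequencies: `H(S) = −Σ_{s∈S} (n_s / Tn) · log2(n_s / Tn)`, where `n_s` is the
symptom's count for that disease and `Tn` is the catalog-wide total. For two
diseases:

    DNF(a, b) = 2 · H(Sa ∩ Sb) / (H(Sa) + H(Sb))

A shared symptom enters the intersection with the minimum of the two counts
(`shared_count="sum"` is available). Because the entropy terms are not a true
partition of probability mass this ratio can exceed 1; it is clamped to
`[0, 1]`. Pairs with no shared symptom, and pairs whose entropy denominator is
zero, get 0. Self-similarity is 1 for diseases with a nonempty symptom set and
0 otherwise, so the kernel fallback (below) covers symptomless diseases.

**Gaussian interaction-profile kernels (DGS, MGS).** With `V_i` the *i*-th row
(disease) or column (metabolite) of `M`:

    K(i, j) = exp(−ω · ‖V_i − V_j‖²),   ω = ω′ / mean_i(‖V_i‖²)

with `ω′ = 1` by default. The bandwidth normalisation makes the kernel
scale-free in the number of associations.

**Integration.** The integrated disease similarity `IDS` takes `DNF` where it
is nonzero and `DGS` elsewhere; `IMS` does the same with `MHS`/`MGS`. The
functional value always wins when present; the kernel fills structural zeros.

## Per-pair features

A pair `(disease i, metabolite j)` is described by the concatenation of three
families, all computed from one (possibly masked) association matrix:

- **F1 — statistical (width 14 with the default 5 histogram bins).** For each
  of the two entities: its association count (row/column sum of `M`), the mean
  of its integrated-similarity row, and the 5-bin histogram proportions of that
  row (equal-width bins on `[0, 1]`, last bin right-closed).
- **F2 — graph-theoretic (width 10).** Each similarity matrix induces a
  threshold graph with an edge wherever similarity strictly exceeds the mean of
  all matrix entries (diagonal included). Per node: degree, betweenness,
  closeness (Wasserman–Faust corrected), eigenvector centrality (dominant
  adjacency eigenvector, unit-maximum normalised, computed by direct
  eigendecomposition so disconnected graphs are handled), and PageRank
  (damping 0.85). Isolated nodes get 0 for the three path-based centralities.
- **F3 — factor-based (width 2k, default k = 20).** Rank-`k` nonnegative matrix
  factorisation `M ≈ A·B` by multiplicative updates (seeded uniform
  initialisation scaled to `sqrt(mean(M)/k)`, 500 iterations, `ε = 1e-10` in
  the denominators). The pair feature is row *i* of `A` concatenated with
  column *j* of `B`. The Frobenius reconstruction error is recorded every 10
  iterations and is non-increasing.

**Dimensionality reduction.** Raw vectors are cleaned of constant columns,
standardised, and projected onto principal components keeping ≥ 95 % of the
training variance. The standardisation and projection are fit on the training
pairs only and applied unchanged to scoring/test pairs.

## Classifier

Positives are the known associations; negatives are sampled uniformly from the
zero entries at a 1:1 ratio. The classifier is LightGBM with 300 trees, depth
7, 15 leaves, 45 histogram bins, minimum 51 samples per leaf, learning rate
0.1, run single-threaded and deterministic. A pure scikit-learn
histogram-gradient-boosting backend with matching settings is selectable.

The `goss_efb` module implements the two LightGBM sampling/bundling primitives
standalone — gradient-based one-side sampling with its estimated variance gain,
and exclusive feature bundling with exact conflict counting — so their
semantics are testable against brute-force oracles. Note one deliberate
convention choice: the sampled set B is sized as a fraction `b` of the *total*
instance count (so the gain amplifier is exactly `(1−a)/b`), because sizing it
as a fraction of the complement makes the gain estimator badly biased (we
measured mean relative deviations above 300 % on small instances). The
remainder convention stays available via `size_mode="remainder"`.

## Evaluation protocols

Both protocols retrain **everything** per fold from a masked matrix: the
held-out positives are zeroed in `M`, and the GIP kernels, integrated
similarities, F1 counts, NMF factors, PCA and classifier are all recomputed
from the masked matrix. Per-fold assertions verify the masking.

- **Leave-one-out.** Each known association in turn is masked and then ranked
  against the unconfirmed metabolites of its disease. Scores are pooled into
  one ROC/AUC; top-k counts how many held-out positives ranked within k among
  their candidates.
- **K-fold (default 5).** Positives are randomly partitioned; each fold's
  positives are masked together, and each is ranked against the unconfirmed
  metabolites of its disease — the same candidate definition as leave-one-out,
  so the two pooled AUCs are directly comparable.

AUC is the rank-based Mann–Whitney statistic (ties count ½). Precision, recall
and F1 use the 0.5 threshold on pooled scores.

## Synthetic data

The generator plants co-association blocks: diseases and metabolites are
partitioned into `n_blocks` contiguous groups, within-block pairs associate
with probability 0.3 and all others with 0.01 (defaults, 40×120 matrix,
4 blocks). Each block owns a template pathway set and symptom set; members
inherit each template bit with probability 0.9 (coherence) and draw a random
bit otherwise. A truth ledger records block memberships, templates, and the
exact expectation and standard deviation of the positive count, so tests can
check realised draws against their sampling distribution. `null_config()`
produces a matched no-signal instance: equal within/background rates (tuned to
the same expected positive count) and zero profile coherence.

## Known limitations

- **Masked-protocol scores are much lower than leaky ones, by design.** The
  evaluation rebuilds all matrix-derived features from the masked matrix. An
  alternative protocol that reuses the full-data features
  (`fast_insecure=True`, provided for comparison only) leaks each held-out
  pair's own entry into its features — through the GIP kernels, the degree
  counts, and especially the rank-20 NMF, which at desk scale can nearly
  memorise individual matrix entries. On the default planted instance the
  leaky protocol reports ≈ 0.91 LOOCV AUC while the honest protocol reports
  ≈ 0.75; published headline numbers for pipelines of this shape are typically
  produced under the leaky protocol and should be read accordingly.
- **The feature design caps honest performance below the planted ceiling.** On
  the default planted instance the Bayes-optimal per-disease ranking (the
  block-membership oracle) achieves ≈ 0.86 pooled LOOCV AUC. The pipeline's
  marginal per-entity blocks (F1, F2) cannot encode which disease–metabolite
  block *pairing* is elevated, and the rank-20 NMF trades block structure for
  entry-level fit, so the honest protocol lands ≈ 0.10 below that ceiling.
  Reducing the NMF rank toward the true block count narrows the gap.
- **Negative sampling treats unconfirmed pairs as negatives.** Some sampled
  "negatives" are unobserved true associations; AUC estimates are accordingly
  conservative.
- The DNF similarity is a non-standard normalised mutual information; its
  global-frequency entropies make it sensitive to catalog composition, which
  is why values are clamped and the kernel fallback exists.
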