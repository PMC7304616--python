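# odorspec

Predicting human odor perception of chemical mixtures — essential oils — from
their GC-MS mass spectra.

Single odorant molecules can be described by molecular-structure parameters,
but a perfume oil is a mixture of hundreds of compounds and has no single
molecular descriptor. Its electron-ionisation mass spectrum, however, *is*
defined for the mixture, and fragment peaks carry structural information about
the components. `odorspec` implements a pipeline that learns to predict, from
a mass spectrum alone, which *odor-descriptor groups* (clusters of words such
as {orange, citrus, lemon}) a human would use for the oil.

The pipeline, for oils annotated with binary descriptor sets and one of seven
essential-oil families (Herbal, Citrus, Floral, Exotic, Resin, Spicy, Woody):

1. **Spectra** — intensities at integer m/z 50–250 (201 channels) are
   extracted and each spectrum is rescaled to [0, 1] by its own maximum.
2. **Descriptor similarity** — binary annotations make near-synonyms
   ("floral", "rose") mutually exclusive, so their correlation vanishes. Each
   descriptor *d* is instead summarised by a 7-dim count vector
   `v_d[g] = #{oils of family g annotated d}`, and descriptors are compared by
   `1 − Pearson(v_i, v_j)`; alternatively by cosine distance between
   pre-trained word embeddings (any word2vec-text file works).
3. **Clustering** — UPGMA (unweighted average linkage) on either distance
   matrix, cut into k odor-descriptor groups (k = 4…8, default 5).
4. **Labels** — oil × group binary targets: 1 iff the oil carries at least one
   descriptor of the group.
5. **Model** — a sparse autoencoder 201 → K_M → D_M → K_M → 201 (sigmoid
   units; defaults K_M = 60, D_M = 20) compresses each spectrum, minimising

   ```
   E = (1/N) Σ_n Σ_k (y_kn − x_kn)² + (λ/2) Σ W² + β Σ_j KL(ρ ‖ ρ̂_j)
   ```

   with λ = 1e-4, β = 1, sparsity target ρ = 0.05. A mapping network
   D_M → 50 → 15 → k is trained on the bottleneck codes with cross-entropy.
   Both train full-batch with scaled conjugate gradient (1000 epochs each);
   composed, they form the six-layer predictor whose outputs are binarised at
   0.5 (a per-group (p, 1−p) softmax pair).
6. **Evaluation** — pooled true-positive / true-negative rates over all
   (oil, group) cells under 6-fold cross-validation (the autoencoder is
   retrained inside every fold), plus a SMOTE experiment: the training split
   (58 of 96 oils) is rebalanced per group by synthetic minority oversampling
   with DMwR-style count semantics, and both arms are scored on the identical
   untouched test split (38 oils).

A synthetic-data generator with planted spectral families, descriptor
vocabularies and toy embeddings makes every stage testable end to end without
any external data.

## Worked example

```sh
odorspec synth --seed 0 --out-dir fixtures      # synthetic 96-oil dataset
odorspec run --spectra fixtures/spectra.csv \
             --descriptors fixtures/descriptors.csv \
             --k 5 --seed 0 --out-dir demo_out
```

prints

```
wrote spectra.csv, descriptors.csv, ground_truth.csv, embeddings.vec to fixtures
[41fdd8fbea27] k=5 backend=correlation: TP 63.98% TN 89.34%
```

i.e. under 6-fold CV the predictor recovers 63.98% of the desired-positive
(oil, group) cells and 89.34% of the desired-negative cells of its own noisy
descriptor-derived labels (96 × 5 = 480 cells pooled). The noise is the
point: each synthetic oil draws descriptors from its family's vocabulary only
with probability 0.8, so many positive cells are random annotation leakage no
spectrum can predict. Scored against the generator's planted ground truth
instead (`cross_validate(..., eval_labels=truth.values)`), the same
predictions reach TP 98.96% / TN 90.10% — the pipeline recovers essentially
all the structure that is actually in the spectra.

`demo_out/` also contains the group label matrix, the dendrogram as Newick,
a JSON report, and the resolved config snapshot named by its hash. Word-
embedding clustering works the same way:

```sh
odorspec cluster --descriptors fixtures/descriptors.csv \
                 --backend word-similarity --embeddings fixtures/embeddings.vec \
                 --k 5 --out ws.nwk
```

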