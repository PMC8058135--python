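# connpred

Predict behavioral scores from functional-connectivity edges.

The package implements a complete connectome-based prediction pipeline:

1. **Data model** (`connpred.connectome_data`) — parcel atlases, symmetric
   parcel×parcel connectivity matrices, canonical upper-triangle edge
   vectorization (a 324-parcel matrix yields 52,326 edges), cohort tables
   and behavioral scores (missing allowed, deficits negative).
2. **Synthetic cohorts** (`connpred.synthetic`) — low-rank generative model
   `X = F Wᵀ + noise` with network-block-structured loadings and scores
   generated linearly from a subset of latent components; full ground truth
   is returned for parameter-recovery testing.
3. **Feature extraction** (`connpred.features`) — PCA (exact SVD, fit once
   and truncate), FastICA on PCA-whitened data, dictionary learning
   (alternating minimization with an L1 code penalty and unit-ball atoms)
   and NNMF (multiplicative updates, seeded restarts). All behind one
   linear-model contract with a comparable reconstruction-MSE and an
   `error_curve` over the default k grid 10..95 step 5 (18 feature sets).
4. **Regression** (`connpred.regression`) — elastic-net family
   `(1/2n)·RSS + λ·Σ(½(1−α)βⱼ² + α|βⱼ|)` with train-fold standardization,
   R², MSE and a non-zero-coefficient BIC.
5. **Model selection** (`connpred.model_selection`) — LOO and nested-LOO
   grid search over (k, λ, α) with λ defaulting to 100 log-spaced values in
   [1e−5, 1e5] and α ∈ {0.001, 0.25, 0.5, 0.75, 1}; nested fold-wise
   selections are aggregated by mean / median / mode snapped to the grid;
   pairwise model comparison by exact/approximate Wilcoxon signed-rank
   tests with Bonferroni correction.
6. **Predictive maps** (`connpred.maps`) — back-projection of
   (un-standardized) coefficients through the extraction weights into edge
   space, symmetric-matrix restoration, top-N edge ranking, per-parcel
   contributions and network-block summaries.
7. **Pipeline + CLI** (`connpred.pipeline`, `connpred.cli`) — a declarative
   YAML config drives the full experiment; identical config + seed gives
   byte-identical outputs.

## CLI

```bash
# generate a synthetic cohort with ground truth
connpred simulate --out data/sim --parcels 64 --subjects 100 --seed 1

# reconstruction-error curve across methods
connpred extract --cohort data/sim/cohort.csv --atlas data/sim/atlas.csv \
    --methods pca,ica --k-grid 5,10,15 --out curve.csv

# cross-validated selection for one method
connpred select --cohort data/sim/cohort.csv --atlas data/sim/atlas.csv \
    --scores data/sim/scores.csv --method pca --k-grid 5,10,15 --out sel/

# back-project saved models into an edge map
connpred maps --feature-model sel/feature_model \
    --regression-model sel/regression_model.json \
    --atlas data/sim/atlas.csv --out maps/

# end-to-end experiment from a YAML config (or --synthetic for a demo)
connpred run --config experiment.yaml
connpred report --results results/
```

A minimal YAML config:

```yaml
synthetic: {P: 64, n: 100, k_true: 10, M: 8, seed: 1}
methods: [pca, ica, dl, nnmf]
grid:
  k_values: [5, 10, 15, 20]
  lambda_min: 1.0e-5
  lambda_max: 1.0e5
  n_lambdas: 100
  alpha_values: [0.001, 0.25, 0.5, 0.75, 1.0]
scheme: loo          # or nested_loo (+ aggregation: mean|median|mode)
seed: 1
outdir: results
```

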