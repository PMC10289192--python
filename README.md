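# ambumetric

Personalized estimation of daily well-being constructs (anxiety, stress,
positive/negative affect) from multimodal ambulatory features, via a
Siamese metric-learning regressor with trait-based personalization.

The estimator learns a shared dense embedding in which the distance
between two same-participant daily samples matches the distance between
their (L2-normalized) construct labels, while a single-node head
regresses the construct from the embedding. Personalization comes from
within-participant pair formation, fine-tuning with a fraction of each
target participant's data, trait-feature augmentation (ML-AT), and
trait-cluster-specific models (ML-C: min-max scaling, 3-component PCA,
K-means with elbow-guided K, one trait-augmented model per cluster).
Baselines: a parameter-matched feed-forward regressor and semi-supervised
maximum independence domain adaptation (SMIDA) with participant-as-domain
and a linear-regression head. Evaluation is participant-independent
10-fold stratified cross-validation with per-restart Pearson scores,
one-tailed paired t-tests, GP-based hyperparameter search, and a
logistic-regression person-identification probe on raw features vs.
embeddings.

The study data is external; the `synthetic_data` module generates cohorts
with the same structure (participant-specific feature shifts, 4-cluster
trait structure, construct-driven signal, skewed label marginals, ~10%
missing feature cells), so the full pipeline is testable offline.

The model is implemented in plain numpy with hand-written gradients
(about 13k parameters), so no deep-learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `schema_io` | feature/trait/label schemas, CSV I/O, participant filter, report round-trip |
| `synthetic_data` | seeded cohort generator + missingness injection |
| `preprocessing` | linear interpolation, daily averaging, train-anchored min-max scaling, per-participant label L2-normalization |
| `pairing` | within-participant similar/dissimilar pairs (|a−b| ≤ 1) and imbalance weights |
| `metric_model` | Siamese architecture, feature/regression losses, SGD training with Pearson early stopping, fine-tune split, predict/embed |
| `personalization` | trait augmentation, trait clustering (PCA + K-means), per-cluster models |
| `baselines` | FNN baseline, HSIC, SMIDA projection + OLS head |
| `evaluation` | fold planner, experiment runner, Pearson/t-tests, GP hyperparameter search, identity probe |

## CLI

```bash
ambumetric simulate --config gen.yaml --out cohort.csv --truth truth.json
ambumetric validate --data cohort.csv --construct stress
ambumetric pairs    --data cohort.csv --construct stress --out pairs.csv
ambumetric cluster  --data cohort.csv --k 4 --out clusters.json
ambumetric evaluate --data cohort.csv --construct stress \
    --variants ml-a,ml-at,ml-c,fnn,smida --fractions 0.0,0.4,0.9 \
    --restarts 20 --out reports/
ambumetric preprocess --data cohort.csv --out normalized.csv --stats stats.json
ambumetric train    --data cohort.csv --construct stress --variant ml-a \
    --out model.json
ambumetric baseline --which smida --data cohort.csv --construct stress \
    --out reports/
ambumetric probe    --model model.json --data cohort.csv
```

`gen.yaml` holds `GeneratorConfig` fields (`n_participants`, `n_days`,
`signal_strength`, `trait_effect`, `subject_shift_scale`, `missing_rate`,
`label_skew`, `seed`, ...).

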