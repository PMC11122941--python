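# Methods

`ganfe` implements a GAN-based feature-enhancement pipeline for predicting a
rare binary outcome (incident myocardial infarction) from a high-dimensional
table of clinical variables and serum metabolites. The pipeline has three
steps: (1) an adversarial generator/discriminator pair trained on the
observed positive records produces synthetic ("feature-enhanced") positives;
(2) an autoencoder embeds observed and generated positives into three
coordinates for generative quality control; (3) a prediction MLP is trained
on the balanced mixture of observed and generated records with a custom loss
(GFE) that re-emphasizes ground-truth positives in proportion to how much
misleading information the generated data carries.

## The GFE loss

For a training batch X with observed-positive subset X′,

    GFE = BCE(X) + W · (1 − Acc(D(P))) · Acc(D(N)) · BCE(X′)

where BCE is mean binary cross entropy, D the frozen GAN discriminator,
P/N the observed positive/negative reference sets, and W the weight of the
observed portion — implemented per batch as (observed records in the batch)
/ (total training-set size), the most literal reading of "batch size over
total training number". Acc(D(P)) is the fraction of reference positives D
scores ≥ 0.5; Acc(D(N)) the fraction of reference negatives it scores
< 0.5. Negatives never enter GAN training, so Acc(D(N)) measures the
discriminator's reliability on unseen data; (1 − Acc(D(P))) measures how
much of the generated data the discriminator can still tell from real.
Acc(D(P)) and Acc(D(N)) are refreshed once per training epoch.

Consequences used as test oracles: GFE ≥ BCE(X) for every batch (all
correction factors are nonnegative), with equality whenever Acc(D(P)) = 1,
Acc(D(N)) = 0, W = 0 or X′ is empty. A worked four-record example
(p = [0.9, 0.8, 0.2, 0.6], all labels 1, first two observed,
Acc(D(P)) = 0.8, Acc(D(N)) = 0.9, W = 0.5) gives
0.6122 + 0.5·0.2·0.9·0.1643 ≈ 0.6270.

The gating is a real behavior, not a corner case: once the generator
converges, the discriminator often scores *everything* — including unseen
negatives — as "real positive", so Acc(D(N)) = 0 and the correction
deactivates, leaving plain BCE. The discriminator-reliability factor exists
precisely to switch the correction off when D's judgement carries no
information.

## Networks and training

All networks run on a small in-package numpy engine (`ganfe.nnet`): dense
layers, ReLU/LeakyReLU/sigmoid, batch normalization with running statistics,
Adam with L2-style weight decay, hand-written backpropagation (verified
against numeric gradients to ~1e-6 relative error). Everything is CPU-only
and bit-reproducible given a seed.

| network | widths | activations | optimizer defaults |
|---|---|---|---|
| discriminator | 382→200→200→200→100→1 | ReLU+BN hidden, sigmoid out | Adam, lr 5e-3, wd 1e-4 |
| generator | enc 382→300→75, dec 75→150→382 | ReLU+BN hidden | Adam, lr 5e-3, wd 1e-4 |
| QC autoencoder | 382→400→300→200→100→3, mirrored decoder | LeakyReLU | Adam, lr 1e-4 |
| prediction MLP | 382→191→95→47→1 | ReLU hidden, sigmoid out | Adam, lr 5e-5, wd 1e-4 |

The MLP's hidden widths are the input width over 2, 4 and 8 (floored,
clamped to ≥ 1 for tiny toy inputs). GAN training runs 3000 alternating 1:1
steps by default; the step count is a config parameter. MLP training runs
200 epochs at batch size 64 by default.

Generator design: the generator is an autoencoder fed real positive
records, not a noise-to-sample map; stochasticity comes from Gaussian noise
(scale σ_z, default 0.1) added at the 75-wide bottleneck. The generator
objective is the non-saturating adversarial BCE of the discriminator
scoring its outputs as real. During the generator update the discriminator
is forwarded on a concatenated real+fake batch with the loss taken on the
fake half only: with an all-fake batch the discriminator's batch
normalization would normalize away exactly the distribution shift that
separates fake from real, leaving the generator with uninformative
gradients. Generated records are clipped to [0, 1] (the min-max-scaled
feature range) at generation time but not inside the training forward pass,
where clipping would zero the gradients at the boundaries.

Batch-norm layer order is Linear → ReLU → BN (normalization after the
activation). Probabilities are clamped to [1e-12, 1 − 1e-12] inside BCE so
saturated sigmoids cannot produce infinities.

Adversarial training at the default lr 5e-3 oscillates on very easy
low-dimensional targets (the discriminator dominates); the moment-recovery
test therefore runs its toy at lr 5e-4 for 4000 steps, where the generated
per-feature means reproduce the observed means within 0.05.

## Preprocessing

Fixed order: (1) metabolite columns with **strictly more than** 20% missing
values are dropped; (2) participants missing strictly more than 10% of the
remaining metabolite columns are dropped; (3) natural-log transform of
metabolite columns (right-skewed, strictly positive ion counts; a
non-positive value is a data error naming the offending row and column);
(4) chained-equation imputation — sklearn's IterativeImputer with
mean-initialized fill, 10 sweeps, no posterior draws, giving a single
deterministic completion; (5) per-feature min-max scaling to [0, 1].
The scaler is fitted on the training partition only and applied everywhere;
constant features map to 0 and out-of-range values clip to [0, 1]. Both
boundary conventions (strict inequalities in the filters, clipping and the
constant-feature rule in the scaler) are frozen in tests.

## Partitioning

Records are clustered into three groups by k-means on a per-feature
min-max-normalized copy of the full matrix (normalization computed inside
the clustering step, used for clustering only — without it the wide-range
metabolite columns dominate the Euclidean geometry). Each group is split
64/16/20 into train/test/validation by seeded shuffling and
largest-remainder rounding, then merged. Grouping is on features, never on
the outcome, so each partition's class ratio tracks the overall ratio up to
sampling error. The GAN sees positives from train+test only; the validation
partition is touched by nothing but final evaluation.

## Resampling schedule

SMOTE and ENN are implemented from scratch (they are part of the method's
contribution surface): SMOTE draws a minority record x, one of its k = 5
nearest minority neighbours x_nn, and emits x + λ(x_nn − x) with
λ ~ U(0, 1); ENN (k = 3) deletes records whose k-nearest-neighbour majority
vote disagrees with their own label, with votes computed on the original
set and deletions applied simultaneously (order-independent); tie votes
retain the record. The iterative schedule mixes pending GAN-generated
positives into the observed training set 100 at a time; after each addition
the SMOTE+ENN pass is applied r times (default r = 2, the best-performing
configuration) and the loop stops at the first iteration where the majority
count is ≤ 1000 or the pending pool is exhausted. When the initial majority
count is already at or below the target the loop still performs one full
iteration, so every run produces a log. Provenance
(observed / gan-generated / smote-synthetic) survives all deletions.

## Synthetic cohort

The simulator is first-class code, not a fixture. Defaults replicate the
study schema: 1376 non-cases, 78 incident cases, 12 continuous clinical
variables, 7 integer-coded categoricals (five binary, a 3-level
glucose-tolerance group, a 4-level physical-activity level) and 363
metabolites — 382 features, no one-hot expansion (the downstream networks
take one input per feature).

Metabolite log-abundances follow a 10-factor latent model
(z = √0.6 · Λf + √0.4 · ε, unit-norm loading columns) before
exponentiation, so marginals are log-normal (right-skewed, strictly
positive) while the panel carries the strong cross-correlation real
metabolomics panels show through pathway-level co-regulation. This
low intrinsic dimension matters mechanically: with 363 *independent*
metabolite axes, SMOTE's interpolated points concentrate radially (the
average of two random high-dimensional points is closer to everything than
either endpoint) and become every record's nearest neighbours, letting ENN
delete the majority class wholesale — a geometry no real cohort exhibits.

Outcome labels follow a logistic model on configurable signal features; the
default plants log-odds effects on sex (1.0), glucose-tolerance group (0.6)
and physical activity (0.35) plus ±0.45 on a sparse set of 10 metabolites —
moderate, epidemiologically plausible conditional effects. The intercept is
solved numerically (Brent bracketing on a 20 000-row probe sample) so the
expected prevalence matches 78/1454, and records are drawn in batches until
the class counts are hit exactly. Planted coefficients are recoverable by
an ordinary logistic refit within ±0.15 at n = 20 000 (a frozen test).
Missingness, when requested, is MCAR on designated metabolite columns/rows;
no informative-missingness mechanism is modelled.

What the simulator does **not** emulate: the study's exact marginal
medians/IQRs, assay-specific measurement error, informative missingness,
and any nonlinearity or interaction in the outcome model. Tests passing on
this cohort show the pipeline's machinery is correct and its contracts
hold; they do not certify predictive performance on real cohort data.

## Sensitivity analysis

For each feature j in turn, every positive record has column j overwritten
by that feature's mean over the negative records (on the min-max scale the
model was trained on — the model never sees any other scale; categorical
codes are replaced by the mean code), the modified records are re-scored,
and the mean absolute score change is recorded. Changes are averaged over
replicates, ranked descending with ties broken by feature name, and the top
k (default 20) flagged. A feature the model provably ignores scores exactly
0. On planted-signal synthetic cohorts the planted features are recovered
in the top decile of the ranking (a frozen, seeded test).

## Replicate harness and determinism

The full pipeline repeats split → GAN → generate → balance → train →
evaluate → sensitivity for 10 independent splits by default and reports
means over replicates. Every stage seed is derived from
(master seed, replicate index, stage tag) through `numpy.random.SeedSequence`
(always < 2³¹), so runs are bit-reproducible and BCE-vs-GFE comparisons
share identical splits and initializations. A failed replicate is logged
and skipped; the others proceed.

## Problem sizes in tests and diagnostics

The packaged test suite exercises the full 1454 × 382 scale where the
claim depends on it (the majority-collapse comparison, the wiring counts)
and reduced cohorts or 2-feature toys elsewhere (GAN moment recovery,
convergence ordering, property tests), chosen so the whole suite runs in
about a minute on one CPU. The acceptance script trains the GAN at the
default 3000 steps on the default cohort. Energy distance
(E = 2·E‖a−b‖ − E‖a−a′‖ − E‖b−b′‖) quantifies the embedded
generated-vs-observed agreement that the three-coordinate visualization
shows qualitatively; it is nonnegative, symmetric, and 0 iff the clouds'
distributions coincide.

## Known limitations

* Adversarial training is oscillation-prone at the default learning rate on
  easy targets; the defaults are kept because they are the method's stated
  operating point, and the QC module exists to detect non-convergence.
* The GFE correction frequently self-deactivates (Acc(D(N)) = 0) once the
  generator converges; under those conditions GFE and BCE trajectories are
  identical by construction.
* ENN in several hundred dimensions prunes the majority class aggressively
  even with correlated features; the balanced set's majority count lands
  well below the 1000 target rather than near it.
* Single deterministic imputation — no multiple-imputation pooling.
* The evaluation threshold is fixed at 0.5; no calibration is performed.
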