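"""Cleaning chain and grouped splitting on a cohort with missing values.

Injects missingness into a small cohort, then runs the full chain —
metabolite-column filter (>20% missing), participant filter (>10% missing
metabolites), log transform, chained-equation imputation, min-max scaling
fitted on the training partition — and splits 64/16/20 within k-means
feature groups. Printed counts show what each filter removed."""

import numpy as np

import ganfe
from ganfe import preprocess as pp

spec = ganfe.CohortSpec(
    n_negative=500, n_positive=50, missing_col_rate=0.25,
    missing_row_rate=0.15, seed=7)
cohort = ganfe.simulate_cohort(spec)
print(f"raw: {cohort.n} records x {cohort.p} features, "
      f"{int(np.isnan(cohort.X).sum())} missing cells")

step1 = pp.filter_metabolites_by_missingness(cohort, 0.20)
print(f"metabolite filter: {cohort.p - step1.p} columns dropped")
step2 = pp.filter_participants_by_missingness(step1, 0.10)
print(f"participant filter: {step1.n - step2.n} records dropped")
step3 = pp.log_transform_metabolites(step2)
clean = pp.impute_chained(step3, n_sweeps=10, seed=0)
print(f"after imputation: {int(np.isnan(clean.X).sum())} missing cells")

groups = ganfe.cluster_groups(clean, k=3, seed=0)
split = ganfe.stratified_split(clean, groups, seed=0)
masks = split.masks(clean.ids)
scaler = pp.minmax_fit(clean.take_rows(masks["train"]))
scaled = pp.minmax_apply(scaler, clean)
print(f"split sizes: train {len(split.train)}, test {len(split.test)}, "
      f"validation {len(split.validation)}")
print(f"scaled range: [{scaled.X.min():.2f}, {scaled.X.max():.2f}]")
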