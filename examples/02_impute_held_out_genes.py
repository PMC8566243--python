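"""Impute spatial expression of genes never used in training.

Fits the mapping on a marker-gene panel, predicts every shared gene via
M^T S, and scores held-out genes by their spatial correlation with the
measurement — the standard holdout validation for spatial imputation.
"""

import numpy as np

import voxmap as vm

truth = vm.standard_suite(seed=0)
sc_n = vm.log1p_transform(vm.normalize_library_size(truth.sc))
panel = vm.training_panel(vm.rank_markers(sc_n), k=10, sp=truth.sp)
density = vm.density_from_segmentation(truth.seg_counts)

scores = vm.holdout_scores(truth.sc, truth.sp, density, panel,
                           epochs=300, seed=0)
train = scores.subset(split="train")["score"]
test = scores.subset(split="test")["score"]
print(f"train genes: {len(train)}, mean spatial correlation {np.nanmean(train):.3f}")
print(f"test genes:  {len(test)}, mean spatial correlation {np.nanmean(test):.3f}")
print(f"90th quantile of training-gene scores: "
      f"{vm.score_quantiles(scores, 0.9, split='train'):.3f}")

regions = vm.sparsity_stratified_summary(scores, threshold=0.4)
print(f"genes by region: {regions['nonsparse_above']} well predicted, "
      f"{regions['nonsparse_below']} dense but poorly predicted, "
      f"{regions['sparse']} too sparsely measured to judge")

# leave-one-out on a small subsample: each gene imputed by a model that
# never saw it
rng = np.random.default_rng(0)
sub = sorted(rng.choice(panel, 8, replace=False))
loo = vm.leave_one_out(truth.sc, truth.sp, density, sub, epochs=300, seed=0)
print(f"leave-one-out over {len(sub)} genes: "
      f"median correlation {loo.table['score'].median():.3f}")
print("(a high held-out correlation means the mapping generalizes beyond its"
      " training panel)")
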