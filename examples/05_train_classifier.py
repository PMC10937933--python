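"""Classify crosslinking status with a SMOTE-balanced random forest.

Simulates a feature table at the study's imbalance (43 crosslinked vs 171
non-crosslinked sites, 246 features, 5 informative) and scores it by
10-fold cross-validated ROC AUC with a bootstrap confidence interval.
"""

from xlink3d import CVConfig, RFConfig, SMOTEConfig, crossval_auc
from xlink3d.fixtures import TableSimSpec, simulate_feature_table

spec = TableSimSpec(seed=7)
dataset = simulate_feature_table(spec)
print(f"dataset: {len(dataset.y)} sites, {int(dataset.y.sum())} crosslinked, "
      f"{dataset.n_features} features")

roc = crossval_auc(dataset, model="rf", cv=CVConfig(k=10, seed=0),
                   smote=SMOTEConfig(seed=0),
                   rf=RFConfig(ntree=100, mtry=17),
                   n_bootstrap=200)
print(f"ROC AUC = {roc.auc:.3f} "
      f"(95% bootstrap CI {roc.ci_lower:.3f}-{roc.ci_upper:.3f}, "
      f"{roc.n_bootstrap} refits)")
# AUC near 1 here because the injected signal is strong by design; on real
# interface features the same protocol lands in the 0.7-0.8 range.
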