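"""Enhancer functional-state classification with the attention model.

Builds synthetic enhancer samples with well-separated class-conditional
(5mC, 5hmC) signatures, trains the self-attention classifier (32-d
projection, 4 heads, 256-unit feed-forward and head layers, elu, dropout
0.2) on everything except chromosome 1, and evaluates one-vs-rest ROC AUC on
the chromosome-1 holdout.  A second model trained on mixture-contaminated
(unenriched-style) data shows the cost of losing feature specificity.
"""

from sixbct import ModelConfig
from sixbct.enhancer import (
    evaluate,
    simulate_enhancer_samples,
    split_by_chromosome,
    train,
)

signatures = {"active": (0.05, 0.35), "poised": (0.40, 0.03),
              "primed": (0.80, 0.10)}

clean = simulate_enhancer_samples(signatures, n_per_class=100, seed=17)
train_set, test_set = split_by_chromosome(clean, holdout="chr1")
model = train(train_set, ModelConfig(seed=0, max_epochs=40))
report = evaluate(model, test_set)
print(f"feature-specific model  : {len(train_set)} train / "
      f"{len(test_set)} chr1 test")
print(f"  accuracy              : {report.accuracy:.3f}")
for cls, curve in report.roc.items():
    print(f"  ROC AUC {cls:<7}       : {curve['auc']:.3f}")
print(f"  macro ROC AUC         : {report.macro_roc_auc:.3f}")

mixed = simulate_enhancer_samples(signatures, n_per_class=100,
                                  contamination=0.7, seed=18)
train_m, test_m = split_by_chromosome(mixed, holdout="chr1")
model_m = train(train_m, ModelConfig(seed=0, max_epochs=40))
report_m = evaluate(model_m, test_m)
print(f"\nmixture-contaminated model macro ROC AUC: "
      f"{report_m.macro_roc_auc:.3f}")
print("\nDiluting per-CpG class signal with background draws (70% of CpGs)")
print("emulates an unenriched whole-genome library; the drop in AUC shows")
print("why feature-specific profiles resolve enhancer states better.")
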