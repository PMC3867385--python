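"""Train and evaluate the bagged 1-norm sparse SVM on the five-marker panel.

Repeats R random learning/test divisions (test = one third, stratified);
per division a B-member bootstrap-bagged SSVM with class-balanced slack
costs is fitted on the learning set and scored on the held-out third.
Prints mean ± SD of the five diagnostic measures, the mean panel weights,
and the LASSO-logistic comparator's numbers on the same divisions.
"""

from sepsispanel import (
    average_roc,
    default_cohort_spec,
    generate_cohort,
    make_labels,
    repeated_evaluation,
)
from sepsispanel.classifiers import make_divisions

PANEL = ("WBC", "Plt", "Segs", "Bands", "CD64")

cohort = generate_cohort(default_cohort_spec(300, 300, seed=42))
ds = make_labels(cohort)
divisions = make_divisions(ds.y, R=20, seed=7)

ssvm = repeated_evaluation(ds, feature_subset=PANEL, R=20, B=25, seed=7,
                           divisions=divisions, collect_roc=True)
llr = repeated_evaluation(ds, feature_subset=PANEL, R=20, B=1, seed=7,
                          divisions=divisions, method="llr")

print(f"{'':6}" + "".join(f"{m:>14}" for m in ssvm.mean))
for tag, s in (("SSVM", ssvm), ("LLR", llr)):
    print(f"{tag:6}" + "".join(f"{s.mean[m]:8.3f}±{s.sd[m]:.3f}"
                               for m in s.mean))

print("\nmean SSVM weights (standardized scale, ± SE over divisions):")
for b, w, se in zip(ssvm.subset, ssvm.weights_mean, ssvm.weights_se):
    print(f"  {b:>5}: {w:+.3f} ± {se:.3f}")
print("positive weights push the score toward a septic diagnosis "
      "(score >= 0), negative toward nonseptic.")

roc = average_roc(ssvm.roc_curves)
print(f"\nvertically averaged ROC: AUC = {roc.auc_mean:.3f} over "
      f"{len(ssvm.roc_curves)} divisions")
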