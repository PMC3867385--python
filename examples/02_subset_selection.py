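"""Exhaustive canonical-correlation subset selection vs forward selection.

Standardizes the cohort, enumerates every biomarker combination per size k,
and prints the selection path: the best subset's correlation with the septic
label, which biomarkers enter or leave between consecutive winners, and the
greedy forward-selection order for comparison.
"""

from sepsispanel import (
    best_subsets,
    default_cohort_spec,
    generate_cohort,
    make_labels,
    standardize,
)

cohort = generate_cohort(default_cohort_spec(300, 300, seed=42))
ds = make_labels(cohort)
sm = standardize(ds.X, names=ds.names)
path = best_subsets(sm.Xtilde, ds.y, names=ds.names)

print(path.to_table().to_string(index=False))
print("\nrho(k) is nondecreasing by construction (subsets nest); where it "
      "plateaus marks how many biomarkers carry the diagnostic signal.")
print("forward selection is greedy and can diverge from the exhaustive "
      "winners when biomarkers are jointly informative.")
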