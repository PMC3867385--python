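# sepsispanel

Biomarker-panel discovery for neonatal sepsis: which small set of routine
hematological biomarkers, taken *as a group*, best predicts a septic
outcome?

Neonatal sepsis is diagnosed definitively by blood culture, which takes
days; bedside decisions rest on CBC-derived scores.  This package
implements a reusable, fully seeded version of a two-pronged
panel-selection analysis over ten biomarkers (Age, WBC, Hgb, Hct, Plt,
Segs, Bands, Lymph, Mono, neutrophil CD64):

1. **Labeling** — the hematologic 2-of-4 score (abnormal ANC, elevated
   ABC, elevated IT-ratio, thrombocytopenia) and blood-culture results
   partition evaluations into culture-proven sepsis, clinical sepsis and
   nonseptic; the first two form the septic label y = +1.
2. **Exhaustive CCA subset selection** — for each panel size k, the
   subset S maximizing the canonical correlation between the label and
   the standardized biomarkers, ρ(S) = max_β corr(y, X̃_S β), over all
   C(p, k) combinations (globally optimal, not greedy), with a
   forward-selection comparator.
3. **Sparse-SVM validation** — a 1-norm soft-margin SVM

       min ‖w‖₁ + C₊ Σ_{yᵢ=+1} ξᵢ + C₋ Σ_{yᵢ=−1} ξᵢ
       s.t. yᵢ(w·x̃ᵢ + b) ≥ 1 − ξᵢ,  ξ ≥ 0,  C₊N₊ = C₋N₋

   solved exactly as a linear program, bootstrap-bagged into a B-member
   ensemble (mean decision score, positive diagnosis iff score ≥ 0) and
   evaluated over R repeated stratified learning/test divisions; plus a
   LASSO-logistic comparator, TPR/TNR/PPV/NPV/ACC summaries and
   vertically averaged ROC curves.

Because the underlying clinical dataset is not publicly deposited, the
package includes a first-class synthetic-cohort generator (lognormal/
Gaussian marginals anchored to published pooled moments, latent Gaussian
copula, planted informative panels with known ground truth) so every
claim about the method is testable against known truth.  It is aimed at
biostatisticians and methods researchers who want to run, stress-test or
extend this style of panel-discovery analysis.

## Worked example

```python
from sepsispanel import (default_cohort_spec, generate_cohort, make_labels,
                         standardize, best_subsets, repeated_evaluation)

cohort = generate_cohort(default_cohort_spec(n_pos=300, n_neg=300, seed=42))
ds = make_labels(cohort)                      # 2-of-4 score + culture -> ±1
sm = standardize(ds.X, names=ds.names)
path = best_subsets(sm.Xtilde, ds.y, names=ds.names)
for sc in path.best[:5]:
    print(sc.k, round(sc.rho, 3), [ds.names[j] for j in sc.indices])

panel = tuple(ds.names[j] for j in path.best[4].indices)
s = repeated_evaluation(ds, feature_subset=panel, R=20, B=25, seed=7)
print({m: round(v, 3) for m, v in s.mean.items()})
```

prints (exactly, given the seeds):

```
1 0.434 ['Plt']
2 0.519 ['Plt', 'CD64']
3 0.545 ['Plt', 'Segs', 'Bands']
4 0.576 ['Plt', 'Segs', 'Lymph', 'CD64']
5 0.609 ['WBC', 'Plt', 'Segs', 'Lymph', 'CD64']
{'TPR': 0.79, 'TNR': 0.75, 'PPV': 0.761, 'NPV': 0.783, 'ACC': 0.77}
```

ρ(k) rises as markers are added and the winners are dominated by the five
informative markers (WBC, Plt, Segs, Bands, CD64 by construction of the
default cohort).  Two instructive wrinkles: the strongly right-skewed
Bands is underrated by a raw-scale Pearson criterion even when its
generative effect is the largest — linear correlation is not threshold
accuracy on skewed data — and Lymph occasionally rides in on its strong
anticorrelation with Segs.  The best *group* need not be the top
individual markers; on the independent-noise cohorts of
`planted_panel_cohort` the selection recovers the planted five exactly.
The bagged sparse-SVM classifier on the selected panel reaches ~0.77
accuracy on held-out thirds, the expected scale for latent group
separations of 0.5–1.2 SD.  The `examples/` directory walks through
each capability (cohort generation, selection, classification, the full
pipeline); `sepsispanel all -c config.yml` runs everything from a shell
and writes a reproducible report bundle (selection path, model report with
weights ± SE, performance table, ROC points, exclusion log, manifest).

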