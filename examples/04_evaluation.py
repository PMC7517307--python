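"""Score a selected feature subset by repeated stratified cross-validation.

Selects features on synthetic data, then evaluates the subset with the four
standard classifiers (Naive Bayes, SVM, 3-NN, decision tree) under repeated
stratified 10-fold CV, reporting accuracy, F-measure (beta = 1) and AUC.
"""

from ffsrrd import (
    EvaluationConfig,
    SyntheticSpec,
    evaluate_selection,
    ffs_rrd,
    generate_synthetic,
    truncate_subset,
)

ds, truth = generate_synthetic(SyntheticSpec(m=200, seed=5))
result = ffs_rrd(ds)
subset = truncate_subset(result.selected, ds.n)
print("evaluating subset:", [ds.feature_names[f] for f in subset])

config = EvaluationConfig(folds=10, repeats=3, seed=5)
report = evaluate_selection(ds, subset, config)
print(report.to_tsv())
print("\nEach row is the mean and SD over all folds and repeats; with the "
      "planted 2-SD class separation, accuracies well above the ~0.5 chance "
      "level show the selected features carry the class signal.")
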