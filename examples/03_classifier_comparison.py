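"""Compare KNN, random forest, SVM and MLP under the jackknife test.

Each classifier is trained n times, leaving one sample out per round, and
the held-out predictions are pooled into one confusion matrix; the table
reports sensitivity (Sn), specificity (Sp), accuracy (Ac), Matthews
correlation (MCC) and ROC AUC per classifier.
"""
import phagehydro as ph

dataset = ph.generate_dataset(
    ph.GeneratorConfig(n_pos=25, n_neg=25, effect_size=0.25, seed=3)
)
matrix = ph.encode_combined(dataset, scheme="all")

specs = [
    ph.ClassifierSpec("k-nearest-neighbor"),
    ph.ClassifierSpec("random-forest", {"n_estimators": 100}, seed=0),
    ph.ClassifierSpec("svm-rbf"),
    ph.ClassifierSpec("multilayer-perceptron", seed=0),
]
table = ph.compare_classifiers(matrix, specs)
print(table.round(3).to_string(index=False))
print("\nHigher MCC means a more balanced confusion matrix; "
      "AUC ranks the decision scores.")
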