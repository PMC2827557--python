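"""Select an inflammation signature by random-forest backward elimination.

Simulates the study, QC-filters and z-scores the matrix, splits samples
two-thirds/one-third stratified by class, runs bootstrap-forest backward
elimination on the training set, and classifies the held-out test set.
"""

from dcsig import (
    SyntheticConfig,
    classify,
    finalize_signature,
    generate_expression,
    backward_elimination,
    qc_filter,
    stratified_split,
    train_forest,
    zscore_transform,
)

config = SyntheticConfig(n_genes=500, seed=0)
matrix, sheet, qc, truth = generate_expression(config)
labels = dict(zip(sheet["sample_id"], sheet["class"]))

matrix, excluded = qc_filter(matrix, qc)  # 3'/5' ratio > 3.0 removed
z = zscore_transform(matrix)

split = stratified_split(sheet, seed=1)
print(f"train {len(split.train_ids)} / test {len(split.test_ids)} (excluded: {len(excluded)})")

sig = backward_elimination(z[split.train_ids], labels, n_trees=200, seed=2)
sig = finalize_signature(sig, z[split.train_ids], labels)
print(f"\nselected {len(sig.gene_ids)} genes "
      f"(smallest set within 1 s.e. of the minimum OOB error):")
print(sig.table.to_string(index=False))

planted = set(truth.signature_gene_ids)
print(f"\nplanted genes among selected: {len(set(sig.gene_ids) & planted)}/{len(sig.gene_ids)}")

model = train_forest(z.loc[sig.gene_ids, split.train_ids], labels, n_trees=200, seed=3)
preds = classify(model, z[split.test_ids])
acc = (preds["predicted_class"] == preds.index.map(labels)).mean()
print(f"held-out test accuracy with the selected signature: {acc:.2f}")
# The OOB trajectory (sig.trajectory) records the error at every
# elimination round, from all genes down to 2.
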