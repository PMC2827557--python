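"""Generate a synthetic dendritic-cell stimulation study.

Builds the default 115-array design (12 stimulus groups, 79 inflammatory /
36 non-inflammatory samples) with a planted 36-up / 18-down signature, and
prints the composition alongside the planted ground truth.
"""

from dcsig import INFLAMMATORY, SyntheticConfig, generate_expression

config = SyntheticConfig(n_genes=2000, seed=0)
matrix, sheet, qc, truth = generate_expression(config)

print(f"expression matrix: {matrix.shape[0]} probe sets x {matrix.shape[1]} arrays")
print(sheet.groupby(["stimulus", "class"]).size().to_string())
n_inf = (sheet["class"] == INFLAMMATORY).sum()
print(f"\ntotal {len(sheet)} arrays, {n_inf} inflammatory")
print(f"planted signature: {len(truth.signature_up)} up, {len(truth.signature_down)} down")
print("first planted up genes:", truth.signature_up[:5])
# The matrix is log2-scale expression-index data; planted genes are shifted
# by effect_size * noise_sd (= 2 log2 units) in inflammatory samples.
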