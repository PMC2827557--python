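# Methods

## Problem and data model

The pipeline classifies dendritic-cell (DC) expression profiles into two
states — *inflammatory* (TLR ligands, live microbes) and *non-inflammatory*
(untreated, dexamethasone, parasite-derived suppressive preparations) — and
extracts the small gene panel that carries the discrimination. Inputs are a
genes × samples matrix of log2-scale normalized expression indices (RMA-level
summaries; probe-level processing is out of scope), a sample sheet with the
class assignment, per-sample 3′/5′ signal ratios for β-actin and GAPDH, and,
for validation, qRT-PCR Ct tables (target and 18s housekeeping Ct per gene ×
condition × replicate).

## Synthetic study generator

`simulate.generate_expression` emulates the reference study design: 115
arrays over 12 stimulus groups (untreated 14; CpG, Listeria, Pam3Cys,
poly I:C 10 each; Leishmania amastigote/promastigote, Schistosoma SLA/eggs,
LPS 8 each; dexamethasone 6; zymosan 15), 79 inflammatory / 36
non-inflammatory. Time points follow the group designs (2–24 h in duplicate
or triplicate) but are treated as replicate samples — the classifier is
time-agnostic, so no temporal autocorrelation is simulated.

Per gene, a baseline mean is drawn once from U(4, 12) on the log2 scale
(mimicking expression-index ranges) and samples add Gaussian noise of sd
`noise_sd` (default 1.0 log2 units, a standard microarray error model).
`n_signature_up` (36) planted genes are shifted by
+`effect_size`·`noise_sd` in inflammatory samples and `n_signature_down`
(18) by the negative shift; `effect_size` defaults to 2 (a strong, cleanly
recoverable signature, matching the reference study's near-perfect test-set
separation). All other genes are identically distributed across classes.
QC ratios are drawn below 3.0 except for a `qc_fail_fraction` of samples
(default 0: the emulated dataset is post-QC). Gene ids follow an
Affymetrix-like `<n>_at` pattern. Everything derives from one seed.

`simulate.generate_ct_table` emits Ct tables for the planted signature
genes: 18s Ct is constant within a replicate batch (housekeeping noise is
not separately identifiable in 2^−ΔΔCt, so all variability is placed on the
target Ct), per-gene base Ct ~ U(20, 30), and the target Ct is lowered or
raised by the planted log2 fold (default `effect_size`·`noise_sd`) with
Gaussian cycle noise (default `noise_sd`, settable to 0 for exact
round-trip checks). Its random stream derives from `(seed, 1)` so
expression and Ct data are independently reproducible.

What the generator does **not** emulate: probe-level effects, batch and
scan-date structure, stimulus-specific expression programs (all
inflammatory stimuli share one planted shift), heavy-tailed or
intensity-dependent noise, and correlated genes. Passing recovery tests
therefore show the procedures are correct and well-calibrated under the
assumed model, not that the biological signature itself is reproduced.

## Preprocessing

- **QC filter**: a sample is excluded when its β-actin *or* GAPDH 3′/5′
  ratio is strictly greater than 3.0 (boundary retained).
- **Z-score**: per gene, mean 0 / sd 1 with denominator n − 1 (the common
  statistical-environment default; the convention is stated because either
  denominator is defensible). Constant rows are zeroed with a warning
  rather than dropped, keeping row indices aligned with annotation.
- **Heat-map transform**: per-gene mean-centring of log2 values (log2 ratio
  to the gene's mean).
- **PCA**: genes are centred across samples; no rescaling (the canonical
  path z-scores first, making rescaling a no-op). Scores come from the SVD
  of the centred samples × genes matrix; the sign of each component is
  fixed so its largest-magnitude gene loading is positive. Requesting more
  components than the achievable rank is an error naming the rank.
- **Clustering**: agglomerative hierarchical clustering on Euclidean
  distances, complete linkage by default (linkage is a parameter; the
  reference procedure specifies only the metric). The dendrogram leaf
  order drives heat-map row/column ordering.

## Partitioning

`stratified_split` assigns round-half-up(f·n) samples of each stratum to
training (f = 2/3 by default), drawing without replacement from the
stratum's sorted sample ids with one seeded generator — so the assignment
is invariant to input row order. If per-stratum rounding misses the global
target round-half-up(f·N), the largest strata are nudged ±1. For the
115-sample preset this yields 77 train / 38 test with a proportional 53/24
class balance. The reference study's realized balance (50/27) is not
proportional and cannot arise from proportional stratification;
`override_counts={"inflammatory": 50, "non_inflammatory": 27}` reproduces
it explicitly rather than guessing the original allocation.

## Forest, importance, selection

One bootstrap sample (size n, with replacement) per tree; trees are CART
classifiers (scikit-learn) with Gini impurity, grown to purity
(min_samples_leaf = 1) with mtry = ⌊√p⌋ candidate genes per split — all
exposed as parameters. Bootstrap indices are stored per tree, so OOB error
is recomputable exactly: each training sample is predicted by majority vote
of the trees whose bootstrap excluded it; samples never OOB are skipped and
counted. Importance is the unnormalized mean decrease in Gini impurity
(node-fraction-weighted impurity decrease summed over a gene's split nodes,
averaged over trees); genes never split on score exactly 0.

Backward elimination retrains the forest on the retained genes each round
and drops the lowest-importance 20% (at least one gene) until 2 remain,
recording the OOB trajectory. The selected signature is the smallest
recorded set with OOB error ≤ min error + 1 · √(e(1−e)/n) — the published
defaults of the OOB-guided variable-selection method this follows. Two
consequences are documented deliberately:

- the smallest-set rule returns *minimal* signatures (often 2–7 genes when
  the signal is clean), not the full planted set; `top_k` evaluates the
  elimination path at a fixed size when set parity is wanted, and
  parameter-recovery experiments use it at the planted size;
- the selected set's OOB error is optimistically biased (min over rounds),
  so generalization claims use the held-out test set, never the selected
  round's OOB error.

Vote ties in classification go to non-inflammatory — conservative toward
the steady state — and are configurable. Directions are assigned from the
training data by class-mean contrast (exact ties → "up", zero margin, with
a warning).

## qRT-PCR scoring

Fold change per replicate is 2^−ΔΔCt with ΔCt = Ct_target − Ct_18s and
ΔΔCt taken against the gene's untreated-reference ΔCt (averaged over
reference replicates); the per-cell value is the arithmetic mean of
replicate folds. The reference column is set to exactly 1 by construction
(the arithmetic mean of noisy self-ratios would exceed 1 by Jensen's
inequality, which would violate the reference-≡-1 contract).

Per gene, the threshold is the arithmetic mean of the median fold change
over known inflammatory reference conditions and the median over known
non-inflammatory ones (even-count medians use the midpoint). This is the
one reading of "mean expression level between the two classes" that yields
a single threshold lying between the class medians. The reference condition
is excluded from threshold derivation and scoring; the reference-condition
set is declared per run. Scoring uses strict inequalities — a fold change
exactly at the threshold scores 0 under either claim — and operates on
condition-level mean fold changes. Concordance percent uses half-up
rounding (matching every printed k/n→% pair the statistic is checked
against). The class call is the majority of per-gene votes (a gene votes
inflammatory when its value sits on its inflammatory threshold side), ties
→ non-inflammatory.

## Pipeline and reproducibility

`run_pipeline` chains the stages; one run seed derives per-stage sub-seeds
via `SeedSequence((seed, stage))`, so stages can be re-run independently.
Reports contain no timestamps and are byte-identical across re-runs of the
same config. All artifacts are plain TSV/CSV/JSON and re-parse under the
package's readers.

## Problem sizes in the test suite

Unit and property tests run at reduced scale (hundreds of genes, tens to
hundreds of trees) — sufficient for the statistical contracts they check,
since every stochastic assertion carries an explicit tolerance derived from
its sampling distribution. The parameter-recovery experiment runs at 500
genes / 20 planted / 30+30 samples / 500 trees over 5 seeds; the
permutation-null OOB check uses 100 structureless samples, where the
finite-sample bias of permutation OOB (each sample's exclusion leaves its
own class in the minority) stays within the stated ±0.1 band.

## Known limitations

- The generator's single shared effect size makes recovery easier than in
  real stimulus-heterogeneous data; recovery rates here are upper bounds.
- No amplification-efficiency correction in 2^−ΔΔCt beyond assuming
  validated primers.
- OOB-guided selection inherits the selection bias discussed above; the
  package reports the full trajectory so users can audit it.
- The packaged 54-gene table records the published panel's identities and
  directions for bookkeeping and fixtures; the selection code does not use
  it.
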