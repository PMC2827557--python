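"""Quality filtering and matrix transforms for expression-index data.

Operations act on genes x samples pandas DataFrames of log2-scale values
and never mutate their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def qc_filter(
    matrix: pd.DataFrame, qc: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose beta-actin or GAPDH 3'/5' ratio exceeds ``threshold``.

    The rule is strictly greater-than: a ratio exactly at the threshold is
    retained. Column order of retained samples is preserved. Returns the
    filtered matrix and the list of excluded sample ids.
    """
    qc_idx = qc.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in qc_idx.index]
    if missing:
        raise ValueError(f"samples missing from QC table: {missing}")
    qc_idx = qc_idx.loc[list(matrix.columns)]
    bad = (qc_idx["actin_ratio"] > threshold) | (qc_idx["gapdh_ratio"] > threshold)
    excluded = [s for s in matrix.columns if bad[s]]
    kept = [s for s in matrix.columns if not bad[s]]
    return matrix[kept], excluded


def zscore_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0 and sd 1 (denominator n-1).

    Constant rows cannot be standardized; they are set to all zeros and a
    warning is recorded, keeping gene indices aligned with annotation.
    """
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sds == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) set to zero during "
            "z-score transform",
            stacklevel=2,
        )
    safe_sds = np.where(sds == 0, 1.0, sds)
    out = (values - means) / safe_sds
    out[constant, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_ratio_to_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centre each gene row on its mean.

    On log2-scale input this is the log2 ratio of each sample to the gene's
    mean expression level — the standard heat-map transform.
    """
    return matrix.sub(matrix.mean(axis=1), axis=0)


@dataclass
class PCAResult:
    """Per-sample principal-component scores with variance bookkeeping."""

    scores: pd.DataFrame  # samples x PC1..PCk
    loadings: pd.DataFrame  # genes x PC1..PCk
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Project gene-centred samples onto the top principal components.

    Genes (rows) are centred across samples; no rescaling is applied, so on
    z-scored input (the pipeline's canonical path) genes already have unit
    variance. Components are ordered by decreasing explained variance and
    each component's sign is fixed so that its largest-magnitude gene
    loading is positive.
    """
    n_samples = matrix.shape[1]
    if n_samples < n_components + 1:
        raise ValueError(
            f"need at least n_components+1={n_components + 1} samples, got {n_samples}"
        )
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds achievable rank {rank}")
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    cols = [f"PC{j + 1}" for j in range(n_components)]
    total_var = Xc.var(axis=0, ddof=1).sum()
    expl = S**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=cols),
        explained_variance=expl,
        explained_variance_ratio=expl / total_var if total_var > 0 else expl * 0.0,
    )


def cluster_order(
    matrix: pd.DataFrame, axis: str = "samples", linkage_method: str = "complete"
) -> list[str]:
    """Dendrogram leaf order from agglomerative clustering (Euclidean).

    ``axis`` selects whether genes (rows) or samples (columns) are
    clustered. Complete linkage is the default; the linkage rule is
    configurable.
    """
    if axis == "samples":
        data = matrix.to_numpy(dtype=float).T
        ids = list(matrix.columns)
    elif axis == "genes":
        data = matrix.to_numpy(dtype=float)
        ids = list(matrix.index)
    else:
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if len(ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    return [ids[i] for i in leaves]
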