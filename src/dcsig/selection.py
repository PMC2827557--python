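"""Backward-elimination gene selection on random-forest importance.

Starting from all genes, the forest is retrained on the retained set and
the lowest-importance fraction of genes is dropped each round until two
genes remain. The selected signature is the smallest gene set whose
out-of-bag (OOB) error is within ``se_rule`` binomial standard errors of
the minimum OOB error along the trajectory — the published default of the
random-forest variable-selection method this follows (drop 20% per round,
1-s.e. rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._constants import DOWN, INFLAMMATORY, NON_INFLAMMATORY, UP
from .forest import ForestModel, gini_importance, oob_error, train_forest


@dataclass
class Signature:
    """Selected genes with direction, importance and the selection path."""

    table: pd.DataFrame  # columns: gene_id, direction, importance, rank
    trajectory: pd.DataFrame  # columns: round, n_genes, oob_error
    selected_round: int
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["direction"]))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def backward_elimination(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    drop_fraction: float = 0.2,
    se_rule: float = 1.0,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
    min_genes: int = 2,
    top_k: int | None = None,
) -> Signature:
    """Iterative importance-ranked gene elimination with the s.e. rule.

    Each round trains a fresh forest (per-round seeds derived from ``seed``)
    on the retained genes, records its OOB error and Gini importance, then
    drops the lowest-importance ``drop_fraction`` of genes (at least one)
    until ``min_genes`` remain. The returned signature is the smallest
    recorded set with OOB error <= min error + ``se_rule`` * s.e.(min).

    ``top_k`` forces a fixed signature size instead: the smallest recorded
    round with at least ``top_k`` genes is taken and its top ``top_k`` genes
    by importance are returned. Directions are left empty; fill them with
    :func:`assign_direction` / :func:`finalize_signature`.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError(f"drop_fraction must lie in (0, 1), got {drop_fraction}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes for backward elimination")

    rng = np.random.default_rng(seed)
    genes = list(matrix.index)
    n_train = matrix.shape[1]
    records: list[dict] = []
    round_genes: list[list[str]] = []
    round_importances: list[pd.Series] = []

    rnd = 0
    while True:
        sub = matrix.loc[genes]
        round_seed = int(rng.integers(0, 2**31 - 1))
        model = train_forest(
            sub, labels, n_trees=n_trees, mtry=mtry, seed=round_seed
        )
        imp = gini_importance(model)
        err = oob_error(model, sub, labels)
        records.append({"round": rnd, "n_genes": len(genes), "oob_error": err})
        round_genes.append(list(genes))
        round_importances.append(imp)
        if len(genes) <= min_genes:
            break
        n_drop = max(1, int(math.floor(len(genes) * drop_fraction)))
        n_keep = max(min_genes, len(genes) - n_drop)
        # stable ranking: importance descending, original gene order breaking ties
        order = imp.reindex(genes).to_numpy()
        keep_pos = np.argsort(-order, kind="stable")[:n_keep]
        genes = [genes[i] for i in sorted(keep_pos)]
        rnd += 1

    trajectory = pd.DataFrame(records)

    if top_k is not None:
        eligible = [i for i, gs in enumerate(round_genes) if len(gs) >= top_k]
        pick = max(eligible)  # smallest recorded set still >= top_k genes
        imp = round_importances[pick].reindex(round_genes[pick])
        chosen = imp.sort_values(ascending=False, kind="stable").head(top_k)
    else:
        errs = trajectory["oob_error"].to_numpy()
        e_min = float(np.nanmin(errs))
        se = math.sqrt(e_min * (1.0 - e_min) / n_train)
        threshold = e_min + se_rule * se
        ok = [i for i in range(len(records)) if errs[i] <= threshold]
        pick = min(ok, key=lambda i: (records[i]["n_genes"], -i))
        imp = round_importances[pick].reindex(round_genes[pick])
        chosen = imp.sort_values(ascending=False, kind="stable")

    table = pd.DataFrame(
        {
            "gene_id": chosen.index,
            "direction": pd.NA,
            "importance": chosen.to_numpy(),
            "rank": np.arange(1, len(chosen) + 1),
        }
    )
    return Signature(table=table, trajectory=trajectory, selected_round=pick, seed=seed)


def assign_direction(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Mark each gene up or down in the inflammatory class by mean contrast.

    A gene is 'up' when its mean expression over inflammatory samples
    exceeds the non-inflammatory mean, else 'down'; the margin (signed mean
    difference, log2 units) is reported. An exact tie is labelled 'up' with
    zero margin and a warning.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [g for g in gene_ids if g not in matrix.index]
    if missing:
        raise ValueError(f"genes missing from matrix: {missing[:10]}")
    cols_inf = [s for s in matrix.columns if labels[s] == INFLAMMATORY]
    cols_ninf = [s for s in matrix.columns if labels[s] == NON_INFLAMMATORY]
    if not cols_inf or not cols_ninf:
        raise ValueError("both classes must be present to assign directions")
    sub = matrix.loc[gene_ids]
    margin = sub[cols_inf].mean(axis=1) - sub[cols_ninf].mean(axis=1)
    ties = margin == 0
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} gene(s) with exactly equal class means assigned "
            "direction 'up' with zero margin",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "direction": np.where(margin >= 0, UP, DOWN),
            "margin": margin.to_numpy(),
        }
    )


def finalize_signature(
    signature: Signature,
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
) -> Signature:
    """Fill the signature's direction column from the training data."""
    dirs = assign_direction(matrix, labels, signature.gene_ids)
    table = signature.table.drop(columns=["direction"]).merge(
        dirs[["gene_id", "direction", "margin"]], on="gene_id"
    )
    table = table[["gene_id", "direction", "importance", "rank", "margin"]]
    return Signature(
        table=table,
        trajectory=signature.trajectory,
        selected_round=signature.selected_round,
        seed=signature.seed,
    )
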