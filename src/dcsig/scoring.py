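"""qRT-PCR fold changes and direction-aware threshold scoring.

Relative transcript levels are computed by the 2^-ddCt method
(dCt = Ct_target - Ct_18s; ddCt = dCt_condition - dCt_untreated). Each
signature gene receives one threshold: the arithmetic mean of its median
fold change over known inflammatory reference conditions and its median
over known non-inflammatory ones. A queried condition is then scored gene
by gene — a score of 1 when the fold change falls on the side of the
threshold consistent with the claimed class given the gene's regulation
direction, 0 otherwise — and summarized as a concordance fraction/percent
and a majority-vote class call.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._constants import DOWN, INFLAMMATORY, NON_INFLAMMATORY, UP, round_half_up


@dataclass
class FoldChangeTable:
    """Mean 2^-ddCt fold change per gene x condition.

    The reference (untreated) column is 1 exactly, by construction — the
    reference compared with itself defines fold change 1.
    """

    values: pd.DataFrame  # genes x conditions, mean fold change
    n_replicates: pd.DataFrame  # genes x conditions, replicate count
    condition_class: dict[str, str]  # condition -> claimed class
    reference_condition: str

    def condition_values(self, condition: str) -> pd.Series:
        return self.values[condition]


def fold_change(ct: pd.DataFrame, reference_condition: str = "untreated") -> FoldChangeTable:
    """Per-gene, per-condition mean fold change from a Ct table.

    Per replicate, dCt = ct_target - ct_18s and ddCt = dCt minus the gene's
    reference dCt (averaged over reference replicates); the cell value is
    the arithmetic mean of the replicate folds 2^-ddCt.
    """
    required = {"gene_id", "condition", "replicate", "ct_target", "ct_18s"}
    missing_cols = required - set(ct.columns)
    if missing_cols:
        raise ValueError(f"Ct table lacks columns {sorted(missing_cols)}")
    if not np.isfinite(ct[["ct_target", "ct_18s"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")

    ct = ct.copy()
    ct["dct"] = ct["ct_target"] - ct["ct_18s"]
    ref = ct[ct["condition"] == reference_condition]
    genes = list(dict.fromkeys(ct["gene_id"]))
    no_ref = [g for g in genes if g not in set(ref["gene_id"])]
    if no_ref:
        raise ValueError(
            f"gene(s) lacking reference condition {reference_condition!r} Ct: {no_ref[:10]}"
        )
    ref_dct = ref.groupby("gene_id")["dct"].mean()

    ct["fold"] = 2.0 ** -(ct["dct"] - ct["gene_id"].map(ref_dct))
    grouped = ct.groupby(["gene_id", "condition"])["fold"]
    conditions = list(dict.fromkeys(ct["condition"]))
    values = grouped.mean().unstack("condition").reindex(index=genes, columns=conditions)
    counts = grouped.size().unstack("condition").reindex(index=genes, columns=conditions)
    values[reference_condition] = 1.0  # reference vs itself, by definition

    cond_class: dict[str, str] = {}
    if "claimed_class" in ct.columns:
        for cond, sub in ct.groupby("condition"):
            cls = sub["claimed_class"].unique()
            cond_class[str(cond)] = str(cls[0]) if len(cls) == 1 else "unknown"
    return FoldChangeTable(
        values=values,
        n_replicates=counts,
        condition_class=cond_class,
        reference_condition=reference_condition,
    )


def derive_thresholds(
    fc: FoldChangeTable | pd.DataFrame,
    reference_conditions: Mapping[str, str],
    directions: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene class medians and their mean, the scoring threshold.

    ``reference_conditions`` maps condition label -> known class; both
    classes need at least one condition. The threshold is the arithmetic
    mean of the gene's median fold change in the known inflammatory and
    known non-inflammatory conditions.
    """
    values = fc.values if isinstance(fc, FoldChangeTable) else fc
    inf_conds = [c for c, k in reference_conditions.items() if k == INFLAMMATORY]
    ninf_conds = [c for c, k in reference_conditions.items() if k == NON_INFLAMMATORY]
    if not inf_conds or not ninf_conds:
        raise ValueError(
            "reference_conditions must name at least one condition per class "
            f"(got {len(inf_conds)} inflammatory, {len(ninf_conds)} non-inflammatory)"
        )
    missing = [c for c in (*inf_conds, *ninf_conds) if c not in values.columns]
    if missing:
        raise ValueError(f"reference condition(s) absent from fold-change table: {missing}")
    no_dir = [g for g in values.index if g not in directions]
    if no_dir:
        raise ValueError(f"direction missing for gene(s): {no_dir[:10]}")

    med_inf = values[inf_conds].median(axis=1)
    med_ninf = values[ninf_conds].median(axis=1)
    degenerate = med_inf == med_ninf
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with equal class medians: "
            "threshold has zero margin",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "median_inflammatory": med_inf,
            "median_noninflammatory": med_ninf,
            "threshold": (med_inf + med_ninf) / 2.0,
            "direction": [directions[g] for g in values.index],
        },
        index=values.index.rename("gene_id"),
    )


def score_condition(
    values: Mapping[str, float] | pd.Series,
    thresholds: pd.DataFrame,
    claimed_class: str,
) -> pd.Series:
    """0/1 score per gene for one condition under a claimed class.

    An upregulated gene scores 1 when its fold change lies above its
    threshold under a claimed inflammatory class, or below it under a
    claimed non-inflammatory class; a downregulated gene scores 1 in the
    opposite cases. A value exactly at the threshold scores 0 (the rule's
    inequalities are strict).
    """
    if claimed_class not in (INFLAMMATORY, NON_INFLAMMATORY):
        raise ValueError(f"claimed_class must be a known class, got {claimed_class!r}")
    values = pd.Series(values, dtype=float)
    unknown = [g for g in values.index if g not in thresholds.index]
    if unknown:
        raise ValueError(f"gene(s) without thresholds: {unknown[:10]}")
    thr = thresholds.loc[values.index, "threshold"]
    direction = thresholds.loc[values.index, "direction"]
    above = values > thr
    below = values < thr
    if claimed_class == INFLAMMATORY:
        hit = np.where(direction == UP, above, below)
    else:
        hit = np.where(direction == UP, below, above)
    return pd.Series(hit.astype(int), index=values.index, name="score")


@dataclass(frozen=True)
class Concordance:
    fraction: float
    percent: int
    k_of_n: str


def concordance(scores) -> Concordance:
    """Fraction of genes scoring 1, its half-up rounded percent, and "k/n"."""
    scores = np.asarray(pd.Series(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    k = int(scores.sum())
    n = int(scores.size)
    fraction = k / n
    return Concordance(fraction=fraction, percent=round_half_up(100.0 * fraction), k_of_n=f"{k}/{n}")


@dataclass(frozen=True)
class ClassCall:
    call: str
    margin: float  # |vote difference| / n genes
    votes: pd.Series = field(repr=False)  # per-gene class vote


def call_class(
    values: Mapping[str, float] | pd.Series, thresholds: pd.DataFrame
) -> ClassCall:
    """Majority class call from per-gene threshold votes.

    Each gene votes inflammatory when its fold change sits on its
    inflammatory side of the threshold (above for up genes, below for down
    genes), non-inflammatory otherwise; exact majority ties resolve to
    non-inflammatory.
    """
    values = pd.Series(values, dtype=float)
    inf_scores = score_condition(values, thresholds, INFLAMMATORY)
    votes = pd.Series(
        np.where(inf_scores == 1, INFLAMMATORY, NON_INFLAMMATORY), index=values.index
    )
    n_inf = int((votes == INFLAMMATORY).sum())
    n = len(votes)
    call = INFLAMMATORY if n_inf > n - n_inf else NON_INFLAMMATORY
    return ClassCall(call=call, margin=abs(2 * n_inf - n) / n, votes=votes)


@dataclass
class ScoreCard:
    """Per-condition validation summary of the signature panel."""

    condition: str
    claimed_class: str
    scores: pd.Series  # gene -> 0/1
    concordance: Concordance
    class_call: str
    call_margin: float
    votes: pd.Series = field(repr=False)

    def to_frame(self, values: pd.Series, thresholds: pd.DataFrame) -> pd.DataFrame:
        """Tabular view mirroring a per-gene scorecard (value, threshold, score)."""
        return pd.DataFrame(
            {
                "gene_id": self.scores.index,
                "direction": thresholds.loc[self.scores.index, "direction"].to_numpy(),
                "fold_change": values.loc[self.scores.index].to_numpy(),
                "threshold": thresholds.loc[self.scores.index, "threshold"].to_numpy(),
                "score": self.scores.to_numpy(),
                "vote": self.votes.to_numpy(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "claimed_class": self.claimed_class,
            "concordance_fraction": self.concordance.fraction,
            "concordance_percent": self.concordance.percent,
            "k_of_n": self.concordance.k_of_n,
            "class_call": self.class_call,
            "call_margin": self.call_margin,
            "scores": {str(g): int(s) for g, s in self.scores.items()},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def build_scorecard(
    fc: FoldChangeTable,
    thresholds: pd.DataFrame,
    condition: str,
    claimed_class: str | None = None,
) -> ScoreCard:
    """Score one condition end to end and package the result.

    With ``claimed_class=None`` the condition's class recorded in the Ct
    table is used; the majority-vote class call is computed either way.
    """
    if condition not in fc.values.columns:
        raise ValueError(f"condition {condition!r} absent from fold-change table")
    values = fc.condition_values(condition).loc[thresholds.index]
    if claimed_class is None:
        claimed_class = fc.condition_class.get(condition, "unknown")
        if claimed_class not in (INFLAMMATORY, NON_INFLAMMATORY):
            raise ValueError(
                f"condition {condition!r} has no usable claimed class; pass one explicitly"
            )
    scores = score_condition(values, thresholds, claimed_class)
    cc = call_class(values, thresholds)
    return ScoreCard(
        condition=condition,
        claimed_class=claimed_class,
        scores=scores,
        concordance=concordance(scores),
        class_call=cc.call,
        call_margin=cc.margin,
        votes=cc.votes,
    )
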