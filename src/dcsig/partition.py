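"""Reproducible stratified train/test partitioning of the sample sheet.

The canonical study design assigns two thirds of the samples to training
and one third to testing, stratified by inflammation class. Sampling is
keyed on sorted sample ids, so the assignment is invariant to the row order
of the input sheet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._constants import round_half_up

TRAIN = "train"
TEST = "test"


@dataclass
class SplitAssignment:
    """Train/test role per sample plus the bookkeeping to reproduce it."""

    assignments: pd.DataFrame  # columns: sample_id, role
    seed: int
    stratum_counts: dict[str, dict[str, int]]  # stratum -> {train, test}

    @property
    def train_ids(self) -> list[str]:
        a = self.assignments
        return a.loc[a["role"] == TRAIN, "sample_id"].tolist()

    @property
    def test_ids(self) -> list[str]:
        a = self.assignments
        return a.loc[a["role"] == TEST, "sample_id"].tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def stratified_split(
    sheet: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    stratify_by: str = "class",
    seed: int = 0,
    override_counts: Mapping[str, int] | None = None,
) -> SplitAssignment:
    """Assign each sample to train or test, stratified by ``stratify_by``.

    Within each stratum, ``round(train_fraction * n)`` samples (half-up)
    are drawn without replacement into the training set. If the per-stratum
    rounding misses the global target ``round(train_fraction * N)``, the
    largest strata are adjusted by one sample each until totals match.
    ``override_counts`` (stratum value -> train count) takes precedence for
    the strata it names and disables the global adjustment for them.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if stratify_by not in sheet.columns:
        raise ValueError(f"stratify_by column {stratify_by!r} not in sample sheet")

    strata: dict[str, list[str]] = {}
    for key, sub in sheet.groupby(stratify_by, sort=True):
        strata[str(key)] = sorted(sub["sample_id"].astype(str))
    n_total = sum(len(v) for v in strata.values())

    override_counts = dict(override_counts or {})
    for key, k in override_counts.items():
        if key not in strata:
            raise ValueError(f"override stratum {key!r} not present in sheet")
        if not 0 <= k <= len(strata[key]):
            raise ValueError(
                f"override train count {k} out of range for stratum {key!r} "
                f"(size {len(strata[key])})"
            )

    train_counts = {
        key: override_counts.get(key, round_half_up(train_fraction * len(ids)))
        for key, ids in strata.items()
    }
    # nudge the largest strata by +/-1 until the global total matches; the
    # adjustment is skipped whenever overrides pin any stratum, since
    # explicit counts take precedence over the rounding target
    if not override_counts:
        target_total = round_half_up(train_fraction * n_total)
        order = sorted(strata, key=lambda k: (-len(strata[k]), k))
        i = 0
        while sum(train_counts.values()) != target_total:
            step = 1 if sum(train_counts.values()) < target_total else -1
            k = order[i % len(order)]
            new = train_counts[k] + step
            if 0 <= new <= len(strata[k]):
                train_counts[k] = new
            i += 1

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    stratum_counts: dict[str, dict[str, int]] = {}
    for key in sorted(strata):
        ids = strata[key]
        k = train_counts[key]
        chosen = set(rng.choice(np.asarray(ids, dtype=object), size=k, replace=False))
        for sid in ids:
            rows.append((sid, TRAIN if sid in chosen else TEST))
        stratum_counts[key] = {TRAIN: k, TEST: len(ids) - k}

    order = {sid: i for i, sid in enumerate(sheet["sample_id"].astype(str))}
    rows.sort(key=lambda r: order[r[0]])
    assignments = pd.DataFrame(rows, columns=["sample_id", "role"])
    return SplitAssignment(assignments=assignments, seed=seed, stratum_counts=stratum_counts)
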