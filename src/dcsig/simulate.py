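"""Synthetic two-class expression datasets with planted inflammation signatures.

Emulates the structure of a 115-array dendritic-cell stimulation study:
a log2-scale expression-index matrix (probe sets x samples), a sample sheet
assigning each array to an inflammatory or non-inflammatory stimulus class,
per-sample 3'/5' RNA-degradation QC ratios, and qRT-PCR Ct tables whose
implied 2^-ddCt fold changes follow the planted gene directions.

The generator plants ``n_signature_up`` genes shifted upward (and
``n_signature_down`` downward) in inflammatory samples by
``effect_size * noise_sd`` log2 units; all other genes are identically
distributed across classes. Ground truth is returned alongside the data so
recovery experiments can score selection output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import DOWN, INFLAMMATORY, NON_INFLAMMATORY, UNKNOWN, UP


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class GroupSpec:
    """One stimulus group: name, array count, class, and time points (h)."""

    stimulus: str
    n: int
    cls: str
    timepoints: tuple[float, ...] = ()

    def resolved_timepoints(self) -> list[float]:
        if self.timepoints:
            if len(self.timepoints) != self.n:
                raise ConfigError(
                    f"group_sizes[{self.stimulus!r}]: {len(self.timepoints)} "
                    f"timepoints for {self.n} arrays"
                )
            return list(self.timepoints)
        cycle = (2.0, 4.0, 8.0, 12.0, 24.0)
        return [cycle[i % len(cycle)] for i in range(self.n)]


def _dup(points: Sequence[float], k: int) -> tuple[float, ...]:
    return tuple(t for t in points for _ in range(k))


#: Default study design: 115 arrays over 12 stimulus groups, 79 inflammatory
#: and 36 non-inflammatory. Ten-array groups cover 2-24 h in duplicate,
#: eight-array groups 4-24 h in duplicate, dexamethasone 4/8/24 h in
#: duplicate, zymosan 2-24 h in triplicate; untreated arrays sit at 0 h.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("untreated", 14, NON_INFLAMMATORY, (0.0,) * 14),
    GroupSpec("CpG", 10, INFLAMMATORY, _dup((2, 4, 8, 12, 24), 2)),
    GroupSpec("Listeria", 10, INFLAMMATORY, _dup((2, 4, 8, 12, 24), 2)),
    GroupSpec("Pam3Cys", 10, INFLAMMATORY, _dup((2, 4, 8, 12, 24), 2)),
    GroupSpec("polyIC", 10, INFLAMMATORY, _dup((2, 4, 8, 12, 24), 2)),
    GroupSpec("Leishmania_amastigote", 8, NON_INFLAMMATORY, _dup((4, 8, 12, 24), 2)),
    GroupSpec("Leishmania_promastigote", 8, INFLAMMATORY, _dup((4, 8, 12, 24), 2)),
    GroupSpec("Schistosoma_SLA", 8, NON_INFLAMMATORY, _dup((4, 8, 12, 24), 2)),
    GroupSpec("Schistosoma_eggs", 8, INFLAMMATORY, _dup((4, 8, 12, 24), 2)),
    GroupSpec("LPS", 8, INFLAMMATORY, _dup((4, 8, 12, 24), 2)),
    GroupSpec("dexamethasone", 6, NON_INFLAMMATORY, _dup((4, 8, 24), 2)),
    GroupSpec("zymosan", 15, INFLAMMATORY, _dup((2, 4, 8, 12, 24), 3)),
)

#: Probe-set count of the full-scale array; the default config uses a
#: smaller matrix for speed, FULL_SCALE_N_GENES is the full-array preset.
FULL_SCALE_N_GENES = 12_488


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``effect_size`` is the planted mean log2 shift in the inflammatory class
    in units of ``noise_sd`` (so the absolute shift is
    ``effect_size * noise_sd`` log2 units). ``qc_fail_fraction`` is the
    probability that a sample's 3'/5' ratio is drawn above the 3.0 QC
    threshold.
    """

    n_genes: int = 2000
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_signature_up: int = 36
    n_signature_down: int = 18
    effect_size: float = 2.0
    noise_sd: float = 1.0
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if not self.groups:
            raise ConfigError("groups must be non-empty")
        for g in self.groups:
            if g.n <= 0:
                raise ConfigError(f"group_sizes[{g.stimulus!r}] must be positive")
            if g.cls not in (INFLAMMATORY, NON_INFLAMMATORY):
                raise ConfigError(f"group_sizes[{g.stimulus!r}] has unknown class {g.cls!r}")
        if self.n_signature_up < 0 or self.n_signature_down < 0:
            raise ConfigError("n_signature_up/n_signature_down must be non-negative")
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise ConfigError(
                "n_signature_up + n_signature_down exceeds n_genes "
                f"({self.n_signature_up}+{self.n_signature_down} > {self.n_genes})"
            )
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ConfigError(
                f"qc_fail_fraction must lie in [0, 1], got {self.qc_fail_fraction}"
            )

    @property
    def n_samples(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass
class GroundTruth:
    """Planted signature and class assignment for recovery scoring."""

    signature_up: list[str]
    signature_down: list[str]
    sample_class: dict[str, str]

    @property
    def directions(self) -> dict[str, str]:
        d = {g: UP for g in self.signature_up}
        d.update({g: DOWN for g in self.signature_down})
        return d

    @property
    def signature_gene_ids(self) -> list[str]:
        return self.signature_up + self.signature_down

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "signature_up": self.signature_up,
                    "signature_down": self.signature_down,
                    "sample_class": self.sample_class,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["signature_up"], d["signature_down"], d["sample_class"])


def _gene_ids(n: int) -> list[str]:
    # Affymetrix-like probe-set identifiers so fixtures resemble real tables
    return [f"{100000 + i}_at" for i in range(n)]


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the expression matrix, sample sheet, QC table, and truth.

    Returns
    -------
    matrix : DataFrame, genes x samples, log2-scale expression indices
    sheet : DataFrame with columns sample_id, stimulus, timepoint_h, class,
        replicate
    qc : DataFrame with columns sample_id, actin_ratio, gapdh_ratio
    truth : GroundTruth with planted gene directions and sample classes
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = _gene_ids(config.n_genes)

    rows = []
    for g in config.groups:
        tps = g.resolved_timepoints()
        for i, tp in enumerate(tps, start=1):
            sid = f"{g.stimulus}_{tp:g}h_r{i:02d}"
            rows.append((sid, g.stimulus, tp, g.cls, i))
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "stimulus", "timepoint_h", "class", "replicate"]
    )
    samples = sheet["sample_id"].tolist()
    n_s = len(samples)

    baseline = rng.uniform(4.0, 12.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_s))

    n_sig = config.n_signature_up + config.n_signature_down
    planted_idx = rng.choice(config.n_genes, size=n_sig, replace=False)
    up_idx = planted_idx[: config.n_signature_up]
    down_idx = planted_idx[config.n_signature_up :]

    infl_mask = (sheet["class"] == INFLAMMATORY).to_numpy()
    shift = config.effect_size * config.noise_sd
    values[np.ix_(up_idx, np.flatnonzero(infl_mask))] += shift
    values[np.ix_(down_idx, np.flatnonzero(infl_mask))] -= shift

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)

    fails = rng.random(n_s) < config.qc_fail_fraction
    which_metric = rng.integers(0, 2, size=n_s)  # 0 -> actin, 1 -> gapdh
    good = rng.uniform(0.8, 2.8, size=(n_s, 2))
    bad = rng.uniform(3.05, 6.0, size=n_s)
    ratios = good.copy()
    for i in range(n_s):
        if fails[i]:
            ratios[i, which_metric[i]] = bad[i]
    qc = pd.DataFrame(
        {"sample_id": samples, "actin_ratio": ratios[:, 0], "gapdh_ratio": ratios[:, 1]}
    )

    truth = GroundTruth(
        signature_up=[genes[i] for i in up_idx],
        signature_down=[genes[i] for i in down_idx],
        sample_class=dict(zip(sheet["sample_id"], sheet["class"])),
    )
    return matrix, sheet, qc, truth


def generate_ct_table(
    config: SyntheticConfig,
    truth: GroundTruth,
    conditions: Sequence[tuple[str, str]] | Mapping[str, str],
    *,
    genes: Sequence[str] | None = None,
    n_replicates: int = 3,
    log2_fold: float | None = None,
    noise_sd: float | None = None,
    reference_condition: str = "untreated",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table for the planted signature genes.

    Each (gene, condition, replicate) row carries a target Ct and an 18s
    housekeeping Ct. Target Cts are placed so that the implied 2^-ddCt fold
    change (relative to ``reference_condition``) is centred at
    ``2**log2_fold`` for genes whose planted direction agrees with the
    condition's class (up gene + inflammatory condition, or down gene +
    non-inflammatory condition) and at ``2**-log2_fold`` for the opposite
    pairings. Gaussian noise of sd ``noise_sd`` cycles (default
    ``config.noise_sd``; 0 gives exact planted folds) is added to every
    target Ct; the 18s Ct is constant within a replicate batch, since
    housekeeping noise is not separately identifiable in 2^-ddCt.

    ``conditions`` maps condition label -> claimed class. ``log2_fold``
    defaults to ``config.effect_size * config.noise_sd`` to mirror the
    array-side planted shift. A dedicated random stream is derived from
    ``(config.seed, 1)`` unless ``seed`` is given.
    """
    cond_items = list(conditions.items()) if isinstance(conditions, Mapping) else list(conditions)
    for label, cls in cond_items:
        if cls not in (INFLAMMATORY, NON_INFLAMMATORY):
            raise ValueError(f"condition {label!r} has unknown class {cls!r}")
    if genes is None:
        genes = truth.signature_gene_ids
    directions = truth.directions
    unknown = [g for g in genes if g not in directions]
    if unknown:
        raise ValueError(f"unknown gene ids (not in planted signature): {unknown}")
    if log2_fold is None:
        log2_fold = config.effect_size * config.noise_sd
    if noise_sd is None:
        noise_sd = config.noise_sd
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")

    ss = np.random.SeedSequence((config.seed, 1)) if seed is None else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    base_ct = {g: rng.uniform(20.0, 30.0) for g in genes}
    ct_18s = 10.0  # constant per replicate batch by construction

    rows = []
    all_conditions = [(reference_condition, UNKNOWN, 0.0)]
    for label, cls in cond_items:
        sign = (1.0 if cls == INFLAMMATORY else -1.0)
        all_conditions.append((label, cls, sign))
    for gid in genes:
        dir_sign = 1.0 if directions[gid] == UP else -1.0
        for label, cls, cond_sign in all_conditions:
            planted = dir_sign * cond_sign * log2_fold
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                # fold = 2^-ddCt, so a +planted log2 fold lowers the target Ct
                target = base_ct[gid] - planted + noise
                rows.append((gid, label, cls, rep, target, ct_18s))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "condition", "claimed_class", "replicate", "ct_target", "ct_18s"],
    )


def write_dataset(
    config: SyntheticConfig,
    outdir: str | Path,
    *,
    ct_conditions: Sequence[tuple[str, str]] | None = None,
) -> dict[str, Path]:
    """Generate and write all synthetic artifacts to ``outdir``.

    Writes the expression matrix, sample sheet and QC table as TSV, the
    ground truth as JSON and, when ``ct_conditions`` is given, a Ct table
    CSV. Returns the mapping of artifact name to path.
    """
    from . import io  # local import: io depends only on pandas

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, sheet, qc, truth = generate_expression(config)
    paths = {
        "matrix": outdir / "expression.tsv",
        "sheet": outdir / "samples.tsv",
        "qc": outdir / "qc.tsv",
        "truth": outdir / "ground_truth.json",
    }
    io.write_expression_tsv(matrix, paths["matrix"])
    io.write_table(sheet, paths["sheet"])
    io.write_table(qc, paths["qc"])
    truth.to_json(paths["truth"])
    if ct_conditions is not None:
        ct = generate_ct_table(config, truth, ct_conditions)
        paths["ct"] = outdir / "ct.csv"
        io.write_table(ct, paths["ct"], sep=",")
    return paths
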