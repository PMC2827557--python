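"""End-to-end orchestration: simulate/load -> QC -> transform -> split ->
select -> classify -> qPCR scoring, with a JSON-serializable run report.

The single run ``seed`` deterministically derives one sub-seed per stage
via ``numpy.random.SeedSequence((seed, stage_index))`` (stage indices:
0 simulation, 1 Ct simulation — inside the generator —, 2 split,
3 selection), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._constants import INFLAMMATORY, NON_INFLAMMATORY
from . import io
from .forest import classify, train_forest
from .partition import stratified_split
from .preprocess import cluster_order, log2_ratio_to_mean, pca_scores, qc_filter, zscore_transform
from .scoring import ScoreCard, build_scorecard, derive_thresholds, fold_change
from .selection import backward_elimination, finalize_signature
from .simulate import SyntheticConfig, generate_ct_table, generate_expression

#: qPCR validation panel mirroring the six in vitro reference stimuli:
#: three TLR-ligand (inflammatory) and three suppressive treatments.
DEFAULT_CT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("LPS_24h", INFLAMMATORY),
    ("polyIC_24h", INFLAMMATORY),
    ("zymosan_24h", INFLAMMATORY),
    ("dexamethasone_24h", NON_INFLAMMATORY),
    ("IL10_24h", NON_INFLAMMATORY),
    ("vitaminD_24h", NON_INFLAMMATORY),
)


@dataclass
class RunConfig:
    """Every knob of a pipeline run, with documented defaults.

    Either ``simulation`` is set (synthetic inputs are generated) or the
    four input paths are. ``override_counts`` pins per-class training-set
    sizes; ``top_k`` forces a fixed signature size instead of the s.e. rule.
    """

    simulation: SyntheticConfig | None = None
    matrix_path: str | None = None
    sheet_path: str | None = None
    qc_path: str | None = None
    ct_path: str | None = None
    qc_threshold: float = 3.0
    train_fraction: float = 2.0 / 3.0
    stratify_by: str = "class"
    override_counts: dict[str, int] | None = None
    n_trees: int = 1000
    mtry: int | None = None
    drop_fraction: float = 0.2
    se_rule: float = 1.0
    top_k: int | None = None
    ct_conditions: tuple[tuple[str, str], ...] = DEFAULT_CT_CONDITIONS
    reference_conditions: dict[str, str] | None = None  # default: all ct_conditions
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SyntheticConfig(**sim)
        if cfg.ct_conditions is not None:
            cfg.ct_conditions = tuple((str(a), str(b)) for a, b in cfg.ct_conditions)
        return cfg


@dataclass
class RunReport:
    """Everything a run produced, regenerable from config + inputs."""

    seed: int
    parameters: dict
    n_samples: int
    excluded_samples: list[str]
    split_counts: dict
    signature: list[dict]
    oob_trajectory: list[dict]
    confusion: dict
    test_accuracy: float
    scorecards: list[dict]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and assemble the run report.

    Stages: (a) expression-index input (simulated or loaded), QC filtering
    and z-score transform; (b) stratified split and random-forest backward
    elimination on the training set; (c) classification of the held-out test
    set; (d) qRT-PCR fold-change scoring of the validation panel against
    per-gene thresholds. Idempotent for a fixed config.
    """
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        report = _run(config, caught)
    report.warnings = caught + [str(w.message) for w in wrec]
    return report


def _run(config: RunConfig, caught: list[str]) -> RunReport:
    truth = None
    ct = None
    if config.simulation is not None:
        # the run seed governs every stage: the simulation's own seed field
        # is replaced by the stage-0 sub-seed
        sim = replace(config.simulation, seed=_stage_seed(config.seed, 0))
        matrix, sheet, qc, truth = generate_expression(sim)
        if config.ct_conditions:
            ct = generate_ct_table(sim, truth, list(config.ct_conditions))
    else:
        if not (config.matrix_path and config.sheet_path):
            raise ValueError("run_pipeline: provide either simulation or matrix/sheet paths")
        matrix = io.read_expression_tsv(config.matrix_path)
        sheet = io.read_sample_sheet(config.sheet_path)
        qc = io.read_qc_tsv(config.qc_path) if config.qc_path else None
        ct = io.read_ct_csv(config.ct_path) if config.ct_path else None

    excluded: list[str] = []
    if qc is not None:
        matrix, excluded = qc_filter(matrix, qc, threshold=config.qc_threshold)
        sheet = sheet[~sheet["sample_id"].isin(excluded)].reset_index(drop=True)

    zmatrix = zscore_transform(matrix)
    labels = dict(zip(sheet["sample_id"], sheet["class"]))

    split = stratified_split(
        sheet,
        train_fraction=config.train_fraction,
        stratify_by=config.stratify_by,
        seed=_stage_seed(config.seed, 2),
        override_counts=config.override_counts,
    )
    train_m = zmatrix[split.train_ids]
    test_m = zmatrix[split.test_ids]

    sig = backward_elimination(
        train_m,
        labels,
        drop_fraction=config.drop_fraction,
        se_rule=config.se_rule,
        n_trees=config.n_trees,
        mtry=config.mtry,
        seed=_stage_seed(config.seed, 3),
        top_k=config.top_k,
    )
    sig = finalize_signature(sig, train_m, labels)

    model = train_forest(
        train_m.loc[sig.gene_ids],
        labels,
        n_trees=config.n_trees,
        mtry=config.mtry,
        seed=_stage_seed(config.seed, 3) + 1,
    )
    preds = classify(model, test_m)
    truth_labels = pd.Series({s: labels[s] for s in preds.index})
    confusion = {
        "tp": int(((preds["predicted_class"] == INFLAMMATORY) & (truth_labels == INFLAMMATORY)).sum()),
        "fp": int(((preds["predicted_class"] == INFLAMMATORY) & (truth_labels == NON_INFLAMMATORY)).sum()),
        "fn": int(((preds["predicted_class"] == NON_INFLAMMATORY) & (truth_labels == INFLAMMATORY)).sum()),
        "tn": int(((preds["predicted_class"] == NON_INFLAMMATORY) & (truth_labels == NON_INFLAMMATORY)).sum()),
    }
    accuracy = (confusion["tp"] + confusion["tn"]) / max(1, len(preds))

    scorecards: list[ScoreCard] = []
    fc = thresholds = None
    if ct is not None:
        # restrict the panel to signature genes measured in the Ct table
        panel = [g for g in sig.gene_ids if g in set(ct["gene_id"])]
        if panel:
            fc = fold_change(ct[ct["gene_id"].isin(panel)])
            refs = config.reference_conditions or {
                c: k for c, k in (config.ct_conditions or []) if c in fc.values.columns
            }
            thresholds = derive_thresholds(fc, refs, sig.directions)
            for cond in fc.values.columns:
                if cond == fc.reference_condition:
                    continue
                scorecards.append(build_scorecard(fc, thresholds, cond))
        else:
            caught.append("no signature gene measured in the Ct table; scoring skipped")

    report = RunReport(
        seed=config.seed,
        parameters={
            "qc_threshold": config.qc_threshold,
            "train_fraction": config.train_fraction,
            "stratify_by": config.stratify_by,
            "override_counts": config.override_counts,
            "n_trees": config.n_trees,
            "mtry": config.mtry,
            "drop_fraction": config.drop_fraction,
            "se_rule": config.se_rule,
            "top_k": config.top_k,
            "stage_seeds": {s: _stage_seed(config.seed, s) for s in (0, 2, 3)},
            "simulation": asdict_config(config.simulation) if config.simulation else None,
        },
        n_samples=matrix.shape[1],
        excluded_samples=excluded,
        split_counts=split.stratum_counts,
        signature=sig.table.to_dict(orient="records"),
        oob_trajectory=sig.trajectory.to_dict(orient="records"),
        confusion=confusion,
        test_accuracy=float(accuracy),
        scorecards=[sc.to_dict() for sc in scorecards],
    )

    if config.outdir:
        render_outputs(
            report,
            Path(config.outdir),
            matrix=zmatrix,
            signature=sig,
            split=split,
            pca_input=zmatrix,
            fc=fc,
            thresholds=thresholds,
            scorecards=scorecards,
        )
    return report


def asdict_config(sim: SyntheticConfig | None) -> dict | None:
    """JSON-serializable view of a simulation config (for the report)."""
    return None if sim is None else asdict(sim)


def render_outputs(
    report: RunReport,
    outdir: Path,
    *,
    matrix: pd.DataFrame,
    signature,
    split,
    pca_input: pd.DataFrame,
    fc=None,
    thresholds: pd.DataFrame | None = None,
    scorecards: Sequence[ScoreCard] = (),
) -> dict[str, Path]:
    """Write every run artifact as plain text under ``outdir``.

    Emits the signature TSV, OOB-trajectory CSV, split TSV, PCA scores TSV,
    a cluster-ordered log2-ratio-to-mean heat-map matrix TSV restricted to
    the signature genes, per-condition scorecard TSVs, and the JSON report.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["signature"] = outdir / "signature.tsv"
    signature.write_tsv(paths["signature"])
    paths["trajectory"] = outdir / "oob_trajectory.csv"
    signature.trajectory.to_csv(paths["trajectory"], index=False)
    paths["split"] = outdir / "split.tsv"
    split.write_tsv(paths["split"])

    pca = pca_scores(pca_input, n_components=2)
    paths["pca"] = outdir / "pca_scores.tsv"
    pca.scores.rename_axis("sample_id").to_csv(paths["pca"], sep="\t")

    sig_matrix = log2_ratio_to_mean(matrix.loc[signature.gene_ids])
    row_order = cluster_order(sig_matrix, axis="genes") if len(sig_matrix) > 1 else list(sig_matrix.index)
    col_order = cluster_order(sig_matrix, axis="samples")
    paths["heatmap"] = outdir / "heatmap_matrix.tsv"
    io.write_expression_tsv(sig_matrix.loc[row_order, col_order], paths["heatmap"])

    if fc is not None:
        paths["fold_changes"] = outdir / "fold_changes.csv"
        fc.values.rename_axis("gene_id").to_csv(paths["fold_changes"])
    if thresholds is not None:
        paths["thresholds"] = outdir / "thresholds.csv"
        thresholds.to_csv(paths["thresholds"])
    for sc in scorecards:
        p = outdir / f"scorecard_{sc.condition}.tsv"
        sc.to_frame(fc.condition_values(sc.condition), thresholds).to_csv(p, sep="\t", index=False)
        paths[f"scorecard_{sc.condition}"] = p

    paths["report"] = outdir / "report.json"
    report.to_json(paths["report"])
    return paths
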