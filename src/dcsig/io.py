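"""Plain-text readers/writers for all pipeline tables.

Every format is TSV/CSV with a header row, or JSON for nested structures.
The expression matrix convention is: first column ``gene_id``, remaining
columns one per sample, values log2-scale expression indices.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

SHEET_COLUMNS = ["sample_id", "stimulus", "timepoint_h", "class", "replicate"]
QC_COLUMNS = ["sample_id", "actin_ratio", "gapdh_ratio"]
CT_COLUMNS = ["gene_id", "condition", "claimed_class", "replicate", "ct_target", "ct_18s"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (gene_id-indexed)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return sheet


def read_qc_tsv(path: str | Path) -> pd.DataFrame:
    qc = pd.read_csv(path, sep="\t")
    missing = [c for c in QC_COLUMNS if c not in qc.columns]
    if missing:
        raise ValueError(f"QC table {path} lacks columns {missing}")
    return qc


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table {path} lacks columns {missing}")
    return ct


def read_split_tsv(path: str | Path) -> pd.DataFrame:
    split = pd.read_csv(path, sep="\t")
    if not {"sample_id", "role"}.issubset(split.columns):
        raise ValueError(f"split table {path} needs sample_id and role columns")
    return split


def read_signature_tsv(path: str | Path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t")
    if "gene_id" not in sig.columns or "direction" not in sig.columns:
        raise ValueError(f"signature table {path} needs gene_id and direction columns")
    return sig


def load_published_signature() -> pd.DataFrame:
    """The packaged 54-gene dendritic-cell inflammation signature.

    Columns: gene_id (Affymetrix MG-U74Av2 probe set), gene_symbol, and
    direction ('up' = higher under inflammatory stimulation, 'down' =
    repressed by inflammation; 18 down / 36 up).
    """
    with resources.files("dcsig.data").joinpath("signature_54.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
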