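"""Cell-table schema: the universal input of the pipeline.

A cell table is a :class:`pandas.DataFrame` with one row per cell and columns
``cell_id`` (int), ``x_um``/``y_um`` (float, micrometres) and ``class`` (str,
one of :data:`ALL_CLASSES`).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# H&E channel classes
HE_CLASSES = ("cancer", "stromal", "lymphocyte")

# IHC immune subsets (the six lymphocyte classes used in interaction analysis)
IMMUNE_SUBSETS = (
    "CD8",
    "CD4_FOXP3neg",
    "CD4_FOXP3pos",
    "CD20_CXCR5neg",
    "CD20_CXCR5pos",
    "CD79b",
)

B_SUBSETS = ("CD20_CXCR5neg", "CD20_CXCR5pos", "CD79b")
T_SUBSETS = ("CD8", "CD4_FOXP3neg", "CD4_FOXP3pos")

# P40+ neoplastic cells (IHC); excluded from immune interaction graphs
NEOPLASTIC_IHC = "P40"

ALL_CLASSES = HE_CLASSES + IMMUNE_SUBSETS + (NEOPLASTIC_IHC,)

REQUIRED_COLUMNS = ("x_um", "y_um", "class")

#: Default mapping from cell class to hotspot channel.  IHC immune subsets
#: count as lymphocytes, P40+ counts as cancer; stromal cells occupy tissue
#: but contribute to neither channel.
DEFAULT_CHANNEL_MAP: Mapping[str, str] = {
    "cancer": "cancer",
    "P40": "cancer",
    "lymphocyte": "lymphocyte",
    **{s: "lymphocyte" for s in IMMUNE_SUBSETS},
    "stromal": "ignored",
}


class CellTableError(ValueError):
    """Raised when a cell table fails schema validation."""


def make_cell_table(x, y, labels) -> pd.DataFrame:
    """Assemble a validated cell table from coordinate and label arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if not (x.shape == y.shape == labels.shape):
        raise CellTableError("x, y and labels must have identical shapes")
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(x), dtype=int),
            "x_um": x,
            "y_um": y,
            "class": labels.astype(str),
        }
    )
    return validate_cell_table(df)


def validate_cell_table(
    df: pd.DataFrame, vocabulary: Iterable[str] = ALL_CLASSES
) -> pd.DataFrame:
    """Validate required columns, finite coordinates, and the label vocabulary.

    Returns the validated frame (with ``cell_id`` added if missing).  Raises
    :class:`CellTableError` naming offending rows otherwise.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"cell table is missing required columns: {missing}")
    if len(df) == 0:
        out = df.copy()
        if "cell_id" not in out.columns:
            out.insert(0, "cell_id", pd.Series(dtype=int))
        return out

    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise CellTableError(
                f"non-finite or non-numeric {col} at rows {bad[:10].tolist()}"
            )

    vocab = set(vocabulary)
    labels = df["class"].astype(str)
    unknown_mask = ~labels.isin(vocab)
    if unknown_mask.any():
        rows = np.flatnonzero(unknown_mask.to_numpy())
        bad_labels = sorted(labels[unknown_mask].unique())
        raise CellTableError(
            f"unknown class labels {bad_labels} at rows {rows[:10].tolist()}"
        )

    out = df.copy()
    out["x_um"] = pd.to_numeric(out["x_um"])
    out["y_um"] = pd.to_numeric(out["y_um"])
    out["class"] = labels
    if "cell_id" not in out.columns:
        out.insert(0, "cell_id", np.arange(len(out), dtype=int))
    return out


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": pd.Series(dtype=int),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "class": pd.Series(dtype=str),
        }
    )
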