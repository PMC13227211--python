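"""Readers and writers for every tabular artifact the pipeline touches.

All tables are tab-separated UTF-8 text with "." decimals; an empty
cell means missing.  Protein and TF identifiers are opaque strings
matched exactly — identifier mapping is upstream curation, not this
pipeline's job.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .concordance import BindingMatrix, normalize_binary_cell
from .design import ChannelAssignment, Condition, DesignMap
from .quant import AbundanceMatrix

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_DETECTED_COLUMN = "detected"


def read_abundance_table(path: PathLike, design: DesignMap) -> AbundanceMatrix:
    """Read a proteins x channels grouped-abundance table.

    First column: protein identifier; remaining columns named by
    channel label; empty cells mean not quantified.  An optional
    boolean ``detected`` column carries the identified-by-PSM flag
    (defaults to True).  Every channel in the design must be present;
    unknown non-channel columns are an error, as are duplicate protein
    identifiers and non-numeric non-empty cells.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no columns found")
    id_col = frame.columns[0]
    frame = frame.set_index(id_col)
    frame.index.name = "protein"
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate protein identifiers {list(dup)[:5]}")

    detected = pd.Series(True, index=frame.index)
    if _DETECTED_COLUMN in frame.columns:
        detected = frame[_DETECTED_COLUMN].str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if detected.isna().any():
            raise ValueError(f"{path}: non-boolean value in 'detected' column")
        frame = frame.drop(columns=[_DETECTED_COLUMN])

    wanted = design.channels
    missing = [ch for ch in wanted if ch not in frame.columns]
    if missing:
        raise ValueError(f"{path}: design channel(s) missing from file: {missing}")
    unknown = [c for c in frame.columns if c not in wanted]
    if unknown:
        raise ValueError(f"{path}: unknown channel column(s): {unknown}")

    values = frame[wanted].replace("", np.nan)
    try:
        values = values.astype(float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric non-empty cell ({err})") from None
    if len(values) == 0:
        logger.warning("%s: abundance table has no data rows", path)
    return AbundanceMatrix(values, detected)


def write_abundance_table(matrix: AbundanceMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out[_DETECTED_COLUMN] = matrix.detected
    out.to_csv(path, sep="\t", na_rep="")


def read_gene_list(path: PathLike) -> set:
    """Read a one-symbol-per-line gene list into a case-preserved set.

    A first line matching a common header word (gene/symbol/protein/
    id/tf, plural tolerated) is skipped.  Duplicate symbols are
    deduplicated and counted in the log; an empty file yields an empty
    set with a warning.
    """
    lines = [
        ln.strip()
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if lines and lines[0].lower().rstrip("s") in {"gene", "symbol", "protein", "id", "tf"}:
        lines = lines[1:]
    if not lines:
        logger.warning("%s: empty gene list", path)
        return set()
    symbols = set(lines)
    duplicates = len(lines) - len(symbols)
    if duplicates:
        logger.info("%s: %d duplicate symbol(s) removed", path, duplicates)
    return symbols


def write_gene_list(symbols, path: PathLike) -> None:
    Path(path).write_text(
        "\n".join(sorted(symbols)) + ("\n" if symbols else ""), encoding="utf-8"
    )


def read_binding_matrix(path: PathLike) -> BindingMatrix:
    """Read a TF x locus binary table (cells in {0, 1, Yes, No, Y, N})."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    frame.index.name = "tf"
    return BindingMatrix.from_raw(frame)


def write_binding_matrix(matrix: BindingMatrix, path: PathLike) -> None:
    matrix.cells.to_csv(path, sep="\t")


def read_expression_table(path: PathLike) -> pd.Series:
    """Read a gene -> log2(TPM+1) expression table."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    col = "log2_tpm_plus1" if "log2_tpm_plus1" in frame.columns else frame.columns[0]
    series = frame[col].astype(float)
    if (series < 0).any():
        raise ValueError(f"{path}: log2(TPM+1) expression must be nonnegative")
    return series


def read_detection_table(path: PathLike) -> pd.DataFrame:
    """Read a TF detection-status table (tf, status, expression)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "status" not in frame.columns:
        raise ValueError(f"{path}: detection table needs a 'status' column")
    return frame


def write_detection_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t")


def read_ct_table(path: PathLike) -> pd.DataFrame:
    """Read a long-format qPCR Ct table."""
    return pd.read_csv(path, sep="\t")


def write_ct_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


_CONDITION_VALUES = {c.value: c for c in Condition}


def read_design(path: PathLike) -> DesignMap:
    """Read a channel/condition/bio_replicate design table."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"channel_label", "condition", "bio_replicate"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: design table needs columns {sorted(needed)}")
    assignments = []
    for _, row in frame.iterrows():
        cond = _CONDITION_VALUES.get(row["condition"])
        if cond is None:
            raise ValueError(f"{path}: unknown condition {row['condition']!r}")
        rep = row["bio_replicate"].strip()
        assignments.append(
            ChannelAssignment(
                row["channel_label"], cond, int(rep) if rep else None
            )
        )
    return DesignMap(tuple(assignments))


def write_design(design: DesignMap, path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "channel_label": [a.channel_label for a in design.assignments],
            "condition": [a.condition.value for a in design.assignments],
            "bio_replicate": [
                "" if a.bio_replicate is None else a.bio_replicate
                for a in design.assignments
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_truth_table(truth, path: PathLike) -> None:
    """Write a ground-truth protein table (class, flags, expression, status)."""
    truth.proteins.to_csv(path, sep="\t")
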