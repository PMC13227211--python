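"""Quantification preprocessing: normalization, detection filters, and
per-condition summaries with propagated uncertainty.

Raw grouped protein abundances (reporter-ion rollups per TMT channel)
are median normalized within each channel, filtered for proteins that
cannot support a ratio, and summarized per biological condition as a
mean with a standard error.  The log2 transform needed for the Z
contrast carries its uncertainty through the first-order delta method:
``sem_log2 = sem_y / (y * ln 2)``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    Condition,
    DesignMap,
    ON_TARGET_CONDITIONS,
    LABELING_CONDITIONS,
    SemPoolingRule,
)

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: Condition-summary labels produced by :func:`summarize_conditions`.
SUMMARY_CONDITIONS = ("on_target", "NoGplus", "NoGminus", "labeling", "pool")


@dataclasses.dataclass
class AbundanceMatrix:
    """Proteins x channels abundance table.

    ``values`` is a DataFrame indexed by protein identifier with one
    column per channel label; missing (not-quantified) cells are NaN.
    ``detected`` flags proteins identified by at least one PSM even if
    no channel produced a quantification.
    """

    values: pd.DataFrame
    detected: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein identifiers: {list(dup)[:5]}")
        if not self.values.index.equals(self.detected.index):
            self.detected = self.detected.reindex(self.values.index, fill_value=True)
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError("abundances must be positive where present")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.detected.copy())


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each channel so its median matches the grand reference.

    The reference is the mean of the original per-channel medians, which
    keeps the overall abundance scale (and therefore linear-space SEMs)
    comparable before and after normalization.  Missing cells stay
    missing.  Raises on an all-missing channel.
    """
    values = matrix.values
    medians = values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"channel(s) with no quantified values: {bad}")
    reference = medians.mean()
    scaled = values * (reference / medians)
    return AbundanceMatrix(scaled, matrix.detected.copy())


def filter_unquantified(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, int]:
    """Drop proteins with no quantified value in any channel."""
    keep = matrix.values.notna().any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_unquantified removed %d protein(s)", removed)
    out = AbundanceMatrix(matrix.values.loc[keep], matrix.detected.loc[keep])
    return out, removed


def filter_undetected_conditions(
    matrix: AbundanceMatrix, design: DesignMap
) -> tuple[AbundanceMatrix, int]:
    """Drop proteins lacking a value in any of the four reference groups.

    The groups are NoG-, NoG+, pooled gRNAs (union of g1/g2/g3 channels)
    and the sample pool; a protein absent from one of them would produce
    an undefined ratio downstream.
    """
    groups = [
        design.channels_for(Condition.NOG_MINUS),
        design.channels_for(Condition.NOG_PLUS),
        design.on_target_channels,
        design.channels_for(Condition.POOL),
    ]
    keep = pd.Series(True, index=matrix.proteins)
    for chans in groups:
        keep &= matrix.values[chans].notna().any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_undetected_conditions removed %d protein(s)", removed)
    out = AbundanceMatrix(matrix.values.loc[keep], matrix.detected.loc[keep])
    return out, removed


def _mean_sem(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise mean, sample-SD-based SEM and contributing count."""
    n = values.notna().sum(axis=1)
    y = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)  # NaN when n < 2
    sem = sd / np.sqrt(n.where(n > 0))
    return pd.DataFrame({"y": y, "sem_y": sem, "n_values": n})


def summarize_conditions(
    matrix: AbundanceMatrix,
    design: DesignMap,
    rule: SemPoolingRule = SemPoolingRule.PER_CHANNEL_VALUES,
    add_log2: bool = True,
) -> pd.DataFrame:
    """Per-protein, per-condition mean abundance with SEM.

    Returns a tidy frame indexed by (protein, condition) with columns
    ``y``, ``sem_y``, ``n_values`` and — unless ``add_log2`` is False —
    ``log2_y``, ``sem_log2``.  Conditions summarized:

    - ``on_target``: pooled g1/g2/g3 channels (pooling per ``rule``),
    - ``NoGplus`` / ``NoGminus``: the three replicate channels each,
    - ``labeling``: all channels where labeling occurred (g1/g2/g3 and
      NoG+), pooled in parallel with the on-target rule — the reference
      for the contaminant contrast,
    - ``pool``: the single sample-pool channel.

    Missing cells are excluded from both mean and SEM, reducing
    ``n_values``.  A condition with a single contributing value has an
    undefined (NaN) SEM; such proteins are excluded from inferential
    contrasts downstream.
    """
    rule = SemPoolingRule(rule)
    values = matrix.values
    pieces: dict[str, pd.DataFrame] = {}

    grna_groups = [design.channels_for(c) for c in ON_TARGET_CONDITIONS]
    if rule is SemPoolingRule.PER_CHANNEL_VALUES:
        pieces["on_target"] = _mean_sem(values[design.on_target_channels])
        pieces["labeling"] = _mean_sem(values[design.labeling_channels])
    else:  # per_gRNA_means: collapse replicates within a gRNA first
        grna_means = pd.concat(
            [values[chans].mean(axis=1, skipna=True) for chans in grna_groups],
            axis=1,
        )
        pieces["on_target"] = _mean_sem(grna_means)
        nog_plus = values[design.channels_for(Condition.NOG_PLUS)].mean(
            axis=1, skipna=True
        )
        pieces["labeling"] = _mean_sem(pd.concat([grna_means, nog_plus], axis=1))

    pieces["NoGplus"] = _mean_sem(values[design.channels_for(Condition.NOG_PLUS)])
    pieces["NoGminus"] = _mean_sem(values[design.channels_for(Condition.NOG_MINUS)])
    pool_channels = design.channels_for(Condition.POOL)
    if pool_channels:
        pieces["pool"] = _mean_sem(values[pool_channels])

    summary = pd.concat(pieces, names=["condition", "protein"]).swaplevel()
    summary = summary.sort_index(level="protein", sort_remaining=False)
    if add_log2:
        summary = log2_with_delta_error(summary)
    return summary


def log2_with_delta_error(summary: pd.DataFrame) -> pd.DataFrame:
    """Add log2-scale mean and delta-method SEM to a linear summary.

    ``log2_y = log2(y)`` and ``sem_log2 = sem_y / (y * ln 2)``, the
    first-order propagation of the linear-scale standard error through
    the log2 transform.  Requires y > 0 wherever defined.
    """
    out = summary.copy()
    y = out["y"]
    if (y <= 0).any():
        raise ValueError("log2 transform requires positive condition means")
    out["log2_y"] = np.log2(y)
    out["sem_log2"] = out["sem_y"] / (y * LN2)
    return out


def decoy_fdr(n_decoys: int, n_targets: int) -> float:
    """Protein-level decoy false-discovery rate as a percentage.

    100 * decoys / targets, reported to one decimal — the conventional
    target-decoy estimate at the protein level.
    """
    if n_targets <= 0:
        raise ValueError("n_targets must be positive")
    if n_decoys < 0:
        raise ValueError("n_decoys must be nonnegative")
    return round(100.0 * n_decoys / n_targets, 1)
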