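"""ChIP-qPCR enrichment by the 2^-ddCt method.

Relative enrichment of a pulled-down locus over an off-target reference
locus is computed as ddCt = (Ct_chip,target - Ct_chip,reference) -
(Ct_input,target - Ct_input,reference), after normalizing the diluted
input aliquot to 100% by subtracting log2(dilution / input_fraction)
cycles from its raw Ct (9.966 cycles for a ten-fold dilution of a 1%
input).  The fold change is 2^-ddCt; replicate fold changes are
averaged on the linear scale and reported as mean +/- SEM.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import TTestVariant

#: Required columns of a long-format Ct table.
CT_COLUMNS = (
    "condition",      # e.g. pooled_gRNAs / NoG
    "fraction",       # chip | input
    "primer",         # primer-pair name
    "primer_role",    # target | reference
    "bio_replicate",
    "tech_replicate",
    "well",
    "ct",
    "dilution",       # 1 for chip rows
    "input_fraction", # 1.0 for chip rows
)


def input_adjustment(dilution: float, input_fraction: float) -> float:
    """Cycles to subtract from a diluted input Ct to represent 100% input.

    offset = log2(dilution / input_fraction); e.g. a 10x dilution of a
    1% input is 1000-fold less template than the pulldown's reference
    point, i.e. log2(1000) = 9.966 cycles.
    """
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if not 0 < input_fraction <= 1:
        raise ValueError("input fraction must lie in (0, 1]")
    return math.log2(dilution / input_fraction)


def ddct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate ddCt and fold change from a long-format Ct table.

    Processing order follows the assay design: quadruplicate qPCR wells
    are averaged on the Ct scale, Ct values of multiple target primer
    pairs within a replicate are averaged, diluted input Cts are
    reduced by :func:`input_adjustment`, and then
    ddCt = chip(Ct_target - Ct_ref) - adjusted input(Ct_target -
    Ct_ref), with fc = 2^-ddCt.  Raises if any of the four Ct
    components is missing for a replicate.
    """
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks column(s): {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    work = table.copy()
    offsets = np.array(
        [
            input_adjustment(d, f) if frac == "input" else 0.0
            for frac, d, f in zip(
                work["fraction"], work["dilution"], work["input_fraction"]
            )
        ]
    )
    work["ct_adj"] = work["ct"].to_numpy(dtype=float) - offsets

    # wells -> primer means -> role means (target primer pairs averaged)
    keys = ["condition", "bio_replicate", "tech_replicate", "fraction", "primer_role"]
    per_primer = (
        work.groupby(keys + ["primer"], sort=True)["ct_adj"].mean().reset_index()
    )
    per_role = per_primer.groupby(keys, sort=True)["ct_adj"].mean().unstack(
        ["fraction", "primer_role"]
    )

    needed = [
        ("chip", "target"),
        ("chip", "reference"),
        ("input", "target"),
        ("input", "reference"),
    ]
    for col in needed:
        if col not in per_role.columns or per_role[col].isna().any():
            raise ValueError(f"missing Ct component {col} for some replicate")

    delta_chip = per_role[("chip", "target")] - per_role[("chip", "reference")]
    delta_input = per_role[("input", "target")] - per_role[("input", "reference")]
    out = per_role.index.to_frame(index=False)
    out["delta_delta_ct"] = (delta_chip - delta_input).to_numpy()
    out["fc"] = np.exp2(-out["delta_delta_ct"])
    return out


@dataclasses.dataclass
class EnrichmentSummary:
    condition: str
    n: int
    mean_fc: float
    sem_fc: float


def summarize_enrichment(
    results: pd.DataFrame,
    reference_condition: Optional[str] = None,
    variant: TTestVariant = TTestVariant.WELCH,
    null_fc: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group replicate fold changes and test for enrichment.

    ``results`` is the output of :func:`ddct` (one row per replicate).
    Fold changes are averaged on the linear scale per condition (mean
    +/- SEM over the flat replicate list).  When
    ``reference_condition`` is given, each other condition is compared
    to it with a two-sided t-test (Welch by default); otherwise each
    condition is tested against the no-enrichment value ``null_fc``
    with a one-sample t-test.  Requires at least two replicates per
    condition.
    """
    variant = TTestVariant(variant)
    groups = {
        cond: sub["fc"].to_numpy(dtype=float)
        for cond, sub in results.groupby("condition")
    }
    for cond, fcs in groups.items():
        if len(fcs) < 2:
            raise ValueError(f"condition {cond!r} has a single replicate")
    summary = pd.DataFrame(
        [
            dataclasses.asdict(
                EnrichmentSummary(
                    cond,
                    len(fcs),
                    float(np.mean(fcs)),
                    float(np.std(fcs, ddof=1) / math.sqrt(len(fcs))),
                )
            )
            for cond, fcs in groups.items()
        ]
    )
    rows = []
    if reference_condition is not None:
        ref = groups[reference_condition]
        for cond, fcs in groups.items():
            if cond == reference_condition:
                continue
            res = stats.ttest_ind(
                fcs, ref, equal_var=(variant is TTestVariant.POOLED)
            )
            rows.append(
                {"condition": cond, "versus": reference_condition,
                 "t": float(res.statistic), "p": float(res.pvalue)}
            )
    else:
        for cond, fcs in groups.items():
            res = stats.ttest_1samp(fcs, null_fc)
            rows.append(
                {"condition": cond, "versus": f"fc={null_fc:g}",
                 "t": float(res.statistic), "p": float(res.pvalue)}
            )
    return summary, pd.DataFrame(rows)
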