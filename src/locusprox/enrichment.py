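"""The enrichment-calling core: Z contrasts, multiple-testing
corrections, contaminant list and enriched-protein calls.

For each protein, the difference x of log2 condition means (test minus
reference) is standardized by the combined standard error,
Z = x / sqrt(sem_test^2 + sem_ref^2), and converted to a two-tailed
p-value from the standard normal.  Background ("contaminant") proteins
are those enriched in the no-labeling control versus all labeling
conditions at FC > threshold with Bonferroni-significant p; they are
removed before the on-target versus untargeted-labeling contrast, whose
hits are called at FC > threshold and Storey q below alpha.

The Storey correction estimates the null proportion pi0 from the flat
upper tail of the p-value histogram, pi0 = #(p > lambda) / (n (1 -
lambda)), and converts ranked p-values into q-values by the step-up
recursion q_i = min(pi0 n p_i / rank_i, q_{i+1}).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import RunConfig

logger = logging.getLogger(__name__)


def combine_sem(sem_a: float, sem_b: float) -> float:
    """Standard error of a difference: sqrt(sem_a^2 + sem_b^2)."""
    a = np.asarray(sem_a, dtype=float)
    b = np.asarray(sem_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("standard errors must be nonnegative")
    out = np.sqrt(a**2 + b**2)
    return float(out) if out.ndim == 0 else out


def z_contrast(test: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-protein Z contrast between two summarized conditions.

    ``test`` and ``reference`` are condition summaries indexed by
    protein with columns ``log2_y`` and ``sem_log2``.  Returns a frame
    with x (difference of log2 means), sigma_x, Z, two-tailed normal p,
    linear fold change FC = 2^x and an ``excluded`` flag.

    Proteins with an undefined SEM on either side (single contributing
    value) are excluded with NaN statistics.  A protein with sigma_x = 0
    and x != 0 has an infinite Z; it is flagged excluded and given p = 0
    with a logged warning rather than a silently fabricated finite
    value (x = 0 with sigma_x = 0 is the degenerate no-change case,
    Z = 0, p = 1).
    """
    proteins = test.index
    if not proteins.equals(reference.index):
        reference = reference.reindex(proteins)
    x = test["log2_y"].to_numpy(dtype=float) - reference["log2_y"].to_numpy(dtype=float)
    sigma = combine_sem(
        test["sem_log2"].to_numpy(dtype=float),
        reference["sem_log2"].to_numpy(dtype=float),
    )
    excluded = np.isnan(x) | np.isnan(sigma)

    z = np.full_like(x, np.nan)
    p = np.full_like(x, np.nan)
    ok = ~excluded & (sigma > 0)
    z[ok] = x[ok] / sigma[ok]
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))

    degenerate_zero = ~excluded & (sigma == 0) & (x == 0)
    z[degenerate_zero] = 0.0
    p[degenerate_zero] = 1.0

    infinite = ~excluded & (sigma == 0) & (x != 0)
    if infinite.any():
        logger.warning(
            "%d protein(s) with zero combined SEM and nonzero difference: "
            "infinite Z, p set to 0 and protein flagged excluded",
            int(infinite.sum()),
        )
        z[infinite] = np.sign(x[infinite]) * np.inf
        p[infinite] = 0.0
        excluded = excluded | infinite

    return pd.DataFrame(
        {
            "x": x,
            "sigma_x": sigma,
            "Z": z,
            "p": p,
            "FC": np.exp2(x),
            "excluded": excluded,
        },
        index=proteins,
    )


def replace_zero_p(pvalues: Sequence[float]) -> np.ndarray:
    """Replace exact-zero p-values with the smallest nonzero p.

    Used for reporting (a volcano plot cannot place -log10 of zero);
    inference uses the raw values.  Raises when every p is zero.
    """
    p = np.asarray(pvalues, dtype=float)
    zero = p == 0
    if not zero.any():
        return p.copy()
    nonzero = p[~np.isnan(p) & (p > 0)]
    if nonzero.size == 0:
        raise ValueError("all p-values are zero; nothing to substitute")
    out = p.copy()
    out[zero] = nonzero.min()
    return out


def bonferroni(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: p_adj = min(1, n p); flag at raw p < alpha/n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    adjusted = np.minimum(1.0, n * p)
    flags = p < alpha / n
    return adjusted, flags


def estimate_pi0(pvalues: Sequence[float], lambda_: float = 0.4) -> float:
    """Estimate the null proportion from the upper p-value tail.

    pi0 = #(p > lambda) / (n (1 - lambda)), clamped into (1/n, 1]; a
    clamp is logged.  Uniform null p-values put ~(1 - lambda) n values
    above lambda, so the estimate is ~1 under the complete null and
    shrinks as true signals pile mass near zero.
    """
    if not 0 < lambda_ < 1:
        raise ValueError("lambda must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        raise ValueError("empty p-value list")
    raw = (p > lambda_).sum() / (n * (1.0 - lambda_))
    eps = 1.0 / n
    pi0 = min(1.0, max(eps, raw))
    if pi0 != raw:
        logger.info("pi0 estimate %.4f clamped to %.4f", raw, pi0)
    return float(pi0)


def storey_qvalues(pvalues: Sequence[float], pi0: float) -> np.ndarray:
    """Storey q-values by the rank/step-up recursion.

    With p-values sorted ascending, raw_i = pi0 n p_i / rank_i and
    q_i = min(raw_i, q_{i+1}) from the largest rank downward, capped at
    1.  Tied p-values share the larger rank before the cumulative-min
    pass (which leaves them with equal q).  Returned in input order.
    """
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # maximal rank within each tie group
    ranks = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)
    raw = pi0 * n * sorted_p / ranks
    q_sorted = np.minimum.accumulate(np.minimum(raw, 1.0)[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclasses.dataclass
class ContaminantCall:
    """Outcome of the background-contrast filter."""

    contrast: pd.DataFrame  # per-protein x/sigma/Z/p/FC/p_bonf/contaminant
    contaminants: set


def call_contaminants(summaries: pd.DataFrame, config: RunConfig) -> ContaminantCall:
    """Flag streptavidin / endogenous-biotin background proteins.

    Contrast: NoG- (no-labeling control) versus the pooled labeling
    conditions (all gRNAs plus NoG+).  Proteins enriched in NoG- at
    FC > fc_threshold with Bonferroni-adjusted p < alpha are called
    contaminants and removed from the downstream enrichment universe.
    Strict family-wise control keeps false positives (real signals
    wrongly discarded) rare.
    """
    test = summaries.xs("NoGminus", level="condition")
    reference = summaries.xs("labeling", level="condition")
    contrast = z_contrast(test, reference)
    testable = contrast["p"].notna()
    p = contrast.loc[testable, "p"].to_numpy()
    adjusted, _ = bonferroni(p, config.alpha)
    contrast["p_bonf"] = np.nan
    contrast.loc[testable, "p_bonf"] = adjusted
    contrast["contaminant"] = (
        (contrast["FC"] > config.fc_threshold) & (contrast["p_bonf"] < config.alpha)
    ).fillna(False)
    contaminants = set(contrast.index[contrast["contaminant"]])
    logger.info("contaminant filter flagged %d protein(s)", len(contaminants))
    return ContaminantCall(contrast=contrast, contaminants=contaminants)


def call_enriched(
    summaries: pd.DataFrame,
    contaminants: Iterable[str],
    config: RunConfig,
) -> pd.DataFrame:
    """Call promoter-enriched proteins (pooled on-target vs NoG+).

    Contaminants are removed first, so Storey's n is the size of the
    post-filter universe.  A protein is enriched when FC >
    fc_threshold and q < alpha; ``fc_only`` marks the FC criterion
    alone (hits ignoring significance).  Depleted proteins are reported
    with their statistics but never flagged enriched.  Zero p-values
    are kept for inference; the reporting column ``p_volcano``
    substitutes the smallest nonzero p so -log10 stays finite.
    """
    contaminants = set(contaminants)
    test = summaries.xs("on_target", level="condition")
    reference = summaries.xs("NoGplus", level="condition")
    keep = [prot for prot in test.index if prot not in contaminants]
    contrast = z_contrast(test.loc[keep], reference.loc[keep])

    testable = contrast["p"].notna()
    p = contrast.loc[testable, "p"].to_numpy()
    contrast["p_bonf"] = np.nan
    contrast.loc[testable, "p_bonf"], _ = bonferroni(p, config.alpha)
    pi0 = estimate_pi0(p, config.lambda_pi0)
    contrast["q"] = np.nan
    contrast.loc[testable, "q"] = storey_qvalues(p, pi0)
    contrast.attrs["pi0"] = pi0

    contrast["fc_only"] = (contrast["FC"] > config.fc_threshold).fillna(False)
    contrast["enriched"] = (
        contrast["fc_only"] & (contrast["q"] < config.alpha)
    ).fillna(False)
    with np.errstate(invalid="ignore"):
        nonmissing = contrast["p"].dropna()
        contrast["p_volcano"] = contrast["p"]
        if (nonmissing == 0).any() and (nonmissing > 0).any():
            contrast.loc[testable, "p_volcano"] = replace_zero_p(p)
    logger.info(
        "enrichment call: %d q<%.3g, %d enriched (FC>%.3g & q), %d FC-only",
        int((contrast["q"] < config.alpha).sum()),
        config.alpha,
        int(contrast["enriched"].sum()),
        config.fc_threshold,
        int(contrast["fc_only"].sum()),
    )
    return contrast
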