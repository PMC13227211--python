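"""Binary TF x locus binding matrices and their concordance with MS
detection and gene expression.

A binding matrix records, for every TF assayed by ChIP-Seq, whether a
reproducible peak was called at each genomic locus (1) or not (0).
Cochran's Q asks whether the proportion of binders differs across the
matched loci; McNemar's test follows up pairwise on the discordant
cells.  The detection-side analyses ask whether MS detection of a TF is
independent of its binding status (Fisher's exact test on the 2x2
overlap) and how detection relates to expression (stratified t-tests on
log2(TPM+1) values).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import TTestVariant

logger = logging.getLogger(__name__)

#: Accepted cell vocabulary for binary binding calls.
_BINARY_VOCAB = {
    "0": 0, "1": 1,
    "no": 0, "yes": 1,
    "n": 0, "y": 1,
}

#: MS detection states for a TF.
DETECTION_STATES = ("quantified", "detected_not_quantified", "undetected")


def normalize_binary_cell(cell) -> int:
    """Map a Yes/No/Y/N/0/1 cell onto {0, 1}."""
    key = str(cell).strip().lower()
    if key not in _BINARY_VOCAB:
        raise ValueError(f"cell value {cell!r} outside accepted vocabulary "
                         "{0, 1, Yes, No, Y, N}")
    return _BINARY_VOCAB[key]


@dataclasses.dataclass
class BindingMatrix:
    """TF (rows) x locus (columns) binary occupancy."""

    cells: pd.DataFrame  # int {0,1}, index = TFs, columns = loci

    def __post_init__(self) -> None:
        arr = self.cells.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("binding matrix cells must be 0/1")
        self.cells = self.cells.astype(int)

    @classmethod
    def from_raw(cls, raw: pd.DataFrame) -> "BindingMatrix":
        """Canonicalize a mixed-vocabulary (Yes/No/0/1) table."""
        return cls(raw.map(normalize_binary_cell))

    @classmethod
    def from_peak_counts(cls, counts: pd.DataFrame, min_peaks: int = 1) -> "BindingMatrix":
        """Threshold an integer peak-count table into a binary view.

        ``min_peaks=1`` is the standard binary call; ``min_peaks=4``
        derives the "more than three peaks" view used for gene-body
        columns.
        """
        return cls((counts >= min_peaks).astype(int))

    @property
    def tfs(self) -> pd.Index:
        return self.cells.index

    @property
    def loci(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def k(self) -> int:
        return self.cells.shape[1]

    @property
    def column_totals(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def row_totals(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.cells.to_numpy().sum())

    def drop_loci(self, loci: Iterable[str]) -> "BindingMatrix":
        return BindingMatrix(self.cells.drop(columns=list(loci)))

    def drop_all_zero_loci(self) -> "BindingMatrix":
        keep = self.column_totals > 0
        dropped = [c for c, k in keep.items() if not k]
        if dropped:
            logger.info("dropping all-zero locus column(s): %s", dropped)
        return BindingMatrix(self.cells.loc[:, keep])


def locus_proportions(matrix: BindingMatrix) -> pd.DataFrame:
    """Per-locus binder count and percentage of assayed TFs."""
    n = len(matrix.tfs)
    if n == 0:
        raise ValueError("binding matrix has no TF rows")
    counts = matrix.column_totals
    return pd.DataFrame(
        {"count": counts, "percentage": (100.0 * counts / n).round(1)}
    )


def cochran_q(matrix: BindingMatrix) -> tuple[float, int, float]:
    """Cochran's Q for equality of binding proportions across loci.

    Q = k(k-1) * sum_j (G_j - N/k)^2 / sum_i x_i (k - x_i), with loci in
    columns (totals G_j), TFs in rows (totals x_i), N the grand total of
    1-cells.  Referred to chi-square with k-1 degrees of freedom.
    Fully concordant rows (all-0 or all-1) contribute nothing to the
    denominator; a matrix with no discordant row has no within-row
    variation and is reported as Q = 0, p = 1.
    """
    k = matrix.k
    if k < 2:
        raise ValueError("Cochran's Q needs at least two loci")
    G = matrix.column_totals.to_numpy(dtype=float)
    x = matrix.row_totals.to_numpy(dtype=float)
    N = G.sum()
    denom = float((x * (k - x)).sum())
    df = k - 1
    if denom == 0.0:
        return 0.0, df, 1.0
    q = k * (k - 1) * float(((G - N / k) ** 2).sum()) / denom
    return q, df, float(stats.chi2.sf(q, df))


@dataclasses.dataclass
class McNemarResult:
    locus_a: str
    locus_b: str
    b: int  # rows bound at locus_a only
    c: int  # rows bound at locus_b only
    statistic: float
    p: float
    p_bonf: float


def mcnemar_pairwise(matrix: BindingMatrix) -> list[McNemarResult]:
    """Uncorrected McNemar tests on all locus pairs, Bonferroni adjusted.

    For each pair, b and c count the discordant rows; the statistic is
    (b-c)^2/(b+c), chi-square with 1 df.  No discordance (b+c=0) gives
    statistic 0 and p = 1 by convention.  The Bonferroni family is the
    set of pairs among the loci present in the matrix.
    """
    if matrix.k < 2:
        raise ValueError("pairwise McNemar needs at least two loci")
    pairs = list(itertools.combinations(matrix.loci, 2))
    n_pairs = len(pairs)
    results = []
    for la, lb in pairs:
        a_col = matrix.cells[la].to_numpy()
        b_col = matrix.cells[lb].to_numpy()
        b = int(((a_col == 1) & (b_col == 0)).sum())
        c = int(((a_col == 0) & (b_col == 1)).sum())
        if b + c == 0:
            stat, p = 0.0, 1.0
        else:
            stat = (b - c) ** 2 / (b + c)
            p = float(stats.chi2.sf(stat, 1))
        results.append(
            McNemarResult(la, lb, b, c, float(stat), p, min(1.0, p * n_pairs))
        )
    return results


def mcnemar_table(matrix: BindingMatrix) -> pd.DataFrame:
    """Pairwise McNemar results as a tidy frame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in mcnemar_pairwise(matrix)])


def detection_binding_tables(
    matrix: BindingMatrix,
    detection: pd.DataFrame,
    locus: str,
    detected_definition: str = "quantified_or_detected",
) -> tuple["ContingencyTable2x2", float, float]:
    """Binding x MS-detection 2x2 at one locus, with expected overlap.

    ``detection`` must carry a ``status`` column over the matrix's TFs.
    ``detected_definition`` chooses the detection boundary:
    ``quantified_or_detected`` counts quantified plus
    detected-not-quantified TFs as detected (default); ``quantified``
    counts only quantified ones.  Returns the table, the
    margin-product expected overlap (row total x column total / grand
    total), and the two-sided Fisher exact p.
    """
    from .classes import ContingencyTable2x2  # local import avoids cycle

    det = detection.set_index("tf") if "tf" in detection.columns else detection
    status = det["status"].reindex(matrix.tfs)
    if status.isna().any():
        missing = list(status.index[status.isna()])[:5]
        raise ValueError(f"detection table missing TF(s): {missing}")
    if detected_definition == "quantified_or_detected":
        detected = status.isin(["quantified", "detected_not_quantified"])
    elif detected_definition == "quantified":
        detected = status == "quantified"
    else:
        raise ValueError(f"unknown detected_definition {detected_definition!r}")
    bound = matrix.cells[locus] == 1

    a = int((bound & detected).sum())
    b = int((~bound & detected).sum())
    c = int((bound & ~detected).sum())
    d = int((~bound & ~detected).sum())
    table = ContingencyTable2x2(a, b, c, d)
    grand = a + b + c + d
    expected_overlap = (a + b) * (a + c) / grand if grand else float("nan")
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return table, float(expected_overlap), float(fisher_p)


def _ttest(x: np.ndarray, y: np.ndarray, variant: TTestVariant) -> tuple[float, float]:
    res = stats.ttest_ind(x, y, equal_var=(variant is TTestVariant.POOLED))
    return float(res.statistic), float(res.pvalue)


def expression_stratified_tests(
    detection: pd.DataFrame,
    matrix: BindingMatrix,
    variant: TTestVariant = TTestVariant.WELCH,
    detected_definition: str = "quantified_or_detected",
    loci: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression by MS-detection and binding status, with t-tests.

    For each locus (and pooled across loci, where every TF-locus pair
    is an observation) the log2(TPM+1) expression is summarized per
    stratum of detection (detected / undetected) x binding (bound /
    unbound), and all pairwise strata are compared with a two-sided
    t-test (Welch by default).  P-values are Bonferroni adjusted over
    the full family of comparisons performed in the call.  Strata with
    fewer than two observations are skipped with a warning.

    Returns ``(strata, tests)`` frames.
    """
    variant = TTestVariant(variant)
    det = detection.copy()
    if "tf" in det.columns:
        det = det.set_index("tf")
    det = det.reindex(matrix.tfs)
    if det["expression"].isna().any():
        raise ValueError("detection table lacks expression for some TFs")
    if detected_definition == "quantified_or_detected":
        det["detected"] = det["status"].isin(
            ["quantified", "detected_not_quantified"]
        )
    else:
        det["detected"] = det["status"] == "quantified"

    use_loci = list(loci) if loci is not None else matrix.loci
    long = []
    for locus in use_loci:
        frame = pd.DataFrame(
            {
                "locus": locus,
                "detected": det["detected"].to_numpy(),
                "bound": matrix.cells[locus].to_numpy().astype(bool),
                "expression": det["expression"].to_numpy(),
            }
        )
        long.append(frame)
    pooled = pd.concat(long, ignore_index=True)
    scopes = {"pooled": pooled}
    scopes.update({locus: frame for locus, frame in zip(use_loci, long)})

    strata_rows, test_rows = [], []
    for scope, frame in scopes.items():
        groups = {}
        for (is_det, is_bound), sub in frame.groupby(["detected", "bound"]):
            name = ("detected" if is_det else "undetected") + "/" + (
                "bound" if is_bound else "unbound"
            )
            vals = sub["expression"].to_numpy(dtype=float)
            groups[name] = vals
            strata_rows.append(
                {
                    "scope": scope,
                    "stratum": name,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                }
            )
        for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
            if len(va) < 2 or len(vb) < 2:
                logger.warning(
                    "skipping %s vs %s in %s: stratum smaller than 2", na, nb, scope
                )
                continue
            t, p = _ttest(va, vb, variant)
            test_rows.append(
                {"scope": scope, "group_a": na, "group_b": nb,
                 "t": t, "p": p}
            )
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["p_bonf"] = (tests["p"] * len(tests)).clip(upper=1.0)
    return pd.DataFrame(strata_rows), tests


def detection_expression_tests(
    detection: pd.DataFrame,
    variant: TTestVariant = TTestVariant.WELCH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression by three-way MS detection status, pairwise t-tests.

    Compares log2(TPM+1) between quantified, detected-not-quantified and
    undetected TFs (two-sided, Bonferroni over the three comparisons).
    """
    variant = TTestVariant(variant)
    det = detection.copy()
    if "tf" in det.columns:
        det = det.set_index("tf")
    groups = {
        s: det.loc[det["status"] == s, "expression"].to_numpy(dtype=float)
        for s in DETECTION_STATES
    }
    summary = pd.DataFrame(
        [
            {
                "status": s,
                "n": len(v),
                "mean": float(np.mean(v)) if len(v) else float("nan"),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            }
            for s, v in groups.items()
        ]
    )
    rows = []
    for (sa, va), (sb, vb) in itertools.combinations(groups.items(), 2):
        if len(va) < 2 or len(vb) < 2:
            logger.warning("skipping %s vs %s: stratum smaller than 2", sa, sb)
            continue
        t, p = _ttest(va, vb, variant)
        rows.append({"group_a": sa, "group_b": sb, "t": t, "p": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_bonf"] = (tests["p"] * len(tests)).clip(upper=1.0)
    return summary, tests
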