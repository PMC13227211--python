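"""Stage orchestration: from raw tables to per-stage TSV outputs.

The quantification path follows the analysis funnel: exclude proteins
never quantified, exclude proteins undetected in any of the four
reference condition groups, median normalize, summarize per condition,
build the contaminant list from the no-labeling contrast, and call
enrichment on the post-contaminant universe.  Downstream stages
(protein-class enrichment, binding-matrix concordance, qPCR) run when
their inputs are supplied.  Outputs are a pure function of (inputs,
config, seed): no timestamps or machine state leak into the files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classes as classes_mod
from . import concordance as conc
from . import io as lio
from . import qpcr as qpcr_mod
from . import quant
from . import synthetic
from .design import DesignMap, RunConfig, default_design
from .enrichment import call_contaminants, call_enriched

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FunnelCounts:
    """Protein counts surviving each analysis filter, in filter order."""

    total: int
    quantified: int
    detected_four_conditions: int
    post_contaminant: int
    q_significant: int
    enriched: int
    fc_only: int  # FC criterion ignoring significance; not a funnel step

    def ordered(self) -> list[tuple[str, int]]:
        return [
            ("total", self.total),
            ("quantified", self.quantified),
            ("detected_four_conditions", self.detected_four_conditions),
            ("post_contaminant", self.post_contaminant),
            ("q_significant", self.q_significant),
            ("enriched", self.enriched),
        ]


@dataclasses.dataclass
class QuantifyResult:
    normalized: quant.AbundanceMatrix
    summary: pd.DataFrame
    n_total: int
    n_unquantified: int
    n_undetected_conditions: int


def quantify_stage(
    matrix: quant.AbundanceMatrix, design: DesignMap, config: RunConfig
) -> QuantifyResult:
    n_total = len(matrix.proteins)
    filtered, n_unq = quant.filter_unquantified(matrix)
    filtered, n_und = quant.filter_undetected_conditions(filtered, design)
    normalized = quant.median_normalize(filtered)
    summary = quant.summarize_conditions(
        normalized, design, rule=config.sem_pooling_rule
    )
    return QuantifyResult(normalized, summary, n_total, n_unq, n_und)


@dataclasses.dataclass
class EnrichResult:
    contaminant_contrast: pd.DataFrame
    contaminants: set
    contrast: pd.DataFrame
    funnel: FunnelCounts


def enrich_stage(
    quantified: QuantifyResult, config: RunConfig
) -> EnrichResult:
    cont = call_contaminants(quantified.summary, config)
    contrast = call_enriched(quantified.summary, cont.contaminants, config)
    n_post_quant = quantified.n_total - quantified.n_unquantified
    n_post_det = n_post_quant - quantified.n_undetected_conditions
    funnel = FunnelCounts(
        total=quantified.n_total,
        quantified=n_post_quant,
        detected_four_conditions=n_post_det,
        post_contaminant=len(contrast),
        q_significant=int((contrast["q"] < config.alpha).sum()),
        enriched=int(contrast["enriched"].sum()),
        fc_only=int(contrast["fc_only"].sum()),
    )
    return EnrichResult(cont.contrast, cont.contaminants, contrast, funnel)


def classes_stage(
    universe: set,
    hit_sets: dict[str, set],
    class_lists: dict[str, set],
) -> pd.DataFrame:
    """Class-enrichment table over every (class list, hit set) pair.

    The comparison universe is the full inferred-protein list, not the
    post-filter universe, so the class fraction among hits is judged
    against the whole experiment.
    """
    rows = []
    for class_name, class_list in class_lists.items():
        for set_name, hits in hit_sets.items():
            table = classes_mod.build_contingency(universe, class_list, hits)
            count, pct = classes_mod.class_fraction(hits, class_list)
            stat, df, p = classes_mod.chi2_test(table)
            rows.append(
                {
                    "class": class_name,
                    "set": set_name,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "count_in_class": count,
                    "fraction_pct": pct,
                    "chi2": stat,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ConcordanceResult:
    proportions: pd.DataFrame
    cochran: pd.DataFrame
    mcnemar: pd.DataFrame
    fisher: Optional[pd.DataFrame]
    strata: Optional[pd.DataFrame]
    strata_tests: Optional[pd.DataFrame]


def concordance_stage(
    matrix: conc.BindingMatrix,
    detection: Optional[pd.DataFrame] = None,
    config: Optional[RunConfig] = None,
    drop_all_zero_loci_for_tests: bool = True,
) -> ConcordanceResult:
    """Binding-matrix concordance with optional detection coupling.

    Cochran's Q and McNemar run on the full locus panel and — when an
    all-zero locus (a no-binder control) is present and dropping is
    requested — also on the reduced panel; both rows are reported.
    """
    config = config or RunConfig()
    proportions = conc.locus_proportions(matrix).reset_index(names="locus")

    cochran_rows = []
    q, df, p = conc.cochran_q(matrix)
    cochran_rows.append({"panel": "all_loci", "k": matrix.k, "Q": q, "df": df, "p": p})
    mcnemar = conc.mcnemar_table(matrix)
    mcnemar.insert(0, "panel", "all_loci")
    if drop_all_zero_loci_for_tests and (matrix.column_totals == 0).any():
        reduced = matrix.drop_all_zero_loci()
        q2, df2, p2 = conc.cochran_q(reduced)
        cochran_rows.append(
            {"panel": "no_zero_loci", "k": reduced.k, "Q": q2, "df": df2, "p": p2}
        )
        mc2 = conc.mcnemar_table(reduced)
        mc2.insert(0, "panel", "no_zero_loci")
        mcnemar = pd.concat([mcnemar, mc2], ignore_index=True)
    cochran = pd.DataFrame(cochran_rows)

    fisher = strata = strata_tests = None
    if detection is not None:
        fisher_rows = []
        for locus in matrix.loci:
            table, expected, p_f = conc.detection_binding_tables(
                matrix, detection, locus
            )
            fisher_rows.append(
                {
                    "locus": locus,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "observed_overlap": table.a,
                    "expected_overlap": expected,
                    "fisher_p": p_f,
                }
            )
        fisher = pd.DataFrame(fisher_rows)
        nonzero = [l for l in matrix.loci if matrix.column_totals[l] > 0]
        strata, strata_tests = conc.expression_stratified_tests(
            detection, matrix, variant=config.ttest_variant, loci=nonzero
        )
    return ConcordanceResult(proportions, cochran, mcnemar, fisher, strata, strata_tests)


def qpcr_stage(
    ct_table: pd.DataFrame, config: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicate-level ddCt plus per-condition summary and t-tests."""
    config = config or RunConfig()
    replicates = qpcr_mod.ddct(ct_table)
    conditions = replicates["condition"].unique()
    reference = "NoG" if "NoG" in conditions and len(conditions) > 1 else None
    summary, tests = qpcr_mod.summarize_enrichment(
        replicates, reference_condition=reference, variant=config.ttest_variant
    )
    return replicates, summary, tests


def simulate_inputs(
    config: RunConfig,
    outdir: Path,
    scenario: Optional[synthetic.SimScenario] = None,
    design: Optional[DesignMap] = None,
) -> dict[str, Path]:
    """Generate a full synthetic input bundle under ``outdir``.

    Writes the abundance/design/truth tables, TF and spliceosome class
    lists derived from the truth flags, a binding matrix over the
    default locus panel, a detection table for its TFs, and Ct tables
    for an enriched (true fold change 2) and a null condition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design or default_design()
    scenario = scenario or synthetic.SimScenario(seed=config.seed)

    matrix, truth = synthetic.simulate_abundance(scenario, design)
    binding, _ = synthetic.simulate_binding_matrix(
        n_tfs=218,
        locus_probs=list(synthetic.DEFAULT_LOCUS_PROBS.values()),
        tf_concordance=0.5,
        seed=config.seed,
        locus_names=list(synthetic.DEFAULT_LOCUS_PROBS),
    )
    detection = synthetic.simulate_expression_detection(
        binding.tfs.size, seed=config.seed
    )
    detection.index = binding.tfs
    ct = pd.concat(
        [
            synthetic.simulate_ct_table(
                2.0, 0.6, 6, seed=config.seed, condition="pooled_gRNAs"
            ),
            synthetic.simulate_ct_table(
                1.0, 0.6, 6, seed=config.seed + 1, condition="NoG"
            ),
        ],
        ignore_index=True,
    )

    paths = {
        "abundance": outdir / "abundance.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "tf_list": outdir / "tf_list.tsv",
        "spliceosome_list": outdir / "spliceosome_list.tsv",
        "binding": outdir / "binding_matrix.tsv",
        "detection": outdir / "detection.tsv",
        "ct": outdir / "ct_table.tsv",
    }
    lio.write_abundance_table(matrix, paths["abundance"])
    lio.write_design(design, paths["design"])
    lio.write_truth_table(truth, paths["truth"])
    prot = truth.proteins
    lio.write_gene_list(set(prot.index[prot["is_tf"]]), paths["tf_list"])
    lio.write_gene_list(set(prot.index[prot["is_spliceosome"]]), paths["spliceosome_list"])
    lio.write_binding_matrix(binding, paths["binding"])
    lio.write_detection_table(detection, paths["detection"])
    lio.write_ct_table(ct, paths["ct"])
    return paths


def run_pipeline(
    config: RunConfig,
    inputs: dict[str, Path],
    outdir: Path,
) -> dict:
    """Run every stage whose inputs are present; write per-stage TSVs.

    Requires ``abundance`` and ``design`` in ``inputs``; the keys
    ``tf_list``/``spliceosome_list`` (class stage), ``binding`` and
    ``detection`` (concordance stage) and ``ct`` (qPCR stage) gate the
    downstream analyses.  Writes a run log with the configuration and
    the filter-funnel counts.  Returns the in-memory result bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    design = lio.read_design(inputs["design"])
    stage = "quantify"
    try:
        matrix = lio.read_abundance_table(inputs["abundance"], design)
        quantified = quantify_stage(matrix, design, config)
        lio.write_abundance_table(
            quantified.normalized, outdir / "normalized_abundance.tsv"
        )
        quantified.summary.to_csv(outdir / "condition_summary.tsv", sep="\t")

        stage = "enrich"
        enriched = enrich_stage(quantified, config)
        enriched.contaminant_contrast.to_csv(outdir / "contaminants.tsv", sep="\t")
        enriched.contrast.to_csv(outdir / "contrast_on_target.tsv", sep="\t")
        lio.write_gene_list(
            set(enriched.contrast.index[enriched.contrast["enriched"]]),
            outdir / "enriched_proteins.tsv",
        )
        bundle["quantified"] = quantified
        bundle["enriched"] = enriched

        if inputs.get("tf_list") or inputs.get("spliceosome_list"):
            stage = "classes"
            class_lists = {}
            if inputs.get("tf_list"):
                class_lists["TF"] = lio.read_gene_list(inputs["tf_list"])
            if inputs.get("spliceosome_list"):
                class_lists["spliceosome"] = lio.read_gene_list(
                    inputs["spliceosome_list"]
                )
            universe = set(matrix.proteins)
            contrast = enriched.contrast
            hit_sets = {
                "enriched": set(contrast.index[contrast["enriched"]]),
                "fc_only": set(contrast.index[contrast["fc_only"]]),
            }
            class_table = classes_stage(universe, hit_sets, class_lists)
            class_table.to_csv(outdir / "class_enrichment.tsv", sep="\t", index=False)
            bundle["classes"] = class_table

        if inputs.get("binding"):
            stage = "concordance"
            binding = lio.read_binding_matrix(inputs["binding"])
            detection = (
                lio.read_detection_table(inputs["detection"])
                if inputs.get("detection")
                else None
            )
            result = concordance_stage(binding, detection, config)
            result.proportions.to_csv(
                outdir / "concordance_proportions.tsv", sep="\t", index=False
            )
            result.cochran.to_csv(outdir / "concordance_cochran.tsv", sep="\t", index=False)
            result.mcnemar.to_csv(outdir / "concordance_mcnemar.tsv", sep="\t", index=False)
            if result.fisher is not None:
                result.fisher.to_csv(
                    outdir / "concordance_fisher.tsv", sep="\t", index=False
                )
                result.strata.to_csv(
                    outdir / "concordance_strata.tsv", sep="\t", index=False
                )
                result.strata_tests.to_csv(
                    outdir / "concordance_tests.tsv", sep="\t", index=False
                )
            bundle["concordance"] = result

        if inputs.get("ct"):
            stage = "qpcr"
            ct = lio.read_ct_table(inputs["ct"])
            replicates, summary, tests = qpcr_stage(ct, config)
            replicates.to_csv(outdir / "qpcr_replicates.tsv", sep="\t", index=False)
            summary.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False)
            tests.to_csv(outdir / "qpcr_tests.tsv", sep="\t", index=False)
            bundle["qpcr"] = (replicates, summary, tests)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_run_log(outdir / "run_log.txt", config, bundle)
    return bundle


def _write_run_log(path: Path, config: RunConfig, bundle: dict) -> None:
    lines = ["# run configuration"]
    lines.append(f"fc_threshold\t{config.fc_threshold}")
    lines.append(f"alpha\t{config.alpha}")
    lines.append(f"lambda_pi0\t{config.lambda_pi0}")
    lines.append(f"sem_pooling_rule\t{config.sem_pooling_rule.value}")
    lines.append(f"ttest_variant\t{config.ttest_variant.value}")
    lines.append(f"seed\t{config.seed}")
    if "enriched" in bundle:
        funnel = bundle["enriched"].funnel
        lines.append("# filter funnel")
        for name, count in funnel.ordered():
            lines.append(f"{name}\t{count}")
        lines.append(f"fc_only\t{funnel.fc_only}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
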