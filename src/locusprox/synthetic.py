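"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a multiplexed
proximity-labeling experiment: negative-binomial protein abundances
(overdispersed counts, variance mu + mu^2/k), multiplicative
per-channel biases and per-cell replicate noise (lognormal),
condition-specific effect classes (on-target signal in the gRNA
channels, labeling background in all labeling channels, bead/biotin
contaminants in the no-labeling control), abundance-dependent
missingness (logistic, missing-not-at-random), correlated binary
binding columns (Gaussian copula), a logistic expression-to-detection
coupling, and Ct tables whose noise-free ddCt equals -log2 of a known
fold change.

Every operation draws from its own named substream of a single global
seed, so re-running any one stage with the same seed is reproducible
without replaying the others.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .concordance import BindingMatrix
from .design import Condition, DesignMap, ON_TARGET_CONDITIONS
from .quant import AbundanceMatrix

#: Named RNG substreams (second word of the seed sequence).
_STREAMS = {"abundance": 1, "binding": 2, "expression": 3, "ct": 4}

PROTEIN_CLASSES = ("on_target", "background", "contaminant", "null")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclasses.dataclass
class SimScenario:
    """Parameters of a simulated abundance experiment.

    Class fractions must sum to at most 1; the remainder is the null
    class (no condition effect).  Effects are multiplicative fold
    factors applied to the affected channels.  Noise SDs are on the
    natural-log scale.  ``missing_midpoint`` is the abundance at which
    a cell is missing with probability one half; a nonpositive value
    disables missingness entirely.
    """

    n_proteins: int = 5000
    frac_contaminant: float = 0.10
    frac_background: float = 0.10
    frac_on_target: float = 0.05
    effect_on_target: float = 2.0
    effect_background: float = 2.0
    effect_contaminant: float = 4.0
    nb_mean: float = 2.0e5
    nb_dispersion: float = 2.0
    channel_bias_sd: float = 0.2
    replicate_noise_sd: float = 0.25
    missing_midpoint: float = 5000.0
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.frac_contaminant + self.frac_background + self.frac_on_target
        if fr > 1 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        if min(self.frac_contaminant, self.frac_background, self.frac_on_target) < 0:
            raise ValueError("class fractions must be nonnegative")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("effect_on_target", "effect_background", "effect_contaminant",
                     "nb_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("channel_bias_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclasses.dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests.

    ``proteins`` carries one row per protein: class label, TF and
    spliceosome flags, expression (log2(TPM+1)) and detection status.
    ``binding`` (when produced by the binding simulator) is the true
    TF x locus occupancy.
    """

    proteins: Optional[pd.DataFrame] = None
    binding: Optional[pd.DataFrame] = None

    def class_members(self, label: str) -> set:
        if self.proteins is None:
            raise ValueError("no protein truth available")
        return set(self.proteins.index[self.proteins["class_label"] == label])


def missingness_probability(
    abundance: np.ndarray, midpoint: float, slope: float
) -> np.ndarray:
    """Missing-not-at-random probability, logistic in -log2(abundance).

    P(missing) = expit(slope * (log2(midpoint) - log2(abundance))); at
    the midpoint the probability is one half, and it falls toward zero
    for abundant proteins.  A nonpositive midpoint disables
    missingness.
    """
    a = np.asarray(abundance, dtype=float)
    if midpoint <= 0:
        return np.zeros_like(a)
    return expit(slope * (np.log2(midpoint) - np.log2(a)))


# class composition of TF / spliceosome annotation, loosely mirroring the
# observed fractions (promoter machinery concentrates TFs and splicing
# factors relative to the whole inferred proteome)
_TF_PROB = {"on_target": 0.60, "background": 0.14, "contaminant": 0.14, "null": 0.14}
_SPLICE_PROB = {"on_target": 0.15, "background": 0.025, "contaminant": 0.025, "null": 0.025}


def simulate_abundance(
    scenario: SimScenario, design: DesignMap
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Simulate a grouped-abundance matrix for a TMT design.

    Baselines are negative binomial with mean ``nb_mean`` and
    dispersion ``nb_dispersion`` (variance mu + mu^2/k).  On-target
    proteins are multiplied by ``effect_on_target`` in the gRNA
    channels, background proteins by ``effect_background`` in every
    labeling channel, and contaminants by ``effect_contaminant`` in
    the NoG- channels (for the contrast, extra abundance without
    labeling is equivalent to depletion under labeling).  The pool
    channel is the mean of all sample channels before missingness.
    """
    rng = _rng(scenario.seed, "abundance")
    n = scenario.n_proteins
    proteins = pd.Index([f"P{i:05d}" for i in range(1, n + 1)], name="protein")

    k = scenario.nb_dispersion
    p_nb = k / (k + scenario.nb_mean)
    baseline = rng.negative_binomial(k, p_nb, size=n).astype(float)
    baseline = np.maximum(baseline, 1.0)  # abundances are positive

    counts = {
        "contaminant": int(round(scenario.frac_contaminant * n)),
        "background": int(round(scenario.frac_background * n)),
        "on_target": int(round(scenario.frac_on_target * n)),
    }
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    start = 0
    for cls in ("contaminant", "background", "on_target"):
        labels[perm[start:start + counts[cls]]] = cls
        start += counts[cls]

    sample_channels = design.sample_channels
    pool_channels = design.channels_for(Condition.POOL)
    channels = design.channels
    bias = {
        ch: rng.lognormal(0.0, scenario.channel_bias_sd) for ch in channels
    }
    noise = rng.lognormal(
        0.0, scenario.replicate_noise_sd, size=(n, len(sample_channels))
    )

    on_target_channels = set(design.on_target_channels)
    labeling_channels = set(design.labeling_channels)
    nog_minus_channels = set(design.channels_for(Condition.NOG_MINUS))

    effect = np.ones((n, len(sample_channels)))
    for j, ch in enumerate(sample_channels):
        col = np.ones(n)
        if ch in on_target_channels:
            col[labels == "on_target"] *= scenario.effect_on_target
        if ch in labeling_channels:
            col[labels == "background"] *= scenario.effect_background
        if ch in nog_minus_channels:
            col[labels == "contaminant"] *= scenario.effect_contaminant
        effect[:, j] = col

    sample_values = baseline[:, None] * effect * noise
    sample_values *= np.array([bias[ch] for ch in sample_channels])[None, :]

    values = pd.DataFrame(sample_values, index=proteins, columns=sample_channels)
    for pool_ch in pool_channels:
        values[pool_ch] = sample_values.mean(axis=1)
    values = values[channels]

    miss_p = missingness_probability(
        values.to_numpy(), scenario.missing_midpoint, scenario.missing_slope
    )
    miss_draw = rng.uniform(size=values.shape) < miss_p
    observed = values.mask(miss_draw)

    quantified = observed.notna().any(axis=1).to_numpy()
    # detection limit sits below the quantification midpoint: proteins
    # with every cell missing may still be identified by a stray PSM
    det_p = 1.0 - missingness_probability(
        baseline, scenario.missing_midpoint / 4.0, scenario.missing_slope
    )
    detected = quantified | (rng.uniform(size=n) < det_p)

    tf_p = np.vectorize(_TF_PROB.get)(labels).astype(float)
    splice_p = np.vectorize(_SPLICE_PROB.get)(labels).astype(float)
    is_tf = rng.uniform(size=n) < tf_p
    is_splice = rng.uniform(size=n) < splice_p
    expression = np.log2(rng.lognormal(2.0, 1.5, size=n) + 1.0)

    status = np.where(
        quantified, "quantified",
        np.where(detected, "detected_not_quantified", "undetected"),
    )
    truth = GroundTruth(
        proteins=pd.DataFrame(
            {
                "class_label": labels,
                "is_tf": is_tf,
                "is_spliceosome": is_splice,
                "expression": expression,
                "baseline": baseline,
                "status": status,
            },
            index=proteins,
        )
    )
    matrix = AbundanceMatrix(observed, pd.Series(detected, index=proteins))
    return matrix, truth


def simulate_binding_matrix(
    n_tfs: int,
    locus_probs: Sequence[float],
    tf_concordance: float = 0.0,
    seed: int = 0,
    locus_names: Optional[Sequence[str]] = None,
) -> tuple[BindingMatrix, GroundTruth]:
    """Simulate correlated binary TF x locus binding calls.

    A per-TF latent propensity u_i shared across loci induces
    within-row association (Gaussian copula with latent correlation
    ``tf_concordance``): cell_ij = 1 iff
    sqrt(rho) u_i + sqrt(1-rho) e_ij < Phi^{-1}(p_j).  Column means
    converge to ``locus_probs`` for any rho.
    """
    if not 0 <= tf_concordance < 1:
        raise ValueError("tf_concordance must lie in [0, 1)")
    probs = np.asarray(locus_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("locus probabilities must lie in [0, 1]")
    rng = _rng(seed, "binding")
    k = probs.size
    names = (
        list(locus_names)
        if locus_names is not None
        else [f"locus{j + 1}" for j in range(k)]
    )
    tfs = pd.Index([f"TF{i:04d}" for i in range(1, n_tfs + 1)], name="tf")

    u = rng.normal(size=(n_tfs, 1))
    eps = rng.normal(size=(n_tfs, k))
    latent = np.sqrt(tf_concordance) * u + np.sqrt(1.0 - tf_concordance) * eps
    thresholds = norm.ppf(probs)
    cells = (latent < thresholds[None, :]).astype(int)

    frame = pd.DataFrame(cells, index=tfs, columns=names)
    truth = GroundTruth(binding=frame.copy())
    truth.binding.attrs["locus_probs"] = dict(zip(names, probs.tolist()))
    return BindingMatrix(frame), truth


#: Default locus panel mirroring a promoter, its distal regulatory
#: region, and off-target promoters spanning silent to housekeeping.
DEFAULT_LOCUS_PROBS = {
    "TSS1": 0.606,
    "e330": 0.445,
    "GAPDH": 0.541,
    "IRX6": 0.234,
    "MAGI1": 0.330,
    "NANOG": 0.0,
}


def simulate_expression_detection(
    truth: Union[GroundTruth, pd.DataFrame, int],
    det_intercept: float = -2.2,
    det_slope: float = 0.45,
    seed: int = 0,
    tpm_meanlog: float = 2.0,
    tpm_sdlog: float = 1.5,
    quantified_margin: float = 1.5,
) -> pd.DataFrame:
    """Simulate MS detection status coupled to gene expression.

    TPM values are lognormal; expression is stored as log2(TPM+1).  A
    TF is detected with probability expit(det_intercept +
    quantified_margin + det_slope * expression) and, when detected,
    quantified with the tighter probability expit(det_intercept +
    det_slope * expression); the band between the two thresholds is
    the detected-but-not-quantified state.  ``det_slope`` >= 0, so
    higher expression never lowers detectability.
    """
    if det_slope < 0:
        raise ValueError("det_slope must be nonnegative")
    if isinstance(truth, GroundTruth):
        if truth.binding is not None:
            ids = truth.binding.index
        elif truth.proteins is not None:
            ids = truth.proteins.index
        else:
            raise ValueError("GroundTruth carries no identifiers")
    elif isinstance(truth, pd.DataFrame):
        ids = truth.index
    else:
        ids = pd.Index([f"TF{i:04d}" for i in range(1, int(truth) + 1)], name="tf")

    rng = _rng(seed, "expression")
    n = len(ids)
    expression = np.log2(rng.lognormal(tpm_meanlog, tpm_sdlog, size=n) + 1.0)
    p_quant = expit(det_intercept + det_slope * expression)
    p_det = expit(det_intercept + quantified_margin + det_slope * expression)
    u = rng.uniform(size=n)
    status = np.where(
        u < p_quant, "quantified",
        np.where(u < p_det, "detected_not_quantified", "undetected"),
    )
    out = pd.DataFrame({"expression": expression, "status": status}, index=ids)
    out.index.name = ids.name or "tf"
    return out


def simulate_ct_table(
    true_fc: float,
    ct_noise_sd: float = 0.0,
    n_reps: int = 6,
    seed: int = 0,
    condition: str = "pooled_gRNAs",
    dilution: float = 10.0,
    input_fraction: float = 0.01,
) -> pd.DataFrame:
    """Simulate a long-format ChIP-qPCR Ct table for one condition.

    Constructed so that the noise-free ddCt equals -log2(true_fc):
    the chip-fraction target/reference Ct gap is smaller than the
    (dilution-adjusted) input gap by exactly log2(true_fc) cycles.
    Two target primer pairs with opposite fixed offsets and
    quadruplicate wells exercise the averaging steps; replicates are
    laid out as ceil(n_reps/2) biological x 2 technical.  Gaussian
    noise of SD ``ct_noise_sd`` is added per well.
    """
    if true_fc <= 0:
        raise ValueError("true_fc must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be nonnegative")
    rng = _rng(seed, "ct")
    from .qpcr import input_adjustment  # local import avoids cycle at import time

    offset = input_adjustment(dilution, input_fraction)
    delta_input = 1.0          # target minus reference gap in the input
    chip_ref, input_ref_adj = 25.0, 15.0
    primers = [
        ("g1g2", "target", +0.2),
        ("g3", "target", -0.2),
        ("GAPDH", "reference", 0.0),
    ]
    rows = []
    for rep in range(1, n_reps + 1):
        bio = (rep - 1) // 2 + 1
        tech = (rep - 1) % 2 + 1
        for fraction in ("chip", "input"):
            for primer, role, prim_off in primers:
                if fraction == "chip":
                    base = chip_ref if role == "reference" else (
                        chip_ref + delta_input - np.log2(true_fc) + prim_off
                    )
                    dil, frac_in = 1.0, 1.0
                else:
                    adj = input_ref_adj if role == "reference" else (
                        input_ref_adj + delta_input + prim_off
                    )
                    base = adj + offset
                    dil, frac_in = dilution, input_fraction
                for well in range(1, 5):
                    rows.append(
                        {
                            "condition": condition,
                            "fraction": fraction,
                            "primer": primer,
                            "primer_role": role,
                            "bio_replicate": bio,
                            "tech_replicate": tech,
                            "well": well,
                            "ct": base + rng.normal(0.0, ct_noise_sd),
                            "dilution": dil,
                            "input_fraction": frac_in,
                        }
                    )
    return pd.DataFrame(rows)
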