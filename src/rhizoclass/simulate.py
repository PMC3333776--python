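"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the four kinds of raw input the pipeline consumes:

* two-channel slide tables with planted differential expression, a smooth
  intensity-dependent dye-bias curve, lognormal replicate noise and additive
  spot background;
* the contrast design (indirect: each rhizosphere against a glucose-grown
  laboratory baseline; direct: rhizosphere against rhizosphere, with dye
  swaps);
* CFU plate-count sheets for competition assays with a planted colonization
  fitness;
* qPCR Ct tables with a planted expression ratio against a reference gene.

Every record is tied to a :class:`SyntheticTruth`, so tests can ask whether
the pipeline recovers exactly what was planted.

Planted-fold margins
--------------------
Specificity categories are turned into per-rhizosphere expression ratios with
deliberate margins around the classifier's thresholds (3-fold primary, 2-fold
secondary, 0.3 down): primary rhizospheres draw folds in [3.5, 30], secondary
members of multi-rhizosphere categories in [2.3, 2.9], excluded rhizospheres
in [0.9, 1.05], fully repressed genes in [0.1, 0.25], and null genes are
exactly 1.  The margins absorb the small residual shift that lowess
normalization introduces when ~10% of genes are differentially expressed, so
a noise-free cohort is classified with zero error; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import Contrast, SlideTable
from .competition import CompetitionAssay, PlantCount
from .errors import ConfigurationError, DesignError, ParameterError

RHIZOSPHERES = ("pea", "alfalfa", "sugarbeet")
BASELINE_CONDITION = "glucose"

CATEGORIES = (
    "ALL",
    "PEA_ONLY",
    "ALFALFA_ONLY",
    "SUGARBEET_ONLY",
    "LEGUME",
    "ALFALFA_SUGARBEET",
    "PEA_SUGARBEET",
    "DOWN_ALL",
    "NONE",
)

#: rhizospheres in which each category plants elevated expression
CATEGORY_MEMBERS: dict[str, tuple[str, ...]] = {
    "ALL": ("pea", "alfalfa", "sugarbeet"),
    "PEA_ONLY": ("pea",),
    "ALFALFA_ONLY": ("alfalfa",),
    "SUGARBEET_ONLY": ("sugarbeet",),
    "LEGUME": ("pea", "alfalfa"),
    "ALFALFA_SUGARBEET": ("alfalfa", "sugarbeet"),
    "PEA_SUGARBEET": ("pea", "sugarbeet"),
    "DOWN_ALL": (),
    "NONE": (),
}

# roughly 10% of genes differentially expressed, the scale the study reports
DEFAULT_PROPORTIONS: dict[str, float] = {
    "ALL": 0.02,
    "PEA_ONLY": 0.015,
    "ALFALFA_ONLY": 0.01,
    "SUGARBEET_ONLY": 0.01,
    "LEGUME": 0.01,
    "ALFALFA_SUGARBEET": 0.005,
    "PEA_SUGARBEET": 0.005,
    "DOWN_ALL": 0.025,
    "NONE": 0.90,
}

PRIMARY_FOLD_RANGE = (3.5, 30.0)
SECONDARY_FOLD_RANGE = (2.3, 2.9)
EXCLUDED_FOLD_RANGE = (0.9, 1.05)
DOWN_FOLD_RANGE = (0.1, 0.25)

REPLICONS = ("chromosome", "pRL7", "pRL8", "pRL9", "pRL10", "pRL11", "pRL12")
REPLICON_WEIGHTS = (0.62, 0.02, 0.02, 0.05, 0.10, 0.07, 0.12)
#: pea-specific genes land on plasmid pRL8 with this probability, mirroring
#: the disproportionate share of pea-rhizosphere-specific genes that plasmid
#: carries in R. leguminosarum bv. viciae 3841
PEA_ONLY_PRL8_PROBABILITY = 0.37

_STREAMS = {"truth": 0, "slides": 1, "competition": 2, "qpcr": 3}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one gene: category, planted ratios, replicon."""

    gene_id: str
    category: str
    planted_fold: dict[str, float]
    replicon: str


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    n_replicates_per_contrast: int = 4
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    noise_sd_log2: float = 0.25
    dye_bias_amplitude: float = 0.4
    baseline_intensity_range: tuple[float, float] = (6.0, 14.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates_per_contrast < 2:
            raise ConfigurationError(
                "n_replicates_per_contrast must be >= 2 for P-value computation"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if self.dye_bias_amplitude < 0:
            raise ConfigurationError("dye_bias_amplitude must be >= 0")
        lo, hi = self.baseline_intensity_range
        if not lo < hi:
            raise ConfigurationError("baseline_intensity_range must be increasing")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        fractions = list(self.category_proportions.values())
        if any(f < 0 for f in fractions):
            raise ConfigurationError("category proportions must be >= 0")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category proportions sum to {sum(fractions)!r}, expected 1"
            )


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` items to categories by the largest-remainder method.

    Deterministic: ties in fractional remainder are broken by category name
    order, so the same proportions always produce the same counts.
    """
    quotas = {c: n * p for c, p in proportions.items()}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(
        proportions, key=lambda c: (-(quotas[c] - counts[c]), c)
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def generate_truth(config: SimulationConfig) -> list[SyntheticTruth]:
    """Draw the planted ground truth: one record per gene.

    Category counts follow ``category_proportions`` exactly (largest-remainder
    rounding); planted folds are constructed from the category, with one
    randomly chosen "primary" rhizosphere per elevated category carrying a
    >= 3.5-fold ratio.  Null genes are planted at ratio 1 in every rhizosphere.
    """
    config.validate()
    rng = _rng(config.seed, "truth")
    counts = largest_remainder_counts(config.n_genes, config.category_proportions)
    labels = np.array(
        [c for c in CATEGORIES for _ in range(counts.get(c, 0))], dtype=object
    )
    labels = labels[rng.permutation(config.n_genes)]
    width = max(5, len(str(config.n_genes)))
    truths = []
    for i, category in enumerate(labels):
        gene_id = f"G{i + 1:0{width}d}"
        members = CATEGORY_MEMBERS[category]
        folds: dict[str, float] = {}
        if category == "DOWN_ALL":
            for r in RHIZOSPHERES:
                folds[r] = float(rng.uniform(*DOWN_FOLD_RANGE))
        elif category == "NONE":
            for r in RHIZOSPHERES:
                folds[r] = 1.0
        else:
            primary = members[rng.integers(len(members))]
            for r in RHIZOSPHERES:
                if r == primary:
                    folds[r] = float(rng.uniform(*PRIMARY_FOLD_RANGE))
                elif r in members:
                    folds[r] = float(rng.uniform(*SECONDARY_FOLD_RANGE))
                else:
                    folds[r] = float(rng.uniform(*EXCLUDED_FOLD_RANGE))
        if category == "PEA_ONLY" and rng.random() < PEA_ONLY_PRL8_PROBABILITY:
            replicon = "pRL8"
        else:
            replicon = str(rng.choice(REPLICONS, p=REPLICON_WEIGHTS))
        truths.append(
            SyntheticTruth(
                gene_id=gene_id,
                category=str(category),
                planted_fold=folds,
                replicon=replicon,
            )
        )
    return truths


def dye_bias_curve(
    a: np.ndarray, amplitude: float, intensity_range: tuple[float, float]
) -> np.ndarray:
    """The planted dye-bias function: a cubic in mean log2 intensity.

    Scaled so ``|bias| <= amplitude`` over ``intensity_range``, with value 0
    at the interval midpoint.  The same curve is applied to every slide of a
    batch, the artifact lowess normalization is designed to remove.
    """
    lo, hi = intensity_range
    x = (2.0 * np.asarray(a, float) - lo - hi) / (hi - lo)
    return amplitude * x**3


def _condition_fold(truth: SyntheticTruth, condition: str) -> float:
    if condition == BASELINE_CONDITION:
        return 1.0
    try:
        return truth.planted_fold[condition]
    except KeyError:
        raise DesignError(f"unknown condition {condition!r}") from None


def generate_slides(
    truths: list[SyntheticTruth],
    design: list[Contrast],
    config: SimulationConfig,
) -> list[SlideTable]:
    """Simulate one two-channel slide per replicate per contrast.

    Each spot's channels encode the planted fold ratio between the two
    hybridized conditions, the dye-bias curve at the spot's intensity, and
    (for ``noise_sd_log2 > 0``) lognormal replicate noise; an additive
    background is planted per channel so background subtraction recovers the
    signal exactly.  Even replicates are dye-swapped: channel 1 carries the
    denominator condition.
    """
    config.validate()
    valid = set(RHIZOSPHERES) | {BASELINE_CONDITION}
    for contrast in design:
        for cond in (contrast.numerator, contrast.denominator):
            if cond not in valid:
                raise DesignError(
                    f"contrast {contrast.name}: unknown condition {cond!r}"
                )
    rng = _rng(config.seed, "slides")
    n = len(truths)
    log_true = {}
    for contrast in design:
        num = np.array([_condition_fold(t, contrast.numerator) for t in truths])
        den = np.array([_condition_fold(t, contrast.denominator) for t in truths])
        log_true[contrast] = np.log2(num / den)
    gene_ids = np.array([t.gene_id for t in truths])
    lo, hi = config.baseline_intensity_range
    slides = []
    for contrast in design:
        n_rep = contrast.n_replicates or config.n_replicates_per_contrast
        for rep in range(1, n_rep + 1):
            swap = rep % 2 == 0
            a = rng.uniform(lo, hi, n)
            noise = (
                rng.normal(0.0, config.noise_sd_log2, n)
                if config.noise_sd_log2 > 0
                else np.zeros(n)
            )
            oriented = log_true[contrast] + noise
            # dye bias rides on the channels, so it keeps its sign under a swap
            channel_m = (-oriented if swap else oriented) + dye_bias_curve(
                a, config.dye_bias_amplitude, config.baseline_intensity_range
            )
            ch1_sig = np.exp2(a + channel_m / 2.0)
            ch2_sig = np.exp2(a - channel_m / 2.0)
            ch1_bg = rng.uniform(40.0, 120.0, n)
            ch2_bg = rng.uniform(40.0, 120.0, n)
            spots = pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "ch1_fg": ch1_sig + ch1_bg,
                    "ch1_bg": ch1_bg,
                    "ch2_fg": ch2_sig + ch2_bg,
                    "ch2_bg": ch2_bg,
                }
            )
            slides.append(
                SlideTable(
                    slide_id=f"{contrast.name}_r{rep}",
                    condition_ch1=contrast.denominator if swap else contrast.numerator,
                    condition_ch2=contrast.numerator if swap else contrast.denominator,
                    dye_swap=swap,
                    spots=spots,
                    replicate=rep,
                )
            )
    return slides


def generate_competition_counts(
    true_rci_target: float,
    baseline_pct: float = 9.7,
    n_plants: int = 8,
    cfu_scale: int = 10_000,
    seed: int = 0,
    mutant_id: str = "synthetic_mutant",
    rhizosphere: str = "pea",
) -> CompetitionAssay:
    """Simulate per-plant CFU counts with a planted colonization index.

    Inverts the RCI definition: the expected wild-type recovery percentage is
    ``baseline_pct / true_rci_target``.  Each plant contributes ``cfu_scale``
    total dilution-corrected CFU, with the wild-type count binomial at that
    recovery probability.
    """
    if true_rci_target <= 0:
        raise ParameterError("true_rci_target must be > 0")
    if not 0 < baseline_pct < 100:
        raise ParameterError("baseline_pct must be in (0, 100)")
    if n_plants < 1:
        raise ParameterError("n_plants must be >= 1")
    expected_recovery = baseline_pct / true_rci_target
    if not 0 < expected_recovery < 100:
        raise ParameterError(
            f"implied wild-type recovery {expected_recovery:.2f}% outside (0, 100); "
            "choose a larger true_rci_target or smaller baseline_pct"
        )
    rng = _rng(seed, "competition")
    wt = rng.binomial(cfu_scale, expected_recovery / 100.0, n_plants)
    plants = [
        PlantCount(wildtype_cfu=int(w), mutant_cfu=int(cfu_scale - w)) for w in wt
    ]
    return CompetitionAssay(
        mutant_id=mutant_id,
        rhizosphere=rhizosphere,
        plants=plants,
        baseline_pct=baseline_pct,
    )


def generate_ct_table(
    planted_ratio: float,
    ref_gene: str = "mdh",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    target_gene: str = "target",
    reference_base_ct: float = 18.0,
    target_base_ct: float = 24.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with a planted treatment/control ratio.

    The target gene's treatment Ct is offset from its control Ct by
    ``-log2(planted_ratio)`` (doubling per cycle), the reference gene is flat
    across conditions, and Gaussian cycle noise of SD ``ct_noise_sd`` is added
    to every well.  Columns: gene_id, condition, replicate, ct, is_reference.
    """
    if planted_ratio <= 0:
        raise ParameterError("planted_ratio must be > 0")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = _rng(seed, "qpcr")
    rows = []
    base = {
        (target_gene, "control"): target_base_ct,
        (target_gene, "treatment"): target_base_ct - math.log2(planted_ratio),
        (ref_gene, "control"): reference_base_ct,
        (ref_gene, "treatment"): reference_base_ct,
    }
    for gene in (target_gene, ref_gene):
        for condition in ("treatment", "control"):
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct": base[(gene, condition)] + noise,
                        "is_reference": int(gene == ref_gene),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-table IO


def write_truth_table(truths: list[SyntheticTruth], path: str) -> None:
    rows = [
        {
            "gene_id": t.gene_id,
            "category": t.category,
            "replicon": t.replicon,
            **{f"fold_{r}": t.planted_fold[r] for r in RHIZOSPHERES},
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> list[SyntheticTruth]:
    table = pd.read_csv(path, sep="\t")
    return [
        SyntheticTruth(
            gene_id=str(row.gene_id),
            category=str(row.category),
            planted_fold={r: float(getattr(row, f"fold_{r}")) for r in RHIZOSPHERES},
            replicon=str(row.replicon),
        )
        for row in table.itertuples(index=False)
    ]
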