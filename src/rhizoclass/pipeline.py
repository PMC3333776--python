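"""End-to-end orchestration: simulate -> process -> classify -> rci -> qpcr.

One :class:`RunConfig` (optionally loaded from YAML) drives every stage
through a single seed; :func:`run_all` writes all intermediate tables plus a
JSON summary and returns the summary dict.  Stage outputs are pure functions
of the inputs and the configuration, so a repeated run with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import arrays, competition, qpcr, simulate, specificity
from .arrays import Contrast
from .errors import ConfigurationError

log = logging.getLogger("rhizoclass")


@dataclass
class RunConfig:
    outdir: str = "rhizoclass_run"
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    # classifier thresholds (ratios; down-thresholds as ratios < 1)
    primary_fold: float = 3.0
    secondary_fold: float = 2.0
    alpha: float = 0.05
    down_threshold: float = 0.3
    down_all_threshold: float = 0.5
    slight_band: tuple[float, float] = (0.4, 0.8)
    require_secondary_p: bool = True
    # array processing
    span: float = arrays.DEFAULT_SPAN
    background_floor: float = arrays.DEFAULT_BACKGROUND_FLOOR
    # reconciliation
    reconcile_focal: str = "pea"
    # competition stage: planted colonization indices to simulate and recover
    rci_targets: tuple[float, ...] = (0.14, 0.5, 0.97, 1.0)
    baseline_pct: float = 9.7
    n_plants: int = 8
    cfu_scale: int = 10_000
    # qPCR stage
    qpcr_ratio: float = 4.0
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 4
    qpcr_permutations: int = 2000
    reference_gene: str = "mdh"

    def validate(self) -> None:
        if not self.primary_fold >= self.secondary_fold >= 1.0:
            raise ConfigurationError(
                "thresholds must satisfy primary_fold >= secondary_fold >= 1"
            )
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        for name in ("down_threshold", "down_all_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        self.simulation.validate()

    @property
    def seed(self) -> int:
        return self.simulation.seed

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_kwargs = raw.pop("simulation", {})
        config = cls(**raw)
        config.simulation = simulate.SimulationConfig(**sim_kwargs)
        return config


def default_design(config: RunConfig) -> list[Contrast]:
    """Indirect contrasts (each rhizosphere vs. glucose) plus all direct pairs."""
    indirect = [
        Contrast(r, simulate.BASELINE_CONDITION) for r in simulate.RHIZOSPHERES
    ]
    direct = [
        Contrast(a, b)
        for i, a in enumerate(simulate.RHIZOSPHERES)
        for b in simulate.RHIZOSPHERES[i + 1 :]
    ]
    return indirect + direct


def process_slides(
    slides: list[arrays.SlideTable],
    design: list[Contrast],
    span: float = arrays.DEFAULT_SPAN,
    floor: float = arrays.DEFAULT_BACKGROUND_FLOOR,
) -> dict[Contrast, "pd.DataFrame"]:  # noqa: F821
    """Normalize every slide and aggregate each contrast's replicates."""
    normalized = [arrays.normalize_slide(s, span=span, floor=floor) for s in slides]
    return {c: arrays.aggregate_contrast(normalized, c) for c in design}


def run_all(config: RunConfig) -> dict:
    """Run the whole synthetic pipeline and write outputs under ``outdir``.

    Outputs: slide tables + design, planted truth table, per-contrast result
    tables, gene-call table, CFU sheet and RCI table, Ct table, and a
    ``summary.json`` with category counts, Venn regions, replicon fractions,
    the RCI table and the qPCR result.
    """
    config.validate()
    sim = config.simulation
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    log.info("run_all: seed=%d outdir=%s", config.seed, outdir)

    # --- simulate -----------------------------------------------------------
    log.info("simulate: %d genes, noise_sd_log2=%.3g", sim.n_genes, sim.noise_sd_log2)
    truths = simulate.generate_truth(sim)
    design = default_design(config)
    slides = simulate.generate_slides(truths, design, sim)
    simulate.write_truth_table(truths, os.path.join(outdir, "truth.tsv"))
    design_path = arrays.write_slide_tables(slides, os.path.join(outdir, "slides"))

    # --- process (round-trips through the on-disk dialect) ------------------
    log.info("process: %d slides, span=%.2f", len(slides), config.span)
    slides = arrays.read_slide_tables(design_path)
    results = process_slides(
        slides, design, span=config.span, floor=config.background_floor
    )
    contrast_dir = os.path.join(outdir, "contrasts")
    os.makedirs(contrast_dir, exist_ok=True)
    for contrast, table in results.items():
        arrays.write_contrast_table(
            table, os.path.join(contrast_dir, f"{contrast.name}.tsv")
        )

    # --- classify -----------------------------------------------------------
    indirect = {
        c.numerator: t
        for c, t in results.items()
        if c.denominator == simulate.BASELINE_CONDITION
    }
    direct = {
        (c.numerator, c.denominator): t
        for c, t in results.items()
        if c.denominator != simulate.BASELINE_CONDITION
    }
    replicon_map = {t.gene_id: t.replicon for t in truths}
    calls = specificity.make_gene_calls(
        indirect,
        replicon_map=replicon_map,
        direct=direct,
        primary_threshold=config.primary_fold,
        secondary_threshold=config.secondary_fold,
        alpha=config.alpha,
        require_secondary_p=config.require_secondary_p,
        down_threshold=config.down_threshold,
        down_all_threshold=config.down_all_threshold,
        slight_band=config.slight_band,
        rhizospheres=simulate.RHIZOSPHERES,
    )
    specificity.write_gene_calls(calls, os.path.join(outdir, "gene_calls.tsv"))
    report = specificity.summarize_calls(
        calls,
        venn_threshold=config.primary_fold,
        venn_alpha=config.alpha,
        rhizospheres=simulate.RHIZOSPHERES,
    )
    focal_label = specificity.category_name(
        {config.reconcile_focal}, simulate.RHIZOSPHERES
    )
    reconciled = specificity.reconcile_specific(
        calls,
        direct,
        focal=config.reconcile_focal,
        threshold=config.primary_fold,
        alpha=config.alpha,
        rhizospheres=simulate.RHIZOSPHERES,
    )
    prl8 = specificity.replicon_report(calls, focal_label, "pRL8")
    log.info(
        "classify: %d genes, %d %s, %d reconciled",
        len(calls),
        report.up_counts.get(focal_label, 0),
        focal_label,
        len(reconciled),
    )

    # --- competition --------------------------------------------------------
    assays = [
        simulate.generate_competition_counts(
            target,
            baseline_pct=config.baseline_pct,
            n_plants=config.n_plants,
            cfu_scale=config.cfu_scale,
            seed=config.seed + i,
            mutant_id=f"mutant_rci_{target:g}",
        )
        for i, target in enumerate(config.rci_targets)
    ]
    competition.write_cfu_sheet(assays, os.path.join(outdir, "cfu.tsv"))
    rci = competition.rci_table(assays)
    rci.to_csv(os.path.join(outdir, "rci.tsv"), sep="\t", index=False)
    log.info("competition: %d assays, n_plants=%d", len(assays), config.n_plants)

    # --- qPCR ---------------------------------------------------------------
    ct = simulate.generate_ct_table(
        config.qpcr_ratio,
        ref_gene=config.reference_gene,
        n_replicates=config.qpcr_replicates,
        ct_noise_sd=config.qpcr_noise_sd,
        seed=config.seed,
    )
    qpcr.write_ct_table(ct, os.path.join(outdir, "qpcr_ct.tsv"))
    fold = qpcr.ddct_fold(ct, "target", reference_gene=config.reference_gene)
    p = qpcr.permutation_ratio_test(
        ct,
        "target",
        reference_gene=config.reference_gene,
        n_permutations=config.qpcr_permutations,
        seed=config.seed,
    )
    log.info("qpcr: planted ratio %.3g, ddCt fold %.3g (p=%.3g)", config.qpcr_ratio, fold, p)

    # --- summary ------------------------------------------------------------
    planted_counts: dict[str, int] = {}
    for t in truths:
        planted_counts[t.category] = planted_counts.get(t.category, 0) + 1
    summary = {
        "seed": config.seed,
        "parameters": {
            "n_genes": sim.n_genes,
            "n_replicates_per_contrast": sim.n_replicates_per_contrast,
            "noise_sd_log2": sim.noise_sd_log2,
            "dye_bias_amplitude": sim.dye_bias_amplitude,
            "primary_fold": config.primary_fold,
            "secondary_fold": config.secondary_fold,
            "alpha": config.alpha,
            "span": config.span,
        },
        "planted_category_counts": planted_counts,
        "called_category_counts": {
            cat: len(g) for cat, g in report.genes.items()
        },
        "up_counts": report.up_counts,
        "down_counts": report.down_counts,
        "venn_regions": report.venn_regions,
        "reconciled_focal_specific": {
            "focal": config.reconcile_focal,
            "count": len(reconciled),
        },
        "replicon": {
            "category": focal_label,
            "replicon": "pRL8",
            "count_in_category": prl8.count_in_category,
            "count_on_replicon": prl8.count_on_replicon,
            "fraction": prl8.fraction,
        },
        "rci": rci.to_dict(orient="records"),
        "qpcr": {
            "planted_ratio": config.qpcr_ratio,
            "ddct_fold": fold,
            "permutation_p": p,
        },
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return summary


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def dump_yaml(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
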