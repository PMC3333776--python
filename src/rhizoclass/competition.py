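"""Competition assays and the Rhizosphere Colonization Index (RCI).

A mutant is co-inoculated with the wild type at a 10:1 mutant:wild-type
ratio; after growth in the rhizosphere, bacteria are recovered, plated on
selective media and scored as colony-forming units (CFU).  The wild-type
recovery percentage is normalized against a wild-type-vs-wild-type control
(the baseline, theoretically 100/11 = 9.1% at 10:1) to give

    RCI = 1 / (recovery_vs_mutant / recovery_vs_control)
        = baseline_pct / mean_recovery_pct

An RCI of 1 means the mutant competes as well as the wild type; the lower the
RCI, the less competitive the mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AssayError, InputError, ParameterError

#: raw plate counts below this trigger a counting-statistics warning
LOW_COLONY_COUNT = 10

CFU_SHEET_COLUMNS = [
    "mutant_id",
    "rhizosphere",
    "plant",
    "strain",
    "dilution_factor",
    "colonies",
]


@dataclass(frozen=True)
class PlantCount:
    """Dilution-corrected CFU recovered from one plant replicate."""

    wildtype_cfu: float
    mutant_cfu: float


@dataclass
class CompetitionAssay:
    """All plant replicates of one mutant in one rhizosphere."""

    mutant_id: str
    rhizosphere: str
    plants: list[PlantCount]
    baseline_pct: float

    def __post_init__(self) -> None:
        if not 0 < self.baseline_pct < 100:
            raise ParameterError(
                f"{self.mutant_id}: baseline_pct must be in (0, 100)"
            )
        if any(p.wildtype_cfu < 0 or p.mutant_cfu < 0 for p in self.plants):
            raise InputError(f"{self.mutant_id}: CFU counts must be >= 0")
        if not any(p.wildtype_cfu + p.mutant_cfu > 0 for p in self.plants):
            raise AssayError(f"{self.mutant_id}: no plant with a nonzero total count")


@dataclass(frozen=True)
class RCIResult:
    mutant_id: str
    rhizosphere: str
    mean_recovery_pct: float
    sem_recovery_pct: float
    rci: float
    n_plants: int


def recovery_percentage(wildtype_cfu: float, mutant_cfu: float) -> float:
    """Wild-type share of the recovered population, in percent."""
    total = wildtype_cfu + mutant_cfu
    if total <= 0:
        raise AssayError("recovery percentage undefined for a zero total count")
    return 100.0 * wildtype_cfu / total


def expected_baseline(inoculum_ratio_mutant_to_wt: float) -> float:
    """Expected minority-strain recovery percentage under equal fitness.

    At the standard 10:1 inoculum this is 100/11 = 9.09%, the theoretical
    value the wild-type-vs-wild-type control is checked against.
    """
    if inoculum_ratio_mutant_to_wt <= 0:
        raise ParameterError("inoculum ratio must be > 0")
    return 100.0 / (1.0 + inoculum_ratio_mutant_to_wt)


def rci_from_recovery(mean_recovery_pct: float, baseline_pct: float) -> float:
    """RCI = baseline_pct / mean_recovery_pct."""
    if mean_recovery_pct <= 0:
        raise ParameterError("mean recovery percentage must be > 0")
    return baseline_pct / mean_recovery_pct


def compute_rci(assay: CompetitionAssay) -> RCIResult:
    """Per-plant recovery percentages, their mean and SEM, and the RCI.

    Percentages are averaged per plant (not pooled over counts), matching how
    mean +/- SEM over plant replicates is reported; plants with a zero total
    count are excluded with a warning.
    """
    percentages = []
    for i, plant in enumerate(assay.plants):
        if plant.wildtype_cfu + plant.mutant_cfu <= 0:
            warnings.warn(
                f"{assay.mutant_id}: plant {i + 1} has zero total CFU, excluded",
                stacklevel=2,
            )
            continue
        percentages.append(recovery_percentage(plant.wildtype_cfu, plant.mutant_cfu))
    if not percentages:
        raise AssayError(f"{assay.mutant_id}: all plant records excluded")
    arr = np.asarray(percentages, float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return RCIResult(
        mutant_id=assay.mutant_id,
        rhizosphere=assay.rhizosphere,
        mean_recovery_pct=mean,
        sem_recovery_pct=sem,
        rci=rci_from_recovery(mean, assay.baseline_pct),
        n_plants=len(arr),
    )


def rci_table(assays: list[CompetitionAssay]) -> pd.DataFrame:
    """RCI results for a batch of assays, one row per mutant/rhizosphere."""
    rows = []
    for assay in assays:
        r = compute_rci(assay)
        rows.append(
            {
                "mutant_id": r.mutant_id,
                "rhizosphere": r.rhizosphere,
                "mean_recovery_pct": r.mean_recovery_pct,
                "sem_recovery_pct": r.sem_recovery_pct,
                "rci": r.rci,
                "rci_2dp": round(r.rci, 2),
                "n_plants": r.n_plants,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CFU sheet IO


def write_cfu_sheet(
    assays: list[CompetitionAssay], path: str, dilution_factor: float = 1.0
) -> None:
    """Write assays as a long-format plate-count sheet.

    Counts are stored as (colonies, dilution_factor) pairs; the reader
    multiplies them back.  ``dilution_factor`` must divide the counts evenly
    for a lossless round-trip, which holds for the default of 1.
    """
    rows = []
    for assay in assays:
        for i, plant in enumerate(assay.plants, start=1):
            for strain, cfu in (
                ("wildtype", plant.wildtype_cfu),
                ("mutant", plant.mutant_cfu),
            ):
                rows.append(
                    {
                        "mutant_id": assay.mutant_id,
                        "rhizosphere": assay.rhizosphere,
                        "plant": i,
                        "strain": strain,
                        "dilution_factor": dilution_factor,
                        "colonies": cfu / dilution_factor,
                    }
                )
    pd.DataFrame(rows, columns=CFU_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cfu_sheet(
    path: str,
    baseline_pct: float | None = None,
    control_id: str = "control",
) -> list[CompetitionAssay]:
    """Read a plate-count sheet into assays, dilution-correcting the counts.

    If a control block (``mutant_id == control_id``, a wild-type-vs-wild-type
    co-inoculation) is present, its mean recovery defines the baseline for
    every assay in the sheet; otherwise ``baseline_pct`` must be given.  Raw
    colony counts below ``LOW_COLONY_COUNT`` trigger a warning.
    """
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in CFU_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise InputError(f"CFU sheet {path}: missing columns {missing}")
    low = sheet["colonies"] < LOW_COLONY_COUNT
    if low.any():
        warnings.warn(
            f"{path}: {int(low.sum())} plate counts below {LOW_COLONY_COUNT} "
            "colonies; percentages from such plates are noisy",
            stacklevel=2,
        )
    sheet = sheet.assign(cfu=sheet["colonies"] * sheet["dilution_factor"])

    def _plants(block: pd.DataFrame) -> list[PlantCount]:
        wide = (
            block.pivot_table(
                index="plant", columns="strain", values="cfu", aggfunc="sum"
            )
            .reindex(columns=["wildtype", "mutant"])
            .fillna(0.0)
        )
        return [
            PlantCount(wildtype_cfu=row.wildtype, mutant_cfu=row.mutant)
            for row in wide.itertuples(index=False)
        ]

    control = sheet[sheet["mutant_id"] == control_id]
    if baseline_pct is None:
        if control.empty:
            raise InputError(
                f"CFU sheet {path}: no '{control_id}' block and no baseline_pct given"
            )
        pcts = [
            recovery_percentage(p.wildtype_cfu, p.mutant_cfu)
            for p in _plants(control)
            if p.wildtype_cfu + p.mutant_cfu > 0
        ]
        baseline_pct = float(np.mean(pcts))

    assays = []
    body = sheet[sheet["mutant_id"] != control_id]
    for (mutant_id, rhizosphere), block in body.groupby(
        ["mutant_id", "rhizosphere"], sort=True
    ):
        assays.append(
            CompetitionAssay(
                mutant_id=str(mutant_id),
                rhizosphere=str(rhizosphere),
                plants=_plants(block),
                baseline_pct=baseline_pct,
            )
        )
    return assays
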