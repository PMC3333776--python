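"""Cross-rhizosphere specificity calls, Venn summaries, replicon enrichment.

A gene measured against a common baseline in several rhizospheres is scored
*elevated* in a rhizosphere when its fold-change reaches the three-fold
primary threshold at P <= 0.05, or reaches the two-fold secondary threshold
while some other rhizosphere carries a primary call.  The resulting elevated
set maps onto a specificity category: general (ALL), single-plant specific
(PEA_ONLY, ...), legume-specific (pea + alfalfa), or another pair.
Down-regulation is called separately (<= 0.3-fold at P <= 0.05, extended to
DOWN_ALL when the remaining rhizospheres are <= 0.5-fold; a 0.4-0.8-fold band
is reported as SLIGHT_DOWN).

Indirect calls (each rhizosphere vs. a glucose baseline) can be reconciled
with direct rhizosphere-vs-rhizosphere hybridizations: a gene is retained as
strictly plant-specific only when both designs support it
(:func:`reconcile_specific`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .errors import DesignError, InputError

DEFAULT_RHIZOSPHERES = ("pea", "alfalfa", "sugarbeet")

#: canonical category names for the default pea/alfalfa/sugar-beet design
DEFAULT_CATEGORY_NAMES: dict[frozenset, str] = {
    frozenset(): "NONE",
    frozenset({"pea"}): "PEA_ONLY",
    frozenset({"alfalfa"}): "ALFALFA_ONLY",
    frozenset({"sugarbeet"}): "SUGARBEET_ONLY",
    frozenset({"pea", "alfalfa"}): "LEGUME",
    frozenset({"alfalfa", "sugarbeet"}): "ALFALFA_SUGARBEET",
    frozenset({"pea", "sugarbeet"}): "PEA_SUGARBEET",
    frozenset({"pea", "alfalfa", "sugarbeet"}): "ALL",
}

DOWN_CATEGORIES = ("DOWN_ALL", "DOWN_SOME", "SLIGHT_DOWN", "NONE")

FoldP = tuple[float, float]


@dataclass
class GeneCall:
    """Final per-gene classification with the evidence behind it."""

    gene_id: str
    folds: dict[str, FoldP]
    up_category: str
    down_category: str
    replicon: str | None = None
    direct_folds: dict[tuple[str, str], FoldP] | None = None
    conflict: bool = False

    @property
    def category(self) -> str:
        """Single label: the up category, else DOWN_ALL, else NONE.

        Matches the vocabulary of the synthetic truth table, where only fully
        repressed genes carry a down label.
        """
        if self.up_category != "NONE":
            return self.up_category
        if self.down_category == "DOWN_ALL":
            return "DOWN_ALL"
        return "NONE"


def _check_folds(
    folds: Mapping[str, FoldP], rhizospheres: Iterable[str]
) -> None:
    missing = [r for r in rhizospheres if r not in folds]
    if missing:
        raise InputError(f"missing rhizosphere entries: {missing}")


def call_elevated(
    folds: Mapping[str, FoldP],
    primary_threshold: float = 3.0,
    secondary_threshold: float = 2.0,
    alpha: float = 0.05,
    require_secondary_p: bool = True,
    rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES,
) -> set[str]:
    """Rhizospheres in which a gene is scored elevated.

    A rhizosphere gets a *primary* call at fold >= primary_threshold with
    P <= alpha.  If any rhizosphere has a primary call, rhizospheres at
    fold >= secondary_threshold join the elevated set (by default also
    requiring P <= alpha; set ``require_secondary_p=False`` for a pure
    fold-based secondary rule).  Without any primary call the set is empty.
    """
    rhizospheres = tuple(rhizospheres)
    _check_folds(folds, rhizospheres)
    primary = {
        r
        for r in rhizospheres
        if folds[r][0] >= primary_threshold and folds[r][1] <= alpha
    }
    if not primary:
        return set()
    secondary = {
        r
        for r in rhizospheres
        if folds[r][0] >= secondary_threshold
        and (folds[r][1] <= alpha or not require_secondary_p)
    }
    return primary | secondary


def call_repressed(
    folds: Mapping[str, FoldP],
    down_threshold: float = 0.3,
    down_all_threshold: float = 0.5,
    slight_band: tuple[float, float] = (0.4, 0.8),
    alpha: float = 0.05,
    rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES,
) -> str:
    """Down-regulation category for one gene.

    DOWN in a rhizosphere means fold <= down_threshold at P <= alpha.  With at
    least one DOWN rhizosphere, the call is DOWN_ALL when every remaining
    rhizosphere is at fold <= down_all_threshold, else DOWN_SOME.  With no
    DOWN rhizosphere, all folds inside ``slight_band`` give SLIGHT_DOWN
    (fold-only band, no P filter); otherwise NONE.
    """
    rhizospheres = tuple(rhizospheres)
    _check_folds(folds, rhizospheres)
    down = {
        r
        for r in rhizospheres
        if folds[r][0] <= down_threshold and folds[r][1] <= alpha
    }
    if down:
        rest = [r for r in rhizospheres if r not in down]
        if all(folds[r][0] <= down_all_threshold for r in rest):
            return "DOWN_ALL"
        return "DOWN_SOME"
    lo, hi = slight_band
    if all(lo <= folds[r][0] <= hi for r in rhizospheres):
        return "SLIGHT_DOWN"
    return "NONE"


def category_name(
    elevated: set[str], rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES
) -> str:
    """Map an elevated set to its category label.

    The default pea/alfalfa/sugar-beet design uses the study's vocabulary
    (ALL, PEA_ONLY, LEGUME, ...); any other rhizosphere set falls back to
    generated names (ALL, <NAME>_ONLY, alphabetical joins).
    """
    rhizospheres = tuple(rhizospheres)
    key = frozenset(elevated)
    if set(rhizospheres) == set(DEFAULT_RHIZOSPHERES) and key in DEFAULT_CATEGORY_NAMES:
        return DEFAULT_CATEGORY_NAMES[key]
    if not elevated:
        return "NONE"
    if key == frozenset(rhizospheres):
        return "ALL"
    if len(elevated) == 1:
        return f"{next(iter(elevated)).upper()}_ONLY"
    return "_".join(sorted(r.upper() for r in elevated))


def classify(
    gene_id: str,
    folds: Mapping[str, FoldP],
    replicon: str | None = None,
    direct_folds: Mapping[tuple[str, str], FoldP] | None = None,
    primary_threshold: float = 3.0,
    secondary_threshold: float = 2.0,
    alpha: float = 0.05,
    require_secondary_p: bool = True,
    down_threshold: float = 0.3,
    down_all_threshold: float = 0.5,
    slight_band: tuple[float, float] = (0.4, 0.8),
    rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES,
) -> GeneCall:
    """Combine elevation and repression rules into one GeneCall.

    A gene never carries both an up and a down label: if both rules fire
    (possible across different rhizospheres), the elevation call wins and the
    gene is marked ``conflict=True``.
    """
    rhizospheres = tuple(rhizospheres)
    elevated = call_elevated(
        folds,
        primary_threshold=primary_threshold,
        secondary_threshold=secondary_threshold,
        alpha=alpha,
        require_secondary_p=require_secondary_p,
        rhizospheres=rhizospheres,
    )
    up = category_name(elevated, rhizospheres)
    down = call_repressed(
        folds,
        down_threshold=down_threshold,
        down_all_threshold=down_all_threshold,
        slight_band=slight_band,
        alpha=alpha,
        rhizospheres=rhizospheres,
    )
    conflict = up != "NONE" and down != "NONE"
    if conflict:
        down = "NONE"
    return GeneCall(
        gene_id=gene_id,
        folds=dict(folds),
        up_category=up,
        down_category=down,
        replicon=replicon,
        direct_folds=dict(direct_folds) if direct_folds is not None else None,
        conflict=conflict,
    )


def make_gene_calls(
    indirect: Mapping[str, pd.DataFrame],
    replicon_map: Mapping[str, str] | None = None,
    direct: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    **classify_kwargs,
) -> list[GeneCall]:
    """Classify every gene from per-rhizosphere indirect contrast tables.

    ``indirect`` maps rhizosphere -> ContrastResult table (vs. the shared
    baseline); ``direct`` optionally maps ordered rhizosphere pairs to direct
    contrast tables, attached to the calls for later reconciliation.
    """
    rhizospheres = tuple(
        classify_kwargs.pop("rhizospheres", tuple(indirect.keys()))
    )
    tables = {}
    gene_sets = []
    for r in rhizospheres:
        if r not in indirect:
            raise InputError(f"no indirect contrast table for rhizosphere {r!r}")
        t = indirect[r].set_index("gene_id")
        tables[r] = t
        gene_sets.append(set(t.index))
    common = set.intersection(*gene_sets)
    direct_lookup = (
        {pair: t.set_index("gene_id") for pair, t in direct.items()} if direct else None
    )
    calls = []
    for gene_id in sorted(common):
        folds = {
            r: (
                float(tables[r].at[gene_id, "fold_change"]),
                float(tables[r].at[gene_id, "p_value"]),
            )
            for r in rhizospheres
        }
        dfolds = None
        if direct_lookup is not None:
            dfolds = {
                pair: (
                    float(t.at[gene_id, "fold_change"]),
                    float(t.at[gene_id, "p_value"]),
                )
                for pair, t in direct_lookup.items()
                if gene_id in t.index
            }
        replicon = replicon_map.get(gene_id) if replicon_map else None
        calls.append(
            classify(
                gene_id,
                folds,
                replicon=replicon,
                direct_folds=dfolds,
                rhizospheres=rhizospheres,
                **classify_kwargs,
            )
        )
    return calls


def reconcile_specific(
    calls: Iterable[GeneCall],
    direct_tables: Mapping[tuple[str, str], pd.DataFrame],
    focal: str = "pea",
    threshold: float = 3.0,
    alpha: float = 0.05,
    rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES,
) -> set[str]:
    """Genes specific to ``focal`` under both the indirect and direct designs.

    Keeps genes whose indirect category is the focal singleton AND whose
    direct fold versus *each* other rhizosphere is >= threshold at
    P <= alpha.  Direct tables may be keyed in either pair orientation; folds
    are inverted as needed.  The combination rule is an intersection, the
    conservative reading of requiring both designs.
    """
    rhizospheres = tuple(rhizospheres)
    others = [r for r in rhizospheres if r != focal]
    lookups = {}
    for other in others:
        if (focal, other) in direct_tables:
            t, invert = direct_tables[(focal, other)], False
        elif (other, focal) in direct_tables:
            t, invert = direct_tables[(other, focal)], True
        else:
            raise DesignError(
                f"no direct contrast table for pair ({focal}, {other})"
            )
        lookups[other] = (t.set_index("gene_id"), invert)
    focal_label = category_name({focal}, rhizospheres)
    retained = set()
    for call in calls:
        if call.up_category != focal_label:
            continue
        ok = True
        for other, (table, invert) in lookups.items():
            if call.gene_id not in table.index:
                ok = False
                break
            fold = float(table.at[call.gene_id, "fold_change"])
            p = float(table.at[call.gene_id, "p_value"])
            if invert:
                fold = 1.0 / fold
            if not (fold >= threshold and p <= alpha):
                ok = False
                break
        if ok:
            retained.add(call.gene_id)
    return retained


@dataclass(frozen=True)
class RepliconSummary:
    count_in_category: int
    count_on_replicon: int
    fraction: float | None  # None when the category is empty


def replicon_report(
    calls: Iterable[GeneCall], category: str, replicon: str
) -> RepliconSummary:
    """How much of a specificity category sits on one replicon."""
    in_category = [c for c in calls if c.category == category]
    on_replicon = [c for c in in_category if c.replicon == replicon]
    n = len(in_category)
    return RepliconSummary(
        count_in_category=n,
        count_on_replicon=len(on_replicon),
        fraction=len(on_replicon) / n if n else None,
    )


def venn(sets: Mapping[str, set]) -> dict[str, int]:
    """Disjoint region counts for two or three gene sets.

    Region labels join set names with ``&`` (e.g. ``"pea&alfalfa"``); the
    ``total`` entry is the size of the union, which the disjoint regions sum
    to by construction.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise InputError(f"venn needs 2 or 3 sets, got {len(names)}")
    regions: dict[str, int] = {}
    union: set = set().union(*sets.values())
    for k in range(1, len(names) + 1):
        for include in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in include))
            outside = set().union(
                *(sets[n] for n in names if n not in include), set()
            )
            regions["&".join(include)] = len(inside - outside)
    regions["total"] = len(union)
    return regions


@dataclass
class CategoryReport:
    """Aggregate view of a cohort of gene calls."""

    up_counts: dict[str, int]
    down_counts: dict[str, int]
    genes: dict[str, list[str]]
    replicon_counts: dict[str, dict[str, int]]
    venn_regions: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "up_counts": self.up_counts,
            "down_counts": self.down_counts,
            "replicon_counts": self.replicon_counts,
            "venn_regions": self.venn_regions,
        }


def summarize_calls(
    calls: list[GeneCall],
    venn_threshold: float = 3.0,
    venn_alpha: float = 0.05,
    rhizospheres: Iterable[str] = DEFAULT_RHIZOSPHERES,
) -> CategoryReport:
    """Category counts, per-category replicon breakdowns and a Venn summary.

    The Venn uses the per-rhizosphere sets of genes at fold >= venn_threshold
    with P <= venn_alpha, the selection classically used to draw the
    three-rhizosphere diagrams.
    """
    rhizospheres = tuple(rhizospheres)
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    genes: dict[str, list[str]] = {}
    replicon_counts: dict[str, dict[str, int]] = {}
    for call in calls:
        up_counts[call.up_category] = up_counts.get(call.up_category, 0) + 1
        down_counts[call.down_category] = down_counts.get(call.down_category, 0) + 1
        genes.setdefault(call.category, []).append(call.gene_id)
        if call.replicon is not None:
            by_rep = replicon_counts.setdefault(call.category, {})
            by_rep[call.replicon] = by_rep.get(call.replicon, 0) + 1
    for lst in genes.values():
        lst.sort()
    venn_sets = {
        r: {
            c.gene_id
            for c in calls
            if c.folds[r][0] >= venn_threshold and c.folds[r][1] <= venn_alpha
        }
        for r in rhizospheres
    }
    return CategoryReport(
        up_counts=up_counts,
        down_counts=down_counts,
        genes=genes,
        replicon_counts=replicon_counts,
        venn_regions=venn(venn_sets),
    )


def write_gene_calls(calls: list[GeneCall], path: str) -> None:
    rows = []
    for c in calls:
        row = {
            "gene_id": c.gene_id,
            "up_category": c.up_category,
            "down_category": c.down_category,
            "category": c.category,
            "replicon": c.replicon if c.replicon is not None else "",
            "conflict": int(c.conflict),
        }
        for r, (fold, p) in c.folds.items():
            row[f"fold_{r}"] = fold
            row[f"p_{r}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_replicon_map(path: str) -> dict[str, str]:
    """Tab-separated gene_id -> replicon mapping."""
    table = pd.read_csv(path, sep="\t")
    if not {"gene_id", "replicon"} <= set(table.columns):
        raise InputError(f"replicon map {path}: needs gene_id and replicon columns")
    return dict(zip(table["gene_id"].astype(str), table["replicon"].astype(str)))
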