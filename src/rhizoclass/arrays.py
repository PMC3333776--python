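"""Two-color microarray processing.

Raw spotted-array data arrive as per-slide tables of two-channel foreground and
local-background intensities.  The processing chain implemented here is the
standard one for such arrays:

1. local background subtraction per channel (:func:`background_correct`),
2. MA transform: per-spot log2 ratio ``M`` and mean log2 intensity ``A``
   (:func:`ma_transform`),
3. intensity-dependent normalization: a robust lowess fit of M on A is
   subtracted, removing dye bias (:func:`lowess_normalize`),
4. replicate aggregation per contrast: mean log2 ratio, fold-change and a
   one-sample t-test P-value per gene (:func:`aggregate_contrast`),
5. optionally, an *indirect* contrast between two conditions that were each
   hybridized against a common baseline (:func:`derive_indirect_ratio`).

Slides hybridizing two conditions directly, and slides hybridizing each
condition against a glucose-grown baseline culture, are both expressed with
the same :class:`SlideTable` / :class:`Contrast` vocabulary; dye-swapped
replicates are reconciled by orientation, not discarded.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DesignError, InputError, NormalizationError, StatisticsError

SLIDE_COLUMNS = ["gene_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]
DESIGN_COLUMNS = ["slide_id", "condition_ch1", "condition_ch2", "replicate", "dye_swap"]
CONTRAST_COLUMNS = [
    "gene_id",
    "numerator",
    "denominator",
    "fold_change",
    "mean_log2_ratio",
    "sd_log2_ratio",
    "p_value",
    "n_replicates",
    "flags",
]

#: floor applied to a background-corrected intensity so log-ratios stay finite
DEFAULT_BACKGROUND_FLOOR = 0.5
#: lowess span (fraction of spots in each local window)
DEFAULT_SPAN = 0.3
#: robustifying iterations of the lowess fit
DEFAULT_LOWESS_ITERATIONS = 3
#: minimum number of finite (M, A) spots required to fit the lowess curve
MIN_SPOTS_FOR_LOWESS = 20


@dataclass(frozen=True)
class SpotRecord:
    """One spot: two-channel foreground/background fluorescence intensities."""

    gene_id: str
    ch1_fg: float
    ch1_bg: float
    ch2_fg: float
    ch2_bg: float


@dataclass
class SlideTable:
    """Raw (or background-corrected) intensities for one hybridization.

    ``condition_ch1`` / ``condition_ch2`` name the biological samples labeled
    into channel 1 and channel 2.  ``dye_swap`` records that this replicate
    had the fluorophore assignment reversed relative to the reference
    orientation of its contrast; the condition labels always describe what is
    actually in each channel, so the flag is informational.
    """

    slide_id: str
    condition_ch1: str
    condition_ch2: str
    dye_swap: bool
    spots: pd.DataFrame
    replicate: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in SLIDE_COLUMNS if c not in self.spots.columns]
        if missing:
            raise InputError(f"slide {self.slide_id}: missing columns {missing}")
        if self.spots["gene_id"].duplicated().any():
            raise InputError(f"slide {self.slide_id}: duplicate gene_id values")
        values = self.spots[SLIDE_COLUMNS[1:]].to_numpy(float)
        if not np.all(np.isfinite(values)) or (values < 0).any():
            raise InputError(
                f"slide {self.slide_id}: intensities must be finite and non-negative"
            )


@dataclass
class NormalizedSlide:
    """Per-gene M (log2 ratio, ch1 over ch2) and A (mean log2 intensity).

    ``data`` columns: gene_id, M, A, flagged.  Flagged genes failed background
    correction in at least one channel; they are retained, never dropped.
    """

    slide_id: str
    condition_ch1: str
    condition_ch2: str
    dye_swap: bool
    data: pd.DataFrame
    replicate: int = 1


@dataclass(frozen=True)
class Contrast:
    """A condition pair, reported as numerator over denominator."""

    numerator: str
    denominator: str
    n_replicates: int | None = None

    @property
    def name(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"


def background_correct(
    slide: SlideTable, floor: float = DEFAULT_BACKGROUND_FLOOR
) -> SlideTable:
    """Subtract each channel's local background from its foreground.

    Corrected intensities are floored at ``floor`` so downstream log-ratios
    remain finite; any spot with foreground <= background in either channel is
    flagged (column ``flagged``) but retained.  Backgrounds in the returned
    table are zeroed to mark the correction as applied.
    """
    spots = slide.spots.copy()
    c1 = spots["ch1_fg"].to_numpy(float) - spots["ch1_bg"].to_numpy(float)
    c2 = spots["ch2_fg"].to_numpy(float) - spots["ch2_bg"].to_numpy(float)
    flagged = (c1 <= 0.0) | (c2 <= 0.0)
    spots["ch1_fg"] = np.maximum(c1, floor)
    spots["ch2_fg"] = np.maximum(c2, floor)
    spots["ch1_bg"] = 0.0
    spots["ch2_bg"] = 0.0
    if "flagged" in spots.columns:
        flagged |= spots["flagged"].to_numpy(bool)
    spots["flagged"] = flagged
    return replace(slide, spots=spots)


def ma_transform(slide: SlideTable) -> NormalizedSlide:
    """Convert corrected channel intensities to (M, A) coordinates.

    Expects a background-corrected slide (backgrounds zero); any residual
    background is subtracted defensively with the same floor rule.
    """
    corrected = slide
    if (slide.spots["ch1_bg"].to_numpy(float) != 0).any() or (
        slide.spots["ch2_bg"].to_numpy(float) != 0
    ).any():
        corrected = background_correct(slide)
    c1 = corrected.spots["ch1_fg"].to_numpy(float)
    c2 = corrected.spots["ch2_fg"].to_numpy(float)
    m = np.log2(c1) - np.log2(c2)
    a = 0.5 * (np.log2(c1) + np.log2(c2))
    flagged = (
        corrected.spots["flagged"].to_numpy(bool)
        if "flagged" in corrected.spots.columns
        else np.zeros(len(c1), bool)
    )
    data = pd.DataFrame(
        {
            "gene_id": corrected.spots["gene_id"].to_numpy(),
            "M": m,
            "A": a,
            "flagged": flagged,
        }
    )
    return NormalizedSlide(
        slide_id=slide.slide_id,
        condition_ch1=slide.condition_ch1,
        condition_ch2=slide.condition_ch2,
        dye_swap=slide.dye_swap,
        data=data,
        replicate=slide.replicate,
    )


def lowess_normalize(
    nslide: NormalizedSlide,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_LOWESS_ITERATIONS,
) -> NormalizedSlide:
    """Subtract a robust lowess trend of M on A: ``M' = M - fhat(A)``.

    The trend is fitted on unflagged spots with tricube-weighted local linear
    regression and ``iterations`` robustifying passes, then evaluated for
    flagged spots by interpolation so no gene is dropped.  A slide with fewer
    than ``MIN_SPOTS_FOR_LOWESS`` usable spots raises
    :class:`~rhizoclass.errors.NormalizationError`.
    """
    data = nslide.data
    m = data["M"].to_numpy(float)
    a = data["A"].to_numpy(float)
    flagged = data["flagged"].to_numpy(bool)
    usable = ~flagged & np.isfinite(m) & np.isfinite(a)
    if usable.sum() < MIN_SPOTS_FOR_LOWESS:
        raise NormalizationError(
            f"slide {nslide.slide_id}: {int(usable.sum())} usable spots "
            f"(need >= {MIN_SPOTS_FOR_LOWESS}) for lowess normalization"
        )
    fit = np.empty_like(m)
    fit_usable = _sm_lowess(
        m[usable], a[usable], frac=span, it=iterations, return_sorted=False
    )
    fit[usable] = fit_usable
    if (~usable).any():
        order = np.argsort(a[usable], kind="stable")
        fit[~usable] = np.interp(
            a[~usable], a[usable][order], fit_usable[order]
        )
    out = data.copy()
    out["M"] = m - fit
    return replace(nslide, data=out)


def normalize_slide(
    slide: SlideTable,
    span: float = DEFAULT_SPAN,
    floor: float = DEFAULT_BACKGROUND_FLOOR,
) -> NormalizedSlide:
    """Full per-slide chain: background correction, MA transform, lowess."""
    return lowess_normalize(ma_transform(background_correct(slide, floor)), span)


def _orientation_sign(nslide: NormalizedSlide, contrast: Contrast) -> float:
    if (
        nslide.condition_ch1 == contrast.numerator
        and nslide.condition_ch2 == contrast.denominator
    ):
        return 1.0
    if (
        nslide.condition_ch1 == contrast.denominator
        and nslide.condition_ch2 == contrast.numerator
    ):
        return -1.0
    raise DesignError(
        f"slide {nslide.slide_id} ({nslide.condition_ch1} vs "
        f"{nslide.condition_ch2}) does not hybridize contrast {contrast.name}"
    )


def aggregate_contrast(
    nslides: list[NormalizedSlide], contrast: Contrast
) -> pd.DataFrame:
    """Combine replicate slides of one contrast into per-gene statistics.

    Dye-swapped slides (channel 1 carrying the denominator) have M negated so
    every replicate reports numerator over denominator.  Per gene the output
    carries the mean log2 ratio over unflagged replicates, the fold-change
    ``2**mean``, and the two-sided P-value of a one-sample t-test of the
    replicate log-ratios against zero.

    Degenerate cases are resolved deterministically and flagged: genes flagged
    on every replicate get ``p_value = 1`` (flag ``all_flagged``); genes whose
    replicates have exactly zero variance get ``p_value = 1`` if the mean is
    zero, else ``p_value = 0`` (flag ``degenerate``); genes with a single
    usable replicate get ``p_value = 1`` (flag ``insufficient``).
    """
    matching = [
        s
        for s in nslides
        if {s.condition_ch1, s.condition_ch2}
        == {contrast.numerator, contrast.denominator}
    ]
    if len(matching) < 2:
        raise StatisticsError(
            f"contrast {contrast.name}: {len(matching)} replicate slides (need >= 2)"
        )
    gene_ids = np.sort(matching[0].data["gene_id"].to_numpy())
    columns_m, columns_f = [], []
    for s in matching:
        idx = s.data.set_index("gene_id")
        try:
            d = idx.loc[gene_ids]
        except KeyError as exc:
            raise InputError(
                f"slide {s.slide_id}: gene set differs from other replicates"
            ) from exc
        columns_m.append(_orientation_sign(s, contrast) * d["M"].to_numpy(float))
        columns_f.append(d["flagged"].to_numpy(bool))
    m_mat = np.column_stack(columns_m)
    f_mat = np.column_stack(columns_f)

    vals = np.where(f_mat, np.nan, m_mat)
    n_used = (~f_mat).sum(axis=1)
    all_flagged = n_used == 0
    # report a ratio even for fully flagged genes, from the raw replicates
    vals = np.where(all_flagged[:, None], m_mat, vals)
    n_eff = np.where(all_flagged, m_mat.shape[1], n_used)

    mean = np.nanmean(vals, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; their P-values
        # are overwritten by the deterministic degenerate rule below
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(vals, axis=1, ddof=1)
        res = stats.ttest_1samp(vals, 0.0, axis=1, nan_policy="omit")
    p = np.asarray(res.pvalue, float).copy()

    multi = n_eff >= 2
    zero_var = multi & (np.nan_to_num(sd, nan=-1.0) == 0.0)
    p[zero_var & (mean == 0.0)] = 1.0
    p[zero_var & (mean != 0.0)] = 0.0
    insufficient = n_eff < 2
    p[insufficient] = 1.0
    p[all_flagged] = 1.0

    flags = np.where(all_flagged, "all_flagged", "")
    flags = np.where(zero_var & ~all_flagged, "degenerate", flags)
    flags = np.where(insufficient & ~all_flagged, "insufficient", flags)

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "numerator": contrast.numerator,
            "denominator": contrast.denominator,
            "fold_change": np.exp2(mean),
            "mean_log2_ratio": mean,
            "sd_log2_ratio": sd,
            "p_value": np.clip(p, 0.0, 1.0),
            "n_replicates": n_eff.astype(int),
            "flags": flags,
        }
    )


def derive_indirect_ratio(
    a_vs_base: pd.DataFrame, b_vs_base: pd.DataFrame
) -> pd.DataFrame:
    """Contrast two conditions through their shared baseline.

    Given per-gene results for A-vs-baseline and B-vs-baseline, returns the
    derived A-vs-B contrast: fold ratio of the two folds, mean log2 ratio the
    difference of means, and a Welch two-sample t-test P-value computed from
    the two replicate summaries.  Both inputs must share the denominator
    condition.
    """
    den_a = a_vs_base["denominator"].unique()
    den_b = b_vs_base["denominator"].unique()
    if len(den_a) != 1 or len(den_b) != 1 or den_a[0] != den_b[0]:
        raise DesignError(
            f"indirect contrasts must share one baseline, got {den_a} and {den_b}"
        )
    num_a = a_vs_base["numerator"].iloc[0]
    num_b = b_vs_base["numerator"].iloc[0]
    merged = a_vs_base.merge(
        b_vs_base, on="gene_id", suffixes=("_a", "_b"), how="inner", validate="1:1"
    )
    ma = merged["mean_log2_ratio_a"].to_numpy(float)
    mb = merged["mean_log2_ratio_b"].to_numpy(float)
    sa = merged["sd_log2_ratio_a"].to_numpy(float)
    sb = merged["sd_log2_ratio_b"].to_numpy(float)
    na = merged["n_replicates_a"].to_numpy(int)
    nb = merged["n_replicates_b"].to_numpy(int)
    mean = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind_from_stats(
            ma, sa, na, mb, sb, nb, equal_var=False
        )
    p = np.asarray(res.pvalue, float).copy()
    degenerate = ~np.isfinite(p)
    p[degenerate & (mean == 0.0)] = 1.0
    p[degenerate & (mean != 0.0)] = 0.0

    flags_a = merged["flags_a"].fillna("").astype(str)
    flags_b = merged["flags_b"].fillna("").astype(str)
    flags = np.where(
        degenerate,
        "degenerate",
        np.where((flags_a != "") | (flags_b != ""), "component_flagged", ""),
    )
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "numerator": num_a,
            "denominator": num_b,
            "fold_change": np.exp2(mean),
            "mean_log2_ratio": mean,
            "sd_log2_ratio": np.sqrt(sa**2 / np.maximum(na, 1) + sb**2 / np.maximum(nb, 1)),
            "p_value": np.clip(p, 0.0, 1.0),
            "n_replicates": np.minimum(na, nb),
            "flags": flags,
        }
    )


# ---------------------------------------------------------------------------
# tab-separated IO (dialect shared with the synthetic generator / real exports)


def write_slide_tables(slides: list[SlideTable], directory: str) -> str:
    """Write one TSV per slide plus a design table; returns the design path."""
    os.makedirs(directory, exist_ok=True)
    design_rows = []
    for slide in slides:
        path = os.path.join(directory, f"{slide.slide_id}.tsv")
        slide.spots[SLIDE_COLUMNS].to_csv(path, sep="\t", index=False)
        design_rows.append(
            {
                "slide_id": slide.slide_id,
                "condition_ch1": slide.condition_ch1,
                "condition_ch2": slide.condition_ch2,
                "replicate": slide.replicate,
                "dye_swap": int(slide.dye_swap),
            }
        )
    design_path = os.path.join(directory, "design.tsv")
    pd.DataFrame(design_rows, columns=DESIGN_COLUMNS).to_csv(
        design_path, sep="\t", index=False
    )
    return design_path


def read_slide_tables(design_path: str) -> list[SlideTable]:
    """Read the design table and the slide TSVs it points at."""
    design = pd.read_csv(design_path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise InputError(f"design file {design_path}: missing columns {missing}")
    directory = os.path.dirname(os.path.abspath(design_path))
    slides = []
    for row in design.itertuples(index=False):
        spot_path = os.path.join(directory, f"{row.slide_id}.tsv")
        if not os.path.exists(spot_path):
            raise InputError(f"slide table not found: {spot_path}")
        spots = pd.read_csv(spot_path, sep="\t")
        slides.append(
            SlideTable(
                slide_id=str(row.slide_id),
                condition_ch1=str(row.condition_ch1),
                condition_ch2=str(row.condition_ch2),
                dye_swap=bool(row.dye_swap),
                spots=spots,
                replicate=int(row.replicate),
            )
        )
    return slides


def write_contrast_table(result: pd.DataFrame, path: str) -> None:
    result[CONTRAST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_contrast_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CONTRAST_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"contrast table {path}: missing columns {missing}")
    table["flags"] = table["flags"].fillna("").astype(str)
    return table
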