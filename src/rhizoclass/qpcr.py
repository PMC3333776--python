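"""Comparative-Ct (ddCt) qPCR quantification and a permutation ratio test.

Threshold cycles (Ct) from target and reference genes measured under a
treatment and a control condition are combined as

    dCt(condition)  = mean Ct(target) - mean Ct(reference)
    ddCt            = dCt(treatment) - dCt(control)
    fold            = E ** (-ddCt)

with amplification efficiency E = 2 (perfect doubling) unless overridden.
Significance is assessed with a permutation test on replicate-paired dCt
values: condition labels are shuffled and the two-sided P-value is the
fraction of label permutations with |ddCt| at least as large as observed
(with the standard +1 correction).  This is a generic randomization test in
the spirit of ratio-randomization tools for qPCR, not a re-implementation of
any of them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, StatisticsError

CT_COLUMNS = ["gene_id", "condition", "replicate", "ct", "is_reference"]


def _frame(wells) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of well records."""
    if isinstance(wells, pd.DataFrame):
        table = wells.copy()
    else:
        table = pd.DataFrame([vars(w) if hasattr(w, "__dict__") else w for w in wells])
    missing = [c for c in CT_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise InputError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise InputError("Ct values must be finite and positive")
    return table


def _gene_condition_means(table: pd.DataFrame, gene: str) -> dict[str, float]:
    sub = table[table["gene_id"] == gene]
    if sub.empty:
        raise InputError(f"no wells for gene {gene!r}")
    return sub.groupby("condition")["ct"].mean().to_dict()


def ddct_fold(
    ct_table,
    target_gene: str,
    reference_gene: str = "mdh",
    treatment: str = "treatment",
    control: str = "control",
    efficiency: float = 2.0,
) -> float:
    """Fold-change of the target gene by the comparative-Ct method.

    Target Ct values are normalized against the reference gene within each
    condition, and the treatment/control difference converted to a ratio with
    the given amplification efficiency (classically 2).
    """
    if efficiency <= 1:
        raise ParameterError("amplification efficiency must be > 1")
    table = _frame(ct_table)
    t_means = _gene_condition_means(table, target_gene)
    r_means = _gene_condition_means(table, reference_gene)
    for cond in (treatment, control):
        if cond not in t_means or cond not in r_means:
            raise InputError(
                f"condition {cond!r} missing for target or reference gene"
            )
    ddct = (t_means[treatment] - r_means[treatment]) - (
        t_means[control] - r_means[control]
    )
    return float(efficiency ** (-ddct))


def _paired_dct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    condition: str,
) -> np.ndarray:
    t = table[(table["gene_id"] == target_gene) & (table["condition"] == condition)]
    r = table[
        (table["gene_id"] == reference_gene) & (table["condition"] == condition)
    ]
    merged = t.merge(r, on="replicate", suffixes=("_t", "_r"))
    if merged.empty:
        raise InputError(
            f"no replicate-paired wells for condition {condition!r}"
        )
    return merged["ct_t"].to_numpy(float) - merged["ct_r"].to_numpy(float)


def permutation_ratio_test(
    ct_table,
    target_gene: str,
    reference_gene: str = "mdh",
    treatment: str = "treatment",
    control: str = "control",
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided permutation P-value for the ddCt statistic.

    Replicate-paired dCt values from both conditions are pooled; condition
    labels are randomly reassigned ``n_permutations`` times and the P-value is
    ``(1 + #{|ddCt*| >= |ddCt|}) / (1 + n_permutations)``.  Requires at least
    three replicates per condition.
    """
    table = _frame(ct_table)
    d_treat = _paired_dct(table, target_gene, reference_gene, treatment)
    d_ctrl = _paired_dct(table, target_gene, reference_gene, control)
    if len(d_treat) < 3 or len(d_ctrl) < 3:
        raise StatisticsError(
            "permutation test needs >= 3 replicates per condition, got "
            f"{len(d_treat)} and {len(d_ctrl)}"
        )
    observed = abs(d_treat.mean() - d_ctrl.mean())
    pooled = np.concatenate([d_treat, d_ctrl])
    n_t = len(d_treat)
    rng = np.random.default_rng(seed)
    hits = 0
    # tolerance keeps exact ties (e.g. a zero observed ddCt) counted as hits
    tol = 1e-12 * max(1.0, observed)
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n_t].mean() - perm[n_t:].mean())
        if stat >= observed - tol:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def read_ct_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return _frame(table)


def write_ct_table(table: pd.DataFrame, path: str) -> None:
    cols = [c for c in CT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
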