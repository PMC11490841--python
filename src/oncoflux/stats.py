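"""Downstream normalisation and significance stages.

Proteomics differential abundance (total-peptide normalisation → log₂ →
per-protein Welch t-test → Benjamini–Hochberg FDR → conjunctive
significance rule) and the growth/apoptosis curve normalisations
(measurements relative to the first timepoint; green-object counts per
unit relative confluence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_total",
    "differential_proteome",
    "relative_growth",
    "relative_apoptosis",
    "SIG_Q",
    "SIG_NEGLOG10P",
    "SIG_ABS_LOG2FC",
]

# significance rule: FDR < 5% AND -log10 p > 1.3 AND |log2 FC| > 0.48
SIG_Q = 0.05
SIG_NEGLOG10P = 1.3
SIG_ABS_LOG2FC = 0.48


def normalize_total(abundances: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) so all samples share the same total.

    Mirrors normalisation of protein abundances to total peptide amount:
    columns are divided by their sum and rescaled to the mean of the
    original column totals, preserving the overall intensity scale.
    """
    if (abundances <= 0).any().any():
        raise ValueError("abundances must be > 0 before normalisation/log transform")
    totals = abundances.sum(axis=0)
    return abundances / totals * totals.mean()


def differential_proteome(
    abundances: pd.DataFrame,
    sample_groups: pd.Series,
    group1: str,
    group2: str,
    normalise: bool = True,
) -> pd.DataFrame:
    """Per-protein Welch tests with BH correction and the conjunctive flag.

    Parameters
    ----------
    abundances
        protein × sample matrix of strictly positive abundances (linear
        scale; log₂ applied internally after total normalisation).
    sample_groups
        sample id → group label, covering every column.
    group1, group2
        Groups to contrast; log₂ fold change is group2 − group1 on the
        log scale (i.e. log₂ of the group2/group1 ratio of geometric means).

    Returns a volcano-ready frame: log2_fc, p, q, neg_log10_p, significant,
    direction.  A protein constant across all samples gets p = 1 and a flag.
    """
    missing = [s for s in abundances.columns if s not in sample_groups.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    cols1 = [s for s in abundances.columns if sample_groups[s] == group1]
    cols2 = [s for s in abundances.columns if sample_groups[s] == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {group1}: {len(cols1)}, "
            f"{group2}: {len(cols2)})"
        )
    data = normalize_total(abundances) if normalise else abundances
    log2 = np.log2(data.to_numpy(dtype=float))
    a = log2[:, [data.columns.get_loc(c) for c in cols1]]
    b = log2[:, [data.columns.get_loc(c) for c in cols2]]

    # Welch t (Satterthwaite df) on log2 values, vectorised over proteins
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    constant = np.isclose(np.concatenate([a, b], axis=1).std(axis=1), 0.0)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    log2_fc = b.mean(axis=1) - a.mean(axis=1)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    neg_log10_p = -np.log10(np.clip(p, 1e-300, None))
    significant = (q < SIG_Q) & (neg_log10_p > SIG_NEGLOG10P) & (np.abs(log2_fc) > SIG_ABS_LOG2FC)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "q": q,
            "neg_log10_p": neg_log10_p,
            "significant": significant,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "constant_flag": constant,
        },
        index=abundances.index,
    )


def relative_growth(series: pd.Series) -> pd.Series:
    """Each value divided by the first-timepoint anchor (0 h / day 0 → 1.0)."""
    anchor = series.iloc[0]
    if not anchor > 0:
        raise ValueError(f"anchor measurement must be > 0 (got {anchor})")
    return series / anchor


def relative_apoptosis(
    green_count: pd.Series, relative_confluence: pd.Series
) -> pd.Series:
    """Green-object count per unit relative confluence at each timepoint.

    Timepoints with missing or zero relative confluence yield NaN (flagged
    not computable); the rest of the series is produced.
    """
    conf = relative_confluence.reindex(green_count.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = green_count / conf
    out[~(conf > 0)] = np.nan
    return out
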