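"""Two-group differential expression and target-gene overlap.

Welch two-sample t-tests per probe on log2-scale intensities,
Benjamini-Hochberg step-up FDR adjustment, and intersection of the
significant genes with the target gene list from the enrichment stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_i = min_{j >= i} (m * p_(j) / j), capped at 1, in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "case",
    control_label: str = "control",
    exclude_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-probe Welch t-test and log2 fold change (case - control means).

    ``expr`` is probes x samples on the log2 scale.  Zero variance in
    both groups yields p = 1 when the means are equal and p -> 0
    (flagged) otherwise.  Returns columns ``probe, log2fc, p, p_adj``.
    """
    if exclude_samples:
        keep = [s for s in expr.columns if s not in set(exclude_samples)]
        expr = expr[keep]
        groups = groups.loc[keep]
    case_cols = groups.index[groups == case_label]
    ctrl_cols = groups.index[groups == control_label]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    a = expr[case_cols].to_numpy()
    b = expr[ctrl_cols].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), np.nextafter(0, 1), p)
    out = pd.DataFrame(
        {
            "probe": expr.index,
            "log2fc": log2fc,
            "p": p,
            "zero_variance": degenerate,
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def significant_genes(
    de: pd.DataFrame, probe_map: pd.DataFrame, fdr: float = 0.05
) -> list[str]:
    """Genes with at least one BH-significant probe (the DE gene set)."""
    merged = de.merge(probe_map, on="probe")
    return sorted(merged.loc[merged["p_adj"] < fdr, "gene"].unique())


def overlap_with_targets(
    de: pd.DataFrame,
    probe_map: pd.DataFrame,
    target_genes: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Target genes with a BH-significant probe, one row per gene.

    Each gene is reported through its most significant probe (minimum
    adjusted p), with the probe's log2 fold change and fold change
    FC = 2^log2FC.  Sorted by descending log2FC, then gene name.
    """
    merged = de.merge(probe_map, on="probe")
    merged = merged[
        merged["gene"].isin(set(target_genes)) & (merged["p_adj"] < fdr)
    ]
    if merged.empty:
        return pd.DataFrame(
            columns=["gene", "probe", "p_adj", "log2fc", "fc"]
        )
    best = merged.sort_values(["p_adj", "probe"], kind="mergesort").groupby(
        "gene", as_index=False
    ).first()
    best["fc"] = 2.0 ** best["log2fc"]
    best = best[["gene", "probe", "p_adj", "log2fc", "fc"]]
    return best.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
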