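"""Contrast fold changes, the cross-stimulus concordance screen, and
co-expression correlation of gene pairs.

The screen operationalizes the prioritization rule for flow-responsive
candidates: a gene passes if its pulsatile/oscillatory (PS/OS) log2 fold
change agrees in sign with its statin-treatment fold change (both protective)
and opposes its TNFa-treatment fold change (inflammatory), with strict
inequalities so a zero fold change never passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import LogExpressionMatrix, design_for_samples

__all__ = [
    "ContrastFC",
    "contrast_log2fc",
    "per_timepoint_log2fc",
    "concordance_screen",
    "coexpression_correlation",
]


@dataclass
class ContrastFC:
    """Per-gene log2 fold change for one contrast (mean log2 difference)."""

    label: str
    log2fc: pd.Series  # indexed by gene_id
    n_a: int
    n_b: int


def _group_columns(m, design, condition, timepoint_policy):
    des = design_for_samples(design, m.sample_ids)
    sel = des["condition"] == condition
    if timepoint_policy == "endpoint":
        times = des.loc[sel, "time_h"]
        sel = sel & (des["time_h"] == times.max())
    elif timepoint_policy != "all":
        raise ValueError(f"unknown timepoint_policy {timepoint_policy!r}")
    return sel.to_numpy()


def contrast_log2fc(
    m: LogExpressionMatrix,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    timepoint_policy: str = "all",
    label: str | None = None,
) -> ContrastFC:
    """Mean log2-expression difference (group_a minus group_b) per gene.

    ``timepoint_policy``: "all" uses every sample of each condition;
    "endpoint" restricts each condition to its final timepoint.
    """
    sel_a = _group_columns(m, design, group_a, timepoint_policy)
    sel_b = _group_columns(m, design, group_b, timepoint_policy)
    if not sel_a.any():
        raise ValueError(f"empty group {group_a!r} under policy {timepoint_policy!r}")
    if not sel_b.any():
        raise ValueError(f"empty group {group_b!r} under policy {timepoint_policy!r}")
    vals = m.values.to_numpy(dtype=float)
    fc = vals[:, sel_a].mean(axis=1) - vals[:, sel_b].mean(axis=1)
    return ContrastFC(
        label=label or f"{group_a}/{group_b}",
        log2fc=pd.Series(fc, index=m.gene_ids, name="log2fc"),
        n_a=int(sel_a.sum()),
        n_b=int(sel_b.sum()),
    )


def per_timepoint_log2fc(
    m: LogExpressionMatrix, design: pd.DataFrame, group_a: str, group_b: str
) -> pd.DataFrame:
    """Genes x timepoints frame of per-timepoint log2 fold changes."""
    des = design_for_samples(design, m.sample_ids)
    vals = m.values.to_numpy(dtype=float)
    times = np.sort(des.loc[des["condition"].isin([group_a, group_b]), "time_h"].unique())
    cols = {}
    for t in times:
        a = ((des["condition"] == group_a) & (des["time_h"] == t)).to_numpy()
        b = ((des["condition"] == group_b) & (des["time_h"] == t)).to_numpy()
        if not a.any() or not b.any():
            raise ValueError(f"timepoint {t} missing one of the groups")
        cols[t] = vals[:, a].mean(axis=1) - vals[:, b].mean(axis=1)
    return pd.DataFrame(cols, index=m.gene_ids)


def concordance_screen(
    ranking: pd.DataFrame,
    fc_ps_os: ContrastFC,
    fc_atv: ContrastFC,
    fc_tnfa: ContrastFC,
    top_n: int = 50,
    min_abs_fc: float = 0.0,
) -> pd.DataFrame:
    """Filter the top-ranked eigengenes by cross-stimulus sign concordance.

    A candidate must satisfy, with strict inequalities:
      concordant_atv: sign(PS/OS FC) == sign(ATV/control FC), both non-zero;
      discordant_tnfa: sign(PS/OS FC) == -sign(TNFa/control FC).
    Rows are ordered by eigengene rank; ``pass_screen`` marks candidates.
    ``min_abs_fc`` optionally requires |FC| >= threshold in every contrast.
    """
    top = ranking.nsmallest(top_n, "rank").copy()
    genes = top["gene_id"]
    missing = [
        fc.label
        for fc in (fc_ps_os, fc_atv, fc_tnfa)
        if not genes.isin(fc.log2fc.index).all()
    ]
    if missing:
        raise ValueError(f"contrast(s) missing genes from the ranking: {missing}")
    ps = fc_ps_os.log2fc.loc[genes].to_numpy()
    atv = fc_atv.log2fc.loc[genes].to_numpy()
    tnfa = fc_tnfa.log2fc.loc[genes].to_numpy()
    big = (
        (np.abs(ps) >= min_abs_fc)
        & (np.abs(atv) >= min_abs_fc)
        & (np.abs(tnfa) >= min_abs_fc)
    )
    concordant_atv = (ps * atv > 0) & big
    discordant_tnfa = (ps * tnfa < 0) & big
    out = pd.DataFrame({
        "rank": top["rank"].to_numpy(),
        "gene_id": genes.to_numpy(),
        "fc_ps_os": ps,
        "fc_atv": atv,
        "fc_tnfa": tnfa,
        "concordant_atv": concordant_atv,
        "discordant_tnfa": discordant_tnfa,
        "pass_screen": concordant_atv & discordant_tnfa,
    })
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def coexpression_correlation(
    m: LogExpressionMatrix, gene_a: str, gene_b: str, method: str = "spearman"
):
    """Correlate two genes' expression across samples.

    Returns (coefficient, p_value, n).  ``method`` is "spearman" or
    "pearson"; a constant gene makes the correlation undefined and is an
    error.
    """
    for g in (gene_a, gene_b):
        if g not in m.gene_ids:
            raise KeyError(f"gene {g!r} not in matrix")
    a = m.values.loc[gene_a].to_numpy(dtype=float)
    b = m.values.loc[gene_b].to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant gene")
    if method == "spearman":
        res = scipy.stats.spearmanr(a, b)
    elif method == "pearson":
        res = scipy.stats.pearsonr(a, b)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(res.statistic), float(res.pvalue), n
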