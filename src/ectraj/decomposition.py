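"""Mean-centred SVD of the expression matrix and trajectory diagnostics.

The analysis matrix is samples x genes, so with X = U S V* the columns of V
are gene loading vectors ("eigengenes") and U S are per-sample component
scores.  Per-condition score-vs-time curves ("trajectories") and per-component
diagnostics identify the component along which two flow conditions diverge
over the time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .containers import LogExpressionMatrix, design_for_samples

__all__ = [
    "PCADecomposition",
    "TrajectorySet",
    "ComponentDiagnostics",
    "center",
    "svd_pca",
    "fit_pca",
    "trajectory_curves",
    "component_diagnostics",
    "select_divergent_component",
    "rank_eigengenes",
]

SIGN_CONVENTION = "largest-|loading| entry positive per component"


@dataclass
class PCADecomposition:
    """A fitted SVD of the centred samples x genes matrix.

    loadings: genes x components, orthonormal columns (right singular vectors).
    scores: samples x components (U S), i.e. centred matrix @ loadings.
    """

    gene_ids: pd.Index
    sample_ids: pd.Index
    gene_means: pd.Series
    loadings: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    sign_convention: str = SIGN_CONVENTION

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum()

    def save(self, prefix) -> None:
        """Serialize as a TSV set under the given path prefix."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        comps = [f"PC{i + 1}" for i in range(self.n_components)]
        pd.DataFrame(self.loadings, index=self.gene_ids, columns=comps).to_csv(
            f"{prefix}.loadings.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(self.scores, index=self.sample_ids, columns=comps).to_csv(
            f"{prefix}.scores.tsv", sep="\t", index_label="sample_id")
        self.gene_means.rename("mean").to_csv(
            f"{prefix}.gene_means.tsv", sep="\t", index_label="gene_id")
        pd.Series(self.singular_values, index=comps, name="sigma").to_csv(
            f"{prefix}.singular_values.tsv", sep="\t", index_label="component")


@dataclass
class TrajectorySet:
    """Score-vs-time curves for one component.

    curves: tidy frame (condition, replicate, time_h, score), times strictly
    increasing within each (condition, replicate).
    condition_means: conditions x times mean score across replicates.
    """

    component: int
    curves: pd.DataFrame
    condition_means: pd.DataFrame

    def terminus_means(self) -> pd.Series:
        """Per-condition mean score at the final timepoint."""
        return self.condition_means.iloc[:, -1]


@dataclass
class ComponentDiagnostics:
    """Per-component variance, time-correlation, divergence and spikiness.

    table columns: component (1-based), variance_fraction, time_correlation
    (Spearman of score vs time pooled over both conditions), divergence_score
    (mean over timepoints of |between-condition mean gap| / pooled within-
    (condition, time) SD) and spike_score (excess kurtosis, floored at 0).
    """

    table: pd.DataFrame
    conditions: tuple[str, str]


def center(m: LogExpressionMatrix):
    """Transpose to samples x genes and remove each gene's mean.

    Returns (centred ndarray samples x genes, gene_means Series).  The means
    are stored so external data can be projected into the same space.
    """
    if m.values.shape[1] < 2:
        raise ValueError("centring needs at least 2 samples")
    x = m.values.to_numpy(dtype=float).T
    gene_means = pd.Series(x.mean(axis=0), index=m.gene_ids, name="mean")
    return x - gene_means.to_numpy(), gene_means


def svd_pca(
    centered: np.ndarray,
    gene_ids: pd.Index,
    sample_ids: pd.Index,
    gene_means: pd.Series,
) -> PCADecomposition:
    """Thin SVD of the centred matrix with a deterministic sign convention.

    Signs of singular vectors are arbitrary; each component is flipped so its
    largest-|loading| gene has a positive loading, making repeated fits and
    sample permutations reproducible.
    """
    if not np.all(np.isfinite(centered)):
        raise ValueError("centred matrix contains non-finite values")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T  # genes x components
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    scores = u * s * flip
    return PCADecomposition(
        gene_ids=pd.Index(gene_ids),
        sample_ids=pd.Index(sample_ids),
        gene_means=gene_means,
        loadings=v,
        scores=scores,
        singular_values=s,
    )


def fit_pca(m: LogExpressionMatrix) -> PCADecomposition:
    """Convenience: centre a log-expression matrix and run the SVD."""
    centered, gene_means = center(m)
    return svd_pca(centered, m.gene_ids, m.sample_ids, gene_means)


def trajectory_curves(
    d: PCADecomposition, design: pd.DataFrame, component: int
) -> TrajectorySet:
    """Build per-(condition, replicate) score-vs-time curves for a component.

    ``component`` is 1-based, matching PC numbering in figures.
    """
    if not 1 <= component <= d.n_components:
        raise ValueError(f"component {component} out of range 1..{d.n_components}")
    des = design_for_samples(design, d.sample_ids)
    des = des.assign(score=d.scores[:, component - 1])
    curves = (
        des[["condition", "replicate", "time_h", "score"]]
        .sort_values(["condition", "replicate", "time_h"], kind="stable")
        .reset_index(drop=True)
    )
    dup = curves.duplicated(["condition", "replicate", "time_h"])
    if dup.any():
        bad = curves.loc[dup, ["condition", "replicate", "time_h"]].iloc[0]
        raise ValueError(
            f"multiple samples at condition={bad.condition!r} "
            f"replicate={bad.replicate!r} t={bad.time_h}")
    condition_means = (
        curves.pivot_table(index="condition", columns="time_h",
                           values="score", aggfunc="mean")
        .sort_index(axis=1)
    )
    return TrajectorySet(component=component, curves=curves,
                         condition_means=condition_means)


def _pooled_within_sd(scores: np.ndarray, groups: pd.Series) -> float:
    """Pooled SD across (condition, time) cells, n-1 denominator per cell."""
    ss = 0.0
    df = 0
    for _, idx in groups.groupby(groups).groups.items():
        vals = scores[np.asarray(idx)]
        if len(vals) >= 2:
            ss += np.sum((vals - vals.mean()) ** 2)
            df += len(vals) - 1
    return float(np.sqrt(ss / df)) if df > 0 else 0.0


def component_diagnostics(
    d: PCADecomposition,
    design: pd.DataFrame,
    conditions: tuple[str, str],
    n_components: int = 8,
) -> ComponentDiagnostics:
    """Score each component for time-correlation, divergence and spikiness.

    divergence_score_k = (1/T) sum_t |mean_A(t) - mean_B(t)| / s_k with s_k
    the pooled within-(condition, time) SD of component-k scores; it is 0 if
    both numerator and s_k vanish and +inf if only s_k does.
    """
    if len(conditions) != 2 or conditions[0] == conditions[1]:
        raise ValueError("exactly two distinct condition labels required")
    des = design_for_samples(design, d.sample_ids)
    present = set(des["condition"])
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"condition(s) not in design: {missing}")
    sel = des["condition"].isin(conditions).to_numpy()
    sub = des.loc[sel].reset_index(drop=True)
    cell = sub["condition"].astype(str) + "@" + sub["time_h"].astype(str)
    n_components = min(n_components, d.n_components)
    times = np.sort(sub["time_h"].unique())
    rows = []
    var_frac = d.variance_fractions
    for k in range(n_components):
        sc_all = d.scores[:, k]
        sc = sc_all[sel]
        if np.ptp(sc) == 0:  # constant scores carry no time trend
            rho = 0.0
        else:
            rho = scipy.stats.spearmanr(sub["time_h"], sc).statistic
        gaps = []
        for t in times:
            at_t = sub["time_h"] == t
            a = sc[at_t & (sub["condition"] == conditions[0])]
            b = sc[at_t & (sub["condition"] == conditions[1])]
            if len(a) and len(b):
                gaps.append(abs(a.mean() - b.mean()))
        mean_gap = float(np.mean(gaps)) if gaps else 0.0
        s_k = _pooled_within_sd(sc, cell)
        if s_k == 0.0:
            divergence = 0.0 if mean_gap == 0.0 else np.inf
        else:
            divergence = mean_gap / s_k
        spike = max(0.0, float(scipy.stats.kurtosis(sc_all, fisher=True, bias=False)))
        rows.append({
            "component": k + 1,
            "variance_fraction": float(var_frac[k]),
            "time_correlation": float(rho),
            "divergence_score": divergence,
            "spike_score": spike,
        })
    return ComponentDiagnostics(table=pd.DataFrame(rows), conditions=tuple(conditions))


def select_divergent_component(
    diag: ComponentDiagnostics, max_time_corr: float = 0.8
) -> int:
    """Pick the component with the largest condition divergence.

    Components whose |Spearman(score, time)| exceeds ``max_time_corr`` are
    excluded first: the dominant shared time-drift axis is not a candidate
    for between-condition divergence.  Ties break to the smaller index.
    Returns a 1-based component index.
    """
    t = diag.table
    ok = t[np.abs(t["time_correlation"]) <= max_time_corr]
    if ok.empty:
        raise ValueError(
            "no component passes the time-correlation gate; "
            f"raise max_time_corr (now {max_time_corr})")
    best = ok.sort_values(["divergence_score", "component"],
                          ascending=[False, True], kind="stable").iloc[0]
    return int(best["component"])


def rank_eigengenes(d: PCADecomposition, component: int) -> pd.DataFrame:
    """Rank all genes by |loading| on a component, descending.

    Ties break by gene_id ascending.  Returns a frame with columns rank
    (1-based, contiguous), gene_id, component, loading, abs_loading.
    """
    if not 1 <= component <= d.n_components:
        raise ValueError(f"component {component} out of range 1..{d.n_components}")
    load = d.loadings[:, component - 1]
    out = pd.DataFrame({
        "gene_id": d.gene_ids,
        "component": component,
        "loading": load,
        "abs_loading": np.abs(load),
    })
    out = out.sort_values(["abs_loading", "gene_id"],
                          ascending=[False, True], kind="stable")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)
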