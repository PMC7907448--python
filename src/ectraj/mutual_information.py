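"""Mutual information between continuous expression and a discrete label.

Implements the k-nearest-neighbour estimator for one continuous and one
discrete variable: for each point, the distance to its k-th nearest neighbour
*within its own class* defines a radius; counting how many points of *any*
class fall strictly inside that radius converts class-conditional density
into a digamma-based MI estimate,

    MI = psi(n) - <psi(n_class_i)> + psi(k) - <psi(m_i)>   (nats),

clamped at zero.  Exact ties (common in log2 CPM data: zeros) are broken by a
deterministic jitter of 1e-10 of the value range, assigned in value-sorted
order so the estimate is invariant under permutations of sample order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .containers import LogExpressionMatrix, design_for_samples

__all__ = ["mi_mixed", "rank_by_mi"]

_JITTER_SCALE = 1e-10


def _jittered(values: np.ndarray, tie_seed: int) -> np.ndarray:
    """Add tiny deterministic jitter, assigned in value-sorted order.

    Sorting before assignment makes the jitter a function of the empirical
    distribution, not of the array order, so permuting samples permutes the
    jittered values identically.
    """
    n = len(values)
    span = float(np.ptp(values))
    scale = _JITTER_SCALE * (span if span > 0 else 1.0)
    rng = np.random.default_rng(tie_seed)
    noise = rng.uniform(-1.0, 1.0, size=n) * scale
    order = np.argsort(values, kind="stable")
    out = values.astype(float).copy()
    out[order] += noise
    return out


def mi_mixed(values, labels, k: int = 3, tie_seed: int = 0) -> float:
    """kNN mutual information (nats) between continuous values and labels.

    Requires every class to have at least k+1 members (so a k-th same-class
    neighbour exists).  Neighbour counts use strict inequality (< radius) and
    include the point itself.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    n = len(values)
    if len(labels) != n:
        raise ValueError("values and labels must have equal length")
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, class_idx, class_counts = np.unique(
        labels, return_inverse=True, return_counts=True)
    small = classes[class_counts < k + 1]
    if len(small):
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than k+1={k + 1} samples")

    x = _jittered(values, tie_seed)[:, None]
    radius = np.empty(n)
    for c in range(len(classes)):
        mask = class_idx == c
        tree = cKDTree(x[mask])
        dist, _ = tree.query(x[mask], k=k + 1)
        radius[mask] = dist[:, -1]
    full_tree = cKDTree(x)
    # strict "< radius": shrink the radius by one ulp before an inclusive query
    m = full_tree.query_ball_point(
        x, np.nextafter(radius, 0.0), return_length=True)
    mi = (
        digamma(n)
        - np.mean(digamma(class_counts[class_idx]))
        + digamma(k)
        - np.mean(digamma(np.maximum(m, 1)))
    )
    return max(0.0, float(mi))


def rank_by_mi(
    m: LogExpressionMatrix,
    design: pd.DataFrame,
    conditions,
    k: int = 3,
    tie_seed: int = 0,
    units: str = "nats",
) -> pd.DataFrame:
    """Rank every gene by MI between its expression and the condition label.

    Samples are restricted to the designated conditions.  Returns a frame
    with columns rank, gene_id, mi (in ``units``), n_samples, k_neighbors;
    ties break by gene_id ascending.
    """
    if units not in ("nats", "bits"):
        raise ValueError("units must be 'nats' or 'bits'")
    des = design_for_samples(design, m.sample_ids)
    sel = des["condition"].isin(set(conditions)).to_numpy()
    if not sel.any():
        raise ValueError(f"no samples with condition(s) {list(conditions)}")
    labels = des.loc[sel, "condition"].to_numpy()
    sub = m.values.to_numpy(dtype=float)[:, sel]
    mis = np.array([
        mi_mixed(sub[g], labels, k=k, tie_seed=tie_seed)
        for g in range(sub.shape[0])
    ])
    if units == "bits":
        mis = mis / np.log(2.0)
    out = pd.DataFrame({
        "gene_id": m.gene_ids,
        "mi": mis,
        "n_samples": int(sel.sum()),
        "k_neighbors": k,
    })
    out = out.sort_values(["mi", "gene_id"], ascending=[False, True],
                          kind="stable")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)
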