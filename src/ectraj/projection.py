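"""Projecting external expression data into a fitted component space.

An external matrix X' (normalized exactly like the training data) is aligned
to the training gene order, centred by the *training* gene means, and mapped
to component scores via X'V.  Each projected sample is then placed relative
to the two condition trajectories by comparing its score on the divergent
component with the final-timepoint condition means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LogExpressionMatrix
from .decomposition import PCADecomposition, TrajectorySet

__all__ = ["ProjectionResult", "project", "place_on_trajectory"]


@dataclass
class ProjectionResult:
    """Scores of external samples in the training component space.

    placement (filled by :func:`place_on_trajectory`): per sample, a signed
    proximity in [-1, 1] (+1 = at the first condition's trajectory terminus,
    -1 = at the second's) and the nearest-condition label.
    """

    sample_ids: pd.Index
    scores: pd.DataFrame  # samples x components ("PC1", ...)
    gene_coverage: float
    placement: pd.DataFrame | None = None


def project(
    d: PCADecomposition,
    external: LogExpressionMatrix,
    training_provenance: str | None = None,
    min_coverage: float = 0.8,
) -> ProjectionResult:
    """Map an external log-expression matrix into the fitted space via X'V.

    Genes absent from the external matrix contribute 0 after centring, i.e.
    they are assumed to sit at the training mean.  ``gene_coverage`` is the
    fraction of training genes present; below ``min_coverage`` it is an error.
    ``training_provenance``, when given, must match the external matrix's
    normalization provenance (same pseudocount and transform).
    """
    if training_provenance is not None and external.provenance:
        if not external.provenance.startswith(training_provenance.split(";")[0]):
            raise ValueError(
                "normalization provenance mismatch: training "
                f"{training_provenance!r} vs external {external.provenance!r}")
    shared = d.gene_ids.intersection(external.gene_ids)
    coverage = len(shared) / len(d.gene_ids)
    if coverage < min_coverage:
        raise ValueError(
            f"gene coverage {coverage:.3f} below required {min_coverage:.3f}")
    # samples x training-genes, missing genes at the training mean
    aligned = external.values.reindex(d.gene_ids).T
    centred = aligned.to_numpy(dtype=float) - d.gene_means.to_numpy()
    centred[:, ~d.gene_ids.isin(shared)] = 0.0
    scores = centred @ d.loadings
    comps = [f"PC{i + 1}" for i in range(d.n_components)]
    return ProjectionResult(
        sample_ids=external.sample_ids,
        scores=pd.DataFrame(scores, index=external.sample_ids, columns=comps),
        gene_coverage=coverage,
    )


def place_on_trajectory(
    p: ProjectionResult, t: TrajectorySet, conditions: tuple[str, str] | None = None
) -> ProjectionResult:
    """Place each projected sample between the two condition termini.

    proximity = (d_B - d_A) / (d_A + d_B) where d_A, d_B are the absolute
    differences between the sample's score on the trajectory component and
    each condition's final-timepoint mean score.  +1 means at condition A's
    terminus, -1 at condition B's; exact ties label "equidistant".
    ``conditions`` fixes the (A, B) order; default is the trajectory set's
    condition order.
    """
    termini = t.terminus_means()
    if len(termini) != 2:
        raise ValueError("trajectory set must cover exactly two conditions")
    if conditions is not None:
        missing = [c for c in conditions if c not in termini.index]
        if missing:
            raise ValueError(f"condition(s) {missing} not in trajectory set")
        termini = termini.loc[list(conditions)]
    cond_a, cond_b = termini.index[:2]
    sc = p.scores[f"PC{t.component}"].to_numpy()
    d_a = np.abs(sc - termini.iloc[0])
    d_b = np.abs(sc - termini.iloc[1])
    total = d_a + d_b
    with np.errstate(invalid="ignore", divide="ignore"):
        proximity = np.where(total > 0, (d_b - d_a) / np.where(total > 0, total, 1.0), 0.0)
    label = np.where(d_a < d_b, cond_a, np.where(d_b < d_a, cond_b, "equidistant"))
    p.placement = pd.DataFrame(
        {"component": t.component, "score": sc,
         "proximity": proximity, "nearest_condition": label},
        index=p.sample_ids,
    )
    return p
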