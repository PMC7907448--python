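"""Core in-memory containers shared across the pipeline.

Matrices are stored genes x samples (the on-disk orientation); analysis code
transposes to samples x genes where linear algebra requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample_id", "condition", "time_h", "replicate", "dataset")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifier(s): {dups}")


@dataclass
class CountsMatrix:
    """Raw gene-level counts, genes x samples, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        col_sums = values.sum(axis=0)
        if np.any(col_sums <= 0):
            bad = self.counts.columns[np.nonzero(col_sums <= 0)[0]].tolist()
            raise ValueError(f"sample(s) with zero total counts: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class LogExpressionMatrix:
    """log2(CPM + pseudocount) values, genes x samples, with provenance."""

    values: pd.DataFrame
    pseudocount: float
    provenance: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("log-expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def cpm(self) -> pd.DataFrame:
        """Invert the log transform back to CPM."""
        return 2.0 ** self.values - self.pseudocount


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample design table and coerce column types.

    Required columns: sample_id, condition, time_h, replicate, dataset.
    Returns a copy with time_h as float and sample_id as plain strings.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing required column(s): {missing}")
    out = design.loc[:, list(DESIGN_COLUMNS)].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    _check_unique(pd.Index(out["sample_id"]), "sample")
    try:
        out["time_h"] = out["time_h"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric time_h in design table: {exc}") from exc
    if (out["time_h"] < 0).any():
        raise ValueError("time_h must be non-negative")
    out = out.reset_index(drop=True)
    return out


def design_for_samples(design: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Subset a design table to given samples, in their order; error on absences."""
    design = validate_design(design)
    lookup = design.set_index("sample_id")
    missing = [s for s in sample_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"sample(s) missing from design table: {missing}")
    return lookup.loc[list(sample_ids)].reset_index()


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated time course.

    ``programs`` has one row per gene: program label, baseline mean count,
    NB dispersion, effect size (log2 units at the final timepoint) and the
    gene's direction (+1 favoured by the first condition, -1 by the second;
    0 for non-divergent programs).  ``stimuli`` records, per generated
    stimulus dataset, the stimulus type and signed shift applied.
    """

    seed: int
    programs: pd.DataFrame
    config: dict
    child_seeds: dict = field(default_factory=dict)
    stimuli: dict = field(default_factory=dict)

    def genes_of(self, program: str) -> pd.Index:
        return self.programs.index[self.programs["program"] == program]
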