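"""Reading count matrices, design tables and biotype maps; CPM normalization.

On-disk conventions
-------------------
* Counts TSV: header row of sample ids, first column gene ids, integer cells.
* Counts MatrixMarket: a ``.mtx`` coordinate file plus sidecar label files
  ``<prefix>.genes.txt`` and ``<prefix>.samples.txt`` (one id per line);
  omitted cells are zeros.
* Design TSV: columns sample_id, condition, time_h, replicate, dataset.
* Biotypes: two-column TSV (gene_id, biotype) or a GENCODE-style GTF whose
  gene lines carry ``gene_id`` and ``gene_type`` attributes.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountsMatrix, LogExpressionMatrix, validate_design

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "read_biotypes",
    "cpm_log2",
    "split_by_biotype",
    "filter_low_expression",
]


def read_counts(path, format: str = "tsv") -> CountsMatrix:
    """Read a gene x sample counts matrix from TSV or MatrixMarket triplet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        bad = df.select_dtypes(exclude=[np.number]).columns.tolist()
        if bad:
            raise ValueError(f"non-numeric counts in column(s): {bad}")
        return CountsMatrix(df)
    if format == "mtx":
        prefix = path.with_suffix("")
        genes = Path(f"{prefix}.genes.txt").read_text().split()
        samples = Path(f"{prefix}.samples.txt").read_text().split()
        mat = scipy.io.mmread(path)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        df = pd.DataFrame(dense, index=pd.Index(genes, dtype=str),
                          columns=pd.Index(samples, dtype=str))
        return CountsMatrix(df)
    raise ValueError(f"unknown counts format {format!r} (use 'tsv' or 'mtx')")


def write_counts(m: CountsMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        m.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        prefix = path.with_suffix("")
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts.to_numpy()))
        Path(f"{prefix}.genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        Path(f"{prefix}.samples.txt").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def read_design(path) -> pd.DataFrame:
    """Read and validate a sample design TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, skipinitialspace=True)
    return validate_design(df)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_biotypes(path, format: str = "tsv") -> pd.Series:
    """Read a gene_id -> biotype map from a two-column TSV or a GTF.

    A gene listed with two distinct biotypes is an error; repeated identical
    assignments (e.g. GTF transcript lines echoing the gene line) collapse.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("biotype TSV needs two columns: gene_id, biotype")
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    elif format == "gtf":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                gid = attrs.get("gene_id")
                btype = attrs.get("gene_type") or attrs.get("gene_biotype")
                if gid is None or btype is None:
                    raise ValueError(
                        f"GTF gene line without gene_id/gene_type: {line[:80]!r}")
                pairs.append((gid, btype))
    else:
        raise ValueError(f"unknown biotype format {format!r} (use 'tsv' or 'gtf')")

    out: dict[str, str] = {}
    for gid, btype in pairs:
        if gid in out and out[gid] != btype:
            raise ValueError(
                f"gene {gid!r} mapped to conflicting biotypes "
                f"{out[gid]!r} and {btype!r}")
        out[gid] = btype
    series = pd.Series(out, name="biotype")
    series.index.name = "gene_id"
    return series


def cpm_log2(m: CountsMatrix, pseudocount: float = 1.0) -> LogExpressionMatrix:
    """Normalize counts to log2(CPM + pseudocount).

    CPM scales each sample's counts to a library of one million reads, so
    samples of different sequencing depth are comparable.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = m.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        bad = m.sample_ids[np.nonzero(lib <= 0)[0]].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = counts * (1e6 / lib)
    values = pd.DataFrame(np.log2(cpm + pseudocount),
                          index=m.gene_ids, columns=m.sample_ids)
    return LogExpressionMatrix(
        values, pseudocount=pseudocount,
        provenance=f"log2(CPM+{pseudocount:g})")


def split_by_biotype(
    m: LogExpressionMatrix,
    biotypes: pd.Series,
    pcg_labels=("protein_coding",),
    ncg_labels=None,
    unannotated: str = "error",
) -> tuple[LogExpressionMatrix, LogExpressionMatrix]:
    """Split into protein-coding (PCG) and non-coding (NCG) submatrices.

    ``ncg_labels=None`` means every annotated biotype not in ``pcg_labels``
    counts as non-coding.  ``unannotated`` is ``"error"`` (strict) or
    ``"drop"`` (drop those genes with a warning).
    """
    known = m.gene_ids.isin(biotypes.index)
    if not known.all():
        missing = m.gene_ids[~known].tolist()
        if unannotated == "error":
            raise ValueError(f"gene(s) without biotype annotation: {missing[:20]}")
        warnings.warn(f"dropping {len(missing)} unannotated gene(s)")
    annotated = m.gene_ids[known]
    btype = biotypes.loc[annotated]
    pcg_set = set(pcg_labels)
    is_pcg = btype.isin(pcg_set)
    if ncg_labels is None:
        is_ncg = ~is_pcg
    else:
        is_ncg = btype.isin(set(ncg_labels)) & ~is_pcg
        dropped = annotated[~is_pcg & ~is_ncg]
        if len(dropped):
            warnings.warn(
                f"{len(dropped)} gene(s) outside PCG/NCG label sets dropped")
    pcg = LogExpressionMatrix(m.values.loc[annotated[is_pcg]],
                              m.pseudocount, m.provenance + "; PCG subset")
    ncg = LogExpressionMatrix(m.values.loc[annotated[is_ncg]],
                              m.pseudocount, m.provenance + "; NCG subset")
    if ncg.values.shape[0] == 0:
        warnings.warn("NCG matrix is empty for the given label selection")
    return pcg, ncg


def filter_low_expression(
    m: LogExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> LogExpressionMatrix:
    """Keep genes with CPM >= min_cpm in at least min_fraction of samples.

    The CPM threshold is converted to a log2(CPM+pseudocount) threshold using
    the pseudocount recorded in the matrix provenance, so the rule is exact.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    threshold = np.log2(min_cpm + m.pseudocount)
    frac = (m.values.to_numpy() >= threshold).mean(axis=1)
    keep = m.gene_ids[frac >= min_fraction]
    if len(keep) == 0:
        warnings.warn("expression filter removed every gene")
    return LogExpressionMatrix(
        m.values.loc[keep], m.pseudocount,
        m.provenance + f"; filtered CPM>={min_cpm:g} in >={min_fraction:g}")
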