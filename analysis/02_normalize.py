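"""Normalize the simulated counts to log2 CPM and split by biotype.

Reads results/data/ written by 01_simulate.py; writes the filtered
protein-coding (PCG) and non-coding (NCG) log2-CPM matrices that the
decomposition step consumes, plus the pooled filtered matrix.
"""

from pathlib import Path

import ectraj as et

DATA = Path("results/data")
OUT = Path("results/normalized")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = et.read_counts(DATA / "timecourse.counts.tsv")
    biotypes = et.read_biotypes(DATA / "biotypes.tsv")
    logm = et.cpm_log2(counts, pseudocount=1.0)
    pcg, ncg = et.split_by_biotype(logm, biotypes)
    for name, m in (("all", logm), ("pcg", pcg), ("ncg", ncg)):
        filt = et.filter_low_expression(m, min_cpm=1.0, min_fraction=0.5)
        filt.values.to_csv(OUT / f"{name}.log2cpm.tsv", sep="\t",
                           index_label="gene_id")
        print(f"{name}: {m.values.shape[0]} genes -> "
              f"{filt.values.shape[0]} after CPM>=1 in >=50% of samples "
              f"({filt.provenance})")


if __name__ == "__main__":
    main()
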