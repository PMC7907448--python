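"""Project the stimulus datasets into the learned component space.

Each external dataset is normalized identically, centred by the training
gene means, mapped through the stored loadings (X'V), and placed between the
PS and OS trajectory termini on the divergent component.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ectraj as et

DATA = Path("results/data")
NORM = Path("results/normalized")
TRAJ = Path("results/trajectories")
OUT = Path("results/projection")


def load_decomposition(name: str) -> et.PCADecomposition:
    loadings = pd.read_csv(TRAJ / f"{name}.pca.loadings.tsv", sep="\t",
                           index_col=0)
    scores = pd.read_csv(TRAJ / f"{name}.pca.scores.tsv", sep="\t",
                         index_col=0)
    means = pd.read_csv(TRAJ / f"{name}.pca.gene_means.tsv", sep="\t",
                        index_col=0)["mean"]
    sigma = pd.read_csv(TRAJ / f"{name}.pca.singular_values.tsv", sep="\t",
                        index_col=0)["sigma"]
    return et.PCADecomposition(
        gene_ids=loadings.index, sample_ids=scores.index, gene_means=means,
        loadings=loadings.to_numpy(), scores=scores.to_numpy(),
        singular_values=sigma.to_numpy())


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    decomp = load_decomposition("all")
    design = et.read_design(DATA / "timecourse.design.tsv")
    curves = pd.read_csv(TRAJ / "all.trajectory.tsv", sep="\t")
    component = int(pd.read_csv(TRAJ / "all.eigengenes.tsv", sep="\t",
                                nrows=1)["component"].iloc[0])
    traj = et.trajectory_curves(decomp, design, component)

    for stim in ("atv_like", "tnfa_like", "hypoxia_like"):
        counts = et.read_counts(DATA / f"{stim}.counts.tsv")
        sdes = et.read_design(DATA / f"{stim}.design.tsv")
        slog = et.cpm_log2(counts, pseudocount=1.0)
        proj = et.project(decomp, slog, min_coverage=0.8)
        proj = et.place_on_trajectory(proj, traj, conditions=("PS", "OS"))
        out = proj.placement.join(sdes.set_index("sample_id")["condition"])
        out.to_csv(OUT / f"{stim}.placement.tsv", sep="\t",
                   index_label="sample_id")
        treated = out[out["condition"] != "CTRL"]
        labels = treated["nearest_condition"].value_counts().to_dict()
        print(f"{stim}: treated samples nearest {labels}, "
              f"median |proximity| {treated['proximity'].abs().median():.2f} "
              f"(coverage {proj.gene_coverage:.2f})")


if __name__ == "__main__":
    main()
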