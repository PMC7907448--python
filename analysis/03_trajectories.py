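"""Fit the mean-centred SVD and extract the divergence-carrying component.

For the pooled, protein-coding and non-coding matrices: fit the SVD, score
the leading components for time correlation, condition divergence and
spikiness, select the divergent component, rank its eigengenes, and write
trajectory curves.  Also draws the score-vs-time trajectory figure.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import ectraj as et

NORM = Path("results/normalized")
DATA = Path("results/data")
OUT = Path("results/trajectories")


def analyse(name: str, design: pd.DataFrame) -> None:
    vals = pd.read_csv(NORM / f"{name}.log2cpm.tsv", sep="\t", index_col=0)
    m = et.LogExpressionMatrix(vals, 1.0, "log2(CPM+1)")
    decomp = et.fit_pca(m)
    decomp.save(OUT / f"{name}.pca")
    diag = et.component_diagnostics(decomp, design, ("PS", "OS"))
    diag.table.to_csv(OUT / f"{name}.diagnostics.tsv", sep="\t", index=False)
    selected = et.select_divergent_component(diag, max_time_corr=0.8)
    ranking = et.rank_eigengenes(decomp, selected)
    ranking.to_csv(OUT / f"{name}.eigengenes.tsv", sep="\t", index=False)
    traj = et.trajectory_curves(decomp, design, selected)
    traj.curves.to_csv(OUT / f"{name}.trajectory.tsv", sep="\t", index=False)

    print(f"[{name}] divergent component: PC{selected} "
          f"(divergence {diag.table.set_index('component').loc[selected, 'divergence_score']:.2f}, "
          f"variance {decomp.variance_fractions[selected - 1]:.1%})")
    print(f"[{name}] top 5 eigengenes: "
          + ", ".join(ranking.head(5)["gene_id"]))

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (cond, rep), grp in traj.curves.groupby(["condition", "replicate"]):
        ax.plot(grp["time_h"], grp["score"], marker="o", ms=3,
                color="tab:blue" if cond == "PS" else "tab:red",
                alpha=0.7, label=f"{cond} {rep}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"PC{selected} score")
    ax.set_title(f"{name.upper()} divergence-carrying trajectory")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / f"{name}.trajectory.png", dpi=150)
    plt.close(fig)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = et.read_design(DATA / "timecourse.design.tsv")
    for name in ("all", "pcg", "ncg"):
        analyse(name, design)


if __name__ == "__main__":
    main()
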