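"""Simulate the flow time course and the three stimulus datasets.

Writes, under results/data/: the 2x10x2 PS/OS counts matrix, its design and
biotype tables, the planted ground truth, and one treated-vs-control counts
matrix per stimulus (statin-like, TNFa-like, hypoxia-like).
"""

import sys
from pathlib import Path

import ectraj as et

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, design, biotypes, truth = et.simulate_timecourse(seed=SEED)
    et.write_counts(counts, OUT / "timecourse.counts.tsv")
    design.to_csv(OUT / "timecourse.design.tsv", sep="\t", index=False)
    biotypes.to_csv(OUT / "biotypes.tsv", sep="\t", header=False)
    truth.programs.to_csv(OUT / "truth.programs.tsv", sep="\t")
    print(f"seed {SEED}: time course {counts.counts.shape[0]} genes x "
          f"{counts.counts.shape[1]} samples")
    print(truth.programs["program"].value_counts().to_string())
    print(f"spike timepoints: {truth.stimuli['spike_times']}")

    for stim in ("atv_like", "tnfa_like", "hypoxia_like"):
        sc, sdes = et.simulate_stimulus_dataset(truth, stim, seed=SEED)
        et.write_counts(sc, OUT / f"{stim}.counts.tsv")
        sdes.to_csv(OUT / f"{stim}.design.tsv", sep="\t", index=False)
        print(f"{stim}: {sc.counts.shape[1]} samples "
              f"({sdes['condition'].value_counts().to_dict()})")


if __name__ == "__main__":
    main()
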