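# ectraj — endothelial transcriptome trajectory analysis

Endothelial cells respond very differently to atheroprotective **pulsatile
shear (PS)** and atheroprone **oscillatory shear (OS)**: over a 24 h flow
time course their transcriptomes drift apart along what can be read as an
"aging" axis. `ectraj` implements the linear-decomposition pipeline for
analysing such time courses:

1. **Ingest / normalize** — gene-level counts (TSV or MatrixMarket) →
   log2(CPM + 1), split into protein-coding and non-coding matrices,
   low-expression filter.
2. **Decompose** — mean-centre the samples × genes matrix and take the SVD
   `X = U Σ Vᵀ`; columns of `V` are *eigengenes* (gene loadings), `U Σ` are
   per-sample component scores. Score-vs-time curves per condition and
   replicate are the *trajectories*; per-component diagnostics (variance
   fraction, time correlation, PS-vs-OS divergence, spikiness) identify the
   **divergence-carrying component**, whose eigengenes are ranked by
   |loading|.
3. **Project** — external datasets, normalized identically, map into the
   learned space via `X'V` (training-centred) and are placed between the PS
   and OS trajectory termini.
4. **Mutual information** — genes are ranked by a kNN mutual-information
   estimator for mixed discrete (condition) / continuous (expression) data.
5. **Screen** — candidate regulators must be sign-concordant across
   stimuli: PS/OS fold change agreeing with statin treatment and opposing
   TNFα.
6. **Simulate** — a negative-binomial generator plants a shared time drift,
   an intermittently bursting program, a condition-divergent program and
   background noise, with full ground truth, so every stage is testable
   offline.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated study (outputs under `results/`):

```bash
python analysis/01_simulate.py      # 2 conditions x 10 timepoints x 2 reps
python analysis/02_normalize.py
python analysis/03_trajectories.py
python analysis/04_project.py
python analysis/05_mi_rank.py
python analysis/06_screen.py
```

Output from a run with the default seed:

```
[all] divergent component: PC2 (divergence 9.06, variance 4.7%)
[all] top 5 eigengenes: G00471, G00447, G00463, G00421, G00491
...
atv_like: treated samples nearest {'PS': 3}, median |proximity| 0.11 (coverage 1.00)
tnfa_like: treated samples nearest {'OS': 3}, median |proximity| 0.54 (coverage 1.00)
hypoxia_like: treated samples nearest {'OS': 3}, median |proximity| 0.14 (coverage 1.00)
...
screen: 95/100 top-ranked genes pass; precision vs planted divergent program 1.00
co-expression G00471 vs G00447: Spearman rho = -0.75 (p = 2.37e-08, n = 40)
```

Reading this: the selector picked PC2 as the axis separating PS from OS
(the dominant PC1 is the shared time drift); the top eigengenes are all
planted divergent genes (`G004xx`); statin-like samples project to the PS
side and TNFα-like to the OS side, while hypoxia-like samples stay near the
middle; and the cross-stimulus sign screen keeps almost exclusively planted
divergent genes.

Library use in a few lines:

```python
import ectraj as et

counts, design, biotypes, truth = et.simulate_timecourse(seed=0)
m = et.filter_low_expression(et.cpm_log2(counts))
d = et.fit_pca(m)
diag = et.component_diagnostics(d, design, ("PS", "OS"))
pc = et.select_divergent_component(diag)      # or pass an index explicitly
ranking = et.rank_eigengenes(d, pc)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — simulation,
normalization, decomposition, component selection, eigengene and MI
ranking, projection/placement of the three stimulus datasets, and the
concordance screen — and writes its JSON report to `--out`.
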