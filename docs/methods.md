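# Methods

## Problem and model

Endothelial cells (ECs) under atheroprotective pulsatile shear (PS) and
atheroprone oscillatory shear (OS) follow diverging transcriptional
trajectories over a 24 h time course. This package models that divergence
with a linear decomposition of the expression time course and uses the
learned axes to (i) rank the genes driving the divergence, (ii) place
external perturbation experiments relative to the two flow states, and
(iii) screen for candidate regulators whose responses are concordant across
independent stimuli.

### Normalization

Counts are scaled to counts per million (CPM) per sample and transformed to
`log2(CPM + c)` with pseudocount `c = 1` by default. The pseudocount is
recorded in the matrix provenance so that downstream steps (projection,
expression filtering) can verify that two matrices were normalized
identically. The default expression filter keeps genes with CPM ≥ 1 in at
least 50% of samples — standard bulk practice; the threshold is converted
exactly into log space via the recorded pseudocount. Gene-length (TPM)
normalization and batch correction are out of scope.

### Decomposition

The analysis matrix is samples × genes. Each gene is centred by its mean
across all samples (both conditions jointly), and the thin SVD `X = U Σ Vᵀ`
is computed. Columns of `V` are orthonormal gene-loading vectors
("eigengenes"); `U Σ` are per-sample component scores. Because singular
vector signs are arbitrary, each component is flipped so its
largest-|loading| gene is positive: this is deterministic, independent of
sample order, and makes repeated fits bit-identical.

Per-component diagnostics over the two designated conditions:

* `variance_fraction` = σ²ₖ / Σσ² (sums to 1 across all components);
* `time_correlation` = Spearman correlation of scores with time, pooled
  over both conditions — identifies the shared time-drift axis;
* `divergence_score` = (1/T) Σₜ |mean_A(t) − mean_B(t)| / s, with `s` the
  pooled within-(condition, time) SD (n−1 per cell; with two replicates a
  cell contributes |difference|/√2). Zero if both the gap and `s` vanish,
  +∞ if only `s` does;
* `spike_score` = excess kurtosis of the score vector, floored at 0. It is
  reported as a diagnostic for intermittent programs (e.g. mitochondrial
  bursts) and never used for automated selection: burst fractions above
  ~20% of samples make a score distribution platykurtic, so kurtosis can
  only flag *rare* bursts.

The divergence-carrying component is the `divergence_score` argmax among
components whose |time correlation| ≤ 0.8 (default gate, excluding the
dominant drift axis); ties break to the smaller index. Divergence-carrying
components are traditionally picked by visual inspection of trajectory
plots; the quantitative selector reproduces that judgement on data with
this structure, and an explicit component index can always be passed
instead (needed when matching a ranking produced from a manually chosen
component). Diagnostics are reported for the first 8 components by
default, which carry the bulk of the variance in a 40-sample design.

Eigengene ranking sorts all genes by |loading| on the chosen component,
descending, ties broken by gene identifier.

### Projection and placement

An external matrix, normalized with the same pseudocount (checked via
provenance), is aligned to the training gene order, centred by the stored
*training* gene means — never its own — and mapped through `X'V`. Genes
missing from the external data enter as centred zeros (i.e. at the training
mean), which is unbiased under the centring model; the fraction of training
genes present is reported and must exceed 0.8 by default.

Each projected sample is placed between the two condition termini (the
final-timepoint mean scores) on the divergent component:
`proximity = (d_B − d_A)/(d_A + d_B) ∈ [−1, 1]`, +1 at condition A's
terminus; the nearest condition is the label, exact ties are
"equidistant". Note that training scores contain a noise component aligned
with the fitted axes that projected external samples lack, so projected
scores are systematically shrunk toward zero relative to training termini;
the placement *label* is unaffected, but |proximity| of genuinely shifted
samples sits well below 1.

### Mutual information

Gene-vs-condition dependence is estimated with the kNN estimator for one
continuous and one discrete variable: for each sample, the distance to its
k-th nearest neighbour among same-label samples defines a radius; `mᵢ`
counts samples of any label strictly inside it (self included), and

MI = ψ(n) − ⟨ψ(n_labelᵢ)⟩ + ψ(k) − ⟨ψ(mᵢ)⟩  (nats, clamped at 0).

Defaults: k = 3; all samples of the two conditions enter (the endpoint-only
variant is a caller choice). log2 CPM data contain exact ties (zeros), so a
deterministic jitter of 1e-10 of the value range is added, assigned in
value-sorted order — this makes the estimate exactly invariant under
permutations of sample order while keeping tie-breaking reproducible via a
seed argument. Clamping at zero introduces a small positive bias under
independence (≤ 0.01 nats at n = 2000), the price of a sign-safe report.

### Concordance screen

"Association" between contrasts is operationalized as strict sign
concordance of per-gene mean log2 fold changes: a top-ranked gene passes if
sign(PS/OS) = sign(ATV/control) and sign(PS/OS) = −sign(TNFα/control); any
zero fold change fails. The PS/OS contrast defaults to the 24 h endpoint
samples; a per-timepoint mode supports fold-change-vs-time curves. The
screen is a deterministic filter, not a hypothesis test, so no
multiple-testing machinery is attached; single-pair co-expression
(Spearman by default) reports its unadjusted p-value.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* the analysis assumes: 2 conditions
× 10 timepoints (0–24 h, the study's grid) × 2 replicates of NB counts with
four planted programs — a shared monotone drift (300 genes, slope ~ U(1, 2)
log2 over the course), an intermittent program bursting at 2 shared
timepoints (100 genes, amplitude ~ U(1, 2)), a condition-divergent program
(100 genes, ±δ·t/24 with δ ~ U(1, 2) and opposite signs per condition), and
NB background. Dispersions ~ U(0.05, 0.3) and log-normal library sizes
around 10⁷ are standard bulk RNA-seq magnitudes. Biotypes cycle through
coding and non-coding labels so every program spans both classes. Planted
program genes draw abundances from the upper half of the log-normal
abundance law: a "regulated" gene with near-zero counts would carry no
observable signal, and real flow-responsive genes are expressed.

Stimulus datasets are single-timepoint treated/control designs (3 + 3):
statin-like shifts every divergent gene 1.0 log2 toward its PS direction,
TNFα-like toward OS, and hypoxia-like leaves the divergent program alone,
perturbing 100 random background genes instead. All randomness derives from
one master seed through fixed per-stage child seeds, so outputs are
bit-identical across regenerations.

The generator does **not** emulate gene–gene correlation beyond the planted
programs, batch effects, library-preparation biases, or read-level noise.
A green recovery test therefore establishes that the pipeline identifies
planted structure under realistic count noise — not that it would rank any
particular real gene at any particular position.

## Numerical choices

* SVD reconstruction and orthonormality are exact to 1e-8 on 40 × 5000
  matrices (thin LAPACK SVD).
* The trailing null-space component of a rank-deficient centred matrix is
  numerically arbitrary; comparisons and diagnostics are meaningful only
  for components with non-negligible singular values.
* With two replicates per (condition, time) cell, NB sampling noise leaves
  a small tail (~2%) of planted divergent genes below the background's 95th
  endpoint-fold-change percentile; separability checks use a 95% criterion.
* Degenerate cases: constant genes get MI 0 and rank last; zero-distance
  trajectory termini give proximity 0 / "equidistant"; an empty
  non-coding split is valid but warned about.

## Known limitations

* The divergence selector assumes exactly two conditions and replicated
  timepoints; unreplicated designs make the pooled within-cell SD, and so
  the divergence score, undefined.
* Projection assumes the external data share the training normalization;
  no cross-platform harmonization is attempted.
* MI significance is not assessed; the ranking is descriptive.
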