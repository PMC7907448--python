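"""Negative-binomial simulator for flow time-course and stimulus datasets.

The generator plants four gene programs on top of log-normal baselines:

* ``time_drift`` — a monotone log2 drift shared by both conditions (the
  dominant time axis a PCA should place on its first component);
* ``mito_spike`` — an intermittent program active at a shared sparse subset
  of timepoints in both conditions (spiky scores, high kurtosis);
* ``divergent`` — genes drifting in *opposite* directions in the two flow
  conditions, so the between-condition gap grows linearly with time;
* ``background`` — pure negative-binomial noise.

Counts are drawn NB(mean = library_size * abundance_g * 2^signal, gene-wise
dispersion), with log-normal library sizes so CPM normalization is exercised
nontrivially.  Companion single-timepoint "stimulus" datasets shift the
divergent program coherently (statin-like toward the first condition,
TNFa-like toward the second, hypoxia-like not at all), emulating external
experiments projected into the learned space.

All randomness flows from one master seed through fixed per-stage child
seeds, recorded in the returned :class:`~ectraj.containers.SyntheticTruth`,
so regeneration from (config, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountsMatrix, SyntheticTruth, validate_design

__all__ = ["SimConfig", "simulate_timecourse", "simulate_stimulus_dataset"]

# cycle of GENCODE-style biotypes, applied by gene index so every planted
# program spans both coding and non-coding genes
_BIOTYPE_CYCLE = (
    "protein_coding", "protein_coding", "protein_coding", "protein_coding",
    "protein_coding", "protein_coding", "lincRNA", "lincRNA", "antisense",
    "processed_transcript",
)

_STIMULI = {"atv_like": +1.0, "tnfa_like": -1.0, "hypoxia_like": 0.0}


@dataclass
class SimConfig:
    """Stated world for the simulator; defaults mirror the study design."""

    n_genes: int = 5000
    n_time_drift: int = 300
    n_mito_spike: int = 100
    n_divergent: int = 100
    timepoints: tuple = (0, 1, 2, 3, 4, 6, 9, 12, 16, 24)
    replicates: int = 2
    conditions: tuple = ("PS", "OS")
    mean_library_size: float = 1e7
    library_sdlog: float = 0.2
    abundance_sdlog: float = 1.5
    dispersion_range: tuple = (0.05, 0.3)
    drift_range: tuple = (1.0, 2.0)          # log2 units at t_max
    spike_amplitude_range: tuple = (1.0, 2.0)
    n_spike_timepoints: int = 2
    divergent_range: tuple = (1.0, 2.0)      # log2 units at t_max, per condition
    # stimulus datasets
    stimulus_shift: float = 1.0              # log2 shift of divergent genes
    stimulus_n_treated: int = 3
    stimulus_n_control: int = 3
    stimulus_time_h: float = 24.0
    hypoxia_n_perturbed: int = 100
    hypoxia_perturb_range: tuple = (0.5, 1.5)

    def validate(self) -> None:
        planted = self.n_time_drift + self.n_mito_spike + self.n_divergent
        if planted > self.n_genes:
            raise ValueError(
                f"program fractions exceed gene count ({planted} > {self.n_genes})")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _nb_sample(rng, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB draw parameterized by mean and dispersion alpha (var = mu + alpha mu^2)."""
    size = 1.0 / np.asarray(dispersion)
    mean = np.asarray(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _gene_table(config: SimConfig, seed: int) -> pd.DataFrame:
    """Assign programs, baselines, dispersions and effect sizes to genes."""
    rng = _rng(seed, 1)
    n = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    program = np.array(["background"] * n, dtype=object)
    a = config.n_time_drift
    b = a + config.n_mito_spike
    c = b + config.n_divergent
    program[:a] = "time_drift"
    program[a:b] = "mito_spike"
    program[b:c] = "divergent"
    abundance = rng.lognormal(0.0, config.abundance_sdlog, n)
    # planted-program genes must be expressed for their signal to be
    # observable: draw them from the upper half of the abundance law
    planted = np.arange(c)
    u = rng.uniform(0.5, 1.0, len(planted))
    abundance[planted] = np.exp(
        config.abundance_sdlog * scipy.stats.norm.ppf(u))
    abundance /= abundance.sum()
    dispersion = rng.uniform(*config.dispersion_range, n)
    effect = np.zeros(n)
    effect[:a] = rng.uniform(*config.drift_range, a)
    effect[a:b] = rng.uniform(*config.spike_amplitude_range, b - a)
    effect[b:c] = rng.uniform(*config.divergent_range, c - b)
    direction = np.zeros(n)
    direction[b:c] = rng.choice([-1.0, 1.0], c - b)
    biotype = np.array(
        [_BIOTYPE_CYCLE[i % len(_BIOTYPE_CYCLE)] for i in range(n)], dtype=object)
    return pd.DataFrame(
        {"program": program, "abundance": abundance, "dispersion": dispersion,
         "effect": effect, "direction": direction, "biotype": biotype},
        index=gene_ids)


def _signal_matrix(programs: pd.DataFrame, config: SimConfig, condition: str,
                   time_h: float, spike_times: set) -> np.ndarray:
    """Per-gene log2 signal for one (condition, timepoint)."""
    t_max = max(config.timepoints)
    frac = time_h / t_max if t_max > 0 else 0.0
    sig = np.zeros(len(programs))
    prog = programs["program"].to_numpy()
    eff = programs["effect"].to_numpy()
    sig[prog == "time_drift"] = eff[prog == "time_drift"] * frac
    if time_h in spike_times:
        sig[prog == "mito_spike"] = eff[prog == "mito_spike"]
    # first condition drifts along +direction, second along -direction
    cond_sign = +1.0 if condition == config.conditions[0] else -1.0
    div = prog == "divergent"
    sig[div] = cond_sign * programs["direction"].to_numpy()[div] * eff[div] * frac
    return sig


def simulate_timecourse(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[CountsMatrix, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Simulate the two-condition flow time course.

    Returns (counts, design, biotypes, truth) with the study layout by
    default: 2 conditions x 10 timepoints x 2 replicates = 40 samples.
    """
    config = config or SimConfig()
    config.validate()
    programs = _gene_table(config, seed)
    rng_spike = _rng(seed, 2)
    nonzero_times = [t for t in config.timepoints if t > 0]
    spike_times = set(rng_spike.choice(
        nonzero_times, size=min(config.n_spike_timepoints, len(nonzero_times)),
        replace=False).tolist())
    rng_counts = _rng(seed, 3)

    columns, records = [], []
    counts_cols = []
    abundance = programs["abundance"].to_numpy()
    dispersion = programs["dispersion"].to_numpy()
    for condition in config.conditions:
        for rep in range(1, config.replicates + 1):
            for t in config.timepoints:
                lib = rng_counts.lognormal(
                    np.log(config.mean_library_size), config.library_sdlog)
                sig = _signal_matrix(programs, config, condition, t, spike_times)
                mu = lib * abundance * 2.0**sig
                counts_cols.append(
                    _nb_sample(rng_counts, mu, dispersion))
                sid = f"{condition}_t{t:02g}_r{rep}"
                columns.append(sid)
                records.append(
                    {"sample_id": sid, "condition": condition, "time_h": float(t),
                     "replicate": f"r{rep}", "dataset": "timecourse"})
    counts = CountsMatrix(pd.DataFrame(
        np.column_stack(counts_cols), index=programs.index,
        columns=pd.Index(columns, name="sample_id")))
    design = validate_design(pd.DataFrame.from_records(records))
    biotypes = programs["biotype"].rename("biotype")
    truth = SyntheticTruth(
        seed=seed,
        programs=programs,
        config=asdict(config),
        child_seeds={"gene_table": [seed, 1], "spike_times": [seed, 2],
                     "timecourse_counts": [seed, 3]},
        stimuli={"spike_times": sorted(spike_times)},
    )
    return counts, design, biotypes, truth


def simulate_stimulus_dataset(
    truth: SyntheticTruth,
    stimulus: str,
    seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Simulate one single-timepoint treated-vs-control external dataset.

    ``atv_like`` shifts every divergent gene by +shift in its first-condition
    direction, ``tnfa_like`` by -shift (second-condition direction), and
    ``hypoxia_like`` leaves the divergent program untouched, instead
    perturbing a random set of background genes in the treated samples.
    """
    if stimulus not in _STIMULI:
        raise ValueError(
            f"unknown stimulus {stimulus!r}; expected one of {sorted(_STIMULI)}")
    config = config or SimConfig(**truth.config)
    programs = truth.programs
    stage = 10 + sorted(_STIMULI).index(stimulus)
    rng = _rng(truth.seed, stage * 1000 + seed)

    sign = _STIMULI[stimulus]
    shift = np.zeros(len(programs))
    div = (programs["program"] == "divergent").to_numpy()
    shift[div] = sign * config.stimulus_shift * programs["direction"].to_numpy()[div]
    if stimulus == "hypoxia_like":
        bg_idx = np.flatnonzero((programs["program"] == "background").to_numpy())
        chosen = rng.choice(bg_idx, size=min(config.hypoxia_n_perturbed, len(bg_idx)),
                            replace=False)
        shift[chosen] = (
            rng.choice([-1.0, 1.0], len(chosen))
            * rng.uniform(*config.hypoxia_perturb_range, len(chosen)))

    abundance = programs["abundance"].to_numpy()
    dispersion = programs["dispersion"].to_numpy()
    treated_label = {"atv_like": "ATV", "tnfa_like": "TNFA",
                     "hypoxia_like": "HYPOXIA"}[stimulus]
    columns, records, counts_cols = [], [], []
    groups = ([treated_label] * config.stimulus_n_treated
              + ["CTRL"] * config.stimulus_n_control)
    for i, grp in enumerate(groups):
        lib = rng.lognormal(np.log(config.mean_library_size), config.library_sdlog)
        sig = shift if grp == treated_label else np.zeros_like(shift)
        mu = lib * abundance * 2.0**sig
        counts_cols.append(_nb_sample(rng, mu, dispersion))
        sid = f"{stimulus}_{grp}_{i + 1}"
        columns.append(sid)
        records.append({"sample_id": sid, "condition": grp,
                        "time_h": config.stimulus_time_h,
                        "replicate": f"s{i + 1}", "dataset": stimulus})
    counts = CountsMatrix(pd.DataFrame(
        np.column_stack(counts_cols), index=programs.index,
        columns=pd.Index(columns, name="sample_id")))
    design = validate_design(pd.DataFrame.from_records(records))
    truth.stimuli[stimulus] = {"shift": sign * config.stimulus_shift, "seed": seed}
    return counts, design
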