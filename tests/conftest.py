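"""Shared fixtures: tiny hand-built matrices and multi-seed pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ectraj as et


@pytest.fixture
def tiny_counts() -> et.CountsMatrix:
    return et.CountsMatrix(pd.DataFrame(
        [[10, 0], [0, 5], [1, 1]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["S1", "S2"],
    ))


@pytest.fixture
def small_design() -> pd.DataFrame:
    rows = []
    for cond in ("PS", "OS"):
        for rep in ("r1", "r2"):
            for t in (0.0, 12.0, 24.0):
                rows.append({
                    "sample_id": f"{cond}_{t:g}_{rep}", "condition": cond,
                    "time_h": t, "replicate": rep, "dataset": "toy"})
    return pd.DataFrame(rows)


def run_pipeline(seed: int, config: et.SimConfig | None = None) -> dict:
    """One full synthetic run: simulate, normalize, fit, select, rank,
    project the three stimulus datasets, and screen candidates."""
    config = config or et.SimConfig()
    counts, design, biotypes, truth = et.simulate_timecourse(config, seed=seed)
    logm = et.cpm_log2(counts)
    filt = et.filter_low_expression(logm)
    decomp = et.fit_pca(filt)
    diag = et.component_diagnostics(decomp, design, ("PS", "OS"))
    selected = et.select_divergent_component(diag)

    # ground-truth component: the one carrying most squared loading mass on
    # the planted divergent genes
    planted = truth.genes_of("divergent").intersection(decomp.gene_ids)
    mask = decomp.gene_ids.isin(planted)
    mass = (decomp.loadings[mask] ** 2).sum(axis=0)
    truth_component = int(np.argmax(mass[: diag.table.shape[0]])) + 1

    ranking = et.rank_eigengenes(decomp, selected)
    top_planted_frac = (
        ranking.head(len(planted))["gene_id"].isin(planted).mean()
        if len(planted) else np.nan)
    traj = et.trajectory_curves(decomp, design, selected)

    placements = {}
    stim_designs = {}
    stim_fcs = {}
    for stim, treated in (("atv_like", "ATV"), ("tnfa_like", "TNFA"),
                          ("hypoxia_like", "HYPOXIA")):
        sc, sdes = et.simulate_stimulus_dataset(truth, stim, seed=seed)
        slog = et.cpm_log2(sc)
        proj = et.project(decomp, slog, training_provenance=logm.provenance)
        proj = et.place_on_trajectory(proj, traj, conditions=("PS", "OS"))
        treated_ids = sdes.loc[sdes["condition"] == treated, "sample_id"]
        placements[stim] = proj.placement.loc[treated_ids]
        stim_designs[stim] = sdes
        if stim != "hypoxia_like":
            stim_fcs[stim] = et.contrast_log2fc(
                slog, sdes, treated, "CTRL", label=f"{treated}/CTRL")

    fc_ps_os = et.contrast_log2fc(filt, design, "PS", "OS",
                                  timepoint_policy="endpoint", label="PS/OS")
    screen = et.concordance_screen(
        ranking, fc_ps_os, stim_fcs["atv_like"], stim_fcs["tnfa_like"],
        top_n=max(len(planted), 1))
    candidates = screen.loc[screen["pass_screen"], "gene_id"]
    precision = (
        candidates.isin(planted).mean() if len(candidates) else np.nan)

    return {
        "seed": seed,
        "truth": truth,
        "design": design,
        "filtered": filt,
        "decomp": decomp,
        "diagnostics": diag,
        "selected": selected,
        "truth_component": truth_component,
        "ranking": ranking,
        "top_planted_frac": float(top_planted_frac),
        "trajectories": traj,
        "placements": placements,
        "screen": screen,
        "screen_precision": float(precision) if precision == precision else np.nan,
    }


@pytest.fixture(scope="session")
def multi_seed_runs() -> list[dict]:
    """Twenty independent default-configuration pipeline runs."""
    return [run_pipeline(seed) for seed in range(20)]
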