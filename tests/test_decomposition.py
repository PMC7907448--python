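"""SVD correctness, trajectories, diagnostics and eigengene ranking."""

import numpy as np
import pandas as pd
import pytest

import ectraj as et
from ectraj.decomposition import ComponentDiagnostics


def make_log_matrix(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return et.LogExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), 1.0,
        "log2(CPM+1)")


class TestCenter:
    def test_two_sample_gene(self):
        m = make_log_matrix([[1.0, 3.0]])
        centered, means = et.center(m)
        assert centered.T[0] == pytest.approx([-1.0, 1.0])
        assert means["G0"] == 2.0

    def test_constant_gene_zeroed(self):
        m = make_log_matrix([[5.0, 5.0, 5.0]])
        centered, _ = et.center(m)
        assert np.all(centered == 0)

    def test_random_matrix_means_vanish(self):
        rng = np.random.default_rng(0)
        m = make_log_matrix(rng.normal(size=(5, 4)))
        centered, _ = et.center(m)
        assert np.all(np.abs(centered.mean(axis=0)) < 1e-12)

    def test_single_sample_error(self):
        with pytest.raises(ValueError, match="2 samples"):
            et.center(make_log_matrix([[1.0]]))


class TestSvdPca:
    def test_orthogonal_2x2(self):
        m = make_log_matrix(np.array([[1.0, 0.0], [0.0, -1.0]]))
        centered = m.values.to_numpy().T  # use uncentred values directly
        d = et.svd_pca(centered, m.gene_ids, m.sample_ids,
                       pd.Series(0.0, index=m.gene_ids))
        assert d.singular_values == pytest.approx([1.0, 1.0])
        recon = d.scores @ d.loadings.T
        assert np.abs(recon - centered).max() < 1e-12

    def test_rank_one(self):
        u = np.array([1.0, 2.0, -1.0])
        v = np.array([0.5, -0.25, 1.0, 2.0])
        centered = np.outer(u, v)
        d = et.svd_pca(centered, [f"G{i}" for i in range(4)],
                       [f"S{i}" for i in range(3)],
                       pd.Series(0.0, index=[f"G{i}" for i in range(4)]))
        assert d.singular_values[1] < 1e-10

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(1)
        m = make_log_matrix(rng.normal(size=(500, 40)))
        centered, means = et.center(m)
        d = et.svd_pca(centered, m.gene_ids, m.sample_ids, means)
        recon = d.scores @ d.loadings.T
        assert np.abs(recon - centered).max() < 1e-8
        gram = d.loadings.T @ d.loadings
        assert np.abs(gram - np.eye(d.n_components)).max() < 1e-8
        assert d.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(d.singular_values) <= 1e-12)

    def test_nonfinite_rejected(self):
        bad = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            et.svd_pca(bad, ["G0", "G1"], ["S0", "S1"],
                       pd.Series(0.0, index=["G0", "G1"]))

    def test_sign_stability_and_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        m = make_log_matrix(rng.normal(size=(30, 12)))
        d1 = et.fit_pca(m)
        d2 = et.fit_pca(m)
        assert np.array_equal(d1.loadings, d2.loadings)
        perm = rng.permutation(12)
        mp = make_log_matrix(m.values.to_numpy()[:, perm],
                             sample_ids=[m.sample_ids[j] for j in perm])
        dp = et.fit_pca(mp)
        # compare only non-degenerate components (the trailing null-space
        # direction of a rank-deficient centred matrix is arbitrary)
        keep = d1.singular_values > 1e-10 * d1.singular_values[0]
        assert np.allclose(dp.loadings[:, keep], d1.loadings[:, keep], atol=1e-9)
        assert np.allclose(dp.singular_values, d1.singular_values)
        # scores permute with the samples
        assert np.allclose(dp.scores[:, keep], d1.scores[perm][:, keep], atol=1e-9)

    def test_save_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        d = et.fit_pca(make_log_matrix(rng.normal(size=(20, 6))))
        d.save(tmp_path / "pca")
        loadings = pd.read_csv(tmp_path / "pca.loadings.tsv", sep="\t",
                               index_col=0)
        assert np.allclose(loadings.to_numpy(), d.loadings)


class TestTrajectories:
    def test_shapes_and_flat_curves(self, small_design):
        # constant scores over time: flat curves
        design = small_design
        vals = np.ones((5, len(design)))
        rng = np.random.default_rng(0)
        vals += rng.normal(size=vals.shape) * 1e-3
        m = make_log_matrix(vals, sample_ids=list(design["sample_id"]))
        d = et.fit_pca(m)
        t = et.trajectory_curves(d, design, 1)
        assert len(t.curves) == len(design)
        assert set(map(tuple, t.curves[["condition", "replicate"]]
                       .drop_duplicates().to_numpy())) == {
            ("PS", "r1"), ("PS", "r2"), ("OS", "r1"), ("OS", "r2")}
        for _, grp in t.curves.groupby(["condition", "replicate"]):
            assert grp["time_h"].is_monotonic_increasing

    def test_missing_sample_error(self, small_design):
        design = small_design.iloc[:-1]
        vals = np.random.default_rng(0).normal(size=(5, len(small_design)))
        m = make_log_matrix(vals, sample_ids=list(small_design["sample_id"]))
        d = et.fit_pca(m)
        with pytest.raises(ValueError, match=small_design["sample_id"].iloc[-1]):
            et.trajectory_curves(d, design, 1)

    def test_divergent_gap_grows_with_time(self, multi_seed_runs):
        run = multi_seed_runs[0]
        t = run["trajectories"]
        gap = (t.condition_means.loc["PS"] - t.condition_means.loc["OS"]).abs()
        # endpoint gap dominates the early gaps on the divergent component
        assert gap.iloc[-1] > gap.iloc[0]
        assert gap.iloc[-1] == gap.max()


class TestDiagnostics:
    def test_score_equal_time_correlation_one(self, small_design):
        # scores exactly equal to time: Spearman correlation is 1
        design = small_design
        n = len(design)
        genes = [f"G{i}" for i in range(3)]
        d = et.PCADecomposition(
            gene_ids=pd.Index(genes),
            sample_ids=pd.Index(design["sample_id"]),
            gene_means=pd.Series(0.0, index=genes),
            loadings=np.eye(3), scores=np.column_stack([
                design["time_h"].to_numpy(),
                np.zeros(n), np.zeros(n)]),
            singular_values=np.array([3.0, 2.0, 1.0]))
        diag = et.component_diagnostics(d, design, ("PS", "OS"))
        assert diag.table.loc[0, "time_correlation"] == pytest.approx(1.0)

    def test_identical_conditions_low_divergence(self):
        # both "conditions" drawn from one distribution: near-null divergence
        scores = []
        for seed in range(20):
            cfg = et.SimConfig(n_genes=400, n_time_drift=40, n_mito_spike=20,
                               n_divergent=20, divergent_range=(0.0, 0.0))
            run = _run_null(cfg, seed)
            scores.append(run["divergence"])
        assert np.mean(scores) <= 2.0  # pure-noise divergence stays small

    def test_wrong_condition_count(self, multi_seed_runs):
        run = multi_seed_runs[0]
        with pytest.raises(ValueError, match="two distinct"):
            et.component_diagnostics(run["decomp"], run["design"], ("PS", "PS"))

    def test_variance_fractions_sum_to_one(self, multi_seed_runs):
        d = multi_seed_runs[0]["decomp"]
        assert d.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)


def _run_null(cfg, seed):
    counts, design, _, truth = et.simulate_timecourse(cfg, seed=seed)
    logm = et.cpm_log2(counts)
    d = et.fit_pca(et.filter_low_expression(logm))
    diag = et.component_diagnostics(d, design, ("PS", "OS"))
    sel = et.select_divergent_component(diag)
    div = diag.table.set_index("component").loc[sel, "divergence_score"]
    return {"design": design, "decomp": d, "diag": diag, "selected": sel,
            "divergence": float(div)}


class TestSelectDivergentComponent:
    def test_direct_argmax_with_gate(self):
        table = pd.DataFrame({
            "component": [1, 2, 3],
            "variance_fraction": [0.5, 0.3, 0.2],
            "time_correlation": [0.2, 0.1, 0.9],
            "divergence_score": [0.1, 2.0, 0.3],
            "spike_score": [0.0, 0.0, 0.0]})
        diag = ComponentDiagnostics(table, ("PS", "OS"))
        assert et.select_divergent_component(diag, max_time_corr=0.8) == 2

    def test_all_fail_gate(self):
        table = pd.DataFrame({
            "component": [1], "variance_fraction": [1.0],
            "time_correlation": [0.95], "divergence_score": [3.0],
            "spike_score": [0.0]})
        diag = ComponentDiagnostics(table, ("PS", "OS"))
        with pytest.raises(ValueError, match="max_time_corr"):
            et.select_divergent_component(diag, max_time_corr=0.8)

    def test_tie_breaks_to_smaller_index(self):
        table = pd.DataFrame({
            "component": [1, 2], "variance_fraction": [0.5, 0.5],
            "time_correlation": [0.0, 0.0],
            "divergence_score": [2.0, 2.0], "spike_score": [0.0, 0.0]})
        diag = ComponentDiagnostics(table, ("PS", "OS"))
        assert et.select_divergent_component(diag) == 1

    def test_null_calibration(self):
        """With exchangeable conditions the selected divergence is not
        significantly above its condition-label permutation distribution."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = et.SimConfig(n_genes=400, n_time_drift=40, n_mito_spike=20,
                               n_divergent=20, divergent_range=(0.0, 0.0))
            run = _run_null(cfg, seed)
            obs = _gated_max_divergence(run["decomp"], run["design"])
            rng = np.random.default_rng(seed + 1000)
            perms = []
            design = run["design"]
            for _ in range(49):
                permuted = design.copy()
                for _, idx in design.groupby("time_h").groups.items():
                    labels = permuted.loc[idx, "condition"].to_numpy()
                    permuted.loc[idx, "condition"] = rng.permutation(labels)
                perms.append(_gated_max_divergence(run["decomp"], permuted))
            p = (1 + sum(v >= obs for v in perms)) / (1 + len(perms))
            ok += p > 0.05
        assert ok >= 0.8 * n_seeds


def _gated_max_divergence(decomp, design, max_time_corr=0.8):
    diag = et.component_diagnostics(decomp, design, ("PS", "OS"))
    t = diag.table
    gated = t[np.abs(t["time_correlation"]) <= max_time_corr]
    return float(gated["divergence_score"].max())


class TestRankEigengenes:
    @staticmethod
    def _decomp_with_loadings(loadings, gene_ids):
        loadings = np.asarray(loadings, dtype=float)
        n_g, n_c = loadings.shape
        return et.PCADecomposition(
            gene_ids=pd.Index(gene_ids), sample_ids=pd.Index(["S1", "S2"]),
            gene_means=pd.Series(0.0, index=gene_ids),
            loadings=np.asarray(loadings, dtype=float),
            scores=np.zeros((2, n_c)), singular_values=np.ones(n_c))

    def test_descending_absolute(self):
        d = self._decomp_with_loadings([[0.9], [-0.95], [0.1]], ["A", "B", "C"])
        r = et.rank_eigengenes(d, 1)
        assert list(r["gene_id"]) == ["B", "A", "C"]
        assert list(r["rank"]) == [1, 2, 3]

    def test_tie_breaks_by_gene_id(self):
        d = self._decomp_with_loadings([[0.5], [-0.5]], ["Z", "A"])
        r = et.rank_eigengenes(d, 1)
        assert list(r["gene_id"]) == ["A", "Z"]
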