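"""Transition matrix assembly, random walks, fate, pseudotime, drivers."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from palatrix import trajectory
from palatrix.trajectory import (
    absorption_probabilities,
    diffusion_pseudotime,
    driver_genes,
    fate_probabilities,
    random_walks,
    stage_blocks,
    stage_profiles,
    stage_motif_enrichment,
    transition_matrix,
)


def random_absorbing_chain(n_states=30, n_absorbing=3, seed=0):
    rng = np.random.default_rng(seed)
    T = rng.random((n_states, n_states))
    T[:n_absorbing] = 0.0
    T[np.arange(n_absorbing), np.arange(n_absorbing)] = 1.0
    T = T / T.sum(axis=1, keepdims=True)
    return T


class TestGrowthRates:
    def test_uniform_expression_gives_unit_growth(self, small_filtered):
        ds, _, prog = small_filtered
        ds2 = ds.subset(np.ones(ds.n_cells, dtype=bool))
        ds2.rna.layers["lognorm"] = np.ones((ds.n_cells, ds.rna.n_vars))
        g = trajectory.growth_rates(ds2, prog.prolif_genes)
        assert np.allclose(g, 1.0)

    def test_monotone_in_proliferation_expression(self, small_filtered):
        ds, _, prog = small_filtered
        g1 = trajectory.growth_rates(ds, prog.prolif_genes)
        ds2 = ds.subset(np.ones(ds.n_cells, dtype=bool))
        layer = np.asarray(ds.rna.layers["lognorm"]).copy()
        idx = pd.Index(ds.rna.var_names).get_indexer(prog.prolif_genes)
        layer[0, idx] *= 2
        ds2.rna.layers["lognorm"] = layer
        g2 = trajectory.growth_rates(ds2, prog.prolif_genes)
        assert g2[0] > g1[0]

    def test_multipotent_cells_have_higher_growth(self, small_filtered):
        ds, _, prog = small_filtered
        g = trajectory.growth_rates(ds, prog.prolif_genes)
        br = ds.obs["branch"].to_numpy()
        assert g[br == -1].mean() > g[br >= 0].mean()

    def test_disjoint_gene_set_rejected(self, small_filtered):
        ds, _, _ = small_filtered
        with pytest.raises(ValueError):
            trajectory.growth_rates(ds, ["nope1", "nope2"])


class TestTransitionMatrix:
    def test_three_stage_toy_equals_hand_assembly(self):
        """Arithmetic oracle: rows are the normalized coupling rows and the
        last stage is its row-normalized symmetric kNN kernel."""
        blocks = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        g01 = np.array([[1.0, 1.0], [0.0, 2.0]])
        g12 = np.array([[3.0, 1.0], [1.0, 1.0]])
        knn = sp.csr_matrix(np.array([[0.0, 2.0], [1.0, 0.0]]))
        T = transition_matrix([g01, g12], knn, blocks).todense()
        expected = np.zeros((6, 6))
        expected[0, 2:4] = [0.5, 0.5]
        expected[1, 2:4] = [0.0, 1.0]
        expected[2, 4:6] = [0.75, 0.25]
        expected[3, 4:6] = [0.5, 0.5]
        expected[4, 4:6] = [0.0, 1.0]   # symmetrized kNN: max(2,1)=2 both ways
        expected[5, 4:6] = [1.0, 0.0]
        assert np.allclose(T, expected)

    def test_rows_sum_to_one_and_last_stage_support(self, small_filtered):
        from palatrix import preprocess
        from palatrix.transport import ot_coupling

        ds, _, prog = small_filtered
        emb = preprocess.reduce_dimensions(ds, d_rna=15, d_atac=10)
        g = trajectory.growth_rates(ds, prog.prolif_genes)
        blocks = stage_blocks(ds.obs["stage"])
        coup = [ot_coupling(emb.pcs[blocks[i]], emb.pcs[blocks[i + 1]],
                            g[blocks[i]])[0] for i in range(3)]
        knn = preprocess.knn_graph(emb.pcs[blocks[-1]], k=10)
        T = transition_matrix(coup, knn, blocks)
        assert np.allclose(np.asarray(T.sum(axis=1)).ravel(), 1.0, atol=1e-8)
        last = set(blocks[-1])
        rows, cols = T.nonzero()
        in_last = np.isin(rows, list(last))
        assert set(cols[in_last]) <= last

    def test_isolated_cell_gets_self_loop(self):
        blocks = [np.array([0]), np.array([1, 2])]
        gamma = np.array([[0.0, 0.0]])
        knn = sp.csr_matrix(np.zeros((2, 2)))
        with pytest.warns(UserWarning):
            T = transition_matrix([gamma], knn, blocks).todense()
        assert T[0, 0] == 1.0 and T[1, 1] == 1.0


class TestRandomWalks:
    def test_endpoint_fraction_matches_analytic(self):
        T = np.array([[1, 0, 0], [0, 1, 0], [0.3, 0.7, 0.0]])
        ends, _ = random_walks(T, [2], n_sims=10_000, n_steps=5, seed=0)
        frac = (ends == 0).mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_identity_matrix_keeps_endpoints_at_start(self):
        T = np.eye(4)
        ends, paths = random_walks(T, [1, 3], n_sims=50, n_steps=3, seed=1)
        assert set(ends) <= {1, 3}
        assert np.array_equal(paths[:, 0], paths[:, -1])

    def test_deterministic_per_seed(self):
        T = random_absorbing_chain()
        _, p1 = random_walks(T, [5], n_sims=100, n_steps=20, seed=9)
        _, p2 = random_walks(T, [5], n_sims=100, n_steps=20, seed=9)
        assert np.array_equal(p1, p2)

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            random_walks(np.eye(2), [0], n_steps=0)


class TestAbsorption:
    def test_one_step_chain_forced_probabilities(self):
        T = np.array([[1, 0, 0], [0, 1, 0], [0.3, 0.7, 0.0]])
        F = absorption_probabilities(T, [[0], [1]])
        assert np.allclose(F[2], [0.3, 0.7])

    def test_matches_monte_carlo_on_random_chain(self):
        """Random-walk oracle: absorption probabilities within 3 MC sd of
        100,000-walk endpoint frequencies on a 30-state chain."""
        T = random_absorbing_chain(seed=3)
        F = absorption_probabilities(T, [[0], [1], [2]])
        start = 17
        n_walk = 100_000
        ends, _ = random_walks(T, [start], n_sims=n_walk, n_steps=60, seed=0)
        for a in range(3):
            mc = (ends == a).mean()
            sd = np.sqrt(max(mc * (1 - mc), 1e-9) / n_walk)
            assert abs(F[start, a] - mc) <= 3 * sd + 1e-9

    def test_rows_sum_to_one_terminal_rows_indicators(self):
        T = random_absorbing_chain(seed=5)
        F = absorption_probabilities(T, [[0], [1], [2]])
        assert np.allclose(F.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(F[:3], np.eye(3))

    def test_unreachable_terminal_state_raises(self):
        T = np.eye(3)
        T[2, 2] = 1.0  # state 2 is its own sink, never reaches 0/1
        with pytest.raises(ValueError):
            absorption_probabilities(T, [[0], [1]])


class TestFateModel:
    def test_terminal_macrostates_match_planted_branches(self, small_filtered):
        from palatrix import preprocess
        from palatrix.transport import ot_coupling

        ds, _, prog = small_filtered
        emb = preprocess.reduce_dimensions(ds, d_rna=15, d_atac=10)
        g = trajectory.growth_rates(ds, prog.prolif_genes)
        blocks = stage_blocks(ds.obs["stage"])
        coup = [ot_coupling(emb.pcs[blocks[i]], emb.pcs[blocks[i + 1]],
                            g[blocks[i]])[0] for i in range(3)]
        knn = preprocess.knn_graph(emb.pcs[blocks[-1]], k=10)
        T = transition_matrix(coup, knn, blocks)
        fm = fate_probabilities(T, n_macrostates=4, seed=0)
        br = ds.obs["branch"].to_numpy()
        majorities = sorted(
            int(np.bincount(br[cells] + 1).argmax()) - 1
            for cells in fm.terminal_cells.values())
        assert majorities == [0, 1, 2]
        assert np.allclose(fm.F.sum(axis=1), 1.0, atol=1e-8)

    def test_no_terminal_state_raises(self):
        # a fast-mixing chain has no metastable terminal macrostate
        rng = np.random.default_rng(0)
        T = rng.random((60, 60)) + 1.0
        T /= T.sum(axis=1, keepdims=True)
        with pytest.raises(ValueError):
            fate_probabilities(T, n_macrostates=3, seed=0)


class TestPseudotime:
    def test_path_graph_monotone_from_root(self):
        """Chain-structure oracle: positions on a path graph order by tau."""
        n = 10
        A = sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1]).tocsr()
        tau = diffusion_pseudotime(None, root=0, n_dcs=8, graph=A)
        assert tau[0] == 0.0
        assert np.all(np.diff(tau) > 0)

    def test_disconnected_graph_raises(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 100.0)])
        with pytest.raises(ValueError, match="components"):
            diffusion_pseudotime(X, root=0, k=2)

    def test_tracks_latent_time_within_branches(self, small_filtered):
        from scipy.stats import spearmanr

        from palatrix import preprocess

        ds, _, prog = small_filtered
        emb = preprocess.reduce_dimensions(ds, d_rna=15, d_atac=10)
        g = trajectory.growth_rates(ds, prog.prolif_genes)
        tau = diffusion_pseudotime(emb.pcs, root=int(np.argmax(g)), k=15)
        br = ds.obs["branch"].to_numpy()
        s = ds.obs["s"].to_numpy()
        cors = [spearmanr(tau[br == b], s[br == b]).statistic
                for b in range(prog.config.n_branches)]
        assert min(cors) > 0.6
        assert np.mean(cors) > 0.8


class TestDrivers:
    def test_affine_function_of_fate_has_corr_one(self):
        rng = np.random.default_rng(0)
        fate = rng.random(100)
        expr = np.column_stack([3 * fate + 1, rng.random(100)])
        out = driver_genes(expr, ["aff", "noise"], fate)
        assert out.loc["aff", "corr"] == pytest.approx(1.0)
        assert out.loc["aff", "driver"]

    def test_small_correlation_not_driver_despite_significance(self):
        rng = np.random.default_rng(1)
        n = 20_000  # large n: tiny correlation is significant but not a driver
        fate = rng.random(n)
        gene = 0.04 * (fate - fate.mean()) / fate.std() + rng.normal(0, 1, n)
        out = driver_genes(gene[:, None], ["g"], fate)
        if out.loc["g", "padj"] < 0.05:
            assert abs(out.loc["g", "corr"]) < 0.05
        assert not out.loc["g", "driver"]

    def test_constant_gene_untested(self):
        fate = np.linspace(0, 1, 50)
        out = driver_genes(np.ones((50, 1)), ["c"], fate)
        assert not out.loc["c", "tested"]
        assert not out.loc["c", "driver"]


class TestStageProfiles:
    def _drivers(self, genes):
        return pd.DataFrame({"driver": [True] * len(genes)},
                            index=pd.Index(genes, name="gene"))

    def test_constructed_peaks_assigned_start_middle_end(self):
        n = 300
        tau = np.linspace(0, 1, n)
        fate = np.ones(n)

        def bump(center):
            return np.exp(-((tau - center) ** 2) / 0.02)

        expr = np.column_stack([bump(0.1), bump(0.5), bump(0.9)])
        groups, _ = stage_profiles(expr, ["early", "mid", "late"],
                                   self._drivers(["early", "mid", "late"]),
                                   tau, fate, quantile=0.0, seed=0)
        assert groups.loc["early", "stage_group"] == "start"
        assert groups.loc["mid", "stage_group"] == "middle"
        assert groups.loc["late", "stage_group"] == "end"

    def test_quantile_zero_extracts_all_cells(self):
        n = 60
        tau = np.linspace(0, 1, n)
        expr = np.column_stack([tau, 1 - tau, tau ** 2])
        groups, profiles = stage_profiles(expr, ["a", "b", "c"],
                                          self._drivers(["a", "b", "c"]),
                                          tau, np.random.default_rng(0).random(n),
                                          quantile=0.0, seed=0)
        assert len(profiles) == n

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        n = 100
        tau = np.linspace(0, 1, n)
        expr = rng.random((n, 6))
        d = self._drivers([f"g{i}" for i in range(6)])
        g1, _ = stage_profiles(expr, d.index, d, tau, np.ones(n), quantile=0.0,
                               seed=5)
        g2, _ = stage_profiles(expr, d.index, d, tau, np.ones(n), quantile=0.0,
                               seed=5)
        pd.testing.assert_frame_equal(g1, g2)

    def test_too_few_drivers_rejected(self):
        with pytest.raises(ValueError):
            stage_profiles(np.ones((10, 2)), ["a", "b"], self._drivers(["a"]),
                           np.linspace(0, 1, 10), np.ones(10))


class TestStageMotifEnrichment:
    def test_foreground_equals_background_fold_one(self):
        groups = pd.DataFrame({"stage_group": ["start", "start"]},
                              index=pd.Index(["g1", "g2"], name="gene"))
        links = pd.DataFrame({"gene": ["g1", "g2"], "peak": ["p1", "p2"]})
        rng = np.random.default_rng(0)
        hits = pd.DataFrame({"m": [True, False]},
                            index=pd.Index(["p1", "p2"]))
        out = stage_motif_enrichment(groups, links, hits)
        assert np.allclose(out["fold_change"], 1.0)

    def test_empty_driver_links_warn_and_empty(self):
        groups = pd.DataFrame({"stage_group": ["start"]},
                              index=pd.Index(["gX"], name="gene"))
        links = pd.DataFrame({"gene": ["other"], "peak": ["p1"]})
        hits = pd.DataFrame({"m": [True]}, index=pd.Index(["p1"]))
        with pytest.warns(UserWarning):
            out = stage_motif_enrichment(groups, links, hits)
        assert len(out) == 0


class TestStageProfilesQuantile:
    def test_quantile_cut_orders_by_peak_position(self):
        n = 200
        tau = np.linspace(0, 1, n)
        centers = [0.05, 0.1, 0.5, 0.55, 0.9, 0.95]
        expr = np.column_stack([np.exp(-((tau - c) ** 2) / 0.01)
                                for c in centers])
        names = [f"g{i}" for i in range(6)]
        drivers = pd.DataFrame({"driver": [True] * 6},
                               index=pd.Index(names, name="gene"))
        groups, _ = stage_profiles(expr, names, drivers, tau, np.ones(n),
                                   quantile=0.0, seed=0, method="quantile")
        assert list(groups["stage_group"]) == ["start", "start", "middle",
                                               "middle", "end", "end"]
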