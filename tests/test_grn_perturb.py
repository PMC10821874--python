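"""GRN inference (candidates, bagging ridge) and in silico knockout fields."""

import numpy as np
import pandas as pd
import pytest

from palatrix import perturb
from palatrix.grn import GRNModel, base_grn, fit_grn
from tests.conftest import toy_genes, toy_peaks
from palatrix.datatypes import GenomeAnnotation


def _features(n):
    return [f"g{i}" for i in range(n)]


def _grn(edge_rows, **kw):
    edges = pd.DataFrame(edge_rows, columns=["tf", "target", "coef", "p",
                                             "peak", "motif"])
    return GRNModel(edges={0: edges}, **kw)


class TestBaseGRN:
    def _annotation(self):
        genes = toy_genes([("gA", "chr1", "+", 1000, 1000, 2000),
                           ("gB", "chr1", "+", 9000, 9000, 10000)])
        peaks = toy_peaks([("chr1", 800, 1200),     # gA promoter
                           ("chr1", 5000, 5400),    # distal
                           ("chr1", 8800, 9200)])   # gB promoter
        return GenomeAnnotation(genes=genes, peaks=peaks,
                                contig_sizes={"chr1": 10 ** 6})

    def test_motif_in_linked_peak_creates_candidate(self):
        ann = self._annotation()
        links = pd.DataFrame({"gene": ["gB"], "peak": ["chr1:5000-5400"]})
        hits = pd.DataFrame({"M": [False, True, False]}, index=ann.peaks.index)
        cand = base_grn(links, hits, {"TFX": "M"}, ann)
        assert ("TFX", "gB") in set(zip(cand["tf"], cand["target"]))

    def test_promoter_peaks_always_eligible(self):
        ann = self._annotation()
        hits = pd.DataFrame({"M": [True, False, False]}, index=ann.peaks.index)
        cand = base_grn(None, hits, {"TFX": "M"}, ann)
        assert set(zip(cand["tf"], cand["target"])) == {("TFX", "gA")}

    def test_tf_without_hit_has_no_candidates(self):
        ann = self._annotation()
        hits = pd.DataFrame({"M": [False] * 3}, index=ann.peaks.index)
        cand = base_grn(None, hits, {"TFX": "M"}, ann)
        assert len(cand) == 0

    def test_coaccessibility_mode_threshold(self):
        ann = self._annotation()
        hits = pd.DataFrame({"M": [False, True, False]}, index=ann.peaks.index)
        coacc = pd.DataFrame({"peak1": ["chr1:5000-5400"],
                              "peak2": ["chr1:8800-9200"],
                              "coaccess": [0.9]})
        cand = base_grn(None, hits, {"TFX": "M"}, ann, coaccess=coacc)
        assert ("TFX", "gB") in set(zip(cand["tf"], cand["target"]))
        # an impossible threshold empties the coaccessibility contribution
        cand2 = base_grn(None, hits, {"TFX": "M"}, ann, coaccess=coacc,
                         coaccess_min=1.01)
        assert ("TFX", "gB") not in set(zip(cand2["tf"], cand2["target"]))

    def test_empty_motif_map_rejected(self):
        with pytest.raises(ValueError):
            base_grn(None, pd.DataFrame(), {}, self._annotation())


class TestFitGRN:
    def _setup(self, n=300, beta=2.0, seed=0):
        rng = np.random.default_rng(seed)
        tf = rng.normal(2, 1, n)
        target = beta * tf + rng.normal(0, 0.5, n)
        other = rng.normal(size=n)
        expr = np.column_stack([tf, target, other])
        cand = pd.DataFrame({"tf": ["g0"], "target": ["g1"],
                             "peak": ["p"], "motif": ["m"]})
        return expr, cand

    def test_planted_linear_edge_recovered(self):
        expr, cand = self._setup()
        grn = fit_grn(expr, _features(3), np.zeros(300, dtype=int), cand,
                      seed=0, min_cells=50)
        e = grn.edges[0]
        assert len(e) == 1
        assert e["coef"].iloc[0] > 0
        assert e["p"].iloc[0] < 1e-3

    def test_permuted_target_filtered_out(self):
        """Null simulation: shuffled targets survive the p<0.001 filter in
        at most a few percent of repeats."""
        rng = np.random.default_rng(1)
        kept = 0
        n_sim = 40
        for i in range(n_sim):
            expr, cand = self._setup(seed=100 + i)
            expr[:, 1] = rng.permutation(expr[:, 1])
            grn = fit_grn(expr, _features(3), np.zeros(300, dtype=int), cand,
                          seed=i, min_cells=50)
            kept += len(grn.edges[0])
        assert kept / n_sim <= 0.05

    def test_edge_cap_keeps_largest_coefficients(self):
        rng = np.random.default_rng(2)
        n = 200
        tfs = rng.normal(size=(n, 6))
        betas = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        targets = tfs * betas + rng.normal(0, 0.1, (n, 6))
        expr = np.column_stack([tfs, targets])
        feats = [f"tf{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
        cand = pd.DataFrame({"tf": [f"tf{i}" for i in range(6)],
                             "target": [f"t{i}" for i in range(6)],
                             "peak": "p", "motif": "m"})
        grn = fit_grn(expr, feats, np.zeros(n, dtype=int), cand, seed=0,
                      min_cells=50, max_edges=3)
        e = grn.edges[0]
        assert len(e) == 3
        assert set(e["target"]) == {"t0", "t1", "t2"}

    def test_p_threshold_monotone(self):
        expr, cand = self._setup(beta=0.4)
        strict = fit_grn(expr, _features(3), np.zeros(300, dtype=int), cand,
                         seed=0, p_threshold=1e-4, min_cells=50)
        loose = fit_grn(expr, _features(3), np.zeros(300, dtype=int), cand,
                        seed=0, p_threshold=1e-2, min_cells=50)
        kept_strict = set(zip(strict.edges[0]["tf"], strict.edges[0]["target"]))
        kept_loose = set(zip(loose.edges[0]["tf"], loose.edges[0]["target"]))
        assert kept_strict <= kept_loose

    def test_no_large_cluster_rejected(self):
        expr, cand = self._setup(n=300)
        with pytest.raises(ValueError):
            fit_grn(expr, _features(3), np.arange(300), cand, min_cells=50)


class TestKnockout:
    def test_tf_with_no_outgoing_edges_only_own_coordinate(self):
        grn = _grn([("g1", "g2", 1.0, 1e-5, "p", "m")])
        expr = np.array([[2.0, 1.0, 3.0], [1.0, 1.0, 1.0]])
        delta = perturb.simulate_knockout(grn, expr, _features(3),
                                          np.zeros(2, dtype=int), "g2")
        # g2 has no outgoing edges; only its own coordinate drops
        assert np.allclose(delta[:, 2], -expr[:, 2])
        assert np.allclose(delta[:, 1], 0)
        assert np.allclose(delta[:, 0], 0)

    def test_single_edge_one_step_linear_algebra(self):
        grn = _grn([("g0", "g1", 0.5, 1e-5, "p", "m")])
        expr = np.array([[4.0, 10.0], [2.0, 10.0]])
        delta = perturb.simulate_knockout(grn, expr, _features(2),
                                          np.zeros(2, dtype=int), "g0",
                                          n_propagation=1)
        assert np.allclose(delta[:, 0], -expr[:, 0])
        assert np.allclose(delta[:, 1], -0.5 * expr[:, 0])

    def test_first_order_linearity_in_coefficients(self):
        e1 = _grn([("g0", "g1", 0.3, 1e-5, "p", "m")])
        e2 = _grn([("g0", "g1", 0.6, 1e-5, "p", "m")])
        expr = np.abs(np.random.default_rng(0).normal(2, 0.5, (5, 2))) + 5
        d1 = perturb.simulate_knockout(e1, expr, _features(2),
                                       np.zeros(5, dtype=int), "g0",
                                       n_propagation=1)
        d2 = perturb.simulate_knockout(e2, expr, _features(2),
                                       np.zeros(5, dtype=int), "g0",
                                       n_propagation=1)
        assert np.allclose(d2[:, 1], 2 * d1[:, 1])

    def test_clipping_never_drops_expression_below_zero(self):
        grn = _grn([("g0", "g1", 5.0, 1e-5, "p", "m")])
        expr = np.array([[4.0, 1.0]])
        delta = perturb.simulate_knockout(grn, expr, _features(2),
                                          np.zeros(1, dtype=int), "g0")
        assert (expr + delta >= -1e-12).all()

    def test_absent_tf_zero_field_with_warning(self):
        grn = _grn([("g0", "g1", 1.0, 1e-5, "p", "m")])
        expr = np.ones((3, 3))
        with pytest.warns(UserWarning, match="absent"):
            delta = perturb.simulate_knockout(grn, expr, _features(3),
                                              np.zeros(3, dtype=int), "g2")
        assert not delta.any()

    def test_ko_gene_delta_never_positive(self):
        grn = _grn([("g0", "g1", -2.0, 1e-5, "p", "m"),
                    ("g1", "g0", -2.0, 1e-5, "p", "m")])
        expr = np.abs(np.random.default_rng(1).normal(3, 1, (10, 2)))
        delta = perturb.simulate_knockout(grn, expr, _features(2),
                                          np.zeros(10, dtype=int), "g0")
        assert (delta[:, 0] <= 1e-12).all()


class TestFields:
    def test_zero_delta_zero_shift(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(50, 2))
        expr = rng.normal(size=(50, 8))
        sh = perturb.embedding_shift(np.zeros_like(expr), expr, E,
                                     n_neighbors=10)
        assert np.allclose(sh, 0)

    def test_perfect_neighbor_match_limit(self):
        """Limit-case oracle: delta equal to one neighbor's expression offset
        with tiny sigma points the shift at that neighbor."""
        rng = np.random.default_rng(1)
        E = rng.normal(size=(30, 2))
        expr = rng.normal(size=(30, 20))
        i = 0
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=6).fit(E)
        _, idx = nn.kneighbors(E)
        j = idx[i, 1]
        delta = np.zeros_like(expr)
        delta[i] = expr[j] - expr[i]
        sh = perturb.embedding_shift(delta, expr, E, n_neighbors=5,
                                     sigma_corr=1e-4)
        offs = E[idx[i, 1:]] - E[i]
        expected = (E[j] - E[i]) - offs.mean(axis=0)
        assert np.allclose(sh[i], expected, atol=1e-6)

    def test_linear_tau_gradient_direction(self):
        rng = np.random.default_rng(2)
        E = rng.uniform(0, 10, size=(400, 2))
        tau = E[:, 0] / 10.0
        _, _, U, V, mask = perturb.developmental_flow(E, tau, n_grid=15)
        assert U[mask].mean() > 0
        assert abs(V[mask].mean()) < 0.2 * abs(U[mask].mean())

    def test_constant_tau_zero_flow(self):
        rng = np.random.default_rng(3)
        E = rng.uniform(0, 10, size=(200, 2))
        _, _, U, V, mask = perturb.developmental_flow(E, np.ones(200), n_grid=10)
        assert np.allclose(U[mask], 0, atol=1e-9)
        assert np.allclose(V[mask], 0, atol=1e-9)

    def test_score_algebra(self):
        rng = np.random.default_rng(4)
        U = rng.normal(size=(8, 8))
        V = rng.normal(size=(8, 8))
        mask = np.ones((8, 8), dtype=bool)
        # shift exactly opposite to flow: maximal reversal score
        assert perturb.perturbation_score((-U, -V), (U, V), mask) == \
            pytest.approx((U ** 2 + V ** 2).sum())
        # orthogonal shift: zero score
        assert perturb.perturbation_score((-V, U), (U, V), mask) == \
            pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            perturb.perturbation_score((U, V), (U, V), np.zeros((8, 8), bool))

    def test_empty_grn_gives_zero_scores(self):
        """Zero-GRN null: without edges the knockout field is identically
        zero and every lineage score vanishes."""
        grn = GRNModel(edges={0: pd.DataFrame(
            columns=["tf", "target", "coef", "p", "peak", "motif"])})
        rng = np.random.default_rng(5)
        expr = np.abs(rng.normal(2, 1, (60, 10)))
        E = rng.normal(size=(60, 2))
        with pytest.warns(UserWarning):
            delta = perturb.simulate_knockout(grn, expr, _features(10),
                                              np.zeros(60, dtype=int), "g0")
        sh = perturb.embedding_shift(delta, expr, E, n_neighbors=10)
        _, _, Us, Vs, _ = perturb.grid_vector_field(E, sh, n_grid=8)
        _, _, Uf, Vf, m = perturb.developmental_flow(E, rng.random(60), n_grid=8)
        assert perturb.perturbation_score((Us, Vs), (Uf, Vf), m) == 0.0
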