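"""Generator tests: determinism, planted structure, count model, round trips."""

import numpy as np
import pandas as pd
import pytest

from palatrix import io, qc
from palatrix.config import SimConfig
from palatrix.datatypes import decode_seq
from palatrix.synth import (
    build_regulatory_program,
    make_ground_truth,
    render_multiome_counts,
    simulate_cell_states,
    simulate_validation_assets,
)
from palatrix.synth.truth import GroundTruth


def revcomp_str(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestProgram:
    def test_config_echo_and_validation(self, small_prog, small_cfg):
        assert small_prog.config.n_branches == small_cfg.n_branches
        assert len(small_prog.tf_programs) == small_cfg.n_tfs
        assert len(small_prog.genes) == small_cfg.n_genes
        assert len(small_prog.peaks) == small_cfg.n_peaks

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_branches=1)
        with pytest.raises(ValueError):
            SimConfig.small(targets_per_branch=50)  # exceeds n_contigs
        with pytest.raises(ValueError):
            # background peaks cannot be placed in the available slots
            build_regulatory_program(SimConfig.small(n_background_peaks=5000))

    def test_determinism_bit_identical(self, small_cfg):
        p1 = build_regulatory_program(small_cfg, seed=7)
        p2 = build_regulatory_program(small_cfg, seed=7)
        pd.testing.assert_frame_equal(p1.genes, p2.genes)
        pd.testing.assert_frame_equal(p1.peaks, p2.peaks)
        for c in p1.genome:
            assert np.array_equal(p1.genome[c], p2.genome[c])

    def test_planted_consensus_in_enhancer_fasta(self, small_prog, tmp_path):
        """String-search oracle over the emitted FASTA: each target has >= 1
        enhancer carrying its driving TF's consensus on either strand."""
        io.write_fasta(small_prog.genome, tmp_path / "g.fa")
        genome = io.read_fasta(tmp_path / "g.fa")
        peaks = small_prog.peaks
        cons_by_key = {(r["branch"], r["timing"]): r["consensus"]
                       for _, r in small_prog.tf_programs.iterrows()}
        targets = small_prog.genes[small_prog.genes["kind"] == "target"]
        for gene, grow in targets.iterrows():
            found = False
            enh = peaks[(peaks["kind"] == "enhancer") & (peaks["gene"] == gene)]
            cons = cons_by_key[(grow["branch"], grow["timing"])]
            for _, prow in enh.iterrows():
                seq = decode_seq(
                    genome[prow["contig"]][int(prow["start"]):int(prow["end"])])
                if cons in seq or revcomp_str(cons) in seq:
                    found = True
            assert found, f"no planted consensus for {gene}"

    def test_mito_only_on_chrm(self, small_prog):
        g = small_prog.genes
        assert set(g.loc[g["contig"] == "chrM", "kind"]) == {"mito"}


class TestCellStates:
    def test_stage_counts_exact(self, small_prog):
        st = simulate_cell_states(small_prog, (100, 100, 100, 100), seed=0)
        assert len(st) == 400
        assert st["stage"].value_counts().to_dict() == {
            "t0": 100, "t1": 100, "t2": 100, "t3": 100}

    def test_zero_stage_rejected(self, small_prog):
        with pytest.raises(ValueError):
            simulate_cell_states(small_prog, (100, 0, 100, 100), seed=0)

    def test_all_cells_before_branch_point_multipotent(self):
        cfg = SimConfig.small(
            branch_point=0.9,
            stage_windows=((0, .2), (.2, .4), (.4, .6), (.6, .8)))
        prog = build_regulatory_program(cfg, seed=0)
        st = simulate_cell_states(prog, (50, 50, 50, 50), seed=0)
        assert (st["branch"] == -1).all()

    def test_branch_fractions_match_weights(self, small_prog):
        """Binomial-CI oracle: empirical branch fractions at n=2000 stay in
        the 99% CI around the configured (uniform) weights."""
        st = simulate_cell_states(small_prog, (500, 500, 500, 500), seed=3)
        branched = st[st["branch"] >= 0]
        n = len(branched)
        p = 1.0 / small_prog.config.n_branches
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        fracs = branched["branch"].value_counts(normalize=True)
        for b in range(small_prog.config.n_branches):
            assert abs(fracs[b] - p) < half + 1e-9

    def test_growth_elevated_for_multipotent(self, small_prog):
        st = simulate_cell_states(small_prog, (200,) * 4, seed=1)
        assert st.loc[st["branch"] == -1, "g_true"].mean() > \
            st.loc[st["branch"] >= 0, "g_true"].mean()


class TestCounts:
    def test_zero_link_weight_kills_correlation(self):
        cfg = SimConfig.small(link_weight=0.0, junk_fraction=0.0)
        prog = build_regulatory_program(cfg, seed=0)
        st = simulate_cell_states(prog, (150,) * 4, seed=1)
        ds = render_multiome_counts(prog, st, seed=2)
        X = np.asarray(ds.rna.X.todense(), float)
        P = np.asarray(ds.atac.X.todense(), float)
        gidx = pd.Index(ds.rna.var_names)
        pidx = pd.Index(ds.atac.var_names)
        rs = []
        for g, p in zip(prog.links["gene"], prog.links["peak"]):
            a, b = X[:, gidx.get_loc(g)], P[:, pidx.get_loc(p)]
            if a.std() and b.std():
                rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.02

    def test_nb_mean_variance_relation(self):
        """Moment oracle: housekeeping genes with fixed depth follow
        var = m + m^2/theta."""
        cfg = SimConfig.small(rna_depth_sigma=0.0, junk_fraction=0.0,
                              nb_theta=5.0)
        prog = build_regulatory_program(cfg, seed=0)
        st = simulate_cell_states(prog, (500,) * 4, seed=1)
        ds = render_multiome_counts(prog, st, seed=2)
        hk = prog.genes.index[prog.genes["kind"] == "housekeeping"]
        X = np.asarray(ds.rna.X.todense(), float)
        gidx = pd.Index(ds.rna.var_names).get_indexer(hk)
        m = X[:, gidx].mean(axis=0)
        v = X[:, gidx].var(axis=0, ddof=1)
        expected = m + m ** 2 / cfg.nb_theta
        keep = m > 0.5
        ratio = v[keep] / expected[keep]
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_junk_barcodes_fail_qc(self):
        cfg = SimConfig.small(junk_fraction=0.1)
        prog = build_regulatory_program(cfg, seed=0)
        st = simulate_cell_states(prog, (250,) * 4, seed=1)
        ds = render_multiome_counts(prog, st, seed=2)
        assert int(ds.obs["is_junk"].sum()) == 100
        table = qc.compute_qc_metrics(ds)
        ok = qc.qc_pass(table)
        junk = ds.obs["is_junk"].to_numpy()
        assert (~ok.loc[junk, "pass"]).mean() > 0.95

    def test_fragment_counts_match_atac_row_sums(self, small_sim):
        ds, _, _ = small_sim
        per_bc = ds.fragments.groupby("barcode")["count"].sum()
        row_sums = pd.Series(np.asarray(ds.atac.X.sum(axis=1)).ravel(),
                             index=ds.barcodes)
        per_bc = per_bc.reindex(row_sums.index).fillna(0).astype(int)
        assert (per_bc == row_sums.astype(int)).all()

    def test_rna_totals_track_depth_factors(self, small_sim):
        from scipy.stats import spearmanr

        ds, _, _ = small_sim
        real = ~ds.obs["is_junk"].to_numpy()
        totals = np.asarray(ds.rna.X.sum(axis=1)).ravel()[real]
        depth = ds.obs["rna_depth"].to_numpy()[real]
        assert spearmanr(totals, depth).statistic > 0.95

    def test_render_determinism(self, small_prog):
        st = simulate_cell_states(small_prog, (60,) * 4, seed=5)
        d1 = render_multiome_counts(small_prog, st, seed=9)
        d2 = render_multiome_counts(small_prog, st, seed=9)
        assert (d1.rna.X != d2.rna.X).nnz == 0
        assert (d1.atac.X != d2.atac.X).nnz == 0
        pd.testing.assert_frame_equal(d1.fragments, d2.fragments)


class TestValidationAssets:
    def test_noise_free_chip_peaks_near_target_tss(self, small_prog):
        st = simulate_cell_states(small_prog, (50,) * 4, seed=0)
        assets = simulate_validation_assets(small_prog, st, seed=0,
                                            noise_rate=0.0)
        genes = small_prog.genes
        for tf, reps in assets["chip"].items():
            targets = small_prog.edges.loc[small_prog.edges["tf"] == tf,
                                           "target"]
            tss = genes.loc[targets, ["contig", "tss"]]
            for rep in reps:
                for _, row in rep.iterrows():
                    mid = (row["start"] + row["end"]) // 2
                    d = (tss[tss["contig"] == row["contig"]]["tss"] - mid).abs()
                    assert (d <= 5000).any()

    def test_replicates_differ_but_share_jaccard(self, small_prog):
        from palatrix.validation import overlaps_any

        st = simulate_cell_states(small_prog, (50,) * 4, seed=0)
        assets = simulate_validation_assets(small_prog, st, seed=1,
                                            noise_rate=0.3)
        r1, r2 = assets["chip"][small_prog.tf_programs.index[0]]
        assert not r1.equals(r2)
        inter = overlaps_any(r1, r2).sum()
        union = len(r1) + len(r2) - inter
        assert inter / union >= 0.4

    def test_curated_overlap_rate_zero(self, small_prog):
        st = simulate_cell_states(small_prog, (50,) * 4, seed=0)
        assets = simulate_validation_assets(small_prog, st, seed=0,
                                            curated_overlap_rate=0.0)
        targets = set(small_prog.genes.index[small_prog.genes["kind"] == "target"])
        assert not (set(assets["curated_genes"]) & targets)


class TestRoundTrips:
    def test_write_read_dataset(self, small_sim, tmp_path):
        ds, truth, prog = small_sim
        io.write_dataset(ds, tmp_path / "d", ground_truth=truth,
                         motif_counts=prog.motif_counts)
        back = io.read_dataset(tmp_path / "d")
        assert (back.rna.X != ds.rna.X).nnz == 0
        assert (back.atac.X != ds.atac.X).nnz == 0
        assert list(back.barcodes) == list(ds.barcodes)
        assert back.annotation.contig_sizes == ds.annotation.contig_sizes
        bed = (tmp_path / "d" / "peaks.bed").read_text().strip().splitlines()
        assert len(bed) == ds.atac.n_vars
        assert back.fragments["count"].sum() == ds.fragments["count"].sum()
        with pytest.raises(FileExistsError):
            io.write_dataset(ds, tmp_path / "d")

    def test_truth_json_round_trip(self, small_sim):
        _, truth, _ = small_sim
        back = GroundTruth.from_json(truth.to_json())
        pd.testing.assert_frame_equal(back.states, truth.states)
        pd.testing.assert_frame_equal(back.links, truth.links)
        pd.testing.assert_frame_equal(back.edges, truth.edges)
        assert back.prolif_genes == truth.prolif_genes
        assert back.config == truth.config
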