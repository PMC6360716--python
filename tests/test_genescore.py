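"""Gene scoring: SNP filters, window mapping, weighted chi-square null, pathway fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from crosspath.genescore import (
    GeneWindow,
    LdMatrix,
    gene_score,
    ld_for_window,
    map_snps_to_genes,
    pathway_score_genescore,
    weighted_chi2_sf,
)
from crosspath.pathways import Pathway
from crosspath.sumstats import SUMSTATS_COLUMNS, load_sumstats

from conftest import make_genes, make_panel, make_sumstats


class TestLoadSumstats:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(
            [
                {"SNP": f"rs{i}", "CHR": "1", "BP": 100 * (i + 1), "A1": "A", "A2": "G",
                 "MAF": m, "P": p}
                for i, (m, p) in enumerate(rows)
            ],
            columns=SUMSTATS_COLUMNS,
        )
        path = tmp_path / "ss.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_maf_filter_is_strict_below_bound(self, tmp_path):
        path = self._write(tmp_path, [(0.01, 0.5), (0.05, 0.5), (0.3, 0.5), (0.49, 0.5)])
        ss = load_sumstats(path, maf_min=0.05)
        assert len(ss) == 3

    def test_p_filter_inclusive_at_threshold(self, tmp_path):
        path = self._write(tmp_path, [(0.3, 0.005), (0.3, 0.01), (0.3, 0.02)])
        ss = load_sumstats(path, p_max=0.01)
        assert sorted(ss.table["P"]) == [0.005, 0.01]

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = self._write(tmp_path, [])
        with caplog.at_level("WARNING"):
            ss = load_sumstats(path)
        assert len(ss) == 0
        assert "empty" in caplog.text

    def test_invalid_pvalues_rejected_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, [(0.3, 0.0), (0.3, 1.5), (0.3, 0.4)])
        with caplog.at_level("WARNING"):
            ss = load_sumstats(path)
        assert len(ss) == 1

    def test_missing_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\tBP\nrs1\t1\t100\n")
        with pytest.raises(ValueError, match="missing"):
            load_sumstats(path)


class TestSnpToGeneMapping:
    def test_window_arithmetic_around_plus_strand_tss(self):
        ss = make_sumstats(
            [("a", 1, 949_999, 0.3, 0.5), ("b", 1, 950_001, 0.3, 0.5),
             ("c", 1, 1_050_000, 0.3, 0.5)]
        )
        genes = make_genes([(1, 1_000_000, 1_020_000, "G1", "+")])
        (w,) = map_snps_to_genes(ss, genes, window_bp=50_000)
        assert w.member_snps == ["b", "c"]

    def test_minus_strand_tss_is_end_coordinate(self):
        ss = make_sumstats(
            [("a", 1, 960_000, 0.3, 0.5), ("b", 1, 1_060_000, 0.3, 0.5)]
        )
        genes = make_genes([(1, 950_000, 1_010_000, "G1", "-")])
        (w,) = map_snps_to_genes(ss, genes, window_bp=50_000)
        # TSS = 1,010,000; window [960,000, 1,060,000]
        assert w.member_snps == ["a", "b"]

    def test_snp_shared_between_overlapping_windows(self):
        ss = make_sumstats([("x", 1, 100_000, 0.3, 0.5)])
        genes = make_genes(
            [(1, 80_000, 90_000, "G1", "+"), (1, 110_000, 120_000, "G2", "+")]
        )
        ws = map_snps_to_genes(ss, genes, window_bp=50_000)
        assert [w.gene_name for w in ws] == ["G1", "G2"]
        assert all(w.member_snps == ["x"] for w in ws)

    def test_genes_without_snps_omitted(self):
        ss = make_sumstats([("x", 1, 100, 0.3, 0.5)])
        genes = make_genes([(2, 80_000, 90_000, "G1", "+")])
        assert map_snps_to_genes(ss, genes) == []

    def test_missing_strand_rejected(self):
        ss = make_sumstats([("x", 1, 100, 0.3, 0.5)])
        genes = make_genes([(1, 50, 150, "G1", ".")])
        with pytest.raises(ValueError, match="strand"):
            map_snps_to_genes(ss, genes)


class TestLdForWindow:
    def test_single_snp(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 3, size=(100, 1)))
        w = GeneWindow("g", "1", 1, 2000, ["rs1"])
        ld = ld_for_window(panel, w)
        assert ld.R.shape == (1, 1) and ld.R[0, 0] == 1.0
        assert ld.eigenvalues.tolist() == [1.0]

    def test_duplicated_snp_gives_rank_one_spectrum(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=(200, 1))
        panel = make_panel(np.hstack([col, col]))
        w = GeneWindow("g", "1", 1, 3000, ["rs1", "rs2"])
        ld = ld_for_window(panel, w)
        assert ld.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)

    def test_independent_snps_have_small_offdiagonals(self):
        rng = np.random.default_rng(1)
        panel = make_panel(rng.binomial(2, 0.3, size=(5000, 8)))
        w = GeneWindow("g", "1", 1, 10_000, [f"rs{i + 1}" for i in range(8)])
        ld = ld_for_window(panel, w)
        off = np.abs(ld.R[np.triu_indices(8, 1)])
        assert off.max() < 0.1

    def test_trace_preserved_by_clipping(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.binomial(2, 0.4, size=(50, 12)))
        w = GeneWindow("g", "1", 1, 20_000, [f"rs{i + 1}" for i in range(12)])
        ld = ld_for_window(panel, w)
        assert ld.eigenvalues.sum() == pytest.approx(12, rel=1e-6)

    def test_absent_snps_dropped_and_empty_window_fails(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 3, size=(60, 1)))
        w = GeneWindow("g", "1", 1, 2000, ["rs1", "zzz"])
        assert ld_for_window(panel, w).snp_ids == ["rs1"]
        with pytest.raises(ValueError):
            ld_for_window(panel, GeneWindow("g", "1", 1, 2000, ["zzz"]))


class TestWeightedChi2:
    def test_single_weight_matches_chi2_1(self):
        assert weighted_chi2_sf(6.6349, [1.0]) == pytest.approx(0.01, rel=1e-4)

    def test_equal_weights_match_chi2_4_closed_form(self):
        x = 20.11
        # chi2 df=4 survival: exp(-x/2) * (1 + x/2)
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert weighted_chi2_sf(x, [1, 1, 1, 1]) == pytest.approx(closed, rel=1e-12)

    def test_matches_monte_carlo_for_unequal_weights(self):
        rng = np.random.default_rng(3)
        lam = np.array([2.0, 1.0])
        draws = (rng.standard_normal((100_000, 2)) ** 2 * lam).sum(axis=1)
        for q in (0.5, 0.1, 0.01):
            x = np.quantile(draws, 1 - q)
            p = weighted_chi2_sf(float(x), lam)
            se = np.sqrt(q * (1 - q) / draws.size)
            assert abs(p - q) < 3 * se + 1e-4

    def test_monotone_non_increasing_in_x(self):
        lam = [3.0, 1.5, 0.5, 0.2]
        xs = np.linspace(0.1, 40, 60)
        ps = [weighted_chi2_sf(x, lam) for x in xs]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_zero_statistic_and_invalid_weights(self):
        assert weighted_chi2_sf(0.0, [1.0, 2.0]) == 1.0
        with pytest.raises(ValueError):
            weighted_chi2_sf(1.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            weighted_chi2_sf(-1.0, [1.0])


class TestGeneScore:
    def _ss_with_p(self, pvals):
        return make_sumstats(
            [(f"rs{i + 1}", 1, 1000 * (i + 1), 0.3, p) for i, p in enumerate(pvals)]
        )

    def test_single_snp_identity(self):
        ss = self._ss_with_p([0.01])
        ld = LdMatrix(["rs1"], np.eye(1), np.array([1.0]))
        w = GeneWindow("g", "1", 1, 5000, ["rs1"])
        assert gene_score(w, ss, ld).p_gene == pytest.approx(0.01, rel=1e-6)

    def test_perfectly_correlated_duplicate_not_double_counted(self):
        ss = self._ss_with_p([0.01, 0.01])
        R = np.ones((2, 2))
        ld = LdMatrix(["rs1", "rs2"], R, np.array([2.0, 0.0]))
        w = GeneWindow("g", "1", 1, 5000, ["rs1", "rs2"])
        gs = gene_score(w, ss, ld)
        q = chi2.isf(0.01, 1)
        assert gs.T == pytest.approx(2 * q)
        assert gs.p_gene == pytest.approx(0.01, rel=1e-6)

    def test_independent_snps_reduce_to_chi2_m(self):
        pvals = [0.2, 0.05, 0.5, 0.9]
        ss = self._ss_with_p(pvals)
        ld = LdMatrix([f"rs{i + 1}" for i in range(4)], np.eye(4), np.ones(4))
        w = GeneWindow("g", "1", 1, 9000, [f"rs{i + 1}" for i in range(4)])
        gs = gene_score(w, ss, ld)
        assert gs.p_gene == pytest.approx(chi2.sf(gs.T, df=4), rel=1e-12)

    def test_adding_null_snp_increases_p(self):
        ss3 = self._ss_with_p([0.01, 0.02, 1.0])
        ld2 = LdMatrix(["rs1", "rs2"], np.eye(2), np.ones(2))
        ld3 = LdMatrix(["rs1", "rs2", "rs3"], np.eye(3), np.ones(3))
        w2 = GeneWindow("g", "1", 1, 9000, ["rs1", "rs2"])
        w3 = GeneWindow("g", "1", 1, 9000, ["rs1", "rs2", "rs3"])
        g2 = gene_score(w2, ss3, ld2)
        g3 = gene_score(w3, ss3, ld3)
        assert g3.T == pytest.approx(g2.T)  # p=1 adds q=0
        assert g3.p_gene > g2.p_gene

    def test_zero_pvalue_clipped(self, caplog):
        ss = self._ss_with_p([0.5])
        ss.table.loc[0, "P"] = 0.0
        ld = LdMatrix(["rs1"], np.eye(1), np.array([1.0]))
        w = GeneWindow("g", "1", 1, 5000, ["rs1"])
        with caplog.at_level("WARNING"):
            gs = gene_score(w, ss, ld)
        assert np.isfinite(gs.T) and gs.p_gene > 0


class TestPathwayAggregation:
    def _setup(self, n_genes, p_unit):
        scores = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(n_genes)],
             "n_snps": 1, "T": 1.0, "p_gene": p_unit}
        )
        windows = [
            GeneWindow(f"G{i}", "1", 1 + 200_000 * i, 100_000 + 200_000 * i, [f"rs{i}"])
            for i in range(n_genes)
        ]
        return scores, windows

    def test_single_gene_pathway_is_identity(self):
        scores, windows = self._setup(1, 0.037)
        pw = Pathway("P", frozenset({"G0"}))
        p, n_units = pathway_score_genescore(scores, pw, windows, None, None)
        assert n_units == 1
        assert p == pytest.approx(0.037, rel=1e-9)

    def test_three_independent_genes_closed_form(self):
        scores, windows = self._setup(3, 0.5)
        pw = Pathway("P", frozenset({"G0", "G1", "G2"}))
        p, n_units = pathway_score_genescore(scores, pw, windows, None, None)
        assert n_units == 3
        stat = 3 * chi2.isf(0.5, 1)
        assert stat == pytest.approx(3 * 0.4549, abs=2e-4)
        assert p == pytest.approx(chi2.sf(stat, 3), rel=1e-12)
        assert p == pytest.approx(0.714, abs=5e-4)

    def test_fully_overlapping_genes_fused_into_one_unit(self):
        # two member genes over the same SNPs: evidence must not be squared
        rng = np.random.default_rng(4)
        panel = make_panel(rng.binomial(2, 0.3, size=(300, 3)))
        ss = make_sumstats(
            [("rs1", 1, 1000, 0.3, 0.04), ("rs2", 1, 2000, 0.3, 0.2),
             ("rs3", 1, 3000, 0.3, 0.6)]
        )
        snps = ["rs1", "rs2", "rs3"]
        wa = GeneWindow("GA", "1", 500, 3500, snps)
        wb = GeneWindow("GB", "1", 600, 3600, snps)
        joint = gene_score(wa, ss, ld_for_window(panel, wa))
        scores = pd.DataFrame(
            {"gene": ["GA", "GB"], "n_snps": 3, "T": joint.T,
             "p_gene": [joint.p_gene, joint.p_gene]}
        )
        pw = Pathway("P", frozenset({"GA", "GB"}))
        p, n_units = pathway_score_genescore(scores, pw, [wa, wb], ss, panel)
        assert n_units == 1
        assert p == pytest.approx(joint.p_gene, rel=1e-6)

    def test_unscored_pathway_reports_missing(self):
        scores, windows = self._setup(2, 0.5)
        pw = Pathway("P", frozenset({"ZZZ"}))
        assert pathway_score_genescore(scores, pw, windows, None, None) is None
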