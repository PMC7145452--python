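"""Gene-based statistics: genomic control, SNP assignment, LD, and the
combined p-value against closed forms and Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amynet import genestats
from amynet._null import CombinedNull, combined_pvalue
from amynet.datatypes import GwasSummary, ReferencePanel
from tests.conftest import gwas_from_z


class TestGenomicControl:
    def test_null_p_values_leave_lambda_at_one(self):
        lam, out = genestats.genomic_control(np.full(1001, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-4)
        assert np.array_equal(out, np.full(1001, 0.5))

    def test_doubled_chi_squares_give_lambda_two(self):
        u = np.linspace(0.001, 0.999, 999)
        chi = stats.chi2.isf(u, 1)
        p = stats.chi2.sf(2 * chi, 1)
        lam, corrected = genestats.genomic_control(p)
        assert lam == pytest.approx(2.0, abs=0.01)
        assert np.median(corrected) == pytest.approx(0.5, abs=0.01)

    def test_single_p_worked_example(self):
        lam, out = genestats.genomic_control([0.05])
        assert lam == pytest.approx(stats.chi2.isf(0.05, 1) / 0.45494,
                                    rel=1e-6)
        assert lam == pytest.approx(8.44, abs=0.01)
        assert out[0] == pytest.approx(0.5, abs=1e-4)

    def test_deflation_not_corrected(self):
        p = np.linspace(0.5, 0.999, 101)  # deflated chi-squares
        lam, out = genestats.genomic_control(p)
        assert lam < 1
        assert np.array_equal(out, p)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            genestats.genomic_control([0.5, 0.0])


class TestAssignment:
    def _genes(self):
        return pd.DataFrame(
            {"chrom": ["1", "1", "2"], "start": [100, 5000, 100],
             "end": [200, 6000, 200], "symbol": ["A", "B", "C"],
             "gene_id": [1, 2, 3]})

    def test_boundary_positions_closed_interval(self):
        gwas = gwas_from_z([1.0, 1.0, 1.0, 1.0],
                           bp=[100, 200, 99, 201])
        out = genestats.assign_snps_to_genes(gwas, self._genes())
        assigned = [gwas.table.at[i, "bp"] for i in out["A"]]
        assert sorted(assigned) == [100, 200]

    def test_flank_extends_interval(self):
        gwas = gwas_from_z([1.0], bp=[201])
        assert genestats.assign_snps_to_genes(gwas, self._genes())["A"] == []
        out = genestats.assign_snps_to_genes(gwas, self._genes(),
                                             flank_bp=10_000)
        assert len(out["A"]) == 1

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(0)
        genes = pd.DataFrame({
            "chrom": rng.choice(["1", "2"], 30),
            "start": rng.integers(1, 10_000, 30),
            "symbol": [f"G{i}" for i in range(30)],
            "gene_id": range(30)})
        genes["end"] = genes["start"] + rng.integers(10, 3000, 30)
        z = rng.standard_normal(100)
        gwas = gwas_from_z(z, bp=rng.integers(1, 12_000, 100))
        gwas.table["chr"] = rng.choice(["1", "2"], 100)
        out = genestats.assign_snps_to_genes(gwas, genes)
        for _, g in genes.iterrows():
            brute = [
                i for i, s in gwas.table.iterrows()
                if str(s["chr"]) == g["chrom"]
                and g["start"] <= s["bp"] <= g["end"]
            ]
            assert sorted(out[g["symbol"]]) == sorted(brute)


class TestLdMatrix:
    def _toy_panel(self):
        # 8 haplotypes x 3 SNPs; hand-checkable dosages
        hap = np.array([
            [1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1],
            [1, 0, 0], [0, 1, 1], [1, 1, 1], [0, 0, 0]], dtype=np.int8)
        snps = pd.DataFrame({"snp": ["a", "b", "c"], "chr": "1",
                             "bp": [10, 20, 30], "a1": "A", "a2": "G"})
        return ReferencePanel(hap, snps)

    def test_hand_computed_correlations(self):
        panel = self._toy_panel()
        dos = panel.dosages(["a", "b", "c"])
        want = np.corrcoef(dos, rowvar=False)
        got = genestats.ld_matrix(panel, ["a", "b", "c"])
        assert np.allclose(got, want)
        # dosage vectors by hand: a=(2,0,1,1), b=(2,0,1,1) -> wait, see dosages
        assert got[0, 0] == 1.0

    def test_duplicated_snp_gives_unit_correlation(self):
        hap = np.array([[0, 0], [0, 0], [1, 1], [0, 0], [1, 1], [1, 1],
                        [0, 0], [1, 1]], dtype=np.int8)
        snps = pd.DataFrame({"snp": ["x", "y"], "chr": "1", "bp": [1, 2],
                             "a1": "A", "a2": "G"})
        panel = ReferencePanel(hap, snps)
        assert genestats.ld_matrix(panel, ["x", "y"])[0, 1] == pytest.approx(1.0)

    def test_independent_snps_small_mean_r(self):
        rng = np.random.default_rng(1)
        hap = (rng.random((1000, 20)) < 0.4).astype(np.int8)
        snps = pd.DataFrame({"snp": [f"s{i}" for i in range(20)],
                             "chr": "1", "bp": np.arange(20) + 1,
                             "a1": "A", "a2": "G"})
        r = genestats.ld_matrix(ReferencePanel(hap, snps), snps["snp"])
        assert np.abs(r[np.triu_indices(20, 1)]).mean() < 0.05

    def test_monomorphic_and_missing_rejected(self):
        hap = np.zeros((6, 1), dtype=np.int8)
        panel = ReferencePanel(hap, pd.DataFrame(
            {"snp": ["m"], "chr": "1", "bp": [1], "a1": "A", "a2": "G"}))
        with pytest.raises(ValueError, match="monomorphic"):
            genestats.ld_matrix(panel, ["m"])
        with pytest.raises(KeyError):
            genestats.ld_matrix(panel, ["absent"])


class TestCombinedP:
    def test_single_snp_identity(self):
        assert genestats.brown_gene_p([0.037], np.ones((1, 1))) == 0.037

    def test_perfect_ld_collapse_exact(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        for p0 in (0.5, 0.05, 1e-4):
            assert genestats.brown_gene_p([p0, p0], R) == pytest.approx(
                p0, rel=1e-9)

    def test_independent_pair_matches_fisher(self):
        want = stats.chi2.sf(-2 * np.log(0.05) * 2, 4)
        assert want == pytest.approx(0.01748, abs=2e-5)
        got = genestats.brown_gene_p([0.05, 0.05], np.eye(2))
        assert got == pytest.approx(want, rel=0.03)
        # the Kost option reduces to Fisher exactly at zero LD
        got_kost = genestats.brown_gene_p([0.05, 0.05], np.eye(2),
                                          method="kost")
        assert got_kost == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("k", [2, 4, 7, 10])
    def test_identity_ld_equals_fisher_closed_form(self, k):
        rng = np.random.default_rng(k)
        p = rng.uniform(0.001, 1, k)
        want = stats.chi2.sf(-2 * np.sum(np.log(p)), 2 * k)
        assert genestats.brown_gene_p(p, np.eye(k), method="kost") == \
            pytest.approx(want, rel=1e-12)
        assert genestats.brown_gene_p(p, np.eye(k)) == \
            pytest.approx(want, rel=0.05, abs=1e-4)

    def test_snp_reordering_invariance(self):
        rng = np.random.default_rng(3)
        k = 6
        L = rng.normal(size=(k, 2))
        R = L @ L.T + np.eye(k)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        p = rng.uniform(0.001, 0.5, k)
        perm = rng.permutation(k)
        a = genestats.brown_gene_p(p, R)
        b = genestats.brown_gene_p(p[perm], R[np.ix_(perm, perm)])
        assert a == pytest.approx(b, rel=1e-9)

    def test_duplicate_noise_snp_never_helps(self):
        """Adding a pure-noise SNP in perfect LD with an existing noise
        SNP dilutes the signal: the gene p-value does not decrease."""
        rng = np.random.default_rng(5)
        k = 4
        R = np.full((k, k), 0.3)
        np.fill_diagonal(R, 1.0)
        # append a perfect copy of (noise) SNP 1
        R_aug = np.zeros((k + 1, k + 1))
        R_aug[:k, :k] = R
        R_aug[k, :k] = R_aug[:k, k] = R[1]
        R_aug[k, k] = 1.0
        R_aug[k, 1] = R_aug[1, k] = 1.0
        worse = 0
        n = 60
        for _ in range(n):
            z = rng.multivariate_normal(np.zeros(k), R, method="cholesky")
            z[0] = rng.normal(3.5, 1.0)  # the real signal sits at SNP 0
            p = 2 * stats.norm.sf(np.abs(z))
            base = genestats.brown_gene_p(p, R)
            aug = genestats.brown_gene_p(np.append(p, p[1]), R_aug)
            worse += aug >= base * 0.999
        assert worse >= 0.9 * n

    def test_mismatched_ld_shape_rejected(self):
        with pytest.raises(ValueError):
            combined_pvalue([0.1, 0.2, 0.3], np.eye(2))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combined_pvalue([0.0, 0.5], np.eye(2))

    def test_quick_null_calibration_exchangeable(self):
        """Type-I error at one representative LD structure (the full sweep
        runs in the acceptance suite)."""
        rng = np.random.default_rng(11)
        k, r = 6, 0.6
        R = np.full((k, k), r)
        np.fill_diagonal(R, 1.0)
        null = CombinedNull(R)
        z = rng.multivariate_normal(np.zeros(k), R, size=50_000,
                                    method="cholesky")
        X = -2 * np.sum(np.log(2 * stats.norm.sf(np.abs(z))), axis=1)
        gp = null.sf(X)
        assert abs((gp < 0.05).mean() - 0.05) < 0.004
        assert abs((gp < 0.01).mean() - 0.01) < 0.0015


class TestGeneScores:
    def test_single_snp_gene_equals_gc_corrected_p(self, small_genetics):
        ann, panel, gwas, _ = small_genetics
        scores = genestats.gene_scores(gwas, ann, panel)
        lam, corrected = genestats.genomic_control(gwas.table["p"].to_numpy())
        singles = scores[scores["n_snps"] == 1]
        if len(singles) == 0:
            pytest.skip("no single-SNP gene in this fixture")
        for _, row in singles.iterrows():
            i = gwas.table.index[gwas.table["snp"] == row["best_snp"]][0]
            assert row["gene_p"] == pytest.approx(corrected[i], rel=1e-9)

    def test_best_snp_is_minimum_p(self, small_genetics):
        ann, panel, gwas, _ = small_genetics
        scores = genestats.gene_scores(gwas, ann, panel,
                                       genomic_control_correction=False)
        assignment = genestats.assign_snps_to_genes(gwas, ann)
        for _, row in scores.head(40).iterrows():
            rows = assignment[row["gene"]]
            in_panel = [i for i in rows if gwas.table.at[i, "snp"] in panel]
            want = gwas.table.loc[in_panel, "p"].min()
            assert row["best_snp_p"] == pytest.approx(want)

    def test_deterministic_ordering(self, small_genetics):
        ann, panel, gwas, _ = small_genetics
        s1 = genestats.gene_scores(gwas, ann, panel)
        s2 = genestats.gene_scores(gwas, ann, panel)
        pd.testing.assert_frame_equal(s1, s2)
        keys = list(zip(s1["chrom"], s1["start"]))
        assert keys == sorted(keys)

    def test_multisnp_beats_bonferroni_for_distributed_signal(self):
        """A gene with several moderate-effect SNPs in weak LD should be
        detected more strongly by combination than by its best SNP with
        Bonferroni correction, most of the time."""
        rng = np.random.default_rng(21)
        k = 6
        R = np.full((k, k), 0.2)
        np.fill_diagonal(R, 1.0)
        chol = np.linalg.cholesky(R)
        null = CombinedNull(R)
        wins = 0
        n_sim = 200
        for _ in range(n_sim):
            mu = np.zeros(k)
            mu[:3] = rng.choice([-1, 1], 3) * 2.5
            z = mu + chol @ rng.standard_normal(k)
            p = 2 * stats.norm.sf(np.abs(z))
            gene_p = float(null.sf(-2 * np.sum(np.log(p))))
            bonf = min(1.0, p.min() * k)
            wins += gene_p < bonf
        assert wins >= 0.6 * n_sim
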