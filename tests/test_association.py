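"""Marker QC, PCs, Pillai-trace ANCOVA, EC10 regression, FDR machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytovar import association as assoc


# ---------------------------------------------------------------------------
# independent oracles


def pillai_oracle(Y, g, X):
    """SSCP oracle via explicit projection matrices and a generalized
    eigenproblem — shares no code path with the implementation."""
    Y = np.asarray(Y, float)
    classes = np.unique(g)
    G = np.column_stack([(g == c).astype(float) for c in classes])
    Xf = np.column_stack([X, G[:, 1:]])
    P = lambda A: A @ np.linalg.pinv(A.T @ A) @ A.T  # noqa: E731
    n, p = Y.shape
    Pf, Pr = P(Xf), P(X)
    E = Y.T @ (np.eye(n) - Pf) @ Y
    H = Y.T @ (Pf - Pr) @ Y
    evals = np.linalg.eigvals(np.linalg.inv(E + H) @ H)
    V = float(np.sum(evals.real))  # tr(H (H+E)^-1) = sum l/(1+l)
    q = len(classes) - 1
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    ve = n - np.linalg.matrix_rank(Xf)
    nn = (ve - p - 1) / 2.0
    df1, df2 = s * (2 * m + s + 1), s * (2 * nn + s + 1)
    F = (df2 / df1) * V / (s - V)
    return V, F, df1, df2, float(stats.f.sf(F, df1, df2))


def bh_oracle(p):
    """Literal step-up definition of Benjamini-Hochberg q-values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def prune_oracle(df, window):
    """Exhaustive interval check of the greedy ascending-p pruning."""
    kept = []
    for idx, row in df.sort_values("p", kind="mergesort").iterrows():
        if all(not (k["chrom"] == row["chrom"]
                    and abs(k["pos"] - row["pos"]) <= window) for k in kept):
            kept.append({"chrom": row["chrom"], "pos": row["pos"], "idx": idx})
    return sorted(k["idx"] for k in kept)


# ---------------------------------------------------------------------------


class TestFilterMarkers:
    def _geno_with_counts(self, counts):
        return np.repeat([0, 1, 2], counts).astype(float)[:, None]

    def test_min_per_genotype_rule(self):
        # Hardy-Weinberg-consistent counts with a 19-sample minor class
        g = self._geno_with_counts([643, 222, 19])
        out = assoc.filter_markers(g, min_per_genotype=20)
        assert out["pass_qc"][0]
        assert not out["pass_manova"][0]

    def test_low_maf_excluded_everywhere(self):
        g = np.zeros((1000, 1))
        g[:10, 0] = 1  # MAF 0.005
        out = assoc.filter_markers(g, min_per_genotype=20)
        assert out["maf"][0] == pytest.approx(0.005)
        assert not out["pass_qc"][0]

    def test_call_rate_filter(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, (100, 1)).astype(float)
        g[:10, 0] = np.nan
        out = assoc.filter_markers(g)
        assert out["call_rate"][0] == pytest.approx(0.9)
        assert not out["pass_qc"][0]

    def test_hwe_departure_excluded(self):
        # all heterozygotes: maximal HWE violation
        g = np.ones((500, 1))
        out = assoc.filter_markers(g)
        assert out["hwe_p"][0] < 1e-6
        assert not out["pass_qc"][0]

    def test_manova_fraction_matches_direct_recount(self):
        rng = np.random.default_rng(1)
        mafs = rng.uniform(0.01, 0.5, 2000)
        g = rng.binomial(2, mafs, (884, 2000)).astype(float)
        out = assoc.filter_markers(g, min_per_genotype=20)
        manual = np.array([
            min((g[:, j] == 0).sum(), (g[:, j] == 1).sum(), (g[:, j] == 2).sum()) >= 20
            for j in range(2000)
        ])
        assert np.array_equal(out["pass_manova"], out["pass_qc"] & manual)


class TestGenotypePcs:
    def test_pc1_separates_populations(self, small_genotypes):
        geno, annot, _ = small_genotypes
        scores = assoc.genotype_pcs(geno, k=5)
        pops = annot["population"].to_numpy()
        between = np.array([
            np.var([scores[pops == p, j].mean() for p in np.unique(pops)])
            for j in range(5)
        ])
        assert between[0] > 10 * between[1:].max()

    def test_scores_pairwise_orthogonal(self, small_genotypes):
        geno, _, _ = small_genotypes
        scores = assoc.genotype_pcs(geno, k=6)
        corr = np.corrcoef(scores.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 1e-10

    def test_rank_one_reconstruction_exact(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        geno = np.column_stack([v, 2 - v / 4, v / 2])  # standardises to rank 1
        scores = assoc.genotype_pcs(geno, k=1)
        z = (geno - geno.mean(0)) / geno.std(0)
        # one component reproduces the standardised matrix exactly
        loadings = z.T @ scores / (scores.T @ scores)
        assert np.allclose(scores @ loadings.T, z, atol=1e-10)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.4, (50, 20)).astype(float)
        geno[:, 3] = 2.0
        scores = assoc.genotype_pcs(geno, k=3)
        assert scores.shape == (50, 3)


class TestMagwas:
    def _instance(self, n=60, p=8, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(n, p)) + effect * g[:, None]
        return Y, g, X

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sscp_oracle(self, seed):
        Y, g, X = self._instance(seed=seed, effect=0.1 * (seed % 3))
        r = assoc.magwas_test(Y, g, X)
        V, F, df1, df2, p = pillai_oracle(Y, g, X)
        assert r["V"] == pytest.approx(V, abs=1e-8)
        assert r["F"] == pytest.approx(F, abs=1e-8)
        assert (r["df1"], r["df2"]) == (df1, df2)
        assert r["p"] == pytest.approx(p, abs=1e-8)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        Y, g, X = self._instance(n=90, seed=3, effect=0.2)
        r = assoc.magwas_test(Y, g, X)
        df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(8)])
        df["g"] = pd.Categorical(g)
        df["x"] = X[:, 1]
        mv = MANOVA.from_formula(
            " + ".join(df.columns[:8]) + " ~ C(g) + x", data=df
        )
        tab = mv.mv_test().results["C(g)"]["stat"]
        assert r["V"] == pytest.approx(tab.loc["Pillai's trace", "Value"], abs=1e-8)
        assert r["p"] == pytest.approx(
            tab.loc["Pillai's trace", "Pr > F"], abs=1e-8
        )

    def test_single_response_equals_ancova(self):
        rng = np.random.default_rng(4)
        n = 80
        g = rng.integers(0, 3, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n) + 0.3 * g
        r = assoc.magwas_test(y[:, None], g, X)
        # explicit ANCOVA F-test of the 2-df genotype term
        G = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        Xf = np.column_stack([X, G])
        rss = lambda A: float(  # noqa: E731
            ((y - A @ np.linalg.lstsq(A, y, rcond=None)[0]) ** 2).sum()
        )
        rss_f, rss_r = rss(Xf), rss(X)
        ve = n - Xf.shape[1]
        F = ((rss_r - rss_f) / 2) / (rss_f / ve)
        p = stats.f.sf(F, 2, ve)
        assert r["F"] == pytest.approx(F, abs=1e-10)
        assert r["p"] == pytest.approx(p, abs=1e-10)

    def test_partial_r2_bounds_and_counts(self):
        Y, g, X = self._instance(n=120, seed=5, effect=0.5)
        r = assoc.magwas_test(Y, g, X)
        assert 0.0 <= r["partial_r2"] <= 1.0
        assert sum(r["genotype_counts"]) == 120

    def test_rank_deficient_design_refused(self):
        Y, g, X = self._instance(seed=6)
        Xbad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            assoc.magwas_test(Y, g, Xbad)


class TestEc10Regression:
    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 200
        dose = rng.binomial(2, 0.3, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = -6 + 0.2 * dose + X[:, 1] * 0.1 + rng.normal(0, 0.3, n)
        r = assoc.ec10_regression(y, dose, X)
        fit = sm.OLS(y, np.column_stack([X, dose])).fit()
        assert r["beta"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert r["p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_power_at_study_scale(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(50):
            dose = rng.binomial(2, 0.3, 884).astype(float)
            y = 0.15 * dose + rng.normal(0, 0.3, 884)
            ps.append(assoc.ec10_regression(y, dose, np.ones((884, 1)))["p"])
        assert np.median(ps) < 1e-6

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = [
            assoc.ec10_regression(
                rng.normal(size=300), rng.binomial(2, 0.3, 300).astype(float),
                np.ones((300, 1)),
            )["p"]
            for _ in range(400)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_int_output_is_permutation_of_normal_quantiles(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=101)
        z = assoc.inverse_normal_transform(y)
        expected = stats.norm.ppf((np.arange(1, 102) - 0.5) / 101)
        assert np.allclose(np.sort(z), expected)
        # transform is rank-preserving
        assert np.array_equal(np.argsort(z), np.argsort(y))

    def test_zero_variance_dosage_skipped(self):
        r = assoc.ec10_regression(np.random.default_rng(0).normal(size=50),
                                  np.ones(50), np.ones((50, 1)))
        assert np.isnan(r["p"])


class TestTwoStageScan:
    def test_empty_when_nothing_passes(self):
        rng = np.random.default_rng(11)
        geno = rng.binomial(2, 0.3, (200, 20)).astype(float)
        out = assoc.two_stage_seq_scan(rng.normal(size=200), geno, np.ones((200, 1)))
        assert out.empty

    def test_outlier_driven_hit_neutralised(self):
        rng = np.random.default_rng(12)
        n = 400
        g = np.zeros(n)
        g[0] = 2.0  # a rare allele carried by the phenotype outlier
        y = rng.normal(0, 0.3, n)
        y[0] = 40.0
        out = assoc.two_stage_seq_scan(y, g[:, None], np.ones((n, 1)))
        assert len(out) == 1
        assert out.iloc[0]["p_stage1"] < 5e-8  # spurious raw-scale hit
        assert out.iloc[0]["p"] > 5e-8  # defused after the transform

    def test_true_effect_survives_both_stages(self):
        rng = np.random.default_rng(13)
        n = 600
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + rng.normal(0, 0.3, n)
        out = assoc.two_stage_seq_scan(y, g[:, None], np.ones((n, 1)))
        assert len(out) == 1
        assert out.iloc[0]["p"] < 5e-8


class TestFdrPruningEnrichment:
    def test_bh_hand_example(self):
        q = assoc.per_chemical_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert np.allclose(assoc.per_chemical_fdr(np.ones(10)), 1.0)

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            p = rng.uniform(1e-8, 1, rng.integers(1, 40))
            assert np.allclose(assoc.per_chemical_fdr(p), bh_oracle(p))

    def test_storey_scales_by_pi0(self):
        p = np.array([0.001, 0.002, 0.2, 0.3, 0.7, 0.9])
        q_bh = assoc.per_chemical_fdr(p, method="bh")
        q_st = assoc.per_chemical_fdr(p, method="storey")
        pi0 = min(1.0, (p > 0.5).mean() / 0.5)
        assert np.allclose(q_st, np.minimum(q_bh * pi0, 1.0))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            assoc.per_chemical_fdr(np.array([0.0, 0.5]))

    def test_prune_close_and_far_pairs(self):
        df = pd.DataFrame({
            "chrom": ["1", "1", "2", "2"],
            "pos": [1_000_000, 1_500_000, 1_000_000, 2_500_000],
            "p": [1e-9, 1e-8, 1e-7, 1e-6],
        })
        kept = assoc.prune_regional(df)
        assert list(kept.index) == [0, 2, 3]  # 500 kb pair pruned, 1.5 Mb kept

    def test_prune_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({
            "chrom": rng.choice(["1", "2"], 200),
            "pos": rng.integers(1, 20_000_000, 200),
            "p": rng.uniform(size=200),
        })
        kept = assoc.prune_regional(df)
        assert sorted(kept.index) == prune_oracle(df, 1_000_000)

    def test_enrichment_saturated(self):
        out = assoc.cross_chemical_enrichment(np.full(100, 0.005))
        assert out["pi0_hat"] == 0.0
        assert out["expected_true_count"] == 100

    def test_enrichment_null_near_zero(self):
        rng = np.random.default_rng(16)
        tdps = [
            assoc.cross_chemical_enrichment(rng.uniform(size=179))
            ["true_discovery_proportion"]
            for _ in range(1000)
        ]
        assert abs(np.mean(tdps)) < 0.1

    def test_too_few_chemicals_rejected(self):
        with pytest.raises(ValueError):
            assoc.cross_chemical_enrichment(np.full(10, 0.5))


class TestHeritabilityConcordance:
    def test_zero_se_gives_perfect_correlation(self):
        rng = np.random.default_rng(17)
        truth = rng.uniform(0, 0.5, 179)
        out = assoc.heritability_concordance_sim(
            truth, np.zeros(179), np.zeros(179), n_reps=200, seed=1
        )
        assert np.all(out["correlations"] == 1.0)

    def test_constant_truth_centres_on_zero(self):
        out = assoc.heritability_concordance_sim(
            np.full(100, 0.3), np.full(100, 0.2), np.full(100, 0.2),
            n_reps=2000, seed=2,
        )
        assert abs(out["mean"]) < 0.02

    def test_self_oracle_at_higher_reps(self):
        truth = np.random.default_rng(18).normal(0.3, 0.15, 179)
        se = np.full(179, 0.3)
        a = assoc.heritability_concordance_sim(truth, se, se, n_reps=1000, seed=3)
        b = assoc.heritability_concordance_sim(truth, se, se, n_reps=5000, seed=4)
        assert a["mean"] == pytest.approx(b["mean"], abs=0.01)
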