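"""Summary-statistics layer: scan, meta-analysis, clumping, PCA, and
post-processing statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitokit.gwas import (
    AssocRecord,
    FinemapRecord,
    GeneInterval,
    assign_genes,
    binary_genotype_pca,
    cochran_q,
    colocalization_clpp,
    define_loci,
    disease_or,
    effectsize_ivw_regression,
    enrichment_rr,
    ivw_meta,
    ld_clump,
    mcfadden_pseudo_r2,
    multinomial_loglik,
    ols_scan,
    replication_flags,
)


def _rec(vid, beta, se, p=None, pos=1, chrom="1", mac=100):
    if p is None:
        z = beta / se
        p = min(max(2 * stats.norm.sf(abs(z)), 1e-300), 1.0)
    return AssocRecord(vid, chrom, pos, "A", beta, se, p, mac)


class TestOlsScan:
    def _simulate(self, n, beta, maf, rng):
        g = rng.binomial(2, maf, n).astype(float)
        y = beta * g + rng.normal(0, 1, n)
        return g, y

    def test_mac_boundary_strict(self, rng):
        n = 1000
        y = pd.Series(rng.normal(size=n))
        g20 = np.zeros(n)
        g20[:20] = 1.0  # MAC exactly 20 -> excluded
        g21 = np.zeros(n)
        g21[:21] = 1.0
        geno = pd.DataFrame({"v20": g20, "v21": g21}, index=y.index)
        recs = ols_scan(geno, y, mac_min=20)
        assert [r.variant_id for r in recs] == ["v21"]

    def test_planted_effect_recovered(self, rng):
        n = 2000
        g, yv = self._simulate(n, 0.5, 0.3, rng)
        geno = pd.DataFrame({"v": g})
        recs = ols_scan(geno, pd.Series(yv), mac_min=20)
        assert len(recs) == 1
        r = recs[0]
        assert abs(r.beta - 0.5) < 2 * r.se

    def test_covariate_projection(self, rng):
        n = 1500
        c = rng.normal(size=n)
        g = rng.binomial(2, 0.4, n).astype(float)
        y = pd.Series(1.0 * c + 0.0 * g + rng.normal(0, 1, n))
        cov = pd.DataFrame({"c": c}, index=y.index)
        recs = ols_scan(pd.DataFrame({"v": g}, index=y.index), y, cov)
        assert recs[0].p > 1e-4  # no false signal through the covariate

    def test_type_one_error_calibrated(self, rng):
        n = 400
        y = pd.Series(rng.normal(size=n))
        geno = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, 400)).astype(float),
            index=y.index,
            columns=[f"v{j}" for j in range(400)],
        )
        recs = ols_scan(geno, y, mac_min=20)
        rej = np.mean([r.p < 0.05 for r in recs])
        se = np.sqrt(0.05 * 0.95 / len(recs))
        assert abs(rej - 0.05) < 3 * se


class TestMeta:
    def test_single_study_passthrough(self):
        r = _rec("v", 0.3, 0.1)
        m = ivw_meta([r])
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1)
        assert m.k == 1

    def test_identical_studies_shrink_se(self):
        rs = [_rec("v", 0.3, 0.1) for _ in range(4)]
        m = ivw_meta(rs)
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1 / 2.0)  # s / sqrt(k), k=4

    def test_order_invariance(self, rng):
        rs = [_rec("v", float(b), float(s)) for b, s in
              zip(rng.normal(0.2, 0.05, 5), rng.uniform(0.05, 0.2, 5))]
        m1 = ivw_meta(rs)
        m2 = ivw_meta(rs[::-1])
        assert m1.beta == pytest.approx(m2.beta)
        assert m1.se == pytest.approx(m2.se)

    def test_weights_scale_invariant(self):
        rs1 = [_rec("v", 0.2, 0.1), _rec("v", 0.4, 0.2)]
        rs2 = [_rec("v", 0.2, 0.2), _rec("v", 0.4, 0.4)]
        assert ivw_meta(rs1).beta == pytest.approx(ivw_meta(rs2).beta)


class TestCochranQ:
    def test_identical_effects_zero(self):
        q, p = cochran_q([_rec("v", 0.3, 0.1), _rec("v", 0.3, 0.1)])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        q, _ = cochran_q([_rec("v", 0.0, 1.0), _rec("v", 2.0, 1.0)])
        assert q == pytest.approx(2.0)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            cochran_q([_rec("v", 0.3, 0.1)])

    def test_null_distribution(self, rng):
        """Under homogeneity Q ~ chi-square(k-1): p-values are uniform."""
        ps = []
        for _ in range(400):
            true = 0.2
            rs = [_rec("v", float(true + rng.normal(0, 0.1)), 0.1) for _ in range(4)]
            ps.append(cochran_q(rs)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def brute_force_clump(records, ld, r2_th, window, positions):
    """Independent greedy oracle written directly from the procedure."""
    unassigned = {r.variant_id: r for r in records}
    out = []
    while unassigned:
        idx = min(
            unassigned.values(),
            key=lambda r: (r.p, positions[r.variant_id][0], positions[r.variant_id][1], r.variant_id),
        )
        del unassigned[idx.variant_id]
        members = []
        ichrom, ipos = positions[idx.variant_id]
        for vid in list(unassigned):
            chrom, pos = positions[vid]
            if chrom == ichrom and abs(pos - ipos) <= window and ld(idx.variant_id, vid) > r2_th:
                members.append(vid)
                del unassigned[vid]
        out.append((idx.variant_id, sorted(members)))
    return out


class TestLdClump:
    def test_no_ld_every_variant_own_clump(self, rng):
        recs = [_rec(f"v{i}", 0.1, 0.05, pos=i * 1000) for i in range(10)]
        clumps = ld_clump(recs, lambda a, b: 0.0)
        assert len(clumps) == 10
        assert all(c.members == [] for c in clumps)

    def test_partition_property(self):
        from mitokit.simulate import simulate_summary_stats

        truth = simulate_summary_stats(seed=5)
        recs = truth.records["g0"]
        clumps = ld_clump(recs, truth.ld_lookup, positions=truth.positions)
        seen = []
        for c in clumps:
            seen.append(c.index_variant)
            seen.extend(c.members)
        assert sorted(seen) == sorted(r.variant_id for r in recs)

    def test_matches_brute_force_oracle(self, rng):
        from mitokit.simulate import simulate_summary_stats

        truth = simulate_summary_stats(
            ld_blocks=(20, 20, 20, 20, 20),
            true_effects=(0.2, 0.1, 0.0, -0.15, 0.05),
            seed=17,
        )
        recs = truth.records["g1"]
        got = ld_clump(recs, truth.ld_lookup, positions=truth.positions)
        expected = brute_force_clump(
            recs, truth.ld_lookup, 0.1, 500_000, truth.positions
        )
        assert [(c.index_variant, sorted(c.members)) for c in got] == expected

    def test_tie_break_by_position(self):
        a = _rec("a", 0.3, 0.1, p=1e-6, pos=5000)
        b = _rec("b", 0.3, 0.1, p=1e-6, pos=1000)
        clumps = ld_clump([a, b], lambda x, y: 1.0)
        assert clumps[0].index_variant == "b"

    def test_missing_ld_warns_and_zero(self):
        recs = [_rec("a", 0.3, 0.05, pos=1), _rec("b", 0.1, 0.1, pos=100)]
        with pytest.warns(UserWarning):
            clumps = ld_clump(recs, lambda x, y: None)
        assert len(clumps) == 2


class TestLoci:
    def test_merge_within_2mb(self):
        leads = [_rec("a", 0.3, 0.05, pos=1_000_000), _rec("b", 0.3, 0.05, pos=2_900_000)]
        loci = define_loci(leads)
        assert len(loci) == 1

    def test_split_beyond_2mb(self):
        leads = [_rec("a", 0.3, 0.05, pos=1_000_000), _rec("b", 0.3, 0.05, pos=3_100_000)]
        loci = define_loci(leads)
        assert len(loci) == 2

    def test_replication_thresholds(self):
        new = [_rec("x", 0.3, 0.05, p=1e-6, pos=2_000_000)]
        flags = replication_flags([("1", 1_000_000)], new)
        row = flags.iloc[0]
        assert row["replicated_p<5e-05"] and not row["replicated_p<5e-08"]


class TestEffectSizeRegression:
    def test_exact_slope_two(self):
        bx = [0.1, 0.2, 0.3, 0.4]
        by = [0.2, 0.4, 0.6, 0.8]
        slope, se, p = effectsize_ivw_regression(bx, [0.1] * 4, by, [0.1] * 4)
        assert slope == pytest.approx(2.0)

    def test_simulated_slope_one(self, rng):
        n = 50
        bx = rng.normal(0.3, 0.1, n)
        sey = np.full(n, 0.05)
        by = bx + rng.normal(0, 0.05, n)
        slope, se, _ = effectsize_ivw_regression(bx, np.full(n, 0.05), by, sey)
        assert abs(slope - 1.0) < 2 * se

    def test_zero_weight_point_ignored(self):
        bx = [0.1, 0.2, 0.3, 10.0]
        by = [0.2, 0.4, 0.6, -50.0]
        # give the outlier a huge se -> negligible weight
        slope, _, _ = effectsize_ivw_regression(
            bx, [0.1, 0.1, 0.1, 1e6], by, [0.1, 0.1, 0.1, 1e6]
        )
        assert slope == pytest.approx(2.0, abs=1e-4)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            effectsize_ivw_regression([1, 2], [1, 1], [1, 2], [1, 1])


class TestBinaryPCA:
    def _matrix(self, rng, n=50, m=30):
        return pd.DataFrame(
            rng.binomial(1, 0.3, size=(n, m)).astype(float),
            index=[f"s{i}" for i in range(n)],
            columns=[f"v{j}" for j in range(m)],
        )

    def test_training_projection_consistency(self, rng):
        M = self._matrix(rng)
        scores, loadings, proj = binary_genotype_pca(M, k=10)
        reproj = proj.project(M)
        assert np.allclose(scores, reproj, atol=1e-8)

    def test_variances_non_increasing(self, rng):
        M = self._matrix(rng)
        _, _, proj = binary_genotype_pca(M, k=10)
        ev = proj.explained_variance
        assert all(a >= b - 1e-12 for a, b in zip(ev, ev[1:]))

    def test_matches_full_svd_oracle(self, rng):
        M = self._matrix(rng)
        scores, _, _ = binary_genotype_pca(M, k=5, maf_min=0.0)
        X = M.to_numpy(float)
        keep = X.std(axis=0) > 0
        Z = (X[:, keep] - X[:, keep].mean(0)) / X[:, keep].std(0)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        oracle = U[:, :5] * S[:5]
        for j in range(5):
            assert np.allclose(scores[:, j], oracle[:, j], atol=1e-6) or np.allclose(
                scores[:, j], -oracle[:, j], atol=1e-6
            )

    def test_held_out_projection(self, rng):
        M = self._matrix(rng, n=60)
        train = [f"s{i}" for i in range(50)]
        scores, _, proj = binary_genotype_pca(M, k=5, training_rows=train)
        held = proj.project(M.loc[[f"s{i}" for i in range(50, 60)]])
        assert held.shape == (10, 5)


class TestMcFadden:
    @pytest.mark.parametrize(
        "llm,lln,expected",
        [(-100.0, -100.0, 0.0), (0.0, -100.0, 1.0), (-50.0, -100.0, 0.5)],
    )
    def test_formula(self, llm, lln, expected):
        assert mcfadden_pseudo_r2(llm, lln) == pytest.approx(expected)

    def test_degenerate_null(self):
        with pytest.raises(ValueError):
            mcfadden_pseudo_r2(0.0, 0.0)

    def test_informative_features_raise_r2(self, rng):
        n = 400
        labels = rng.choice(["A", "B", "C"], n)
        X_info = np.column_stack(
            [(labels == c).astype(float) + rng.normal(0, 0.2, n) for c in "ABC"]
        )
        ll_null = multinomial_loglik(X_info, labels, fit_null=True)
        ll_model = multinomial_loglik(X_info, labels)
        r2 = mcfadden_pseudo_r2(ll_model, ll_null)
        assert 0.5 < r2 <= 1.0


class TestDiseaseOR:
    def test_planted_log_odds_recovered(self, rng):
        n = 5000
        z = rng.normal(size=n)
        logit = -2.0 + 0.3 * z
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = disease_or(pd.Series(z), pd.Series(y.astype(float)))
        assert not res.separation
        assert abs(res.beta - 0.3) < 2 * res.se

    def test_ci_symmetric_on_log_scale(self, rng):
        n = 3000
        z = rng.normal(size=n)
        y = (rng.random(n) < 0.2).astype(float)
        res = disease_or(pd.Series(z), pd.Series(y))
        log_lo = np.log(res.ci_low)
        log_hi = np.log(res.ci_high)
        assert (np.log(res.odds_ratio) - log_lo) == pytest.approx(
            log_hi - np.log(res.odds_ratio)
        )

    def test_null_coverage(self):
        hits = 0
        trials = 30
        for seed in range(trials):
            r = np.random.default_rng(seed)
            z = r.normal(size=800)
            y = (r.random(800) < 0.3).astype(float)
            res = disease_or(pd.Series(z), pd.Series(y))
            if res.ci_low <= 1.0 <= res.ci_high:
                hits += 1
        assert hits / trials >= 0.8


class TestClppEnrichment:
    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1), (0.5, 0.2, 0.1), (0, 0.7, 0)])
    def test_clpp_product(self, a, b, expected):
        assert colocalization_clpp(a, b) == pytest.approx(expected)

    def test_clpp_range_check(self):
        with pytest.raises(ValueError):
            colocalization_clpp(1.2, 0.5)

    def test_rr_worked_example(self):
        finemap = [
            FinemapRecord(f"h{i}", 0.5, annotation="coding") for i in range(20)
        ] + [
            FinemapRecord(f"l{i}", 0.005, annotation="coding" if i < 10 else "non-genic")
            for i in range(20)
        ]
        rr, ci = enrichment_rr(finemap, "coding", bootstrap_b=500, seed=1)
        assert rr == pytest.approx(2.0)
        assert ci[0] <= rr <= ci[1]

    def test_rr_null_ci_covers_one(self, rng):
        finemap = []
        for i in range(300):
            pip = 0.5 if i % 2 == 0 else 0.001
            ann = "coding" if rng.random() < 0.3 else "non-genic"
            finemap.append(FinemapRecord(f"v{i}", pip, annotation=ann))
        rr, ci = enrichment_rr(finemap, "coding", bootstrap_b=1000, seed=2)
        assert ci[0] <= 1.0 <= ci[1]


class TestAssignGenes:
    GENES = [
        GeneInterval("GENE_A", "1", 1000, 2000),
        GeneInterval("GENE_B", "1", 10_000, 12_000),
    ]

    def test_high_pip_coding_assigns_its_gene(self):
        cs = {1: [FinemapRecord("v", 0.95, cs_id=1, annotation="missense",
                                coding_gene="GENE_B", chrom="1", pos=11_000)]}
        out = assign_genes(cs, self.GENES)
        assert out["cs1"] == ["GENE_B"]

    def test_within_3kb(self):
        cs = {1: [FinemapRecord("v", 0.8, cs_id=1, chrom="1", pos=4500)]}
        out = assign_genes(cs, self.GENES)
        assert out["cs1"] == ["GENE_A"]  # 2.5 kb from GENE_A end

    def test_nearest_fallback(self):
        cs = {1: [FinemapRecord("v", 0.8, cs_id=1, chrom="1", pos=7200)]}
        out = assign_genes(cs, self.GENES)
        assert out["cs1"] == ["GENE_B"]

    def test_no_credible_set_uses_top_variant(self):
        out = assign_genes({}, self.GENES, locus_top_variant=("1", 1500))
        assert out["locus"] == ["GENE_A"]  # inside the gene body counts as nearest

    def test_multi_cs_pip_retention(self):
        cs = {
            1: [FinemapRecord("hi", 0.5, cs_id=1, chrom="1", pos=1500)],
            2: [FinemapRecord("lo", 0.05, cs_id=2, chrom="1", pos=11_000)],
        }
        out = assign_genes(cs, self.GENES)
        assert out["cs1"] == ["GENE_A"]
        assert out["cs2"] == []

    def test_empty_gene_catalog(self):
        with pytest.raises(ValueError):
            assign_genes({}, [], locus_top_variant=("1", 1))
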