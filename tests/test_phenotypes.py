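"""Phenotype construction: coding rules, covariate design, residualization,
normalization, coverage-discrepancy traits, transmission, accrual, and
carrier contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitokit.phenotypes import (
    BLOOD_INDICES,
    build_case_control,
    build_case_only,
    build_covariate_design,
    carrier_contrast,
    coverage_discrepancy_traits,
    inverse_rank_normalize,
    recode_fasting,
    residualize_phenotype,
    seasonal_knots,
    transmission_pairs,
    age_accrual_summary,
)
from mitokit.qc import CellState, HeteroplasmyMatrix
from mitokit.reference import CircularGenome, region_catalog_default


@pytest.fixture()
def matrix():
    cells = {
        "carrier": {"chrM:10:A,G": CellState("heteroplasmic", 0.2)},
        "ref": {"chrM:10:A,G": CellState("reference", 0.0)},
        "hom": {"chrM:10:A,G": CellState("homoplasmic", 0.97)},
        "nocall": {"chrM:10:A,G": CellState("missing")},
    }
    return HeteroplasmyMatrix.from_sample_states(cells)


class TestCaseCoding:
    def test_case_only(self, matrix):
        y = build_case_only(matrix, "chrM:10:A,G")
        assert y["carrier"] == pytest.approx(0.2)
        assert y[["ref", "hom", "nocall"]].isna().all()

    def test_case_control(self, matrix):
        y = build_case_control(matrix, "chrM:10:A,G")
        assert y["carrier"] == 1.0
        assert y["ref"] == 0.0
        assert np.isnan(y["hom"]) and np.isnan(y["nocall"])

    def test_consistency(self, matrix):
        co = build_case_only(matrix, "chrM:10:A,G")
        cc = build_case_control(matrix, "chrM:10:A,G")
        assert ((cc == 1.0) | co.isna()).all()

    def test_unknown_variant(self, matrix):
        with pytest.raises(KeyError):
            build_case_only(matrix, "chrM:99:A,G")


class TestCovariateDesign:
    def _table(self, n=200, rng=None):
        rng = rng or np.random.default_rng(7)
        t = pd.DataFrame(
            {
                "draw_time": rng.uniform(480, 1140, n),
                "assessment_date": pd.Timestamp("2008-01-01")
                + pd.to_timedelta(rng.integers(0, 800, n), unit="D"),
                "center": rng.choice(["C1", "C2", "C3"], n),
                "fasting_hours": rng.integers(0, 30, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        for c in BLOOD_INDICES:
            t[c] = rng.normal(size=n)
        return t

    def test_fasting_recode(self):
        hours = pd.Series([0, 1, 5, 18, 24])
        assert recode_fasting(hours).tolist() == [1, 1, 5, 18, 18]

    def test_quarterly_knot_count(self):
        assert len(seasonal_knots("2007-07-01", "2010-07-01")) == 13

    def test_blood_outlier_masked(self):
        t = self._table()
        col = BLOOD_INDICES[0]
        t.loc["s0", col] = 50.0  # far outlier
        design, report = build_covariate_design(t, include="blood")
        assert report.masked_blood_cells >= 1
        assert np.isnan(design.loc["s0", col])

    def test_full_rank_after_drops(self):
        t = self._table()
        design, report = build_covariate_design(t, include="both")
        complete = design.dropna()
        rank = np.linalg.matrix_rank(complete.to_numpy(float))
        assert rank == design.shape[1]

    def test_fasting_24_contributes_to_level_18(self):
        t = self._table()
        t["fasting_hours"] = 24
        t.loc["s0", "fasting_hours"] = 5
        design, _ = build_covariate_design(t, include="technical")
        level_cols = [c for c in design.columns if c.startswith("fasting_")]
        # with only levels {5, 18}, one indicator remains after drop_first
        assert any("18" in c or "5" in c for c in level_cols)


class TestResidualize:
    def test_intercept_only_returns_input(self):
        y = pd.Series(np.random.default_rng(0).normal(10, 1, 100))
        design = pd.DataFrame({"intercept": np.ones(100)}, index=y.index)
        out, report = residualize_phenotype(y, design)
        assert report.gated
        pd.testing.assert_series_equal(out, y)

    def test_orthogonality_to_design(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = pd.Series(2.0 + 1.5 * x + rng.normal(0, 0.5, n))
        design = pd.DataFrame({"intercept": np.ones(n), "x": x}, index=y.index)
        out, report = residualize_phenotype(y, design, gate_alpha=0.05)
        assert not report.gated
        resid = out - out.mean()
        assert abs(np.corrcoef(resid, x)[0, 1]) < 1e-8

    def test_log_mode_rescaling(self, rng):
        n = 300
        x = rng.normal(size=n)
        log_y = 4.0 + 0.3 * x  # zero residual noise
        y = pd.Series(np.exp(log_y))
        design = pd.DataFrame({"intercept": np.ones(n), "x": x}, index=y.index)
        out, _ = residualize_phenotype(y, design, log_transform=True, gate_alpha=0.5)
        expected = np.exp(np.mean(log_y))
        assert np.allclose(out, expected)

    def test_missing_passthrough(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = pd.Series(x * 2 + rng.normal(0, 0.1, n))
        y.iloc[5] = np.nan
        design = pd.DataFrame({"intercept": np.ones(n), "x": x}, index=y.index)
        out, _ = residualize_phenotype(y, design, gate_alpha=0.99)
        assert np.isnan(out.iloc[5])

    def test_insufficient_rows(self):
        y = pd.Series([1.0, 2.0])
        design = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        with pytest.raises(ValueError):
            residualize_phenotype(y, design)

    def test_planted_blood_effect_recovered_then_removed(self, rng):
        """A planted blood-covariate effect on log mtCN is visible before
        residualization and orthogonal to the design after."""
        import statsmodels.api as sm

        n = 1000
        blood = rng.normal(size=n)
        beta = -0.08
        log_mtcn = np.log(100) + beta * blood + rng.normal(0, 0.1, n)
        y = pd.Series(np.exp(log_mtcn))
        fit = sm.OLS(np.log(y), sm.add_constant(blood)).fit()
        assert abs(fit.params.iloc[1] - beta) < 2 * fit.bse.iloc[1]
        design = pd.DataFrame(
            {"intercept": np.ones(n), "blood": blood}, index=y.index
        )
        out, _ = residualize_phenotype(y, design, log_transform=True)
        fit2 = sm.OLS(np.log(out), sm.add_constant(blood)).fit()
        assert abs(fit2.params.iloc[1]) < 2 * fit2.bse.iloc[1]


class TestInverseRankNormalize:
    def test_median_maps_to_zero(self):
        y = pd.Series([3.0, 1.0, 2.0, 5.0, 4.0])
        out = inverse_rank_normalize(y)
        assert out[y == 3.0].iloc[0] == pytest.approx(0.0)

    def test_monotone_transform_invariance(self, rng):
        y = pd.Series(rng.uniform(1, 10, 50))
        assert np.allclose(
            inverse_rank_normalize(y), inverse_rank_normalize(np.exp(y))
        )

    def test_n3_blom_quantiles(self):
        y = pd.Series([10.0, 20.0, 30.0])
        out = inverse_rank_normalize(y)
        expected = stats.norm.ppf([(r - 0.375) / 3.25 for r in (1, 2, 3)])
        assert np.allclose(np.sort(out), expected)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            inverse_rank_normalize(pd.Series([1.0, 1.0, 1.0]))


class TestCoverageDiscrepancy:
    @pytest.fixture()
    def catalog(self):
        g = CircularGenome("chrM", "ACGT" * 300)
        return region_catalog_default(
            g,
            {
                "CSBII": (299, 315), "CSBIII": (346, 363), "LSP": (392, 445),
                "origin_heavy": (110, 191), "7s_dna": (1000, 191),
            },
        )

    def test_scaled_shape_zero_residuals(self, catalog, rng):
        L = catalog.contig_length
        base = rng.uniform(50, 100, L)
        coverages = {
            f"s{i}": base * rng.uniform(0.5, 2.0) for i in range(40)
        }
        hg = pd.Series("H", index=list(coverages))
        t1, t2 = coverage_discrepancy_traits(coverages, catalog, hg, min_group=30)
        assert np.nanmax(np.abs(t1.to_numpy())) < 1e-9
        assert np.nanmax(np.abs(t2.to_numpy())) < 1e-9

    def test_small_haplogroups_excluded(self, catalog, rng):
        L = catalog.contig_length
        coverages = {f"s{i}": rng.uniform(50, 100, L) for i in range(40)}
        hg = pd.Series("H", index=list(coverages))
        hg.iloc[:5] = "RARE"
        t1, _ = coverage_discrepancy_traits(coverages, catalog, hg, min_group=30)
        assert t1[hg == "RARE"].isna().all()

    def test_region_median_matches_brute_force(self, catalog, rng):
        from mitokit.phenotypes import region_median_coverage

        L = catalog.contig_length
        cov = rng.uniform(0, 100, L)
        positions = catalog["dna_primer"].positions(L)
        expected = np.median([cov[p - 1] for p in positions])
        assert region_median_coverage(cov, catalog, "dna_primer") == expected


class TestTransmission:
    def _matrix_with_pairs(self, fractions, n_other=0):
        cells = {}
        for i, (fm, fo) in enumerate(fractions):
            cells[f"m{i}"] = {"v": CellState("heteroplasmic", fm) if fm else CellState("reference", 0.0)}
            cells[f"o{i}"] = {"v": CellState("heteroplasmic", fo) if fo else CellState("reference", 0.0)}
        ped = pd.DataFrame(
            {
                "id1": [f"m{i}" for i in range(len(fractions))],
                "id2": [f"o{i}" for i in range(len(fractions))],
                "relationship": "mother_offspring",
            }
        )
        return HeteroplasmyMatrix.from_sample_states(cells), ped

    def test_rare_variant_omitted(self):
        m, ped = self._matrix_with_pairs([(0.2, 0.25), (0.3, None)])
        out = transmission_pairs(m, ped, min_samples=5)
        assert len(out) == 0

    def test_maternal_slope_near_one(self, rng):
        n = 150
        mom = rng.uniform(0.1, 0.8, n)
        off = np.clip(mom + rng.normal(0, 0.03, n), 0.01, 0.99)
        m, ped = self._matrix_with_pairs(list(zip(mom, off)))
        out = transmission_pairs(m, ped, min_samples=5)
        slope, _, _, _, stderr = stats.linregress(out["fraction1"], out["fraction2"])[:5]
        assert abs(slope - 1.0) < 3 * stderr

    def test_somatic_sharing_at_chance(self, rng):
        n = 200
        mom = rng.uniform(0.1, 0.8, n)
        off = rng.uniform(0.1, 0.8, n)  # independent
        m, ped = self._matrix_with_pairs(list(zip(mom, off)))
        out = transmission_pairs(m, ped, min_samples=5)
        slope, _, _, p, _ = stats.linregress(out["fraction1"], out["fraction2"])[:5]
        assert p > 0.01 or abs(slope) < 0.15


class TestAgeAccrual:
    def test_all_zero_cohort(self):
        counts = pd.DataFrame({"transition": [0, 0, 0]}, index=["a", "b", "c"])
        ages = pd.Series([45, 55, 75], index=counts.index)
        out = age_accrual_summary(counts, ages, bins=[40, 60, 90])
        assert (out["mean"].dropna() == 0).all()

    def test_step_increase_recovered(self, rng):
        n = 2000
        ages = pd.Series(rng.uniform(40, 90, n), index=[f"s{i}" for i in range(n)])
        rate = np.where(ages < 70, 0.3, 1.2)
        counts = pd.DataFrame(
            {"transition": rng.poisson(rate)}, index=ages.index
        )
        out = age_accrual_summary(counts, ages, bins=[40, 70, 90])
        young, old = out["mean"].iloc[0], out["mean"].iloc[1]
        assert abs(young - 0.3) < 0.1
        assert abs(old - 1.2) < 0.15

    def test_zero_inclusion_matters(self):
        counts = pd.DataFrame({"c": [0.0, 0.0, 3.0]}, index=["a", "b", "c"])
        ages = pd.Series([50, 51, 52], index=counts.index)
        with_zeros = age_accrual_summary(counts, ages, bins=[40, 60])["mean"].iloc[0]
        nonzero_only = counts[counts["c"] > 0]["c"].mean()
        assert with_zeros == pytest.approx(1.0)
        assert with_zeros != nonzero_only


class TestCarrierContrast:
    def test_pair_skipped_at_ten_values(self, rng):
        meas = pd.DataFrame(
            {"pheno": rng.normal(size=100)}, index=[f"s{i}" for i in range(100)]
        )
        carriers = {"var1": {f"s{i}" for i in range(10)}}
        out = carrier_contrast(carriers, meas, {f"s{i}" for i in range(50, 100)})
        assert len(out) == 0

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            meas = pd.DataFrame(
                {"pheno": r.normal(size=200)}, index=[f"s{i}" for i in range(200)]
            )
            carriers = {"v": {f"s{i}" for i in range(30)}}
            out = carrier_contrast(carriers, meas, {f"s{i}" for i in range(100, 200)})
            ps.append(out["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bh_qvalues_monotone_in_p(self, rng):
        meas = pd.DataFrame(
            {f"p{j}": rng.normal(size=200) for j in range(5)},
            index=[f"s{i}" for i in range(200)],
        )
        carriers = {"v1": {f"s{i}" for i in range(40)},
                    "v2": {f"s{i}" for i in range(40, 80)}}
        out = carrier_contrast(carriers, meas, {f"s{i}" for i in range(100, 200)})
        srt = out.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            carrier_contrast({}, pd.DataFrame(), set())
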