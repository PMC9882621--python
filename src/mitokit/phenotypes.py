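"""Construction of analysis phenotypes from the heteroplasmy matrix,
coverage vectors, and covariate tables.

Phenotypes are pandas Series indexed by sample id, with missingness always
explicit as NaN (never a sentinel value).  The covariate-correction model
follows the blood-draw design: natural cubic splines for draw time (5 df)
and assessment date (quarterly seasonal knots), indicator variables for
center, month, and recoded fasting hours, and 14 continuous blood indices
with outlying measurements (|Z| > 4) masked.  A phenotype is residualized
only if the covariate model passes a Bonferroni-corrected F-test gate;
residuals are rescaled by adding back the pre-correction mean (and
exponentiated for log-scale traits) so corrected values stay on an
absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qc import HETEROPLASMIC, HOMOPLASMIC, MISSING, REFERENCE, HeteroplasmyMatrix
from .reference import RegionCatalog

#: the 14 blood-composition covariates used for mtCN correction
BLOOD_INDICES = [
    "wbc_count",
    "haematocrit_pct",
    "platelet_crit",
    "monocyte_pct",
    "neutrophil_pct",
    "eosinophil_pct",
    "basophil_pct",
    "reticulocyte_pct",
    "hls_reticulocyte_pct",
    "immature_reticulocyte_fraction",
    "mean_corpuscular_volume",
    "mean_reticulocyte_volume",
    "mean_sphered_cell_volume",
    "mean_platelet_volume",
]

DEFAULT_SEASONAL_SPAN = ("2007-07-01", "2010-07-01")


# ---------------------------------------------------------------------------
# Case-only / case-control heteroplasmy phenotypes
# ---------------------------------------------------------------------------

def build_case_only(matrix: HeteroplasmyMatrix, variant: str) -> pd.Series:
    """Heteroplasmy level among carriers; reference, no-call, and
    homoplasmic samples are missing."""
    if variant not in matrix.variants:
        raise KeyError(f"unknown variant {variant}")
    state = matrix.state[variant]
    frac = matrix.fraction[variant]
    y = pd.Series(np.nan, index=state.index, name=f"{variant}|case_only")
    mask = state == HETEROPLASMIC
    y[mask] = frac[mask]
    return y


def build_case_control(matrix: HeteroplasmyMatrix, variant: str) -> pd.Series:
    """Binary coding: 1 for any detectable heteroplasmy, 0 only for samples
    confidently inferred reference (depth >= 100, QC-pass); homoplasmic and
    no-call samples are missing."""
    if variant not in matrix.variants:
        raise KeyError(f"unknown variant {variant}")
    state = matrix.state[variant]
    y = pd.Series(np.nan, index=state.index, name=f"{variant}|case_control")
    y[state == HETEROPLASMIC] = 1.0
    y[state == REFERENCE] = 0.0
    return y


# ---------------------------------------------------------------------------
# Covariate design
# ---------------------------------------------------------------------------

@dataclass
class DesignReport:
    dropped_columns: list[str] = field(default_factory=list)
    masked_blood_cells: int = 0
    n_columns: int = 0


def _natural_spline(x: np.ndarray, df: int | None = None, knots=None) -> np.ndarray:
    from patsy import dmatrix

    if knots is not None:
        # natural-spline bases need interior knots strictly inside the data
        # range; fixed seasonal knots outside the observed span are dropped
        inner = np.asarray([k for k in knots if x.min() < k < x.max()], dtype=float)
        if inner.size >= 1:
            basis = dmatrix(
                "cr(x, knots=inner) - 1",
                {"x": x, "inner": inner},
                return_type="matrix",
            )
        else:
            basis = dmatrix(
                "cr(x, df=4) - 1", {"x": x}, return_type="matrix"
            )
    else:
        basis = dmatrix("cr(x, df=df) - 1", {"x": x, "df": df}, return_type="matrix")
    return np.asarray(basis)


def seasonal_knots(
    start: str = DEFAULT_SEASONAL_SPAN[0],
    end: str = DEFAULT_SEASONAL_SPAN[1],
    months: int = 3,
) -> list[pd.Timestamp]:
    """Knots at fixed ``months`` increments from ``start`` through ``end``
    inclusive (the default quarterly span yields 13 knots)."""
    knots = []
    t = pd.Timestamp(start)
    end_t = pd.Timestamp(end)
    while t <= end_t:
        knots.append(t)
        t += pd.DateOffset(months=months)
    return knots


def recode_fasting(hours: pd.Series) -> pd.Series:
    """Fasting times > 18 h are labeled 18 and 0 h is labeled 1."""
    out = hours.clip(upper=18)
    out[out == 0] = 1
    return out.astype("Int64")


def build_covariate_design(
    table: pd.DataFrame,
    include: str = "both",
    seasonal_span: tuple[str, str] = DEFAULT_SEASONAL_SPAN,
    blood_z_max: float = 4.0,
) -> tuple[pd.DataFrame, DesignReport]:
    """Build the covariate design matrix.

    ``include`` selects "technical", "blood", or "both" term blocks.
    Technical terms: draw-time natural spline (5 df), assessment-date
    natural spline with quarterly knots over ``seasonal_span``, and
    indicator columns for center, month, and recoded fasting hours.  Blood
    terms: the 14 indices as continuous columns with |Z| > ``blood_z_max``
    entries masked to NaN (rows with a masked value drop out of any
    complete-case fit).  Aliased (collinear) columns are dropped last-in
    with a report.
    """
    if include not in ("technical", "blood", "both"):
        raise ValueError("include must be technical, blood, or both")
    report = DesignReport()
    blocks: list[pd.DataFrame] = []
    idx = table.index

    if include in ("technical", "both"):
        if "draw_time" in table:
            x = table["draw_time"].to_numpy(dtype=float)
            basis = _natural_spline(x, df=5)
            blocks.append(
                pd.DataFrame(
                    basis,
                    index=idx,
                    columns=[f"draw_time_ns{i + 1}" for i in range(basis.shape[1])],
                )
            )
        if "assessment_date" in table:
            dates = pd.to_datetime(table["assessment_date"])
            knots = [k.toordinal() for k in seasonal_knots(*seasonal_span)]
            x = dates.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
            basis = _natural_spline(x, knots=np.array(knots, dtype=float))
            blocks.append(
                pd.DataFrame(
                    basis,
                    index=idx,
                    columns=[f"date_ns{i + 1}" for i in range(basis.shape[1])],
                )
            )
            month = dates.dt.month.astype("category")
            blocks.append(
                pd.get_dummies(month, prefix="month", drop_first=True, dtype=float)
            )
        if "center" in table:
            blocks.append(
                pd.get_dummies(
                    table["center"].astype("category"),
                    prefix="center",
                    drop_first=True,
                    dtype=float,
                )
            )
        if "fasting_hours" in table:
            fasting = recode_fasting(table["fasting_hours"])
            blocks.append(
                pd.get_dummies(
                    fasting.astype("category"),
                    prefix="fasting",
                    drop_first=True,
                    dtype=float,
                )
            )

    if include in ("blood", "both"):
        blood_cols = [c for c in BLOOD_INDICES if c in table.columns]
        blood = table[blood_cols].astype(float).copy()
        z = (blood - blood.mean()) / blood.std(ddof=0)
        mask = z.abs() > blood_z_max
        report.masked_blood_cells = int(mask.sum().sum())
        blood[mask] = np.nan
        blocks.append(blood)

    if not blocks:
        raise ValueError("no covariate columns found for the requested blocks")
    design = pd.concat(blocks, axis=1)
    design.insert(0, "intercept", 1.0)

    # deterministic last-in drop of aliased columns
    complete = design.dropna()
    kept: list[str] = []
    rank = 0
    arr_cols = {}
    for col in design.columns:
        candidate = complete[kept + [col]].to_numpy(dtype=float)
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept.append(col)
            rank = new_rank
        else:
            report.dropped_columns.append(col)
    design = design[kept]
    report.n_columns = design.shape[1]
    return design, report


# ---------------------------------------------------------------------------
# Residualization with F-test gate
# ---------------------------------------------------------------------------

@dataclass
class ResidualizationReport:
    f_pvalue: float
    gated: bool  # True if correction was skipped (gate not passed)
    n_used: int = 0


def residualize_phenotype(
    y: pd.Series,
    design: pd.DataFrame,
    log_transform: bool = False,
    gate_alpha: float = 0.05 / 40,
) -> tuple[pd.Series, ResidualizationReport]:
    """Residualize a phenotype on a covariate design behind an F-test gate.

    The full model is compared with intercept-only by F-test; if its
    p-value is >= ``gate_alpha`` the phenotype is returned unchanged.
    Otherwise residuals (of log(y) when ``log_transform``) are computed on
    complete cases, the pre-correction mean is added back, and the result
    is exponentiated for log-scale traits.  Missing rows pass through as
    missing.
    """
    import statsmodels.api as sm

    if gate_alpha <= 0:
        raise ValueError("gate_alpha must be positive")
    y = y.astype(float)
    X = design.reindex(y.index)
    rows = y.notna() & X.notna().all(axis=1)
    if log_transform:
        rows &= y > 0
    n_used = int(rows.sum())
    if n_used <= X.shape[1]:
        raise ValueError(
            f"insufficient data: {n_used} rows for {X.shape[1]} design columns"
        )
    yy = np.log(y[rows]) if log_transform else y[rows]
    XX = X.loc[rows].to_numpy(dtype=float)
    res = sm.OLS(yy.to_numpy(), XX).fit()
    f_p = float(res.f_pvalue) if res.df_model > 0 else 1.0
    if not np.isfinite(f_p):
        f_p = 1.0
    if f_p >= gate_alpha:
        return y.copy(), ResidualizationReport(f_p, gated=True, n_used=n_used)
    corrected = pd.Series(np.nan, index=y.index, name=y.name)
    resid = res.resid + yy.mean()
    corrected[rows] = np.exp(resid) if log_transform else resid
    return corrected, ResidualizationReport(f_p, gated=False, n_used=n_used)


def inverse_rank_normalize(values: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based inverse normal transform with the Blom offset:
    the value at (tie-averaged) rank r maps to
    ``Phi^-1((r - 3/8) / (n + 1/4))``.  Missing values are preserved."""
    v = values.astype(float)
    mask = v.notna()
    x = v[mask].to_numpy()
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all values identical")
    ranks = stats.rankdata(x, method="average")
    q = (ranks - offset) / (x.size - 2 * offset + 1)
    out = pd.Series(np.nan, index=v.index, name=v.name)
    out[mask] = stats.norm.ppf(q)
    return out


# ---------------------------------------------------------------------------
# Coverage-discrepancy traits
# ---------------------------------------------------------------------------

def region_median_coverage(
    coverage: np.ndarray, catalog: RegionCatalog, region: str
) -> float:
    positions = catalog[region].positions(catalog.contig_length)
    return float(np.median([coverage[p - 1] for p in positions]))


def coverage_discrepancy_traits(
    coverages: Mapping[str, np.ndarray],
    catalog: RegionCatalog,
    haplogroups: pd.Series,
    min_group: int = 30,
) -> tuple[pd.Series, pd.Series]:
    """Replication-intermediate coverage phenotypes.

    Per sample, median coverage is computed over the DNA-primer region
    (CSBII to the heavy-strand origin), the RNA-primer region (CSBIII to
    the LSP), and the first third of the 7s-DNA span.  Samples in
    haplogroups with fewer than ``min_group`` members are excluded.  The
    two returned traits are the residuals of::

        dna_primer ~ x + haplogroup + x * haplogroup

    with x = RNA-primer coverage and x = 7s-DNA coverage respectively.
    """
    import statsmodels.formula.api as smf

    for region in ("dna_primer", "rna_primer", "7s_dna_first_third"):
        if catalog[region].length(catalog.contig_length) < 1:
            raise ValueError(f"empty region {region}")
    rows = []
    for sample, cov in coverages.items():
        rows.append(
            {
                "sample": sample,
                "dna_primer": region_median_coverage(cov, catalog, "dna_primer"),
                "rna_primer": region_median_coverage(cov, catalog, "rna_primer"),
                "seven_s": region_median_coverage(
                    cov, catalog, "7s_dna_first_third"
                ),
            }
        )
    df = pd.DataFrame(rows).set_index("sample")
    df["haplogroup"] = haplogroups.reindex(df.index)
    counts = df["haplogroup"].value_counts()
    keep_groups = counts[counts >= min_group].index
    df = df[df["haplogroup"].isin(keep_groups)].dropna()

    out = []
    for predictor in ("rna_primer", "seven_s"):
        if df["haplogroup"].nunique() > 1:
            formula = f"dna_primer ~ {predictor} * C(haplogroup)"
        else:
            formula = f"dna_primer ~ {predictor}"
        fit = smf.ols(formula, data=df).fit()
        resid = pd.Series(np.nan, index=coverages.keys(), dtype=float)
        resid[df.index] = fit.resid
        resid.name = f"dna_primer_vs_{predictor}"
        out.append(resid)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Transmission, age accrual, carrier contrasts
# ---------------------------------------------------------------------------

def transmission_pairs(
    matrix: HeteroplasmyMatrix,
    pedigree: pd.DataFrame,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Paired heteroplasmy fractions across relative pairs.

    ``pedigree`` has columns id1, id2, relationship (e.g. mother_offspring,
    father_offspring, sibling).  Only variants heteroplasmic in at least
    ``min_samples`` samples are emitted.  Reference samples contribute a
    fraction of 0; missing states are excluded pairwise.
    """
    rows = []
    for variant in matrix.variants:
        state = matrix.state[variant]
        if int((state == HETEROPLASMIC).sum()) < min_samples:
            continue
        frac = matrix.fraction[variant].copy()
        frac[state == REFERENCE] = 0.0
        frac[state == MISSING] = np.nan
        frac[state == HOMOPLASMIC] = np.nan
        for _, pair in pedigree.iterrows():
            a, b = pair["id1"], pair["id2"]
            if a not in frac.index or b not in frac.index:
                continue
            fa, fb = frac[a], frac[b]
            if pd.isna(fa) or pd.isna(fb):
                continue
            rows.append(
                {
                    "variant": variant,
                    "relationship": pair["relationship"],
                    "fraction1": fa,
                    "fraction2": fb,
                }
            )
    return pd.DataFrame(rows, columns=["variant", "relationship", "fraction1", "fraction2"])


def age_accrual_summary(
    counts: pd.DataFrame,
    ages: pd.Series,
    bins: Sequence[float],
) -> pd.DataFrame:
    """Mean variant count (with SEM) per age bin and variant class.

    ``counts`` is samples x classes; individuals with no variants of a
    class are included as zeros — excluding them would bias the mean
    upward.  Empty bins report NaN.
    """
    counts = counts.fillna(0.0)
    age = ages.reindex(counts.index)
    binned = pd.cut(age, bins=list(bins), right=False)
    rows = []
    for interval in binned.cat.categories:
        members = counts[binned == interval]
        for cls in counts.columns:
            if len(members) == 0:
                mean, sem = np.nan, np.nan
            else:
                mean = float(members[cls].mean())
                sem = float(members[cls].sem()) if len(members) > 1 else np.nan
            rows.append(
                {
                    "age_bin": str(interval),
                    "class": cls,
                    "n": len(members),
                    "mean": mean,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def carrier_contrast(
    carrier_sets: Mapping[str, set[str]],
    measurements: pd.DataFrame,
    control_set: set[str],
    min_carriers: int = 10,
) -> pd.DataFrame:
    """Two-sample t-tests of residualized measurements in pathogenic-variant
    carriers versus pan-negative controls, with Benjamini-Hochberg q-values
    over all performed tests.  Pairs with <= ``min_carriers`` defined
    carrier values are skipped."""
    from statsmodels.stats.multitest import multipletests

    if not control_set:
        raise ValueError("empty control set")
    rows = []
    for variant, carriers in sorted(carrier_sets.items()):
        for pheno in measurements.columns:
            vals_c = measurements.loc[
                measurements.index.isin(carriers), pheno
            ].dropna()
            if len(vals_c) <= min_carriers:
                continue
            vals_0 = measurements.loc[
                measurements.index.isin(control_set), pheno
            ].dropna()
            t, p = stats.ttest_ind(vals_c, vals_0, equal_var=False)
            rows.append(
                {
                    "variant": variant,
                    "phenotype": pheno,
                    "n_carriers": len(vals_c),
                    "n_controls": len(vals_0),
                    "carrier_mean": float(vals_c.mean()),
                    "control_mean": float(vals_0.mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "variant", "phenotype", "n_carriers", "n_controls",
            "carrier_mean", "control_mean", "t", "p",
        ],
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df
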