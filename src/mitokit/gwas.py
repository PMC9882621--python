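"""Summary-statistics layer: association scan, fixed-effect meta-analysis,
LD clumping and locus logic, effect-size regression, binary-genotype PCA,
goodness-of-fit and enrichment statistics, and gene-assignment rules.

The association scan is covariate-projected least squares, a stand-in
valid for unrelated samples (cohort-scale work would use a mixed model).
Meta-analysis is fixed-effect inverse-variance weighting with Cochran's Q
for heterogeneity.  Clumping is the standard greedy procedure: the most
significant unassigned variant seeds an index SNP and absorbs unassigned
variants within the window whose LD r^2 exceeds the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AssocRecord:
    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    beta: float
    se: float
    p: float
    mac: int
    ancestry: str = "ALL"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0 for {self.variant_id}")
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1] for {self.variant_id}")


@dataclass(frozen=True)
class MetaRecord:
    variant_id: str
    beta: float
    se: float
    p: float
    q_stat: float
    p_het: float
    k: int


@dataclass(frozen=True)
class FinemapRecord:
    variant_id: str
    pip: float
    cs_id: int | None = None
    annotation: str = "non-genic"
    coding_gene: str | None = None
    chrom: str = "1"
    pos: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pip <= 1.0:
            raise ValueError("pip must be in [0, 1]")


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

def ols_scan(
    genotypes: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    mac_min: int = 20,
    positions: Mapping[str, tuple[str, int]] | None = None,
    ancestry: str = "ALL",
) -> list[AssocRecord]:
    """Per-variant least-squares association of 0/1/2 genotypes with a
    quantitative trait, covariates projected out (Frisch-Waugh-Lovell).

    Variants with minor allele count <= ``mac_min`` (strict ``> mac_min``
    retained) or zero genotype variance are skipped.  ``positions`` maps
    variant id to (chrom, pos) for downstream clumping; defaults to
    chromosome "1" with consecutive positions.
    """
    y = y.astype(float)
    rows = y.notna()
    if covariates is not None:
        covariates = covariates.reindex(y.index)
        rows &= covariates.notna().all(axis=1)
    records: list[AssocRecord] = []
    idx = y.index[rows]
    yv = y[rows].to_numpy()
    if covariates is not None:
        C = np.column_stack([np.ones(len(idx)), covariates.loc[idx].to_numpy(float)])
    else:
        C = np.ones((len(idx), 1))
    # project covariates out of y once
    Q, _ = np.linalg.qr(C)
    y_res = yv - Q @ (Q.T @ yv)
    k_cov = C.shape[1]
    for j, vid in enumerate(genotypes.columns):
        g = genotypes[vid].reindex(idx).to_numpy(dtype=float)
        ok = ~np.isnan(g)
        gg = g[ok]
        if gg.size == 0:
            continue
        mac = int(min(gg.sum(), 2 * gg.size - gg.sum()))
        if mac <= mac_min:
            continue
        if np.all(gg == gg[0]):
            continue  # zero genotype variance
        if ok.all():
            g_res = gg - Q @ (Q.T @ gg)
            yr = y_res
        else:
            Cs = C[ok]
            Qs, _ = np.linalg.qr(Cs)
            g_res = gg - Qs @ (Qs.T @ gg)
            ys = yv[ok]
            yr = ys - Qs @ (Qs.T @ ys)
        denom = float(g_res @ g_res)
        if denom <= 0:
            continue
        beta = float(g_res @ yr) / denom
        resid = yr - beta * g_res
        df = gg.size - k_cov - 1
        if df <= 0:
            continue
        sigma2 = float(resid @ resid) / df
        se = math.sqrt(sigma2 / denom)
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df)
        p = min(max(p, np.finfo(float).tiny), 1.0)
        chrom, pos = (
            positions[vid] if positions and vid in positions else ("1", j + 1)
        )
        records.append(
            AssocRecord(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                effect_allele="A",
                beta=beta,
                se=se,
                p=p,
                mac=mac,
                ancestry=ancestry,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Meta-analysis and heterogeneity
# ---------------------------------------------------------------------------

def ivw_meta(records: Sequence[AssocRecord]) -> MetaRecord:
    """Fixed-effect inverse-variance-weighted meta-analysis of one variant
    across groups: weights ``1/se^2``, pooled se ``(sum w)^-1/2``, two-sided
    normal p."""
    if not records:
        raise ValueError("no records")
    w = np.array([1.0 / r.se**2 for r in records])
    b = np.array([r.beta for r in records])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    if len(records) >= 2:
        q, p_het = cochran_q(records)
    else:
        q, p_het = 0.0, 1.0
    return MetaRecord(
        variant_id=records[0].variant_id,
        beta=beta,
        se=se,
        p=p,
        q_stat=q,
        p_het=p_het,
        k=len(records),
    )


def cochran_q(records: Sequence[AssocRecord]) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and its chi-square(k-1) p-value."""
    if len(records) < 2:
        raise ValueError("Cochran's Q requires k >= 2")
    w = np.array([1.0 / r.se**2 for r in records])
    b = np.array([r.beta for r in records])
    beta = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta) ** 2))
    p = float(stats.chi2.sf(q, len(records) - 1))
    return q, p


# ---------------------------------------------------------------------------
# LD clumping, loci, replication
# ---------------------------------------------------------------------------

@dataclass
class Clump:
    index_variant: str
    members: list[str]


def ld_clump(
    assoc: Sequence[AssocRecord | MetaRecord],
    ld_lookup: Callable[[str, str], float | None],
    r2_threshold: float = 0.1,
    window: int = 500_000,
    p_index: float = 1.0,
    p_clumped: float = 1.0,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> list[Clump]:
    """Greedy LD clumping around index SNPs.

    Repeatedly the smallest-p unassigned variant passing ``p_index`` seeds
    a clump and absorbs unassigned variants on the same chromosome within
    ``window`` bases whose r^2 with the index exceeds ``r2_threshold`` and
    whose p passes ``p_clumped``.  Equal-p index candidates tie-break to
    the lower genomic position.  Missing LD for an in-window pair is
    treated as r^2 = 0 with a warning.
    """

    def _locus(rec) -> tuple[str, int]:
        if positions is not None and rec.variant_id in positions:
            return positions[rec.variant_id]
        return rec.chrom, rec.pos

    unassigned = {r.variant_id: r for r in assoc}
    order = sorted(
        assoc, key=lambda r: (r.p, _locus(r)[0], _locus(r)[1], r.variant_id)
    )
    clumps: list[Clump] = []
    warned = False
    for rec in order:
        if rec.variant_id not in unassigned or rec.p > p_index:
            continue
        del unassigned[rec.variant_id]
        chrom, pos = _locus(rec)
        members = []
        for vid, other in list(unassigned.items()):
            ochrom, opos = _locus(other)
            if ochrom != chrom or abs(opos - pos) > window:
                continue
            if other.p > p_clumped:
                continue
            r2 = ld_lookup(rec.variant_id, vid)
            if r2 is None:
                if not warned:
                    warnings.warn(
                        "missing LD for an in-window pair; treating as r2=0",
                        stacklevel=2,
                    )
                    warned = True
                r2 = 0.0
            if r2 > r2_threshold:
                members.append(vid)
                del unassigned[vid]
        clumps.append(Clump(index_variant=rec.variant_id, members=members))
    return clumps


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    lead_variants: list[str]


def define_loci(
    lead_snps: Sequence[AssocRecord | MetaRecord],
    merge_window: int = 2_000_000,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> list[Locus]:
    """Chain lead SNPs into loci: consecutive leads on a chromosome within
    the merge window join one locus."""

    def _locus(rec) -> tuple[str, int]:
        if positions is not None and rec.variant_id in positions:
            return positions[rec.variant_id]
        return rec.chrom, rec.pos

    by_chrom: dict[str, list] = {}
    for rec in lead_snps:
        chrom, pos = _locus(rec)
        by_chrom.setdefault(chrom, []).append((pos, rec.variant_id))
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        leads = sorted(by_chrom[chrom])
        current = [leads[0]]
        for prev, nxt in zip(leads, leads[1:]):
            if nxt[0] - current[-1][0] <= merge_window:
                current.append(nxt)
            else:
                loci.append(
                    Locus(chrom, current[0][0], current[-1][0], [v for _, v in current])
                )
                current = [nxt]
        loci.append(
            Locus(chrom, current[0][0], current[-1][0], [v for _, v in current])
        )
    return loci


def replication_flags(
    prior_loci: Sequence[tuple[str, int]],
    new_assoc: Sequence[AssocRecord | MetaRecord],
    window: int = 2_000_000,
    thresholds: Sequence[float] = (5e-5, 5e-8),
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Mark each prior locus (given by its top variant's chrom and pos) as
    replicated at each threshold iff any new association below that p lies
    within ``window`` of the prior top variant."""

    def _locus(rec) -> tuple[str, int]:
        if positions is not None and rec.variant_id in positions:
            return positions[rec.variant_id]
        return rec.chrom, rec.pos

    rows = []
    for chrom, pos in prior_loci:
        flags = {}
        for th in thresholds:
            flags[f"replicated_p<{th:g}"] = any(
                _locus(r)[0] == chrom
                and abs(_locus(r)[1] - pos) <= window
                and r.p < th
                for r in new_assoc
            )
        rows.append({"chrom": chrom, "pos": pos, **flags})
    return pd.DataFrame(rows)


def define_loci_and_replication(
    lead_snps: Sequence[AssocRecord | MetaRecord],
    prior_loci: Sequence[tuple[str, int]] = (),
    new_assoc: Sequence[AssocRecord | MetaRecord] | None = None,
    merge_window: int = 2_000_000,
    thresholds: Sequence[float] = (5e-5, 5e-8),
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> tuple[list[Locus], pd.DataFrame]:
    loci = define_loci(lead_snps, merge_window, positions)
    repl = replication_flags(
        prior_loci,
        new_assoc if new_assoc is not None else lead_snps,
        merge_window,
        thresholds,
        positions,
    )
    return loci, repl


# ---------------------------------------------------------------------------
# Effect-size IVW regression (Mendelian-randomization style)
# ---------------------------------------------------------------------------

def effectsize_ivw_regression(
    bx: Sequence[float],
    sex: Sequence[float],
    by: Sequence[float],
    sey: Sequence[float],
) -> tuple[float, float, float]:
    """Weighted least squares of outcome effect sizes on exposure effect
    sizes with per-point weight ``(1/se_x^2) * (1/se_y^2)``.  Returns
    (slope, se, p)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sex = np.asarray(sex, float)
    sey = np.asarray(sey, float)
    if bx.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(sex <= 0) or np.any(sey <= 0):
        raise ValueError("standard errors must be positive")
    import statsmodels.api as sm

    w = (1.0 / sex**2) * (1.0 / sey**2)
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Binary-genotype PCA with projection
# ---------------------------------------------------------------------------

@dataclass
class PCAProjector:
    columns: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_variants, k)
    explained_variance: np.ndarray

    def project(self, M: pd.DataFrame) -> np.ndarray:
        X = M[self.columns].to_numpy(dtype=float)
        Z = (X - self.center) / self.scale
        return Z @ self.loadings


def binary_genotype_pca(
    M: pd.DataFrame,
    k: int = 50,
    maf_min: float = 0.001,
    training_rows: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, PCAProjector]:
    """PCA of a binary homoplasmy-indicator matrix with held-out projection.

    Columns are filtered at MAF >= ``maf_min``; centering and scaling use
    the training rows only; the projector maps held-out rows into the same
    space.  Returns (training scores, loadings, projector).
    """
    if training_rows is None:
        training_rows = list(M.index)
    T = M.loc[list(training_rows)].to_numpy(dtype=float)
    freq = T.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    cols = [c for c, k_ in zip(M.columns, keep) if k_]
    T = T[:, keep]
    center = T.mean(axis=0)
    scale = T.std(axis=0, ddof=0)
    nz = scale > 0
    if not nz.all():
        cols = [c for c, good in zip(cols, nz) if good]
        T = T[:, nz]
        center = center[nz]
        scale = scale[nz]
    Z = (T - center) / scale
    k_eff = min(k, min(Z.shape) - 1) if min(Z.shape) > 1 else 1
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :k_eff], S[:k_eff], Vt[:k_eff]
    scores = U * S
    loadings = Vt.T
    projector = PCAProjector(
        columns=cols,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=S**2 / max(1, Z.shape[0] - 1),
    )
    return scores, loadings, projector


def mcfadden_pseudo_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2 = 1 - ll_model / ll_null."""
    if loglik_null == 0:
        raise ValueError("degenerate null model (single class): ll_null = 0")
    if loglik_null > 0 or loglik_model < loglik_null:
        raise ValueError("need loglik_null <= 0 and loglik_model >= loglik_null")
    return 1.0 - loglik_model / loglik_null


def multinomial_loglik(
    X: np.ndarray, labels: Sequence, fit_null: bool = False
) -> float:
    """Log-likelihood of a maximum-likelihood multinomial logistic model
    (or the intercept-only null), for feeding pseudo-R^2."""
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    n = len(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if fit_null:
        probs = np.bincount(y, minlength=len(classes)) / n
        return float(np.sum(np.log(probs[y])))
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=2000, C=1e6)
    clf.fit(X, y)
    logp = clf.predict_log_proba(X)
    return float(logp[np.arange(n), y].sum())


# ---------------------------------------------------------------------------
# Disease odds ratios
# ---------------------------------------------------------------------------

@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    separation: bool = False


def disease_or(
    trait_z: pd.Series,
    disease: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ORResult:
    """Logistic regression of a binary disease phenotype on a z-scored
    trait plus covariates; OR = exp(beta), 95% CI = exp(beta +/- 1.96 se).
    Complete separation is flagged instead of returning an estimate."""
    import statsmodels.api as sm

    df = pd.DataFrame({"trait": trait_z.astype(float), "disease": disease})
    if covariates is not None:
        df = df.join(covariates.reindex(trait_z.index))
    df = df.dropna()
    X = sm.add_constant(df.drop(columns="disease").to_numpy(float))
    yv = df["disease"].to_numpy(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
    except Exception:
        return ORResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 50:
        return ORResult(np.nan, np.nan, np.nan, np.nan, beta, se, True)
    return ORResult(
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        p=float(fit.pvalues[1]),
        beta=beta,
        se=se,
    )


# ---------------------------------------------------------------------------
# Colocalization, enrichment, gene assignment
# ---------------------------------------------------------------------------

def colocalization_clpp(pip_gwas: float, pip_eqtl: float) -> float:
    """Colocalization posterior: the product of the GWAS and cis-eQTL PIPs."""
    for name, v in [("pip_gwas", pip_gwas), ("pip_eqtl", pip_eqtl)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    return pip_gwas * pip_eqtl


def enrichment_rr(
    finemap: Sequence[FinemapRecord],
    annotation_class: str,
    pip_hi: float = 0.1,
    pip_lo: float = 0.01,
    bootstrap_b: int = 5000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Functional-category enrichment as a relative risk:
    P(annotation | PIP > hi) / P(annotation | PIP <= lo), with a percentile
    bootstrap CI resampling variants within each PIP stratum."""
    hi = [r for r in finemap if r.pip > pip_hi]
    lo = [r for r in finemap if r.pip <= pip_lo]
    if not hi or not lo:
        raise ValueError("both PIP strata must be non-empty")
    hi_in = np.array([r.annotation == annotation_class for r in hi], dtype=float)
    lo_in = np.array([r.annotation == annotation_class for r in lo], dtype=float)
    p_lo = lo_in.mean()
    if p_lo == 0:
        return math.nan, (math.nan, math.nan)
    rr = hi_in.mean() / p_lo
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_b)
    for b in range(bootstrap_b):
        h = hi_in[rng.integers(0, len(hi_in), len(hi_in))].mean()
        l = lo_in[rng.integers(0, len(lo_in), len(lo_in))].mean()
        reps[b] = h / l if l > 0 else np.nan
    reps = reps[np.isfinite(reps)]
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return float(rr), ci


@dataclass(frozen=True)
class GeneInterval:
    name: str
    chrom: str
    start: int
    end: int

    def distance_to(self, pos: int) -> int:
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


def _genes_for_variant(
    rec: FinemapRecord, genes: Sequence[GeneInterval], near: int = 3000
) -> list[str]:
    if rec.pip > 0.9 and rec.coding_gene:
        return [rec.coding_gene]
    same_chrom = [g for g in genes if g.chrom == rec.chrom]
    if not same_chrom:
        return []
    within = [g.name for g in same_chrom if g.distance_to(rec.pos) <= near]
    if within:
        return sorted(within)
    nearest = min(same_chrom, key=lambda g: (g.distance_to(rec.pos), g.name))
    return [nearest.name]


def assign_genes(
    credible_sets: Mapping[int, Sequence[FinemapRecord]],
    gene_intervals: Sequence[GeneInterval],
    locus_top_variant: tuple[str, int] | None = None,
) -> dict[str, list[str]]:
    """Rule-ladder gene assignment for one locus.

    Per credible set, variants that are minimal-PIP, coding, or PIP > 0.7
    are retained; a retained coding variant with PIP > 0.9 assigns its
    gene, otherwise genes within 3 kb of the variant (a variant inside a
    gene body counts as nearest), falling back to the single nearest gene.
    With multiple credible sets where at least one holds a variant at
    PIP > 0.1, only assignments from PIP > 0.1 variants are kept.  A locus
    without any credible set assigns the gene nearest its top variant.
    """
    if not gene_intervals:
        raise ValueError("empty gene catalog")
    if not credible_sets:
        if locus_top_variant is None:
            raise ValueError("need locus_top_variant when no credible set exists")
        chrom, pos = locus_top_variant
        dummy = FinemapRecord("top", 0.0, chrom=chrom, pos=pos)
        return {"locus": _genes_for_variant(dummy, gene_intervals)}

    per_variant: dict[str, tuple[float, list[str]]] = {}
    assignments: dict[str, list[str]] = {}
    any_high = any(
        r.pip > 0.1 for cs in credible_sets.values() for r in cs
    )
    multi = len(credible_sets) > 1
    for cs_id, records in credible_sets.items():
        if not records:
            continue
        min_pip = min(r.pip for r in records)
        retained = [
            r
            for r in records
            if r.pip == min_pip or r.coding_gene is not None or r.pip > 0.7
        ]
        genes: list[str] = []
        for r in retained:
            if multi and any_high and r.pip <= 0.1:
                continue
            genes.extend(_genes_for_variant(r, gene_intervals))
        assignments[f"cs{cs_id}"] = sorted(set(genes))
    return assignments


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def assoc_to_frame(records: Sequence[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "mac": r.mac,
                "ancestry": r.ancestry,
            }
            for r in records
        ]
    )


def frame_to_assoc(df: pd.DataFrame) -> list[AssocRecord]:
    return [
        AssocRecord(
            variant_id=str(row["variant"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row.get("effect_allele", "A")),
            beta=float(row["beta"]),
            se=float(row["se"]),
            p=float(row["p"]),
            mac=int(row.get("mac", 0)),
            ancestry=str(row.get("ancestry", "ALL")),
        )
        for _, row in df.iterrows()
    ]
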