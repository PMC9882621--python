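"""Deterministic synthetic-data generators with planted ground truth.

Everything the pipeline consumes can be generated here at desk scale: a
toy circular genome with the CSBII poly-C motif and NUMT decoys, simulated
cohorts with maternally transmitted indel heteroplasmies, age-accruing
somatic SNVs and planted covariate/QTL effects, aligned reads with
sequencing error and duplicate flags, and LD-block GWAS summary
statistics.  Every generator is a pure function of (params, seed).

What these fixtures emulate — and what they do not: reads carry uniform
substitution error and constant length (no indel errors or quality ramps),
maternal transmission is additive truncated-normal noise on the fraction
scale, and somatic accrual is piecewise-constant Poisson with a
changepoint at age 70.  Passing tests therefore demonstrate algorithmic
correctness under a clean error model, not robustness to real platform
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import AlignedRead, PlacementTarget
from .reference import CircularGenome, RegionCatalog, region_catalog_default
from .variants import VariantCall

_BASES = np.array(list("ACGT"))

#: forward-strand CSBII reference motif: two constant bp, C x 7, spacer T,
#: C x 5, two constant bp — classifies as tract (7, T, 5)
CSBII_MOTIF = "AA" + "C" * 7 + "T" + "C" * 5 + "GC"


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _scrub_motifs(seq: str, rng: np.random.Generator) -> str:
    """Break any accidental poly-C tract that the CSBII classifier could
    match outside the planted locus."""
    import re

    chars = list(seq)
    for m in re.finditer(r"C{4,}", "".join(chars)):
        i = m.start() + (m.end() - m.start()) // 2
        chars[i] = rng.choice([b for b in "AGT"])
    return "".join(chars)


# ---------------------------------------------------------------------------
# Toy genome + NUMT decoys
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    genome: CircularGenome
    catalog: RegionCatalog
    numt_targets: list[PlacementTarget]
    numt_divergence: float
    motif_start: int


def make_toy_genome(
    L: int = 3000,
    motif_start: int = 297,
    numt_spec: Sequence[tuple[int, int, float]] = ((600, 1100, 0.02),),
    seed: int = 0,
    contig_name: str = "chrM",
) -> ToyGenome:
    """Random circular genome with the CSBII motif planted at
    ``motif_start`` and NUMT decoys copied (with per-base divergence) from
    mtDNA segments.

    ``numt_spec`` lists (start, end, divergence) triples; each produces a
    linear decoy contig.  The default 3 kb molecule keeps the real CSBII
    coordinates (motif at 297, locus 300-318) with scaled-down control
    region and 7s-DNA spans.
    """
    if L < 500:
        raise ValueError("L must be >= 500")
    if motif_start + len(CSBII_MOTIF) > L:
        raise ValueError("motif does not fit in L at the requested locus")
    rng = np.random.default_rng(seed)
    seq = _scrub_motifs(_random_sequence(rng, L), rng)
    seq = (
        seq[: motif_start - 1]
        + CSBII_MOTIF
        + seq[motif_start - 1 + len(CSBII_MOTIF) :]
    )
    genome = CircularGenome(contig_name, seq)

    if L >= 16569:
        config = None
    else:
        config = {
            "control_region": (L - 300, 576),
            "CSBII": (299, 315),
            "CSBIII": (346, 363),
            "LSP": (392, 445),
            "origin_heavy": (110, 191),
            "7s_dna": (L - 150, 191),
            "locus_302": (300, 318),
        }
    catalog = region_catalog_default(genome, config)

    decoys: list[PlacementTarget] = []
    divergence = 0.0
    for i, (start, end, d) in enumerate(numt_spec, start=1):
        divergence = d
        segment = list(genome.fetch(start, end))
        n_mut = rng.binomial(len(segment), d)
        sites = rng.choice(len(segment), size=n_mut, replace=False)
        for s in sites:
            alts = [b for b in "ACGT" if b != segment[s]]
            segment[s] = rng.choice(alts)
        decoys.append(
            PlacementTarget(
                name=f"numt{i}",
                genome=CircularGenome(f"numt{i}", "".join(segment)),
                circular=False,
                is_decoy=True,
            )
        )
    return ToyGenome(genome, catalog, decoys, divergence, motif_start)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Planted study conditions for a synthetic cohort.

    Defaults: a -2% per decade age slope on log mtCN, three blood indices
    with real effects on log mtCN, additive truncated-normal maternal
    transmission noise (sigma 0.03 on the fraction scale), somatic SNV
    rates of 0.3 per person below age 70 and 1.2 above, and nuclear QTLs
    shifting case-only indel heteroplasmy.
    """

    baseline_log_mtcn: float = np.log(100.0)
    age_slope_per_year: float = np.log(0.98) / 10.0  # -2% per decade
    blood_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "neutrophil_pct": -0.08,
            "platelet_crit": 0.05,
            "mean_corpuscular_volume": 0.03,
        }
    )
    center_effect_sd: float = 0.05
    log_mtcn_noise_sd: float = 0.15
    transmission_sigma: float = 0.03
    somatic_rate_young: float = 0.3
    somatic_rate_old: float = 1.2
    somatic_changepoint: float = 70.0
    indel_carrier_prob: float = 0.5
    qtl_effects: Mapping[str, float] = field(
        default_factory=lambda: {"qtl_1": 0.04, "qtl_2": -0.03}
    )
    qtl_maf: float = 0.3
    haplogroup_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.45, "U": 0.2, "J": 0.15, "L": 0.2}
    )


@dataclass
class CohortTruth:
    covariates: pd.DataFrame  # per-sample covariate table
    log_mtcn: pd.Series  # true log mtDNA copy number
    indel_fractions: pd.DataFrame  # samples x indel variants (NaN = absent)
    somatic_counts: pd.DataFrame  # samples x SNV classes
    genotypes: pd.DataFrame  # samples x nuclear QTLs (0/1/2)
    pedigree: pd.DataFrame  # id1, id2, relationship
    params: CohortParams


def simulate_cohort(
    n: int,
    params: CohortParams | None = None,
    seed: int = 0,
    n_indel_variants: int = 3,
) -> CohortTruth:
    """Simulate a cohort of ``n`` samples: n/3 mother-offspring pairs plus
    unrelated singletons.

    Mothers' indel heteroplasmies are drawn from a mixture prior
    (Beta(2, 5) among carriers); offspring inherit the maternal value plus
    truncated-normal noise.  Somatic SNV counts are Poisson with an
    age-dependent piecewise rate.  log mtCN is baseline + age and blood
    effects + a random center effect + noise.  Nuclear QTL genotypes shift
    the first indel variant's heteroplasmy by the planted betas.
    """
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    samples = [f"S{i:05d}" for i in range(n)]
    n_pairs = n // 3
    mothers = samples[:n_pairs]
    offspring = samples[n_pairs : 2 * n_pairs]

    hg_names = list(p.haplogroup_freqs)
    hg_probs = np.array([p.haplogroup_freqs[h] for h in hg_names], dtype=float)
    hg_probs /= hg_probs.sum()
    haplogroup = rng.choice(hg_names, size=n, p=hg_probs)
    for i in range(n_pairs):  # offspring share the maternal haplogroup
        haplogroup[n_pairs + i] = haplogroup[i]

    age = rng.uniform(40, 90, size=n).round(1)
    sex = rng.choice(["F", "M"], size=n)
    sex[:n_pairs] = "F"
    centers = rng.choice([f"C{j}" for j in range(4)], size=n)
    draw_time = rng.uniform(8 * 60, 19 * 60, size=n).round()
    dates = pd.Timestamp("2008-01-01") + pd.to_timedelta(
        rng.integers(0, 900, size=n), unit="D"
    )
    fasting = rng.integers(0, 24, size=n)

    from .phenotypes import BLOOD_INDICES

    blood = pd.DataFrame(
        rng.normal(size=(n, len(BLOOD_INDICES))),
        index=samples,
        columns=BLOOD_INDICES,
    )

    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "center": centers,
            "draw_time": draw_time,
            "assessment_date": dates,
            "fasting_hours": fasting,
            "haplogroup": haplogroup,
        },
        index=samples,
    ).join(blood)

    center_shift = {
        c: rng.normal(0, p.center_effect_sd) for c in sorted(set(centers))
    }
    log_mtcn = (
        p.baseline_log_mtcn
        + p.age_slope_per_year * (age - 60.0)
        + sum(
            beta * blood[colname].to_numpy()
            for colname, beta in p.blood_effects.items()
        )
        + np.array([center_shift[c] for c in centers])
        + rng.normal(0, p.log_mtcn_noise_sd, size=n)
    )
    log_mtcn = pd.Series(log_mtcn, index=samples, name="log_mtcn")

    # nuclear QTL genotypes
    qtl_names = list(p.qtl_effects)
    geno = pd.DataFrame(
        rng.binomial(2, p.qtl_maf, size=(n, len(qtl_names))),
        index=samples,
        columns=qtl_names,
    )

    # maternally transmitted indel heteroplasmies
    variant_names = [f"chrM:302:A,A{'C' * (j + 1)}" for j in range(n_indel_variants)]
    frac = pd.DataFrame(np.nan, index=samples, columns=variant_names)
    for v_i, v in enumerate(variant_names):
        carrier = rng.random(n) < p.indel_carrier_prob
        base = rng.beta(2, 5, size=n)
        values = np.where(carrier, base, np.nan)
        # offspring inherit the maternal level plus truncated noise
        for i in range(n_pairs):
            m_val = values[i]
            if np.isnan(m_val):
                values[n_pairs + i] = np.nan
                continue
            noise = rng.normal(0, p.transmission_sigma)
            values[n_pairs + i] = float(np.clip(m_val + noise, 0.005, 0.995))
        # the first variant carries the planted QTL effects
        if v_i == 0:
            shift = np.zeros(n)
            for q, beta in p.qtl_effects.items():
                shift += beta * geno[q].to_numpy()
            values = np.where(
                np.isnan(values), np.nan, np.clip(values + shift, 0.005, 0.995)
            )
        frac[v] = values

    # somatic SNV counts, independent across relatives
    rate = np.where(
        age < p.somatic_changepoint, p.somatic_rate_young, p.somatic_rate_old
    )
    somatic = pd.DataFrame(
        {
            "transition": rng.poisson(rate),
            "transversion": rng.poisson(rate * 0.25),
        },
        index=samples,
    )

    pedigree = pd.DataFrame(
        {
            "id1": mothers,
            "id2": offspring,
            "relationship": "mother_offspring",
        }
    )
    return CohortTruth(cov, log_mtcn, frac, somatic, geno, pedigree, p)


def truth_to_matrix(truth: CohortTruth) -> "HeteroplasmyMatrix":
    """View the cohort's true indel fractions as a QC'ed heteroplasmy
    matrix (carriers heteroplasmic, non-carriers reference)."""
    from .qc import CellState, HeteroplasmyMatrix

    cells: dict[str, dict[str, CellState]] = {}
    for sample, row in truth.indel_fractions.iterrows():
        d = {}
        for v, frac in row.items():
            if np.isnan(frac):
                d[v] = CellState("reference", 0.0)
            elif frac >= 0.95:
                d[v] = CellState("homoplasmic", float(frac))
            else:
                d[v] = CellState("heteroplasmic", float(frac))
        cells[str(sample)] = d
    return HeteroplasmyMatrix.from_sample_states(cells)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleTruth:
    """One sample's true mtDNA state for read simulation."""

    genome: CircularGenome
    variants: list[VariantCall] = field(default_factory=list)  # fraction = truth
    numt_targets: list[PlacementTarget] = field(default_factory=list)
    numt_read_fraction: float = 0.0


def _apply_variants_to_read(
    g: CircularGenome,
    start: int,
    read_length: int,
    chosen: dict[int, VariantCall],
) -> tuple[str, str]:
    """Walk the reference from ``start`` collecting ``read_length`` query
    bases, splicing in the chosen variant alleles; returns (sequence,
    cigar) with modular reference coordinates."""
    L = g.length
    seq_parts: list[str] = []
    cigar_parts: list[tuple[int, str]] = []

    def emit(n: int, op: str) -> None:
        if cigar_parts and cigar_parts[-1][1] == op:
            cigar_parts[-1] = (cigar_parts[-1][0] + n, op)
        else:
            cigar_parts.append((n, op))

    qlen = 0
    p = start
    while qlen < read_length:
        pos = ((p - 1) % L) + 1
        var = chosen.get(pos)
        if var is None:
            seq_parts.append(g.base_at(pos))
            emit(1, "M")
            qlen += 1
            p += 1
        elif len(var.ref) == 1 and len(var.alt) == 1:  # SNV
            seq_parts.append(var.alt)
            emit(1, "M")
            qlen += 1
            p += 1
        elif len(var.alt) > len(var.ref):  # insertion after the anchor
            seq_parts.append(var.alt[0])
            emit(1, "M")
            qlen += 1
            ins = var.alt[1:][: read_length - qlen]
            if ins:
                seq_parts.append(ins)
                emit(len(ins), "I")
                qlen += len(ins)
            p += 1
        else:  # deletion
            seq_parts.append(var.alt[0])
            emit(1, "M")
            qlen += 1
            emit(len(var.ref) - 1, "D")
            p += len(var.ref)
    cigar = "".join(f"{n}{op}" for n, op in cigar_parts)
    return "".join(seq_parts), cigar


def simulate_reads(
    truth: SampleTruth,
    depth: float = 200.0,
    depth_profile: np.ndarray | None = None,
    error_rate: float = 0.003,
    duplicate_rate: float = 0.0,
    read_length: int = 100,
    barcodes: Sequence[str] | None = None,
    seed: int = 0,
) -> list[AlignedRead]:
    """Draw reads from a sample's true mtDNA haplotype mixture.

    Per read, each overlapping variant is included with probability equal
    to its true fraction (independent sites).  Substitution errors occur
    per base at ``error_rate``; a ``duplicate_rate`` fraction of reads is
    emitted twice with the copy flagged duplicate.  ``depth_profile``
    optionally weights read start positions (e.g. a control-region dip).
    Reads may span the circular origin; coordinates are modular.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    g = truth.genome
    L = g.length
    n_reads = int(round(depth * L / read_length))
    if depth_profile is not None:
        w = np.asarray(depth_profile, dtype=float)
        if w.sum() <= 0:
            raise ValueError("zero depth everywhere")
        w = w / w.sum()
        starts = rng.choice(L, size=n_reads, p=w) + 1
    else:
        if n_reads == 0:
            raise ValueError("zero depth everywhere")
        starts = rng.integers(1, L + 1, size=n_reads)

    variants = sorted(truth.variants, key=lambda v: v.pos)
    reads: list[AlignedRead] = []
    n_numt = (
        int(round(n_reads * truth.numt_read_fraction))
        if truth.numt_targets
        else 0
    )

    for i, start in enumerate(starts):
        if i < n_numt:
            decoy = truth.numt_targets[i % len(truth.numt_targets)]
            dl = decoy.genome.length
            if dl <= read_length:
                continue
            s = int(rng.integers(1, dl - read_length + 1))
            seq = decoy.genome.sequence[s - 1 : s - 1 + read_length]
            cigar = f"{read_length}M"
            contig = decoy.name
            left = s
        else:
            chosen: dict[int, VariantCall] = {}
            for v in variants:
                if rng.random() < v.heteroplasmy:
                    chosen[v.pos] = v
            seq, cigar = _apply_variants_to_read(
                g, int(start), read_length, chosen
            )
            contig = g.contig_name
            left = int(start)
        if error_rate > 0:
            chars = list(seq)
            errs = np.nonzero(rng.random(len(chars)) < error_rate)[0]
            for e in errs:
                chars[e] = rng.choice([b for b in "ACGT" if b != chars[e]])
            seq = "".join(chars)
        read = AlignedRead(
            read_id=f"r{i:07d}",
            contig=contig,
            left_pos=left,
            cigar=cigar,
            sequence=seq,
            cell_barcode=(
                str(rng.choice(np.asarray(barcodes))) if barcodes else None
            ),
        )
        reads.append(read)
        if duplicate_rate > 0 and rng.random() < duplicate_rate:
            reads.append(
                AlignedRead(
                    read_id=f"r{i:07d}d",
                    contig=contig,
                    left_pos=left,
                    cigar=cigar,
                    sequence=seq,
                    flags=frozenset({"duplicate"}),
                    cell_barcode=read.cell_barcode,
                )
            )
    return reads


def linearize_reads(
    reads: Sequence[AlignedRead], L: int, shift: int = 0
) -> list[AlignedRead]:
    """Emulate linear alignment against a (possibly rotated) molecule:
    reads crossing the rotation's linearization breakpoint are lost, and
    surviving reads are re-expressed in the rotated coordinate system.

    This reproduces the artificial coverage depression at the reference
    ends that motivates the dual-pass (shifted) calling strategy.
    """
    from dataclasses import replace

    out = []
    for read in reads:
        span = read.reference_span()
        new_left = ((read.left_pos - shift - 1) % L) + 1
        if new_left + span - 1 > L:  # crosses the breakpoint
            continue
        out.append(replace(read, left_pos=new_left))
    return out


def cr_dip_profile(L: int, dip_halfwidth: int = 150, floor: float = 0.3) -> np.ndarray:
    """Start-position weights with a dip around the linearization origin."""
    w = np.ones(L)
    for i in range(L):
        d = min(i, L - 1 - i)
        if d < dip_halfwidth:
            w[i] = floor + (1 - floor) * d / dip_halfwidth
    return w


# ---------------------------------------------------------------------------
# Summary-statistics simulation
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatsTruth:
    records: dict[str, list]  # ancestry -> list[AssocRecord]
    positions: dict[str, tuple[str, int]]
    causal_variants: list[str]
    r2: pd.DataFrame

    def ld_lookup(self, a: str, b: str) -> float:
        return float(self.r2.loc[a, b])


def simulate_summary_stats(
    ld_blocks: Sequence[int] = (10, 10, 10),
    block_r2: float = 0.6,
    true_effects: Sequence[float] = (0.15, 0.0, -0.12),
    k_groups: int = 3,
    n_per_group: int = 5000,
    maf: float = 0.3,
    block_spacing: int = 1_000_000,
    variant_spacing: int = 10_000,
    seed: int = 0,
    heterogeneity_sd: float = 0.0,
) -> SummaryStatsTruth:
    """Per-ancestry association records over LD blocks with one causal
    variant per block.

    Within a block, every variant has r^2 = ``block_r2`` with the causal
    variant (first in the block), so its expected marginal effect is
    ``sqrt(block_r2) * beta``.  Standard errors follow the single-variant
    OLS approximation ``1 / sqrt(2 n maf (1 - maf))``; per-group estimates
    are drawn around truth, optionally with cross-group heterogeneity.
    """
    from .gwas import AssocRecord

    rng = np.random.default_rng(seed)
    names: list[str] = []
    positions: dict[str, tuple[str, int]] = {}
    causal: list[str] = []
    truth_beta: dict[str, float] = {}
    block_of: dict[str, int] = {}
    pos = 1
    for b, (size, beta) in enumerate(zip(ld_blocks, true_effects)):
        for j in range(size):
            vid = f"v{b}_{j}"
            names.append(vid)
            positions[vid] = ("1", pos)
            block_of[vid] = b
            if j == 0:
                causal.append(vid)
                truth_beta[vid] = beta
            else:
                truth_beta[vid] = np.sqrt(block_r2) * beta
            pos += variant_spacing
        pos += block_spacing

    r2 = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b_ in names:
            if a == b_:
                r2.loc[a, b_] = 1.0
            elif block_of[a] == block_of[b_]:
                r2.loc[a, b_] = block_r2

    se = 1.0 / np.sqrt(2 * n_per_group * maf * (1 - maf))
    records: dict[str, list] = {}
    for k in range(k_groups):
        group = f"g{k}"
        group_shift = (
            rng.normal(0, heterogeneity_sd, size=len(names))
            if heterogeneity_sd > 0
            else np.zeros(len(names))
        )
        recs = []
        for j, vid in enumerate(names):
            beta_hat = truth_beta[vid] + group_shift[j] + rng.normal(0, se)
            z = beta_hat / se
            from scipy import stats as _st

            p = float(
                min(max(2 * _st.norm.sf(abs(z)), np.finfo(float).tiny), 1.0)
            )
            recs.append(
                AssocRecord(
                    variant_id=vid,
                    chrom=positions[vid][0],
                    pos=positions[vid][1],
                    effect_allele="A",
                    beta=float(beta_hat),
                    se=float(se),
                    p=p,
                    mac=int(2 * n_per_group * maf),
                    ancestry=group,
                )
            )
        records[group] = recs
    return SummaryStatsTruth(records, positions, causal, r2)
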