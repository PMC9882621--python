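"""Post-calling variant- and sample-level QC.

Variant-level rules (applied per sample-site cell):

* heteroplasmy < 0.01  -> called reference, stored fraction 0
* 0.01 <= heteroplasmy < 0.05 -> removed (missing); this band is enriched
  for NUMT-derived signal
* caller-flagged calls -> missing
* no call with site depth >= 100 -> confidently reference
* no call with site depth < 100 -> missing (cannot distinguish reference
  from a missed call)
* heteroplasmy >= 0.95 -> homoplasmic

Sample-level rules: drop on mtCN < 50 (strict), contamination > 2%
(strict), homoplasmic-variant overlap, or membership in a configurable
processing-year exclusion set.  "Homoplasmic variant overlap" is
implemented as any site where two distinct non-reference alleles each
reach fraction >= 0.5 — an impossible configuration for a clean sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantCall

#: cell states of the samples x variants heteroplasmy matrix
REFERENCE = "reference"
HETEROPLASMIC = "heteroplasmic"
HOMOPLASMIC = "homoplasmic"
MISSING = "missing"

STATES = (REFERENCE, HETEROPLASMIC, HOMOPLASMIC, MISSING)


@dataclass(frozen=True)
class CellState:
    state: str
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == HETEROPLASMIC and not (
            self.fraction is not None and 0.0 < self.fraction < 1.0
        ):
            raise ValueError("heteroplasmic state requires fraction in (0,1)")


@dataclass
class QCThresholds:
    reference_below: float = 0.01
    remove_below: float = 0.05
    homoplasmy_at: float = 0.95
    min_site_depth: int = 100


def variant_qc(
    calls: Sequence[VariantCall],
    site_depth: np.ndarray | Sequence[float],
    variants_of_interest: Sequence[str],
    thresholds: QCThresholds | None = None,
) -> dict[str, CellState]:
    """QC one sample's calls into cell states for each variant of interest.

    ``site_depth`` is the per-base coverage vector in reference coordinates
    (read-level, so calls removed by QC still contribute to depth).
    Variant ids are ``contig:pos:ref,alt`` strings.  Idempotent: reapplying
    the rules to the surviving fractions changes nothing.
    """
    th = thresholds or QCThresholds()
    depth = np.asarray(site_depth, dtype=float)
    by_id = {c.variant_id: c for c in calls}
    out: dict[str, CellState] = {}
    for vid in variants_of_interest:
        call = by_id.get(vid)
        pos = int(vid.split(":")[1])
        if call is None:
            if depth[pos - 1] >= th.min_site_depth:
                out[vid] = CellState(REFERENCE, 0.0)
            else:
                out[vid] = CellState(MISSING)
            continue
        frac = call.heteroplasmy
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} outside [0,1] for {vid}")
        if not call.qc_pass:
            out[vid] = CellState(MISSING)
        elif frac < th.reference_below:
            out[vid] = CellState(REFERENCE, 0.0)
        elif frac < th.remove_below:
            out[vid] = CellState(MISSING)
        elif frac >= th.homoplasmy_at:
            out[vid] = CellState(HOMOPLASMIC, frac)
        else:
            out[vid] = CellState(HETEROPLASMIC, frac)
    return out


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

@dataclass
class SampleQCRecord:
    sample_id: str
    mtcn: float | None = None
    contamination: float | None = None
    homoplasmy_overlap: bool = False
    processing_year: int | None = None
    drop_reasons: list[str] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.drop_reasons


def sample_qc(
    records: Iterable[SampleQCRecord],
    mtcn_floor: float = 50.0,
    contamination_ceiling: float = 0.02,
    excluded_years: frozenset[int] | set[int] = frozenset(),
) -> list[SampleQCRecord]:
    """Apply the sample-drop ladder, recording every applicable reason.

    Boundaries are strict: mtCN exactly at the floor and contamination
    exactly at the ceiling are kept.
    """
    out = []
    for rec in records:
        reasons: list[str] = []
        if rec.mtcn is None or rec.contamination is None:
            reasons.append("incomplete")
        else:
            if rec.mtcn < mtcn_floor:
                reasons.append(f"mtCN<{mtcn_floor:g}")
            if rec.contamination > contamination_ceiling:
                reasons.append(f"contamination>{contamination_ceiling:g}")
        if rec.homoplasmy_overlap:
            reasons.append("homoplasmy_overlap")
        if rec.processing_year is not None and rec.processing_year in excluded_years:
            reasons.append(f"processing_year_{rec.processing_year}")
        rec.drop_reasons = reasons
        out.append(rec)
    return out


def detect_homoplasmy_overlap(calls: Sequence[VariantCall]) -> bool:
    """Two distinct non-reference alleles at one site each with fraction
    >= 0.5 — evidence of sample mixture."""
    per_site: dict[tuple[str, int], int] = {}
    for c in calls:
        if c.heteroplasmy >= 0.5:
            key = (c.contig, c.pos)
            per_site[key] = per_site.get(key, 0) + 1
    return any(n >= 2 for n in per_site.values())


# ---------------------------------------------------------------------------
# Heteroplasmy matrix
# ---------------------------------------------------------------------------

class HeteroplasmyMatrix:
    """Samples x variants matrix of QC'ed cell states.

    Backed by two aligned DataFrames: ``state`` (strings) and ``fraction``
    (floats; NaN where undefined).  States are mutually exclusive.
    """

    def __init__(self, state: pd.DataFrame, fraction: pd.DataFrame):
        if not state.index.equals(fraction.index) or not state.columns.equals(
            fraction.columns
        ):
            raise ValueError("state and fraction frames must be aligned")
        self.state = state
        self.fraction = fraction

    @classmethod
    def from_sample_states(
        cls, cells: Mapping[str, Mapping[str, CellState]]
    ) -> "HeteroplasmyMatrix":
        """Build from {sample_id: {variant_id: CellState}}."""
        samples = sorted(cells)
        variants = sorted({v for d in cells.values() for v in d})
        state = pd.DataFrame(MISSING, index=samples, columns=variants, dtype=object)
        frac = pd.DataFrame(np.nan, index=samples, columns=variants, dtype=float)
        for s, d in cells.items():
            for v, cell in d.items():
                state.loc[s, v] = cell.state
                if cell.fraction is not None:
                    frac.loc[s, v] = cell.fraction
        return cls(state, frac)

    @property
    def samples(self) -> list[str]:
        return list(self.state.index)

    @property
    def variants(self) -> list[str]:
        return list(self.state.columns)

    def drop_samples(self, sample_ids: Iterable[str]) -> "HeteroplasmyMatrix":
        keep = [s for s in self.samples if s not in set(sample_ids)]
        return HeteroplasmyMatrix(
            self.state.loc[keep].copy(), self.fraction.loc[keep].copy()
        )

    def carriers(self, variant: str) -> pd.Series:
        """Heteroplasmic fractions of carrier samples for one variant."""
        mask = self.state[variant] == HETEROPLASMIC
        return self.fraction.loc[mask, variant]

    # -- serialization (sparse long TSV) ----------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s in self.samples:
            for v in self.variants:
                st = self.state.loc[s, v]
                if st == MISSING:
                    continue
                fr = self.fraction.loc[s, v]
                rows.append((s, v, st, "" if pd.isna(fr) else f"{fr:.6g}"))
        with open(path, "w") as fh:
            fh.write("sample\tvariant\tstate\tfraction\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HeteroplasmyMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"fraction": float})
        cells: dict[str, dict[str, CellState]] = {}
        for _, row in df.iterrows():
            fr = None if pd.isna(row["fraction"]) else float(row["fraction"])
            cells.setdefault(str(row["sample"]), {})[str(row["variant"])] = CellState(
                row["state"], fr
            )
        return cls.from_sample_states(cells)


def annotate_common_low_het(
    matrix: HeteroplasmyMatrix, min_rate: float = 0.001
) -> set[str]:
    """Variants where >= ``min_rate`` of samples passing filters show a
    heteroplasmy strictly between 0 and 0.5."""
    if not matrix.samples:
        raise ValueError("empty matrix")
    n = len(matrix.samples)
    flagged = set()
    for v in matrix.variants:
        frac = matrix.fraction[v]
        het = matrix.state[v] == HETEROPLASMIC
        count = int(((frac > 0.0) & (frac < 0.5) & het).sum())
        if count / n >= min_rate:
            flagged.add(v)
    return flagged


def define_common_heteroplasmies(
    matrix: HeteroplasmyMatrix,
    flagged: set[str] | None = None,
    min_carriers: int = 500,
) -> list[str]:
    """Common-low-heteroplasmy variants carried heteroplasmically by at
    least ``min_carriers`` samples."""
    if flagged is None:
        flagged = annotate_common_low_het(matrix)
    out = []
    for v in sorted(flagged):
        n_carriers = int((matrix.state[v] == HETEROPLASMIC).sum())
        if n_carriers >= min_carriers:
            out.append(v)
    return out


def ad_alt_filter(
    calls: Sequence[VariantCall], nuc_mean: float
) -> list[tuple[VariantCall, bool]]:
    """Sensitivity filter: mask calls whose alternate allele depth is below
    the sample's mean nuclear coverage (strict <).  Returns (call, masked)
    pairs."""
    out = []
    for c in calls:
        if c.alt_depth is None:
            raise ValueError(f"call {c.variant_id} has no AD")
        out.append((c, c.alt_depth < nuc_mean))
    return out


def write_qc_report(records: Sequence[SampleQCRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmtCN\tcontamination\tkept\treasons\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t"
                f"{'' if r.mtcn is None else f'{r.mtcn:.4g}'}\t"
                f"{'' if r.contamination is None else f'{r.contamination:.4g}'}\t"
                f"{int(r.kept)}\t{';'.join(r.drop_reasons)}\n"
            )
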