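"""Poly-C length-heteroplasmy genotyping at the CSBII chrM:302 locus.

The reference CSBII motif on the forward strand reads
``AA CCCCCCC T CCCCC GC`` — two poly-C tracts separated by one spacer base,
flanked by two constant base pairs on each side.  In opposite-strand
nomenclature this is G\\ :sub:`m`\\ AG\\ :sub:`n`; the reference is
G\\ :sub:`m`\\ AG\\ :sub:`7`, and the common insertion alleles
chrM:302:A,AC / A,ACC / A,ACCC extend the 302-adjacent run to 8 / 9 / 10.
The variable ("n") tract is therefore the *first* C-run in forward
orientation, the one anchored at position 302.

Reads are classified by the regular expression ``AA(CCC+[CT]CC+)GC``: a
first C-run of >= 3, a single C/T spacer, a second C-run of >= 2.  When the
spacer itself is a C the whole tract is a single homopolymer and the split
is ambiguous; the regex's greedy semantics then yield the canonical
decomposition (longest first run, second run of exactly 2), which preserves
the total tract length.  Reads that do not match are classified NA.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .caller import AlignedRead
from .reference import GenomicInterval
from .variants import VariantCall

#: anchored on the two constant bp on either side of the variant region
TRACT_RE = re.compile(r"AA(C{3,})([CT])(C{2,})GC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: allele labels for the named length classes
REFERENCE_LABEL = "reference"
OTHER_LABEL = "other"
NA_LABEL = "NA"

_ALLELE_BY_RUN = {
    7: REFERENCE_LABEL,
    8: "chrM:302:A,AC",
    9: "chrM:302:A,ACC",
    10: "chrM:302:A,ACCC",
}

NAMED_ALLELES = (REFERENCE_LABEL, "chrM:302:A,AC", "chrM:302:A,ACC", "chrM:302:A,ACCC")


def allele_class_from_tracts(run_302: int) -> str:
    """Map the 302-adjacent tract length to its allele label: 7 is the
    reference, 8/9/10 the A,AC / A,ACC / A,ACCC insertions, anything else
    ``other``."""
    if run_302 < 3:
        raise ValueError("run_302 below the regex minimum of 3")
    return _ALLELE_BY_RUN.get(run_302, OTHER_LABEL)


@dataclass(frozen=True)
class TractCall:
    run_302: int  # length of the C-run anchored at position 302 ("G_n")
    spacer: str  # single base in {C, T}
    run_m: int  # length of the second C-run ("G_m")

    def __post_init__(self) -> None:
        if self.run_302 < 3 or self.run_m < 2:
            raise ValueError("tract lengths below regex minimums")
        if self.spacer not in ("C", "T"):
            raise ValueError(f"spacer must be C or T, got {self.spacer!r}")

    @property
    def allele_label(self) -> str:
        return allele_class_from_tracts(self.run_302)

    @property
    def variant_key(self) -> tuple[int, int]:
        """(run_m, run_302) — the G_mAG_n identity of the tract."""
        return (self.run_m, self.run_302)


def classify_read_tracts(
    read: AlignedRead, locus: GenomicInterval, contig_length: int | None = None
) -> TractCall | None:
    """Classify one locus-spanning read's CSBII tract structure.

    The read must completely span the locus interval (chrM:300-318 at
    reference scale); the caller is expected to pre-filter.  Reverse-strand
    alignments are reverse-complemented so the pattern is always applied to
    the forward strand.  Returns None (NA) for non-matching reads.
    """
    L = contig_length or max(read.left_pos + len(read.sequence), locus.end)
    if not read.spans(locus.start, locus.end, L):
        raise ValueError(
            f"read {read.read_id} does not span {locus.start}-{locus.end}"
        )
    seq = read.sequence
    if read.is_reverse:
        seq = seq.translate(_COMPLEMENT)[::-1]
    m = TRACT_RE.search(seq)
    if m is None:
        return None
    return TractCall(run_302=len(m.group(1)), spacer=m.group(2), run_m=len(m.group(3)))


# ---------------------------------------------------------------------------
# Composition profiles
# ---------------------------------------------------------------------------

@dataclass
class CompositionProfile:
    """Fractions over the length-variant classes for one unit (sample or
    cell), with supporting counts.  Fractions are non-negative and sum to 1."""

    unit_id: str
    fractions: dict[str, float]
    support: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("negative fraction")


def _variant_name(key: tuple[int, int]) -> str:
    return f"G{key[0]}AG{key[1]}"


def cell_length_profiles(
    reads: Sequence[AlignedRead],
    locus: GenomicInterval,
    cell_whitelist: set[str],
    min_reads: int = 20,
    contig_length: int | None = None,
    top_variants: Sequence[tuple[int, int]] | None = None,
) -> dict[str, CompositionProfile]:
    """Per-cell composition over the top three most common length variants.

    Reads with non-whitelisted (or absent) barcodes are dropped; cells with
    fewer than ``min_reads`` locus-spanning reads are excluded.  Fractions
    are computed over the three globally most common (run_m, run_302)
    variants plus an aggregated ``other`` that includes NA-classified
    (non-matching) reads.  Pass ``top_variants`` to fix the named classes,
    e.g. [(6, 8), (6, 9), (6, 10)].
    """
    if not cell_whitelist:
        raise ValueError("empty cell whitelist")
    per_cell: dict[str, list[TractCall | None]] = {}
    for read in reads:
        if read.cell_barcode is None or read.cell_barcode not in cell_whitelist:
            continue
        L = contig_length or max(read.left_pos + len(read.sequence), locus.end)
        if not read.spans(locus.start, locus.end, L):
            continue
        call = classify_read_tracts(read, locus, L)
        per_cell.setdefault(read.cell_barcode, []).append(call)

    retained = {
        cell: calls for cell, calls in per_cell.items() if len(calls) >= min_reads
    }
    if top_variants is None:
        global_counts: Counter = Counter()
        for calls in retained.values():
            for c in calls:
                if c is not None:
                    global_counts[c.variant_key] += 1
        top_variants = [key for key, _ in global_counts.most_common(3)]
    top = list(top_variants)

    profiles: dict[str, CompositionProfile] = {}
    for cell, calls in sorted(retained.items()):
        counts: dict[str, int] = {_variant_name(k): 0 for k in top}
        counts[OTHER_LABEL] = 0
        for c in calls:
            if c is not None and c.variant_key in top:
                counts[_variant_name(c.variant_key)] += 1
            else:
                counts[OTHER_LABEL] += 1
        total = sum(counts.values())
        fractions = {k: v / total for k, v in counts.items()}
        profiles[cell] = CompositionProfile(cell, fractions, counts)
    return profiles


def bulk_profile(
    cell_profiles: Mapping[str, CompositionProfile], unit_id: str = "bulk"
) -> CompositionProfile:
    """Pseudobulk composition: sum the allele counts from the retained
    high-coverage cells and recompute fractions."""
    if not cell_profiles:
        raise ValueError("no retained cells")
    counts: dict[str, int] = {}
    for prof in cell_profiles.values():
        for k, v in prof.support.items():
            counts[k] = counts.get(k, 0) + v
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero total count across cells")
    return CompositionProfile(unit_id, {k: v / total for k, v in counts.items()}, counts)


def composition_from_calls(
    sample_calls: Sequence[VariantCall],
    locus_depth: float,
    unit_id: str = "sample",
    min_depth: float = 100.0,
) -> CompositionProfile | None:
    """Per-sample chrM:302 composition from post-QC variant calls.

    Samples with locus depth < ``min_depth`` are excluded (None).  The
    reference fraction is ``1 - sum(heteroplasmy of any allele at the
    locus)``, floored at 0 (with renormalization if flooring triggers);
    missing allele fractions are imputed as 0, and all alleles other than
    the named A,AC / A,ACC / A,ACCC classes pool into ``other``.  A sample
    with no calls is assigned a reference fraction of 1.
    """
    if locus_depth < min_depth:
        return None
    fractions = {label: 0.0 for label in NAMED_ALLELES}
    fractions[OTHER_LABEL] = 0.0
    total = 0.0
    for call in sample_calls:
        frac = call.heteroplasmy
        total += frac
        vid = call.variant_id
        if vid in fractions:
            fractions[vid] += frac
        else:
            fractions[OTHER_LABEL] += frac
    if total > 1.0 + 1e-6:
        raise ValueError(f"allele fractions at the locus sum to {total} > 1")
    fractions[REFERENCE_LABEL] = max(0.0, 1.0 - total)
    norm = sum(fractions.values())
    if abs(norm - 1.0) > 1e-12:  # flooring triggered
        fractions = {k: v / norm for k, v in fractions.items()}
    support = {k: int(round(v * locus_depth)) for k, v in fractions.items()}
    return CompositionProfile(unit_id, fractions, support)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_barcode_whitelist(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_profiles_tsv(
    profiles: Mapping[str, CompositionProfile], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tvariant\tfraction\tcount\n")
        for unit in sorted(profiles):
            prof = profiles[unit]
            for k in sorted(prof.fractions):
                fh.write(
                    f"{unit}\t{k}\t{prof.fractions[k]:.6g}\t{prof.support.get(k, '')}\n"
                )
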