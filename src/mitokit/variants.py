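"""Variant-call container, allele normalization, and VCF I/O.

A call carries the heteroplasmy fraction (AF), total depth (DP), alternate
allele depth (AD), and a set of filter flags (FT).  Alleles are normalized
to VCF conventions: shared suffix/prefix trimmed and indels left-aligned in
homopolymer context so that, e.g., poly-C insertions at chrM:302 are
anchored consistently across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .reference import CircularGenome


class NormalizationError(ValueError):
    """Raised when allele composition yields an empty allele."""


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    heteroplasmy: float
    depth: int = 0  # DP
    alt_depth: int = 0  # AD of the alternate allele
    filters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise NormalizationError(
                f"empty allele at {self.contig}:{self.pos} ({self.ref!r}>{self.alt!r})"
            )
        if not 0.0 <= self.heteroplasmy <= 1.0 + 1e-9:
            raise ValueError(
                f"heteroplasmy {self.heteroplasmy} outside [0, 1] at {self.pos}"
            )
        if self.depth and not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"AD {self.alt_depth} outside [0, DP={self.depth}] at {self.pos}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref},{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def qc_pass(self) -> bool:
        return not self.filters or self.filters == {"PASS"}


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim shared suffix then shared prefix, keeping >= 1 base."""
    if not ref or not alt:
        raise NormalizationError("cannot trim empty allele")
    # suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    genome: "CircularGenome", pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align a pure insertion or deletion through a homopolymer run.

    Alleles must already be trimmed to the anchored VCF form (one allele is
    a prefix of the other).  Substitutions pass through unchanged.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if len(ref) == len(alt):
        return pos, ref, alt
    while pos > 1:
        if ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                prev = genome.base_at(pos)
                ref, alt = prev + ref, prev + alt
            continue
        break
    return trim_alleles(pos, ref, alt)


def normalize_call(genome: "CircularGenome", call: VariantCall) -> VariantCall:
    pos, ref, alt = left_align(genome, call.pos, call.ref, call.alt)
    if (pos, ref, alt) == (call.pos, call.ref, call.alt):
        return call
    return replace(call, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# VCF I/O (AF / DP / AD / FT as FORMAT fields on a single sample)
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    contig: str,
    contig_length: int,
    sample: str = "SAMPLE",
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line(
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Heteroplasmy fraction">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt allele depth">'
    )
    header.add_line('##FORMAT=<ID=FT,Number=1,Type=String,Description="Filters">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.pos, c.ref, c.alt)):
            rec = vcf.new_record(
                contig=call.contig,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            rec.samples[sample]["AF"] = float(call.heteroplasmy)
            rec.samples[sample]["DP"] = int(call.depth)
            rec.samples[sample]["AD"] = int(call.alt_depth)
            rec.samples[sample]["FT"] = (
                ";".join(sorted(call.filters)) if call.filters else "PASS"
            )
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    import pysam

    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            fmt = rec.samples[samples[0]] if samples else {}
            ft = fmt.get("FT") if samples else None
            filters = (
                frozenset()
                if ft in (None, "PASS", ".")
                else frozenset(str(ft).split(";"))
            )
            for alt in rec.alts or ():
                out.append(
                    VariantCall(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        heteroplasmy=float(fmt.get("AF", 0.0) or 0.0),
                        depth=int(fmt.get("DP", 0) or 0),
                        alt_depth=int(fmt.get("AD", 0) or 0),
                        filters=filters,
                    )
                )
    return out
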