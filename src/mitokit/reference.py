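"""Circular reference-genome model, shifted-genome construction, NUMT
interval preparation, and the control-region catalog.

Coordinates are 1-based inclusive throughout (matching VCF/SAM); BED I/O
converts from 0-based half-open at the boundary.  Position arithmetic on a
circular contig is modular in the contig length, and an interval with
``start > end`` wraps through the linearization origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID_BASES = frozenset("ACGTN")


class MalformedIntervalError(ValueError):
    """Raised for an interval with start > end on a linear contig."""


class ConfigError(ValueError):
    """Raised when a region configuration is inconsistent with the genome."""


@dataclass(frozen=True)
class CircularGenome:
    """A single circular contig (the mtDNA molecule).

    Parameters
    ----------
    contig_name : str
        Contig name, e.g. ``"chrM"``.
    sequence : str
        Base string over {A, C, G, T, N}; its length defines the contig
        length ``L``.  Positions are 1-based in ``[1, L]``.
    """

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"sequence contains invalid bases: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        """Base at a (modularly wrapped) 1-based position."""
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Wrap-aware slice, 1-based inclusive on both ends."""
        L = self.length
        s = (start - 1) % L
        e = (end - 1) % L
        if s <= e:
            return self.sequence[s : e + 1]
        return self.sequence[s:] + self.sequence[: e + 1]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; wraps iff start > end on a circular contig."""

    contig: str
    start: int
    end: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise MalformedIntervalError(
                f"interval positions must be >= 1: {self.contig}:{self.start}-{self.end}"
            )
        if not self.circular and self.start > self.end:
            raise MalformedIntervalError(
                f"start > end on linear contig {self.contig}: {self.start}-{self.end}"
            )

    @property
    def wraps(self) -> bool:
        return self.circular and self.start > self.end

    def length(self, contig_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if contig_length is None:
            raise ValueError("contig_length required for a wrapping interval")
        return contig_length - self.start + 1 + self.end

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def positions(self, contig_length: int | None = None) -> list[int]:
        """All covered 1-based positions, in 5'->3' order along the contig."""
        if not self.wraps:
            return list(range(self.start, self.end + 1))
        if contig_length is None:
            raise ValueError("contig_length required for a wrapping interval")
        return list(range(self.start, contig_length + 1)) + list(
            range(1, self.end + 1)
        )


# ---------------------------------------------------------------------------
# NUMT interval preparation
# ---------------------------------------------------------------------------

def prepare_numt_intervals(
    intervals: Sequence[GenomicInterval],
    pad: int = 500,
    contig_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Pad nuclear NUMT intervals and merge overlapping or touching ones.

    Each interval is extended by ``pad`` bases on both sides, clipped to
    ``[1, contig length]`` when the length is known, and intervals that
    overlap or touch (gap 0) on the same contig are merged.  Output is
    sorted by contig then start.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded: list[GenomicInterval] = []
    for iv in intervals:
        if iv.circular:
            raise MalformedIntervalError(
                "NUMT intervals must lie on linear nuclear contigs"
            )
        start = max(1, iv.start - pad)
        end = iv.end + pad
        if contig_lengths and iv.contig in contig_lengths:
            end = min(end, contig_lengths[iv.contig])
        padded.append(GenomicInterval(iv.contig, start, end))

    padded.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in padded:
        if (
            merged
            and merged[-1].contig == iv.contig
            and iv.start <= merged[-1].end + 1
        ):
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.contig, prev.start, max(prev.end, iv.end)
            )
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# Shifted genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftMap:
    """Bijective position maps between an original and a shifted circular genome."""

    length: int
    shift: int

    def to_shifted(self, pos: int) -> int:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        return ((pos - self.shift - 1) % self.length) + 1

    def to_original(self, pos: int) -> int:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        return ((pos + self.shift - 1) % self.length) + 1


def build_shifted_genome(
    g: CircularGenome, shift: int | None = None
) -> tuple[CircularGenome, ShiftMap]:
    """Rotate a circular genome so the shifted sequence begins at original
    position ``shift + 1``.

    The shifted molecule exists because linear aligners depress coverage at
    the two linearization breakpoints; calling the control region against a
    rotated molecule moves those breakpoints far away.  Default shift is
    ``floor(L / 2)``, which maximally separates the breakpoints.
    """
    L = g.length
    if shift is None:
        shift = L // 2
    if not 0 <= shift < L:
        raise ValueError(f"shift must be in [0, {L}), got {shift}")
    shifted_seq = g.sequence[shift:] + g.sequence[:shift]
    shifted = CircularGenome(g.contig_name, shifted_seq)
    return shifted, ShiftMap(length=L, shift=shift)


# ---------------------------------------------------------------------------
# Region catalog
# ---------------------------------------------------------------------------

#: Default mtDNA non-coding-region coordinates (rCRS annotations; all
#: overridable through :func:`region_catalog_default`).  The control region
#: wraps the linearization origin.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "control_region": (16024, 576),
    "CSBII": (299, 315),
    "CSBIII": (346, 363),
    "LSP": (392, 445),
    "origin_heavy": (110, 191),
    "7s_dna": (16106, 191),
    "locus_302": (300, 318),
}


@dataclass
class RegionCatalog:
    """Named non-coding mtDNA regions used for calling and coverage traits.

    Derived members: the DNA-primer region lies between CSBII and the
    heavy-strand origin (the transient replication flap), the RNA-primer
    region lies between CSBIII and the LSP, and ``7s_dna_first_third`` is
    the first third (rounded down) of the 7s-DNA span counted from the
    boundary nearer the wrap origin.
    """

    contig: str
    contig_length: int
    regions: dict[str, GenomicInterval] = field(default_factory=dict)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return sorted(self.regions)

    def in_region(self, name: str, pos: int) -> bool:
        return self.regions[name].contains(pos)


def _between(
    left: GenomicInterval, right: GenomicInterval, contig: str, L: int
) -> GenomicInterval:
    """Open interval between the end of ``left`` and the start of ``right``
    along the forward direction of the circle."""
    start = left.end % L + 1
    end = (right.start - 2) % L + 1
    return GenomicInterval(contig, start, end, circular=True)


def _first_third(span: GenomicInterval, L: int) -> GenomicInterval:
    """First third (floor) of a span, counted from the boundary nearer the
    linearization origin; for a wrapping span that boundary is the end
    nearer the L|1 junction, walking backwards into the span."""
    positions = span.positions(L)
    n = len(positions) // 3
    if span.wraps:
        # distance of each boundary from the junction
        d_start = L - span.start + 1
        d_end = span.end
        if d_end <= d_start:
            chosen = positions[-n:]
        else:
            chosen = positions[:n]
    else:
        chosen = positions[:n]
    start, end = chosen[0], chosen[-1]
    return GenomicInterval(span.contig, start, end, circular=True)


def region_catalog_default(
    g: CircularGenome, config: dict[str, tuple[int, int]] | None = None
) -> RegionCatalog:
    """Build the region catalog from packaged defaults or an override config.

    ``config`` maps region names to (start, end) 1-based inclusive pairs;
    any name absent from the config falls back to the packaged default.
    Derived regions (DNA primer, RNA primer, 7s first third) are computed.
    """
    L = g.length
    # packaged defaults apply only where they fit the genome (a toy genome
    # shorter than the mtDNA drops out-of-range defaults); explicit config
    # entries are validated strictly
    coords = {
        name: (s, e)
        for name, (s, e) in DEFAULT_REGIONS.items()
        if 1 <= s <= L and 1 <= e <= L
    }
    if config:
        coords.update(config)
    catalog = RegionCatalog(contig=g.contig_name, contig_length=L)
    for name, (start, end) in coords.items():
        if not (1 <= start <= L and 1 <= end <= L):
            raise ConfigError(
                f"region {name} ({start}-{end}) outside genome bounds [1, {L}]"
            )
        catalog.regions[name] = GenomicInterval(
            g.contig_name, start, end, circular=True
        )
    if all(n in catalog for n in ("origin_heavy", "CSBII")):
        catalog.regions["dna_primer"] = _between(
            catalog["origin_heavy"], catalog["CSBII"], g.contig_name, L
        )
    if all(n in catalog for n in ("CSBIII", "LSP")):
        catalog.regions["rna_primer"] = _between(
            catalog["CSBIII"], catalog["LSP"], g.contig_name, L
        )
    if "7s_dna" in catalog:
        catalog.regions["7s_dna_first_third"] = _first_third(catalog["7s_dna"], L)

    spans = {
        name: set(catalog[name].positions(L))
        for name in ("dna_primer", "rna_primer", "7s_dna_first_third")
        if name in catalog
    }
    names = list(spans)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if spans[names[i]] & spans[names[j]]:
                raise ConfigError(
                    f"regions {names[i]} and {names[j]} overlap; "
                    "adjust the region config"
                )
    return catalog


# ---------------------------------------------------------------------------
# I/O: FASTA, BED, region config
# ---------------------------------------------------------------------------

def read_fasta_genome(path: str | Path) -> CircularGenome:
    """Read a single-contig FASTA; circularity is annotated via a
    ``circular=true`` token in the header."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one contig, found {len(records)}")
    rec = records[0]
    return CircularGenome(rec.id, str(rec.seq))


def write_fasta_genome(g: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{g.contig_name} circular=true length={g.length}\n")
        for i in range(0, g.length, width):
            fh.write(g.sequence[i : i + width] + "\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open on disk) into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            out.append(GenomicInterval(contig, start + 1, end))
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\n")


_REGION_LINE = re.compile(r"^(\w+)\s*=\s*([\w.]+):(\d+)-(\d+)$")


def read_region_config(path: str | Path) -> dict[str, tuple[int, int]]:
    """Plain-text region config: one ``name = contig:start-end`` per line."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _REGION_LINE.match(line)
            if not m:
                raise ConfigError(f"cannot parse region line: {line!r}")
            out[m.group(1)] = (int(m.group(3)), int(m.group(4)))
    return out


def write_region_config(catalog: RegionCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in catalog.names():
            iv = catalog[name]
            fh.write(f"{name} = {iv.contig}:{iv.start}-{iv.end}\n")
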