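"""Pileup-based heteroplasmy estimation from aligned reads.

This is a deliberately simple caller: reads are placed competitively
against the mtDNA consensus and NUMT decoy sequences by exact k-mer seeding
plus ungapped extension, piled up with modular (circular) coordinates, and
variants emitted wherever at least ``min_alt_reads`` reads support an
alternate allele.  All fraction thresholds are applied downstream during
post-calling QC.  Control-region calls come from a second pass against a
rotated (shifted) molecule, because linear alignment depresses coverage at
the two linearization breakpoints.

Also houses the coverage/copy-number arithmetic: mean autosomal coverage
from flagstat-style read counts, and mtDNA copy number as
``2 * (mean or median mtDNA coverage) / mean nuclear coverage``.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import CircularGenome, RegionCatalog, ShiftMap
from .variants import VariantCall, normalize_call

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class MalformedReadError(ValueError):
    """CIGAR-consumed query length disagrees with the read sequence."""


@dataclass
class AlignedRead:
    read_id: str
    contig: str
    left_pos: int  # 1-based leftmost aligned reference position
    cigar: str
    sequence: str
    base_qualities: list[int] | None = None
    flags: frozenset[str] = field(default_factory=frozenset)
    cell_barcode: str | None = None
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.base_qualities is None:
            self.base_qualities = [40] * len(self.sequence)
        consumed = sum(
            int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in "MIS=X"
        )
        if consumed != len(self.sequence):
            raise MalformedReadError(
                f"read {self.read_id}: cigar consumes {consumed} query bases, "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def usable(self) -> bool:
        return not (self.flags & {"duplicate", "secondary", "unmapped"})

    def reference_span(self) -> int:
        return sum(
            int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in "MDN=X"
        )

    def spans(self, start: int, end: int, contig_length: int) -> bool:
        """True if the alignment completely covers [start, end] (wrap-aware
        through the interval, not the read: reads use modular coordinates)."""
        span = self.reference_span()
        covered = {
            ((self.left_pos - 1 + i) % contig_length) + 1 for i in range(span)
        }
        if start <= end:
            need = set(range(start, end + 1))
        else:
            need = set(range(start, contig_length + 1)) | set(range(1, end + 1))
        return need <= covered


# ---------------------------------------------------------------------------
# Competitive placement against mtDNA + NUMT decoys
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int, circular: bool) -> dict[str, list[int]]:
    s = seq + seq[: k - 1] if circular else seq
    index: dict[str, list[int]] = defaultdict(list)
    n = len(seq) if circular else len(seq) - k + 1
    for i in range(max(0, n)):
        index[s[i : i + k]].append(i)
    return index


def _target_array(seq: str, circular: bool, pad: int) -> np.ndarray:
    """Byte array of the target, doubled far enough that any in-range
    window of length ``pad`` can be sliced without wrapping."""
    s = seq + seq[:pad] if circular else seq
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _count_mismatches(
    read_arr: np.ndarray, target_arr: np.ndarray, offset: int, L: int, circular: bool
) -> int | None:
    n = read_arr.shape[0]
    if circular:
        offset %= L
    elif offset < 0 or offset + n > L:
        return None
    window = target_arr[offset : offset + n]
    return int(np.count_nonzero(window != read_arr))


@dataclass
class PlacementTarget:
    name: str
    genome: CircularGenome
    circular: bool = True
    is_decoy: bool = False


def place_reads(
    reads: Sequence[AlignedRead],
    targets: Sequence[PlacementTarget],
    k: int = 21,
) -> list[AlignedRead]:
    """Assign each read to the target giving the fewest mismatches under
    exact k-mer seeding plus ungapped extension.

    Ties are assigned to the NUMT decoy (conservative against false
    heteroplasmy); unplaceable reads are flagged unmapped.  Returned reads
    carry the winning target's contig name and alignment position.
    """
    if not targets:
        raise ValueError("empty target set")
    mt = [t for t in targets if not t.is_decoy]
    if len(mt) != 1:
        raise ValueError("targets must include exactly one mtDNA consensus")
    indexes = {t.name: _kmer_index(t.genome.sequence, k, t.circular) for t in targets}
    max_read = max((len(r.sequence) for r in reads), default=0)
    arrays = {
        t.name: _target_array(t.genome.sequence, t.circular, max_read)
        for t in targets
    }
    placed: list[AlignedRead] = []
    for read in reads:
        read_arr = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        best: tuple[int, int, str, int] | None = None  # (mism, decoy_rank, name, offset)
        for t in targets:
            idx = indexes[t.name]
            seen_offsets: set[int] = set()
            for si in range(0, max(1, len(read.sequence) - k + 1), k):
                seed = read.sequence[si : si + k]
                if len(seed) < k:
                    break
                for hit in idx.get(seed, ()):
                    offset = hit - si
                    if t.circular:
                        offset %= t.genome.length
                    if offset in seen_offsets:
                        continue
                    seen_offsets.add(offset)
                    mism = _count_mismatches(
                        read_arr, arrays[t.name], offset, t.genome.length, t.circular
                    )
                    if mism is None:
                        continue
                    # decoy wins ties: rank decoys lower
                    cand = (mism, 0 if t.is_decoy else 1, t.name, offset)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            placed.append(
                replace(read, flags=read.flags | {"unmapped"})
            )
            continue
        mism, _, name, offset = best
        placed.append(
            replace(
                read,
                contig=name,
                left_pos=offset + 1,
                cigar=f"{len(read.sequence)}M",
            )
        )
    return placed


# ---------------------------------------------------------------------------
# Pileup and variant emission
# ---------------------------------------------------------------------------

def pileup_and_call(
    reads: Sequence[AlignedRead],
    g: CircularGenome,
    min_base_quality: int = 20,
    min_alt_reads: int = 2,
) -> tuple[np.ndarray, list[VariantCall]]:
    """Pile reads up on ``g`` with modular coordinates and emit variant calls.

    Depth excludes duplicate/secondary/unmapped reads and bases below
    ``min_base_quality``.  SNV fraction is alt count / depth; insertions and
    deletions are parsed from the CIGAR and left-aligned.  A call is emitted
    whenever the alternate is supported by >= ``min_alt_reads`` reads; all
    fraction thresholds belong to downstream QC.
    """
    L = g.length
    depth = np.zeros(L, dtype=int)
    # vectorized base tally: rows are positions, columns index A/C/G/T/N
    base_order = "ACGTN"
    base_lut = np.full(256, 4, dtype=np.int8)  # unknown bases fall in the N bucket
    for bi, b in enumerate(base_order):
        base_lut[ord(b)] = bi
    counts = np.zeros((L, 5), dtype=np.int64)
    indel_counts: dict[tuple[int, str, str], int] = Counter()

    def _tally(seq_chunk: str, quals: Sequence[int], rpos: int) -> None:
        n = len(seq_chunk)
        pos_idx = (np.arange(rpos - 1, rpos - 1 + n)) % L
        qual_ok = np.asarray(quals[:n]) >= min_base_quality
        bases = base_lut[np.frombuffer(seq_chunk.encode(), dtype=np.uint8)]
        np.add.at(depth, pos_idx[qual_ok], 1)
        np.add.at(counts, (pos_idx[qual_ok], bases[qual_ok]), 1)

    for read in reads:
        if not read.usable or read.contig != g.contig_name:
            continue
        qpos = 0
        rpos = read.left_pos
        for n_str, op in _CIGAR_RE.findall(read.cigar):
            n = int(n_str)
            if op in "M=X":
                _tally(
                    read.sequence[qpos : qpos + n],
                    read.base_qualities[qpos : qpos + n],
                    rpos,
                )
                qpos += n
                rpos += n
            elif op == "I":
                anchor = ((rpos - 2) % L) + 1
                ins = read.sequence[qpos : qpos + n]
                ref_a = g.base_at(anchor)
                indel_counts[(anchor, ref_a, ref_a + ins)] += 1
                qpos += n
            elif op == "D":
                anchor = ((rpos - 2) % L) + 1
                ref_a = g.base_at(anchor)
                deleted = g.fetch(rpos, rpos + n - 1)
                indel_counts[(anchor, ref_a + deleted, ref_a)] += 1
                rpos += n
            elif op == "S":
                qpos += n
            elif op == "N":
                rpos += n
            # H and P consume nothing we track

    calls: list[VariantCall] = []
    ref_idx = base_lut[np.frombuffer(g.sequence.encode(), dtype=np.uint8)]
    alt_mask = counts[:, :4] >= min_alt_reads
    acgt_rows = np.nonzero(ref_idx < 4)[0]
    alt_mask[acgt_rows, ref_idx[acgt_rows]] = False
    for p0, bi in zip(*np.nonzero(alt_mask)):
        site_depth = int(depth[p0])
        n = int(counts[p0, bi])
        if site_depth == 0:
            continue
        ref_base = g.base_at(int(p0) + 1)
        if base_order[bi] == ref_base:
            continue
        calls.append(
            VariantCall(
                contig=g.contig_name,
                pos=int(p0) + 1,
                ref=ref_base,
                alt=base_order[bi],
                heteroplasmy=min(1.0, n / site_depth),
                depth=site_depth,
                alt_depth=min(n, site_depth),
            )
        )
    for (anchor, ref_allele, alt_allele), n in sorted(indel_counts.items()):
        if n < min_alt_reads:
            continue
        site_depth = int(depth[anchor - 1])
        if site_depth == 0:
            continue
        n = min(n, site_depth)
        call = VariantCall(
            contig=g.contig_name,
            pos=anchor,
            ref=ref_allele,
            alt=alt_allele,
            heteroplasmy=n / site_depth,
            depth=site_depth,
            alt_depth=n,
        )
        calls.append(normalize_call(g, call))
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return depth, calls


def dual_pass_merge(
    calls_primary: Sequence[VariantCall],
    calls_shifted: Sequence[VariantCall],
    catalog: RegionCatalog,
    shift_map: ShiftMap,
) -> list[VariantCall]:
    """Merge primary-pass and shifted-pass calls into reference coordinates.

    Shifted calls are lifted back through the rotation; calls inside the
    control region are taken exclusively from the shifted pass, everything
    else exclusively from the primary pass, so no position can appear from
    both passes.
    """
    cr = catalog["control_region"]
    merged = [c for c in calls_primary if not cr.contains(c.pos)]
    for c in calls_shifted:
        orig_pos = shift_map.to_original(c.pos)
        lifted = replace(c, pos=orig_pos)
        if cr.contains(lifted.pos):
            merged.append(lifted)
    merged.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return merged


# ---------------------------------------------------------------------------
# Coverage and copy-number formulas
# ---------------------------------------------------------------------------

def mean_nuc_coverage(
    total_mapped: int,
    singletons: int,
    mate_discordant: int,
    duplicates: int,
    read_length: int,
    genome_length: int,
) -> float:
    """Mean autosomal nuclear coverage from flagstat-style counts:
    ``(total mapped - singletons - discordant-mate reads - duplicates)
    * read length / genome length``, clamped at 0."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    for name, v in [
        ("total_mapped", total_mapped),
        ("singletons", singletons),
        ("mate_discordant", mate_discordant),
        ("duplicates", duplicates),
        ("read_length", read_length),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    usable = total_mapped - singletons - mate_discordant - duplicates
    if usable < 0:
        warnings.warn(
            "exclusion counts exceed total mapped reads; clamping coverage at 0",
            stacklevel=2,
        )
        usable = 0
    return usable * read_length / genome_length


def compute_mtcn(
    mt_coverage_summary: dict[str, float],
    nuc_mean: float,
    use_mean: bool = True,
) -> float:
    """mtDNA copies per diploid genome:
    ``2 * (mean or median mtDNA coverage) / mean nuclear coverage``.
    Defaults to the mean mtDNA coverage."""
    if nuc_mean <= 0:
        raise ValueError("nuc_mean must be positive")
    key = "mean" if use_mean else "median"
    return 2.0 * mt_coverage_summary[key] / nuc_mean


# ---------------------------------------------------------------------------
# I/O: SAM reading, coverage TSV
# ---------------------------------------------------------------------------

_FLAG_DUP = 0x400
_FLAG_SECONDARY = 0x100
_FLAG_UNMAPPED = 0x4
_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_MATE_UNMAPPED = 0x8


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read a SAM/BAM file into AlignedRead records.

    Duplicate = 0x400, secondary = 0x100, unmapped = 0x4; a singleton is a
    paired read whose mate is unmapped, and a discordant mate is a paired,
    mapped read pair that is not proper.  Cell barcodes come from the CB tag.
    """
    import pysam

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            flags: set[str] = set()
            if aln.flag & _FLAG_DUP:
                flags.add("duplicate")
            if aln.flag & _FLAG_SECONDARY:
                flags.add("secondary")
            if aln.flag & _FLAG_UNMAPPED:
                flags.add("unmapped")
            if aln.flag & _FLAG_PAIRED and aln.flag & _FLAG_MATE_UNMAPPED:
                flags.add("singleton")
            if (
                aln.flag & _FLAG_PAIRED
                and not aln.flag & _FLAG_PROPER
                and not aln.flag & _FLAG_MATE_UNMAPPED
                and not aln.flag & _FLAG_UNMAPPED
            ):
                flags.add("mate_discordant")
            reads.append(
                AlignedRead(
                    read_id=aln.query_name or "",
                    contig=aln.reference_name or "*",
                    left_pos=(aln.reference_start or 0) + 1,
                    cigar=aln.cigarstring or f"{aln.query_length}M",
                    sequence=aln.query_sequence or "",
                    base_qualities=(
                        list(aln.query_qualities)
                        if aln.query_qualities is not None
                        else None
                    ),
                    flags=frozenset(flags),
                    cell_barcode=(
                        aln.get_tag("CB") if aln.has_tag("CB") else None
                    ),
                    is_reverse=aln.is_reverse,
                )
            )
    return reads


def write_coverage_tsv(
    depth: Sequence[float] | np.ndarray, contig: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tdepth\n")
        for i, d in enumerate(np.asarray(depth), start=1):
            fh.write(f"{contig}\t{i}\t{d:g}\n")


def read_coverage_tsv(path: str | Path) -> tuple[str, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    return str(df["contig"].iloc[0]), df["depth"].to_numpy(dtype=float)
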