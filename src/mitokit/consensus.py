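"""Per-sample self-reference (consensus) construction and liftover.

A sample's consensus genome is the reference with its homoplasmic mtDNA
calls (and homozygous-alternate NUMT calls) applied as edits.  Variants are
then re-called against the consensus, and every call and per-base coverage
value must be returned to reference coordinates.  The :class:`CoordinateMap`
records the edits and supports exact, monotone position liftover in both
directions, with anchored results inside insertion/deletion footprints.

Within an edit that replaces a reference slice of length ``lr`` with an
alternate of length ``la``, the first ``min(lr, la)`` bases are aligned
positionally; surplus reference bases are "deleted" (they anchor to the
left flanking consensus base) and surplus alternate bases are "inserted"
(they anchor to the left flanking reference base).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .reference import CircularGenome
from .variants import NormalizationError, VariantCall, trim_alleles, left_align


class ReferenceMismatchError(ValueError):
    """A call's ref allele does not match the reference sequence."""


@dataclass(frozen=True)
class ConsensusEdit:
    position: int  # 1-based reference position
    ref_allele: str
    alt_allele: str
    source: Literal["mtDNA_homoplasmy", "nuclear_homozygous"] = "mtDNA_homoplasmy"
    source_fraction: float = 1.0

    @property
    def ref_end(self) -> int:
        return self.position + len(self.ref_allele) - 1

    def overlaps(self, other: "ConsensusEdit") -> bool:
        return self.position <= other.ref_end and other.position <= self.ref_end


def select_consensus_edits(
    calls: Sequence[VariantCall],
    genome: CircularGenome,
    het_threshold: float = 0.95,
) -> list[ConsensusEdit]:
    """Choose the calls that define a sample's self-reference.

    mtDNA calls with heteroplasmy >= ``het_threshold`` (homoplasmies) and
    nuclear calls at homozygous-alternate fraction become edits.  Overlapping
    candidates are resolved by keeping the higher fraction, then the
    leftmost; the result is sorted and non-overlapping.
    """
    if not 0.5 < het_threshold <= 1.0:
        raise ValueError("het_threshold must be in (0.5, 1]")
    candidates: list[ConsensusEdit] = []
    for call in calls:
        if call.heteroplasmy < het_threshold:
            continue
        on_mt = call.contig == genome.contig_name
        if on_mt:
            expected = genome.fetch(call.pos, call.pos + len(call.ref) - 1)
            if call.ref != expected:
                raise ReferenceMismatchError(
                    f"call ref {call.ref!r} at {call.pos} does not match "
                    f"reference {expected!r}"
                )
        candidates.append(
            ConsensusEdit(
                position=call.pos,
                ref_allele=call.ref,
                alt_allele=call.alt,
                source="mtDNA_homoplasmy" if on_mt else "nuclear_homozygous",
                source_fraction=call.heteroplasmy,
            )
        )
    # higher fraction wins an overlap; ties go to the leftmost candidate
    candidates.sort(key=lambda e: (-e.source_fraction, e.position))
    chosen: list[ConsensusEdit] = []
    for cand in candidates:
        if not any(cand.overlaps(c) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda e: e.position)
    return chosen


@dataclass(frozen=True)
class LiftResult:
    pos: int
    flag: Literal["exact", "inside_insertion", "inside_deletion"] = "exact"


@dataclass
class CoordinateMap:
    """Invertible, edit-indexed mapping between reference and consensus
    coordinates."""

    edits: list[ConsensusEdit]
    reference_length: int

    # derived indexes
    _ref_starts: list[int] = field(init=False, repr=False)
    _cons_starts: list[int] = field(init=False, repr=False)
    _offsets: list[int] = field(init=False, repr=False)  # cumulative after edit i

    def __post_init__(self) -> None:
        self.edits = sorted(self.edits, key=lambda e: e.position)
        for a, b in zip(self.edits, self.edits[1:]):
            if b.position <= a.ref_end:
                raise ValueError("overlapping consensus edits")
        if self.edits and self.edits[-1].ref_end > self.reference_length:
            raise ValueError("edit extends past reference end")
        self._ref_starts = []
        self._cons_starts = []
        self._offsets = []
        offset = 0
        for e in self.edits:
            self._ref_starts.append(e.position)
            self._cons_starts.append(e.position + offset)
            offset += len(e.alt_allele) - len(e.ref_allele)
            self._offsets.append(offset)

    @property
    def consensus_length(self) -> int:
        delta = sum(len(e.alt_allele) - len(e.ref_allele) for e in self.edits)
        return self.reference_length + delta

    # -- reference -> consensus -------------------------------------------
    def ref_to_cons(self, pos: int) -> LiftResult:
        if not 1 <= pos <= self.reference_length:
            raise ValueError(f"reference position {pos} out of range")
        i = bisect.bisect_right(self._ref_starts, pos) - 1
        if i < 0:
            return LiftResult(pos)
        e = self.edits[i]
        cons_start = self._cons_starts[i]
        if pos > e.ref_end:  # past this edit
            return LiftResult(pos + self._offsets[i])
        j = pos - e.position  # 0-based within the ref slice
        m = min(len(e.ref_allele), len(e.alt_allele))
        if j < m:
            return LiftResult(cons_start + j)
        # deleted reference base: anchor to left flanking consensus base
        return LiftResult(cons_start + m - 1, "inside_deletion")

    # -- consensus -> reference -------------------------------------------
    def cons_to_ref(self, pos: int) -> LiftResult:
        if not 1 <= pos <= self.consensus_length:
            raise ValueError(f"consensus position {pos} out of range")
        i = bisect.bisect_right(self._cons_starts, pos) - 1
        if i < 0:
            return LiftResult(pos)
        e = self.edits[i]
        cons_start = self._cons_starts[i]
        cons_end = cons_start + len(e.alt_allele) - 1
        if pos > cons_end:
            return LiftResult(pos - self._offsets[i])
        j = pos - cons_start
        m = min(len(e.ref_allele), len(e.alt_allele))
        if j < m:
            return LiftResult(e.position + j)
        # inserted consensus base: anchor to left flanking reference base
        return LiftResult(e.position + m - 1, "inside_insertion")

    def lift_position(
        self,
        pos: int,
        direction: Literal["reference_to_consensus", "consensus_to_reference"],
    ) -> LiftResult:
        if direction == "reference_to_consensus":
            return self.ref_to_cons(pos)
        if direction == "consensus_to_reference":
            return self.cons_to_ref(pos)
        raise ValueError(f"unknown direction {direction!r}")

    # -- chain-style serialization ----------------------------------------
    def to_chain_text(self) -> str:
        """Blocks of match / delete (reference-only) / insert (consensus-only)
        lengths, in reference order."""
        lines = []
        ref_cursor = 1
        for e in self.edits:
            if e.position > ref_cursor:
                lines.append(f"match\t{e.position - ref_cursor}")
            lr, la = len(e.ref_allele), len(e.alt_allele)
            m = min(lr, la)
            if m:
                lines.append(f"match\t{m}")
            if lr > la:
                lines.append(f"delete\t{lr - la}")
            elif la > lr:
                lines.append(f"insert\t{la - lr}")
            ref_cursor = e.ref_end + 1
        if ref_cursor <= self.reference_length:
            lines.append(f"match\t{self.reference_length - ref_cursor + 1}")
        return "\n".join(lines) + "\n"

    def write_chain(self, path: str | Path) -> None:
        Path(path).write_text(self.to_chain_text())


def build_consensus(
    g: CircularGenome, edits: Sequence[ConsensusEdit]
) -> tuple[CircularGenome, CoordinateMap]:
    """Apply edits to the reference, returning the consensus genome and the
    coordinate map that undoes it."""
    cmap = CoordinateMap(list(edits), g.length)
    parts: list[str] = []
    cursor = 1
    for e in cmap.edits:
        expected = g.fetch(e.position, e.ref_end)
        if expected != e.ref_allele:
            raise ReferenceMismatchError(
                f"edit ref {e.ref_allele!r} at {e.position} does not match "
                f"reference {expected!r}"
            )
        parts.append(g.sequence[cursor - 1 : e.position - 1])
        parts.append(e.alt_allele)
        cursor = e.ref_end + 1
    parts.append(g.sequence[cursor - 1 :])
    consensus = CircularGenome(g.contig_name, "".join(parts))
    assert consensus.length == cmap.consensus_length
    return consensus, cmap


# ---------------------------------------------------------------------------
# Lifting calls and coverage
# ---------------------------------------------------------------------------

def _overlapping_edit_span(
    cmap: CoordinateMap, c1: int, c2: int
) -> tuple[int, int, int, int] | None:
    """If consensus span [c1, c2] overlaps any edit footprint, return the
    union span (r1, r2, d1, d2) in reference and consensus coordinates that
    covers the call plus every overlapped edit."""
    hit = False
    r1 = cmap.cons_to_ref(c1).pos
    r2 = cmap.cons_to_ref(c2).pos
    d1, d2 = c1, c2
    for i, e in enumerate(cmap.edits):
        cons_start = cmap._cons_starts[i]
        cons_end = cons_start + len(e.alt_allele) - 1
        if cons_start <= d2 and d1 <= cons_end:
            hit = True
            d1 = min(d1, cons_start)
            d2 = max(d2, cons_end)
            r1 = min(r1, e.position)
            r2 = max(r2, e.ref_end)
    if not hit:
        return None
    return r1, r2, d1, d2


def lift_variant_call(
    cmap: CoordinateMap,
    call: VariantCall,
    reference: CircularGenome,
    consensus: CircularGenome,
) -> list[VariantCall]:
    """Re-express a consensus-space call in reference coordinates.

    Calls clear of every edit footprint are position-shifted only.  A call
    overlapping an edit is composed with it: the asserted local haplotype is
    reconstructed on the consensus and re-aligned against the reference
    slice spanning the call and the edit.  Alleles are parsimony-trimmed and
    left-aligned.  Calls that compose back to the reference allele are
    dropped (their fraction competes against the edit's re-emitted call; see
    :func:`lift_sample_calls`).
    """
    from dataclasses import replace

    c1 = call.pos
    c2 = call.pos + len(call.ref) - 1
    span = _overlapping_edit_span(cmap, c1, c2)
    if span is None:
        new_pos = cmap.cons_to_ref(c1).pos
        lifted = replace(call, pos=new_pos)
        pos, ref, alt = left_align(reference, lifted.pos, lifted.ref, lifted.alt)
        if ref == alt:
            return []
        return [replace(lifted, pos=pos, ref=ref, alt=alt)]
    r1, r2, d1, d2 = span
    ref_slice = reference.fetch(r1, r2)
    # asserted haplotype: consensus flank-left + call alt + flank-right
    left = consensus.sequence[d1 - 1 : c1 - 1]
    right = consensus.sequence[c2 : d2]
    hap = left + call.alt + right
    if not hap or not ref_slice:
        raise NormalizationError("composition yielded an empty allele")
    pos, ref, alt = trim_alleles(r1, ref_slice, hap)
    if ref == alt:
        return []
    pos, ref, alt = left_align(reference, pos, ref, alt)
    return [replace(call, pos=pos, ref=ref, alt=alt)]


def lift_sample_calls(
    cmap: CoordinateMap,
    calls: Sequence[VariantCall],
    reference: CircularGenome,
    consensus: CircularGenome,
) -> list[VariantCall]:
    """Lift all consensus-space calls and re-emit each consensus edit as a
    reference-coordinate call.

    Each edit is emitted with heteroplasmy ``1 - sum(fractions of lifted
    calls at that site asserting a different allele)``, floored at 0: the
    reads that did not contradict the consensus support the edit allele.
    """
    lifted: list[VariantCall] = []
    # (pos, ref) -> list of (alt, fraction); alt == ref marks a call that
    # composed back to the reference allele (it still competes)
    records: dict[tuple[int, str], list[tuple[str, float]]] = {}
    depth_at: dict[tuple[int, str], int] = {}

    def _record(pos: int, ref: str, alt: str, frac: float, depth: int) -> None:
        records.setdefault((pos, ref), []).append((alt, frac))
        depth_at[(pos, ref)] = max(depth_at.get((pos, ref), 0), depth)

    for call in calls:
        out = lift_variant_call(cmap, call, reference, consensus)
        for lc in out:
            lifted.append(lc)
            _record(lc.pos, lc.ref, lc.alt, lc.heteroplasmy, lc.depth)
        if not out:
            span = _overlapping_edit_span(
                cmap, call.pos, call.pos + len(call.ref) - 1
            )
            if span is not None:
                r1, r2, _, _ = span
                ref_slice = reference.fetch(r1, r2)
                p, r, _a = trim_alleles(r1, ref_slice, ref_slice)
                _record(p, r, r, call.heteroplasmy, call.depth)

    for e in cmap.edits:
        if e.source != "mtDNA_homoplasmy":
            continue
        pos, ref, alt = trim_alleles(e.position, e.ref_allele, e.alt_allele)
        pos, ref, alt = left_align(reference, pos, ref, alt)
        here = records.get((pos, ref), [])
        if any(a == alt for a, _ in here):
            continue  # a lifted call already asserts the edit allele
        competing = sum(frac for a, frac in here if a != alt)
        frac = max(0.0, 1.0 - competing)
        depth = depth_at.get((pos, ref), 0)
        lifted.append(
            VariantCall(
                contig=reference.contig_name,
                pos=pos,
                ref=ref,
                alt=alt,
                heteroplasmy=frac,
                depth=depth,
                alt_depth=int(round(frac * depth)),
            )
        )
    lifted.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return lifted


def lift_coverage(
    cmap: CoordinateMap, cov_consensus: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Return per-base consensus depths to reference coordinates.

    Un-edited and substituted positions copy their depth; reference
    positions deleted in the consensus inherit the left flanking consensus
    depth; depths at inserted consensus bases are dropped.
    """
    cov = np.asarray(cov_consensus, dtype=float)
    if cov.shape[0] != cmap.consensus_length:
        raise ValueError(
            f"coverage length {cov.shape[0]} != consensus length "
            f"{cmap.consensus_length}"
        )
    out = np.empty(cmap.reference_length, dtype=float)
    for p in range(1, cmap.reference_length + 1):
        res = cmap.ref_to_cons(p)
        out[p - 1] = cov[res.pos - 1]
    return out
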