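"""Lift genomic intervals through a one-to-one base-level map.

An interval maps to the span of its partner bases on the other genome.
Two filters drop ambiguous cases before a target is reported:

* an interval overlapping paired blocks contributed by two or more
  distinct chains is dropped (``FILTERED_MULTI_CHAIN``);
* an interval whose partner bases fall on two or more chromosomes is
  dropped (``FILTERED_MULTI_CHROM``).

Because the underlying map is bijective, mapping the partner bases of a
mapped element back always recovers exactly the source bases that had
partners — :func:`roundtrip` verifies this.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from tfosmap.formats import GenomicInterval
from tfosmap.reciprocal_map import OneToOneMap, PairedBlock


class MapStatus(enum.Enum):
    MAPPED = "MAPPED"
    FILTERED_MULTI_CHAIN = "FILTERED_MULTI_CHAIN"
    FILTERED_MULTI_CHROM = "FILTERED_MULTI_CHROM"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MappedElement:
    """Outcome of lifting one interval to the other genome.

    ``target`` is the [min, max) span of the partner bases (internal
    unaligned gaps are tolerated); ``mapped_bases`` counts source bases
    that have a partner.
    """

    source: GenomicInterval
    target: GenomicInterval | None
    mapped_bases: int
    chain_ids: frozenset[str]
    status: MapStatus

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_bases / len(self.source)


def _other(direction_source: str) -> str:
    return "B" if direction_source == "A" else "A"


def _parse_direction(direction: str) -> tuple[str, str]:
    key = direction.replace("->", "to").replace("→", "to")
    if key in ("AtoB", "ab"):
        return "A", "B"
    if key in ("BtoA", "ba"):
        return "B", "A"
    raise ValueError(f"direction must be 'AtoB' or 'BtoA', got {direction!r}")


def _partner_segments(
    iv: GenomicInterval, blocks: Sequence[PairedBlock], source: str
) -> list[tuple[str, int, int]]:
    """Partner intervals (chrom, start, end) of the bases of ``iv`` that
    lie inside the given paired blocks."""
    segs: list[tuple[str, int, int]] = []
    for blk in blocks:
        src_iv = blk.ref if source == "A" else blk.qry
        lo = max(iv.start, src_iv.start)
        hi = min(iv.end, src_iv.end)
        if lo >= hi:
            continue
        if source == "A":
            q0, q1 = blk.project_ref(lo, hi)
            segs.append((blk.qry.chrom, q0, q1))
        else:
            r0, r1 = blk.project_qry(lo, hi)
            segs.append((blk.ref.chrom, r0, r1))
    return segs


def map_interval(
    iv: GenomicInterval,
    one_map: OneToOneMap,
    direction: str = "AtoB",
    min_frac: float = 0.0,
) -> MappedElement:
    """Map one interval, applying the multi-chain / multi-chromosome
    filters.

    ``min_frac`` optionally requires at least that fraction of source
    bases to have partners; the default 0 accepts any element with >= 1
    partnered base.
    """
    src, _ = _parse_direction(direction)
    sizes = one_map.sizes(src)
    if iv.chrom in sizes and iv.end > sizes[iv.chrom]:
        raise ValueError(
            f"{iv.chrom}:{iv.start}-{iv.end} exceeds declared size "
            f"{sizes[iv.chrom]}")

    blocks = one_map.overlapping(src, iv.chrom, iv.start, iv.end)
    if not blocks:
        return MappedElement(iv, None, 0, frozenset(), MapStatus.UNMAPPED)

    chain_ids = frozenset(b.chain_id for b in blocks)
    if len(chain_ids) > 1:
        return MappedElement(iv, None, 0, chain_ids,
                             MapStatus.FILTERED_MULTI_CHAIN)

    segs = _partner_segments(iv, blocks, src)
    chroms = {s[0] for s in segs}
    if len(chroms) > 1:
        return MappedElement(iv, None, 0, chain_ids,
                             MapStatus.FILTERED_MULTI_CHROM)

    mapped_bases = sum(e - s for _, s, e in segs)
    if mapped_bases == 0:
        return MappedElement(iv, None, 0, frozenset(), MapStatus.UNMAPPED)
    if mapped_bases < min_frac * len(iv):
        return MappedElement(iv, None, mapped_bases, chain_ids,
                             MapStatus.UNMAPPED)

    chrom = chroms.pop()
    start = min(s for _, s, _ in segs)
    end = max(e for _, _, e in segs)
    target = GenomicInterval(chrom, start, end, name=iv.name)
    return MappedElement(iv, target, mapped_bases, chain_ids, MapStatus.MAPPED)


def map_intervals(
    features: Iterable[GenomicInterval],
    one_map: OneToOneMap,
    direction: str = "AtoB",
    min_frac: float = 0.0,
) -> tuple[list[MappedElement], Counter]:
    """Map a collection, preserving order; the summary counter over
    statuses sums to the input size."""
    out = [map_interval(iv, one_map, direction, min_frac) for iv in features]
    summary = Counter(el.status for el in out)
    return out, summary


def mappable_nucleotide_fraction(elements: Sequence[MappedElement]) -> float:
    """Fraction of feature nucleotides with a partner on the other
    genome: sum(mapped_bases) / sum(lengths)."""
    total = sum(len(el.source) for el in elements)
    if total == 0:
        return 0.0
    return sum(el.mapped_bases for el in elements) / total


def roundtrip(iv: GenomicInterval, one_map: OneToOneMap,
              direction: str = "AtoB") -> bool:
    """Check the bijectivity guarantee on one mapped interval.

    Takes the partner bases of ``iv``, maps each partner segment back
    through the map, and verifies the result is exactly the set of
    source bases that had partners.  True for every MAPPED element of a
    valid one-to-one map.
    """
    src, _ = _parse_direction(direction)
    fwd = map_interval(iv, one_map, direction)
    if fwd.status is not MapStatus.MAPPED:
        raise ValueError("roundtrip is defined for MAPPED elements")

    blocks = one_map.overlapping(src, iv.chrom, iv.start, iv.end)
    segs = _partner_segments(iv, blocks, src)

    back: list[tuple[str, int, int]] = []
    other = _other(src)
    for chrom, s, e in segs:
        bblocks = one_map.overlapping(other, chrom, s, e)
        back.extend(_partner_segments(GenomicInterval(chrom, s, e),
                                      bblocks, other))

    expected = _normalize(
        (iv.chrom, max(iv.start, blk_iv.start), min(iv.end, blk_iv.end))
        for blk_iv in ((b.ref if src == "A" else b.qry) for b in blocks)
        if max(iv.start, blk_iv.start) < min(iv.end, blk_iv.end))
    return _normalize(back) == expected


def _normalize(segs: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge adjacent/overlapping segments."""
    merged: list[list] = []
    for chrom, s, e in sorted(segs):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]
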