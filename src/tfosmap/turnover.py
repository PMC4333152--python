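"""TF binding-site turnover detection.

A binding site has turned over when its homologous location in the
other species is empty but a site for the same factor exists nearby:
the site was lost and regained a short distance away.  For each mapped
TFBS we measure the edge-to-edge distance from its homologous span to
the closest same-TF TFBS in the analogous cell of the other species;
events with a positive distance strictly below the window (default
150 bp) count as turnover.

Distance 0 means the homologous span overlaps (or touches) a site —
conserved placement, not turnover.  Unmapped TFBS are excluded from the
denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tfosmap.formats import GenomicInterval, Peak
from tfosmap.mapper import MapStatus, map_interval
from tfosmap.reciprocal_map import OneToOneMap

DEFAULT_WINDOW = 150


@dataclass(frozen=True)
class TurnoverRecord:
    source: GenomicInterval
    mapped_target: GenomicInterval
    nearest: GenomicInterval | None
    distance: int | None  # None when no site shares the chromosome
    is_turnover: bool


@dataclass(frozen=True)
class TurnoverSummary:
    records: tuple[TurnoverRecord, ...]
    n_unmapped: int
    window: int
    denominator: str  # "seqcons" | "mapped"

    @property
    def n_turnover(self) -> int:
        return sum(r.is_turnover for r in self.records)

    @property
    def fraction(self) -> float:
        if self.denominator == "seqcons":
            # sites whose homologous span shows no same-assay occupancy
            denom = sum(1 for r in self.records
                        if r.distance is None or r.distance > 0)
        else:
            denom = len(self.records)
        return self.n_turnover / denom if denom else 0.0


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap; 0 when the intervals share a base or touch."""
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return 0


def turnover_scan(
    tfbs_a: Sequence[GenomicInterval | Peak],
    one_map: OneToOneMap,
    tfbs_b: Sequence[GenomicInterval | Peak],
    window: int = DEFAULT_WINDOW,
    direction: str = "AtoB",
    denominator: str = "seqcons",
) -> TurnoverSummary:
    """Scan one assay's TFBS for turnover against the same-TF TFBS of
    the analogous cell in the other species."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if denominator not in ("seqcons", "mapped"):
        raise ValueError(f"unknown denominator policy {denominator!r}")

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tfbs_b:
        iv = t.interval if isinstance(t, Peak) else t
        by_chrom.setdefault(iv.chrom, []).append(iv)
    # Per chromosome: starts sorted ascending plus a prefix-argmax over
    # ends, so the nearest element on either side is found in O(log n)
    # even with nested intervals.
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: (v.start, v.end))
        starts = np.array([v.start for v in ivs])
        ends = np.array([v.end for v in ivs])
        prefix_argmax = np.zeros(len(ivs), dtype=int)
        for k in range(1, len(ivs)):
            prev = prefix_argmax[k - 1]
            prefix_argmax[k] = k if ends[k] > ends[prev] else prev
        arrays[chrom] = (starts, prefix_argmax, ivs)

    records: list[TurnoverRecord] = []
    n_unmapped = 0
    for t in tfbs_a:
        iv = t.interval if isinstance(t, Peak) else t
        mapped = map_interval(iv, one_map, direction)
        if mapped.status is not MapStatus.MAPPED:
            n_unmapped += 1
            continue
        target = mapped.target
        if target.chrom not in arrays:
            records.append(TurnoverRecord(iv, target, None, None, False))
            continue
        starts, prefix_argmax, ivs = arrays[target.chrom]
        j = int(np.searchsorted(starts, target.end, side="left"))
        best: GenomicInterval | None = None
        best_d: int | None = None
        if j < len(ivs):  # nearest element starting at/after the span end
            best, best_d = ivs[j], _gap(target, ivs[j])
        if j > 0:  # among elements starting before, the one ending last
            cand = ivs[prefix_argmax[j - 1]]
            d = _gap(target, cand)
            if best_d is None or d < best_d:
                best, best_d = cand, d
        records.append(TurnoverRecord(
            iv, target, best, best_d,
            is_turnover=best_d is not None and 0 < best_d < window))
    return TurnoverSummary(tuple(records), n_unmapped, window, denominator)


def turnover_summary(
    scans: dict[tuple[str, str], TurnoverSummary]
) -> "pandas.DataFrame":
    """Per-assay turnover fraction table from keyed scan results."""
    import pandas as pd

    rows = []
    for (cell, tf), s in sorted(scans.items()):
        rows.append({
            "cell": cell, "tf": tf,
            "n_scanned": len(s.records),
            "n_unmapped": s.n_unmapped,
            "n_turnover": s.n_turnover,
            "window": s.window,
            "denominator": s.denominator,
            "fraction": s.fraction,
        })
    return pd.DataFrame(rows)
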