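"""Assay-sampling saturation curves quantifying TFos re-use.

If regulatory sequence is extensively recycled between factors and cell
types, a modest number of assays from the comparison species should
already cover most of a reference assay's mapped TFos.  We sample k
assays (without replacement, multiple replicates per k), take the union
of their peaks, and count the fraction of reference TFos whose mapped
target overlaps (>= 1 bp) that union.  At k = #assays every replicate
equals the classify-derived (FunctCons + FunctActive) / mappable
fraction.

A null curve repeats the procedure after placing each comparison
assay's peaks uniformly at random on the mappable portion of the
comparison genome (lengths preserved); on data with real re-use the
observed curve dominates the null at every k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from tfosmap.classify import AssayKey
from tfosmap.formats import GenomicInterval, Peak
from tfosmap.mapper import MappedElement, MapStatus
from tfosmap.reciprocal_map import OneToOneMap


@dataclass(frozen=True)
class SaturationCurve:
    reference: AssayKey
    ks: tuple[int, ...]
    coverages: tuple[tuple[float, ...], ...]  # per k, one value per replicate
    reps: int
    seed: int

    def mean(self) -> np.ndarray:
        return np.array([np.mean(c) for c in self.coverages])

    def to_frame(self) -> "pandas.DataFrame":
        import pandas as pd

        rows = [
            {"k": k, "replicate": r, "coverage": cov}
            for k, covs in zip(self.ks, self.coverages)
            for r, cov in enumerate(covs)
        ]
        return pd.DataFrame(rows)


def _hit_matrix(
    targets: Sequence[GenomicInterval],
    assays: Mapping[AssayKey, Sequence[Peak]],
    keys: Sequence[AssayKey],
) -> np.ndarray:
    """Boolean matrix [assay, reference element]: does the element's
    mapped target overlap any peak of that assay?"""
    hits = np.zeros((len(keys), len(targets)), dtype=bool)
    for ai, key in enumerate(keys):
        tree: dict[str, IntervalTree] = {}
        for p in assays[key]:
            tree.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end)
        for ti, t in enumerate(targets):
            if t.chrom in tree and tree[t.chrom].overlaps(t.start, t.end):
                hits[ai, ti] = True
    return hits


def _mapped_targets(ref_tfos: Sequence[MappedElement]) -> list[GenomicInterval]:
    return [el.target for el in ref_tfos if el.status is MapStatus.MAPPED]


def saturation_curve(
    ref_tfos: Sequence[MappedElement],
    comparison_assays: Mapping[AssayKey, Sequence[Peak]],
    ks: Sequence[int],
    reps: int = 20,
    seed: int = 0,
    reference: AssayKey = AssayKey("NA", "NA"),
) -> SaturationCurve:
    """Observed saturation curve over the given subset sizes ``ks``.

    ``ref_tfos`` are the mapped elements of one reference assay;
    coverage is the fraction of its MAPPED elements hit by the union of
    the sampled assays' peaks.
    """
    keys = sorted(comparison_assays)
    n_assays = len(keys)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    for k in ks:
        if not 0 <= k <= n_assays:
            raise ValueError(f"k={k} outside [0, {n_assays}]")
    targets = _mapped_targets(ref_tfos)
    if not targets:
        raise ValueError("reference assay has no MAPPED elements")
    hits = _hit_matrix(targets, comparison_assays, keys)
    rng = np.random.default_rng(seed)
    coverages = []
    for k in ks:
        row = []
        for _ in range(reps):
            chosen = rng.choice(n_assays, size=k, replace=False)
            covered = hits[chosen].any(axis=0) if k else np.zeros(len(targets), bool)
            row.append(float(covered.mean()))
        coverages.append(tuple(row))
    return SaturationCurve(reference, tuple(int(k) for k in ks),
                           tuple(coverages), reps, seed)


def _mappable_segments(one_map: OneToOneMap, which: str) -> dict[str, list[tuple[int, int]]]:
    segs: dict[str, list[tuple[int, int]]] = {}
    for blk in one_map.blocks:
        iv = blk.ref if which == "A" else blk.qry
        segs.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in segs:
        segs[chrom].sort()
    return segs


def randomize_peaks(
    peaks: Sequence[Peak],
    one_map: OneToOneMap,
    which: str,
    rng: np.random.Generator,
) -> list[Peak]:
    """Place each peak uniformly at random on the mappable portion of
    genome ``which``, preserving peak lengths (starts land on mappable
    bases; ends are clipped to the chromosome)."""
    segs = _mappable_segments(one_map, which)
    chroms = sorted(segs)
    seg_list = [(c, s, e) for c in chroms for s, e in segs[c]]
    if not seg_list:
        raise ValueError("map has no mappable sequence")
    weights = np.array([e - s for _, s, e in seg_list], dtype=float)
    weights /= weights.sum()
    sizes = one_map.sizes(which)
    out = []
    for p in peaks:
        length = len(p.interval)
        si = int(rng.choice(len(seg_list), p=weights))
        chrom, s, e = seg_list[si]
        start = int(rng.integers(s, e))
        end = min(start + length, sizes[chrom])
        if end <= start:
            start = max(0, end - length)
            end = max(start + 1, end)
        out.append(Peak(GenomicInterval(chrom, start, end, name=p.interval.name),
                        cell=p.cell, tf=p.tf, signal=p.signal, species=p.species))
    return out


def null_saturation(
    ref_tfos: Sequence[MappedElement],
    comparison_assays: Mapping[AssayKey, Sequence[Peak]],
    one_map: OneToOneMap,
    ks: Sequence[int],
    reps: int = 20,
    seed: int = 0,
    which: str = "B",
    reference: AssayKey = AssayKey("NA", "NA"),
) -> SaturationCurve:
    """Saturation curve after destroying assay/reference association:
    comparison peaks are repositioned uniformly on the mappable genome
    before the union is taken."""
    rng = np.random.default_rng(seed)
    shuffled = {
        key: randomize_peaks(peaks, one_map, which, rng)
        for key, peaks in sorted(comparison_assays.items())
    }
    return saturation_curve(ref_tfos, shuffled, ks, reps=reps,
                            seed=seed, reference=reference)
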