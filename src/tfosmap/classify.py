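"""DHS filtering and conservation classification of TFos.

A TFos (TF occupied segment) is classified against the other species'
peak compendium by what its homologous site shows:

* ``SPECIES_SPECIFIC`` — the element could not be mapped at all;
* ``SEQ_CONS`` — mapped, but the homologous site carries no occupancy;
* ``FUNCT_ACTIVE`` — the homologous site is occupied by another factor
  or in a non-analogous cell type (repurposed);
* ``FUNCT_CONS`` — the homologous site is bound by the same factor in
  the analogous cell type.

"Same cell type" across species always means the analog-table pairing
(e.g. K562<->MEL, GM12878<->CH12), never a string match.  A site whose
evidence contains both the same-assay key and others is FUNCT_CONS:
conservation of the same factor dominates repurposing.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from intervaltree import IntervalTree

from tfosmap.formats import GenomicInterval, Peak
from tfosmap.mapper import MappedElement, MapStatus, map_interval
from tfosmap.reciprocal_map import OneToOneMap


class AssayKey(NamedTuple):
    """A (cell type, transcription factor) experiment identifier."""

    cell: str
    tf: str


class Category(enum.Enum):
    SPECIES_SPECIFIC = "SPECIES_SPECIFIC"
    SEQ_CONS = "SEQ_CONS"
    FUNCT_ACTIVE = "FUNCT_ACTIVE"
    FUNCT_CONS = "FUNCT_CONS"


class AnalogTable:
    """Cross-species analogous cell-type pairs, bidirectional lookup."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs = list(pairs)
        self._a_to_b: dict[str, str] = {}
        self._b_to_a: dict[str, str] = {}
        for a, b in self.pairs:
            if a in self._a_to_b or b in self._b_to_a:
                raise ValueError(
                    f"cell appears more than once in analog table: {(a, b)}")
            self._a_to_b[a] = b
            self._b_to_a[b] = a

    def analog_of(self, cell: str, side: str = "A") -> str | None:
        """Analog of ``cell``; ``side`` is the species the cell lives on."""
        table = self._a_to_b if side == "A" else self._b_to_a
        return table.get(cell)


@dataclass(frozen=True)
class ClassifiedTFos:
    peak: Peak
    mapped: MappedElement
    category: Category
    evidence: frozenset[AssayKey]


def dhs_filter(
    peaks: Sequence[Peak],
    dhs: Iterable[GenomicInterval | Peak],
) -> tuple[list[Peak], int]:
    """Retain peaks overlapping (>= 1 bp) any DHS interval.

    Returns the retained peaks (input order) and the removed count.
    """
    trees: dict[str, IntervalTree] = {}
    for d in dhs:
        iv = d.interval if isinstance(d, Peak) else d
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    retained = [
        p for p in peaks
        if p.interval.chrom in trees
        and trees[p.interval.chrom].overlaps(p.interval.start, p.interval.end)
    ]
    return retained, len(peaks) - len(retained)


def _compendium_tree(
    compendium: Mapping[AssayKey, Sequence[Peak]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for key, peaks in compendium.items():
        for p in peaks:
            trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end, AssayKey(*key))
    return trees


def classify_tfos(
    peaks: Sequence[Peak],
    one_map: OneToOneMap,
    compendium: Mapping[AssayKey, Sequence[Peak]],
    analogs: AnalogTable,
    direction: str = "AtoB",
    min_frac: float = 0.0,
) -> list[ClassifiedTFos]:
    """Classify each peak of one species against the other species'
    (DHS-filtered) peak compendium.

    ``compendium`` maps assay keys of the comparison species to their
    peak lists.  Overlap calls between the mapped target and compendium
    peaks use the >= 1 bp rule.
    """
    side = "A" if direction.replace("->", "to") in ("AtoB", "ab") else "B"
    trees = _compendium_tree(compendium)
    species_b = {p.species for peaks_ in compendium.values() for p in peaks_}
    species_a = {p.species for p in peaks}
    if species_a and species_b and species_a & species_b:
        raise ValueError(
            f"peaks and compendium share a species label: {species_a & species_b}")

    out: list[ClassifiedTFos] = []
    warned: set[str] = set()
    for peak in peaks:
        mapped = map_interval(peak.interval, one_map, direction, min_frac)
        if mapped.status is not MapStatus.MAPPED:
            out.append(ClassifiedTFos(peak, mapped,
                                      Category.SPECIES_SPECIFIC, frozenset()))
            continue
        t = mapped.target
        hits = trees.get(t.chrom, IntervalTree()).overlap(t.start, t.end) \
            if t.chrom in trees else set()
        evidence = frozenset(h.data for h in hits)
        analog = analogs.analog_of(peak.cell, side)
        if analog is None and peak.cell not in warned:
            warnings.warn(
                f"no analog cell for {peak.cell!r}: FUNCT_CONS unreachable",
                stacklevel=2)
            warned.add(peak.cell)
        same_assay = AssayKey(analog, peak.tf) if analog is not None else None
        if same_assay is not None and same_assay in evidence:
            cat = Category.FUNCT_CONS
        elif evidence:
            cat = Category.FUNCT_ACTIVE
        else:
            cat = Category.SEQ_CONS
        out.append(ClassifiedTFos(peak, mapped, cat, evidence))
    return out


def write_classified(classified: Sequence[ClassifiedTFos], stream) -> None:
    """Write the classification TSV (one row per peak; evidence is
    semicolon-joined ``cell:tf``)."""
    stream.write("#chrom\tstart\tend\tname\tcell\ttf\tsignal\tspecies\t"
                 "status\ttarget_chrom\ttarget_start\ttarget_end\t"
                 "mapped_bases\tcategory\tevidence\n")
    for c in classified:
        iv = c.peak.interval
        t = c.mapped.target
        ev = ";".join(f"{k.cell}:{k.tf}" for k in sorted(c.evidence))
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
            f"{c.peak.cell}\t{c.peak.tf}\t{c.peak.signal!r}\t"
            f"{c.peak.species}\t{c.mapped.status.value}\t"
            f"{t.chrom if t else '.'}\t{t.start if t else -1}\t"
            f"{t.end if t else -1}\t{c.mapped.mapped_bases}\t"
            f"{c.category.value}\t{ev}\n")


def read_classified(stream) -> list[ClassifiedTFos]:
    """Read the TSV written by :func:`write_classified` (contributing
    chain ids are not persisted)."""
    out = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                             name="" if f[3] == "." else f[3])
        peak = Peak(iv, cell=f[4], tf=f[5], signal=float(f[6]), species=f[7])
        status = MapStatus(f[8])
        target = None
        if f[9] != ".":
            target = GenomicInterval(f[9], int(f[10]), int(f[11]),
                                     name=iv.name)
        mapped = MappedElement(iv, target, int(f[12]), frozenset(), status)
        evidence = frozenset(
            AssayKey(*e.split(":", 1)) for e in f[14].split(";") if e)
        out.append(ClassifiedTFos(peak, mapped, Category(f[13]), evidence))
    return out


def summarize_categories(
    classified: Sequence[ClassifiedTFos],
    by: str = "all",
) -> "pandas.DataFrame":
    """Counts and fractions per category.

    Fractions of SEQ_CONS / FUNCT_ACTIVE / FUNCT_CONS are over mappable
    elements and sum to 1; SPECIES_SPECIFIC is reported as a fraction of
    all elements.  ``by`` groups by 'assay' (cell, tf), 'cell', or not
    at all ('all').  Groups with zero mappable elements carry NaN
    fractions and ``undefined=True``.
    """
    import pandas as pd

    if by == "all":
        groups = {("all",): list(classified)}
    elif by == "cell":
        groups = {}
        for c in classified:
            groups.setdefault((c.peak.cell,), []).append(c)
    elif by == "assay":
        groups = {}
        for c in classified:
            groups.setdefault((c.peak.cell, c.peak.tf), []).append(c)
    else:
        raise ValueError(f"by must be 'all', 'cell' or 'assay', got {by!r}")

    rows = []
    for key, items in sorted(groups.items()):
        counts = Counter(c.category for c in items)
        n_all = len(items)
        n_ss = counts[Category.SPECIES_SPECIFIC]
        n_map = n_all - n_ss
        row = {
            "group": ":".join(key),
            "n": n_all,
            "n_mappable": n_map,
            "species_specific": n_ss,
            "seq_cons": counts[Category.SEQ_CONS],
            "funct_active": counts[Category.FUNCT_ACTIVE],
            "funct_cons": counts[Category.FUNCT_CONS],
            "frac_species_specific": n_ss / n_all if n_all else float("nan"),
            "frac_seq_cons": counts[Category.SEQ_CONS] / n_map if n_map else float("nan"),
            "frac_funct_active": counts[Category.FUNCT_ACTIVE] / n_map if n_map else float("nan"),
            "frac_funct_cons": counts[Category.FUNCT_CONS] / n_map if n_map else float("nan"),
            "undefined": n_map == 0,
        }
        rows.append(row)
    return pd.DataFrame(rows)
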