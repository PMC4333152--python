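"""Target-gene conservation of classified TFos.

Enhancer-promoter connections (an input table per species, derived
upstream from synchronized DHS activity) assign putative target genes
to a TFos on its own genome and to its homologous site on the other
genome.  Restricting both gene sets to a one-to-one ortholog table, the
conservation score of a TFos is the fraction of its own targets whose
ortholog is also a target of the homologous site.  Comparing the score
distributions of FunctCons and FunctActive TFos asks whether
repurposing propagates to the predicted regulatory output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from intervaltree import IntervalTree
from scipy import stats as sps

from tfosmap.classify import Category, ClassifiedTFos
from tfosmap.formats import GenomicInterval, RecordError
from tfosmap.mapper import MapStatus
from tfosmap.stats import TestResult


@dataclass(frozen=True)
class EnhancerGeneLink:
    enhancer: GenomicInterval
    gene_id: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise RecordError("gene_id must be non-empty")


class OrthologTable:
    """One-to-one orthologous gene pairs with bidirectional lookup."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs = list(pairs)
        self._a_to_b: dict[str, str] = {}
        self._b_to_a: dict[str, str] = {}
        for a, b in self.pairs:
            if a in self._a_to_b or b in self._b_to_a:
                raise ValueError(f"gene repeated in ortholog table: {(a, b)}")
            self._a_to_b[a] = b
            self._b_to_a[b] = a

    def ortholog_of(self, gene: str, side: str = "A") -> str | None:
        return (self._a_to_b if side == "A" else self._b_to_a).get(gene)

    def genes(self, side: str) -> set[str]:
        return set(self._a_to_b) if side == "A" else set(self._b_to_a)


@dataclass(frozen=True)
class TargetConservationRecord:
    tfos: ClassifiedTFos
    targets_a: frozenset[str]
    targets_b: frozenset[str]
    shared_orthologous: int

    @property
    def conservation_score(self) -> float | None:
        """Fraction of own targets retained (via orthology) at the
        homologous site; None when the TFos has no targets."""
        if not self.targets_a:
            return None
        return self.shared_orthologous / len(self.targets_a)


def read_links(stream: TextIO | str, species: str = "") -> list[EnhancerGeneLink]:
    """Read a ``chrom  start  end  geneId`` TSV."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    links = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 4:
            raise RecordError(f"line {lineno}: need chrom, start, end, geneId")
        links.append(EnhancerGeneLink(
            GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], species))
    return links


def read_orthologs(stream: TextIO | str) -> OrthologTable:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 2:
            raise RecordError(f"line {lineno}: need geneA and geneB")
        pairs.append((f[0], f[1]))
    return OrthologTable(pairs)


def _link_tree(links: Sequence[EnhancerGeneLink]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ln in links:
        trees.setdefault(ln.enhancer.chrom, IntervalTree()).addi(
            ln.enhancer.start, ln.enhancer.end, ln.gene_id)
    return trees


def _genes_overlapping(trees: dict[str, IntervalTree],
                       iv: GenomicInterval) -> set[str]:
    if iv.chrom not in trees:
        return set()
    return {h.data for h in trees[iv.chrom].overlap(iv.start, iv.end)}


def link_targets(
    tfos: Sequence[ClassifiedTFos],
    links_a: Sequence[EnhancerGeneLink],
    links_b: Sequence[EnhancerGeneLink],
    orthologs: OrthologTable,
) -> list[TargetConservationRecord]:
    """Assign target-gene sets on both genomes and count shared
    orthologous targets.

    Gene sets are restricted to the ortholog table before comparison,
    so adding non-orthologous genes to either link set cannot change
    any score.  Elements without a mapped target get an empty B-side
    set.
    """
    trees_a = _link_tree(links_a)
    trees_b = _link_tree(links_b)
    out = []
    for c in tfos:
        ga = _genes_overlapping(trees_a, c.peak.interval) & orthologs.genes("A")
        if c.mapped.status is MapStatus.MAPPED:
            gb = _genes_overlapping(trees_b, c.mapped.target) & orthologs.genes("B")
        else:
            gb = set()
        shared = sum(1 for g in ga if orthologs.ortholog_of(g, "A") in gb)
        out.append(TargetConservationRecord(c, frozenset(ga), frozenset(gb),
                                            shared))
    return out


def retained_target_fraction(
    records: Sequence[TargetConservationRecord],
    category: Category,
) -> float | None:
    """Fraction of the category's TFos (among those with at least one
    own target) that retain >= 1 orthologous target at the homologous
    site; None if the category has no scored records."""
    scored = [r for r in records
              if r.tfos.category is category and r.targets_a]
    if not scored:
        return None
    return sum(1 for r in scored if r.shared_orthologous >= 1) / len(scored)


def compare_target_conservation(
    records: Sequence[TargetConservationRecord],
    cat_x: Category = Category.FUNCT_CONS,
    cat_y: Category = Category.FUNCT_ACTIVE,
) -> TestResult:
    """Two-sample two-sided Kolmogorov-Smirnov test between the
    conservation-score distributions of two categories."""
    xs = [r.conservation_score for r in records
          if r.tfos.category is cat_x and r.conservation_score is not None]
    ys = [r.conservation_score for r in records
          if r.tfos.category is cat_y and r.conservation_score is not None]
    if not xs or not ys:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          ci_low=float("nan"), ci_high=float("nan"),
                          expected=float("nan"), alternative="two-sided",
                          n=len(xs) + len(ys), untestable=True,
                          warning="a category has no scored records")
    res = sps.ks_2samp(xs, ys, alternative="two-sided")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      ci_low=float("nan"), ci_high=float("nan"),
                      expected=0.0, alternative="two-sided",
                      n=len(xs) + len(ys))
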