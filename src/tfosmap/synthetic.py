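"""Coordinate-level genome-pair simulator with planted truth.

The simulator emulates the inputs of the cross-species comparison —
pairwise alignment chains, peak/DHS/TFBS sets, enhancer-gene links —
with every downstream answer known by construction:

* evolutionary events (deletions, insertions, inversions) are applied
  along a shared ancestral coordinate walk and projected to both
  descendant genomes, so the planted base-level homology is bijective
  by construction and is emitted as valid UCSC chain records;
* peaks are planted with known conservation categories (a same-assay or
  other-assay partner at the homologous site, no partner, or placement
  on unmappable sequence);
* TF binding sites are planted with exact displacement offsets for the
  turnover scan;
* enhancer-gene links are planted with known shared-orthologous-target
  flags.

Only coordinates are modeled — no nucleotide sequence.  Duplications
are deliberately not simulated (they would break the one-to-one truth);
decoy chains that the score-based cleaning must reject are synthesized
directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from tfosmap.classify import AnalogTable, AssayKey, Category
from tfosmap.formats import Chain, ChainBlock, ChainSide, GenomicInterval, Peak
from tfosmap.reciprocal_map import PairedBlock
from tfosmap.targets import EnhancerGeneLink, OrthologTable


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Genome-pair simulation settings.

    Event rates are per-base probabilities along the walk; gap and block
    lengths are geometric with the given means.  ``unaligned_margin``
    bases at each chromosome end are left unaligned so that
    species-specific placements always exist.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    deletion_rate: float = 5e-4
    insertion_rate: float = 5e-4
    inversion_rate: float = 2e-5
    mean_block_length: int = 800
    min_block_length: int = 50
    mean_gap_length: int = 150
    chain_break_prob: float = 0.15
    n_decoy_chains: int = 0
    unaligned_margin: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.deletion_rate, self.insertion_rate, self.inversion_rate,
                  self.chain_break_prob):
            if not 0 <= r <= 1:
                raise SimulationError(f"rate {r} outside [0, 1]")
        if self.genome_length < self.n_chromosomes * (
                2 * self.unaligned_margin + self.min_block_length):
            raise SimulationError(
                "genome too short for the requested margins: no homology "
                "would remain — increase genome_length or reduce "
                "unaligned_margin")


@dataclass(frozen=True)
class TruthSegment:
    """One planted gapless homologous segment ('+' coordinates both sides)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str  # "same" | "inverted"

    def __len__(self) -> int:
        return self.ref_end - self.ref_start

    def project(self, start: int, end: int) -> tuple[int, int]:
        """Homologous query interval of a reference sub-interval."""
        if self.orientation == "same":
            return (self.qry_start + (start - self.ref_start),
                    self.qry_start + (end - self.ref_start))
        return (self.qry_end - (end - self.ref_start),
                self.qry_end - (start - self.ref_start))


@dataclass
class SyntheticTruth:
    """The exact base-level homology and (as planting proceeds) the
    planted labels of every feature."""

    segments: list[TruthSegment]
    sizes_a: dict[str, int]
    sizes_b: dict[str, int]
    peak_labels: dict[str, Category] = field(default_factory=dict)
    turnover_offsets: dict[str, int] = field(default_factory=dict)
    link_truth: dict[str, bool] = field(default_factory=dict)

    def pairs(self):
        """Every planted (A base, B base) pair — the per-base oracle."""
        for s in self.segments:
            for i in range(len(s)):
                if s.orientation == "same":
                    q = s.qry_start + i
                else:
                    q = s.qry_end - 1 - i
                yield ((s.ref_chrom, s.ref_start + i), (s.qry_chrom, q))

    def paired_blocks(self) -> list[PairedBlock]:
        return [PairedBlock(
            GenomicInterval(s.ref_chrom, s.ref_start, s.ref_end),
            GenomicInterval(s.qry_chrom, s.qry_start, s.qry_end),
            s.orientation, chain_id="truth") for s in self.segments]

    def aligned_bases(self) -> int:
        return sum(len(s) for s in self.segments)

    def ref_gaps(self) -> dict[str, list[tuple[int, int]]]:
        """Unaligned intervals of genome A, per chromosome."""
        covered: dict[str, list[tuple[int, int]]] = {c: [] for c in self.sizes_a}
        for s in self.segments:
            covered[s.ref_chrom].append((s.ref_start, s.ref_end))
        gaps: dict[str, list[tuple[int, int]]] = {}
        for chrom, size in self.sizes_a.items():
            cur = 0
            out = []
            for s, e in sorted(covered[chrom]):
                if s > cur:
                    out.append((cur, s))
                cur = e
            if cur < size:
                out.append((cur, size))
            gaps[chrom] = out
        return gaps


def _geom(rng: np.random.Generator, mean: int) -> int:
    return int(rng.geometric(1.0 / max(mean, 1)))


def simulate_genome_pair(
    params: SimulationParams,
) -> tuple[list[Chain], SyntheticTruth]:
    """Simulate two genomes related by planted block homology.

    Returns valid chain records (plus ``n_decoy_chains`` lower-scoring
    decoys whose reference side is fully shadowed by a real chain, so
    score-based cleaning must reject them) and the exact truth.
    """
    rng = np.random.default_rng(params.seed)
    chrom_len = params.genome_length // params.n_chromosomes
    segments: list[TruthSegment] = []
    sizes_a: dict[str, int] = {}
    sizes_b: dict[str, int] = {}
    breaks: list[bool] = []  # True: new chain starts at this segment

    for ci in range(params.n_chromosomes):
        ca, cb = f"chrA{ci + 1}", f"chrB{ci + 1}"
        sizes_a[ca] = chrom_len
        t = params.unaligned_margin + (
            _geom(rng, params.mean_gap_length) if params.deletion_rate else 0)
        q = params.unaligned_margin + (
            _geom(rng, params.mean_gap_length) if params.insertion_rate else 0)
        limit = chrom_len - params.unaligned_margin
        first = True
        while t + params.min_block_length <= limit:
            size = max(params.min_block_length,
                       _geom(rng, params.mean_block_length))
            size = min(size, limit - t)
            p_inv = 1.0 - (1.0 - params.inversion_rate) ** size
            inverted = rng.random() < p_inv
            segments.append(TruthSegment(ca, t, t + size, cb, q, q + size,
                                         "inverted" if inverted else "same"))
            breaks.append(first or inverted
                          or rng.random() < params.chain_break_prob)
            first = inverted  # an inversion also terminates the next run
            t += size
            q += size
            if rng.random() < 1.0 - (1.0 - params.deletion_rate) ** size:
                t += 1 + _geom(rng, params.mean_gap_length)
            if rng.random() < 1.0 - (1.0 - params.insertion_rate) ** size:
                q += 1 + _geom(rng, params.mean_gap_length)
        sizes_b[cb] = q + params.unaligned_margin
        if not any(s.ref_chrom == ca for s in segments):
            raise SimulationError(
                f"no homology planted on {ca}: event rates/margins leave no "
                "room — lower unaligned_margin or the gap rates")

    truth = SyntheticTruth(segments, sizes_a, sizes_b)
    chains = _emit_chains(truth, breaks)
    chains += _decoy_chains(truth, params.n_decoy_chains, rng,
                            next_id=len(chains) + 1)
    return chains, truth


def _emit_chains(truth: SyntheticTruth, breaks: Sequence[bool]) -> list[Chain]:
    """Group consecutive same-orientation segments into chains.

    Inverted segments become single-block '-' strand chains (their query
    coordinates ascend with the walk, which on the reverse strand cannot
    be chained with neighbours).
    """
    chains: list[Chain] = []
    runs: list[list[TruthSegment]] = []
    for seg, brk in zip(truth.segments, breaks):
        if brk or not runs or runs[-1][-1].ref_chrom != seg.ref_chrom \
                or seg.orientation == "inverted" \
                or runs[-1][-1].orientation == "inverted":
            runs.append([seg])
        else:
            runs[-1].append(seg)
    for run in runs:
        cid = str(len(chains) + 1)
        ca, cb = run[0].ref_chrom, run[0].qry_chrom
        size_a, size_b = truth.sizes_a[ca], truth.sizes_b[cb]
        aligned = sum(len(s) for s in run)
        score = 1000.0 + 10.0 * aligned
        if run[0].orientation == "inverted":
            s = run[0]
            chains.append(Chain(
                score=score,
                ref=ChainSide(ca, size_a, "+", s.ref_start, s.ref_end),
                qry=ChainSide(cb, size_b, "-",
                              size_b - s.qry_end, size_b - s.qry_start),
                id=cid,
                blocks=(ChainBlock(len(s), 0, 0),)))
        else:
            blocks = []
            for i, s in enumerate(run):
                if i + 1 < len(run):
                    nxt = run[i + 1]
                    blocks.append(ChainBlock(
                        len(s), nxt.ref_start - s.ref_end,
                        nxt.qry_start - s.qry_end))
                else:
                    blocks.append(ChainBlock(len(s), 0, 0))
            chains.append(Chain(
                score=score,
                ref=ChainSide(ca, size_a, "+",
                              run[0].ref_start, run[-1].ref_end),
                qry=ChainSide(cb, size_b, "+",
                              run[0].qry_start, run[-1].qry_end),
                id=cid,
                blocks=tuple(blocks)))
    for c in chains:
        c.validate()
    return chains


def _decoy_chains(truth: SyntheticTruth, n: int, rng: np.random.Generator,
                  next_id: int) -> list[Chain]:
    """Low-scoring chains whose reference side lies inside a planted
    segment (already claimed by a higher-scoring real chain) and whose
    query side points somewhere arbitrary: cleaning must drop them."""
    if n == 0:
        return []
    eligible = [s for s in truth.segments if len(s) >= 100]
    if not eligible:
        raise SimulationError("no segment long enough to host decoy chains")
    out = []
    qchroms = sorted(truth.sizes_b)
    for j in range(n):
        s = eligible[int(rng.integers(len(eligible)))]
        size = int(rng.integers(20, min(len(s), 200)))
        r0 = int(rng.integers(s.ref_start, s.ref_end - size + 1))
        qc = qchroms[int(rng.integers(len(qchroms)))]
        q0 = int(rng.integers(0, truth.sizes_b[qc] - size))
        chain = Chain(
            score=float(100 + j),  # always below real chains (>= 1000)
            ref=ChainSide(s.ref_chrom, truth.sizes_a[s.ref_chrom], "+",
                          r0, r0 + size),
            qry=ChainSide(qc, truth.sizes_b[qc], "+", q0, q0 + size),
            id=str(next_id + j),
            blocks=(ChainBlock(size, 0, 0),))
        chain.validate()
        out.append(chain)
    return out


def random_chains(
    rng: np.random.Generator,
    sizes_a: dict[str, int],
    sizes_b: dict[str, int],
    n_chains: int,
    max_blocks: int = 5,
    max_block: int = 200,
    max_gap: int = 100,
) -> list[Chain]:
    """Arbitrary valid chains (random spans, strands, scores) that may
    overlap each other freely on both genomes — adversarial input for
    the score-based cleaning."""
    chroms_a, chroms_b = sorted(sizes_a), sorted(sizes_b)
    chains = []
    for i in range(n_chains):
        ca = chroms_a[int(rng.integers(len(chroms_a)))]
        cb = chroms_b[int(rng.integers(len(chroms_b)))]
        blocks = []
        n_blocks = int(rng.integers(1, max_blocks + 1))
        for bi in range(n_blocks):
            size = int(rng.integers(1, max_block + 1))
            dt = int(rng.integers(0, max_gap + 1)) if bi < n_blocks - 1 else 0
            dq = int(rng.integers(0, max_gap + 1)) if bi < n_blocks - 1 else 0
            blocks.append(ChainBlock(size, dt, dq))
        t_span = sum(b.size + b.dt for b in blocks)
        q_span = sum(b.size + b.dq for b in blocks)
        if t_span >= sizes_a[ca] or q_span >= sizes_b[cb]:
            continue
        t0 = int(rng.integers(0, sizes_a[ca] - t_span))
        q0 = int(rng.integers(0, sizes_b[cb] - q_span))
        strand = "-" if rng.random() < 0.3 else "+"
        chain = Chain(
            score=float(rng.integers(1, 10_000)),
            ref=ChainSide(ca, sizes_a[ca], "+", t0, t0 + t_span),
            qry=ChainSide(cb, sizes_b[cb], strand, q0, q0 + q_span),
            id=str(i + 1),
            blocks=tuple(blocks))
        chain.validate()
        chains.append(chain)
    return chains


# --------------------------------------------------------------------------
# peak planting


@dataclass(frozen=True)
class PeakPlan:
    """Planted peak counts and properties.

    The default category mix (15% FunctCons, 50% FunctActive, 35%
    SeqCons of mappable elements) mirrors the typical observed
    distribution where repurposed elements are the largest class; the
    default 1.3x FunctCons-over-SeqCons signal shift matches the
    magnitude reported for the human assays.
    """

    n_funct_cons: int = 75
    n_funct_active: int = 250
    n_seq_cons: int = 175
    n_species_specific: int = 100
    n_decoy_off_dhs: int = 0
    peak_length: int = 40
    slot_margin: int = 20
    dhs_padding: int = 5
    signal_shift: float = 1.3
    signal_sigma: float = 0.4
    cell_a: str = "cellA"
    cell_b: str = "cellB"
    other_cell_b: str = "cellX"
    tf: str = "TF1"
    other_tf: str = "TF2"
    species_a: str = "speciesA"
    species_b: str = "speciesB"


@dataclass
class PlantedPeaks:
    peaks_a: list[Peak]                       # planted TFos, DHS-covered
    decoys_a: list[Peak]                      # off-DHS decoys (to be filtered)
    labels: dict[str, Category]               # peak name -> planted category
    compendium_b: dict[AssayKey, list[Peak]]  # comparison-species peaks
    dhs_a: list[GenomicInterval]
    dhs_b: list[GenomicInterval]
    analogs: AnalogTable


def _carve_slots(intervals: Iterable[tuple[str, int, int]], pitch: int,
                 length: int, margin: int) -> list[tuple[str, int]]:
    """Disjoint candidate start positions, ``pitch`` apart, at least
    ``margin`` from interval ends."""
    slots = []
    for chrom, s, e in intervals:
        pos = s + margin
        while pos + length + margin <= e:
            slots.append((chrom, pos))
            pos += pitch
    return slots


def plant_peaks(truth: SyntheticTruth, plan: PeakPlan,
                rng: np.random.Generator) -> PlantedPeaks:
    """Plant peaks of every conservation category, the matching
    comparison-species compendium, and covering DHS sets.

    Noiseless by construction: each planted label is exactly what the
    classifier must recover.  Raises :class:`SimulationError` when the
    genome cannot host the requested counts.
    """
    pitch = plan.peak_length + plan.slot_margin
    mappable_slots: list[tuple[TruthSegment, int]] = []
    for s in truth.segments:
        for chrom, pos in _carve_slots([(s.ref_chrom, s.ref_start, s.ref_end)],
                                       pitch, plan.peak_length, 1):
            mappable_slots.append((s, pos))
    gap_slots = _carve_slots(
        ((chrom, s, e) for chrom, gaps in truth.ref_gaps().items()
         for s, e in gaps),
        pitch, plan.peak_length, plan.dhs_padding + 1)

    n_mappable = plan.n_funct_cons + plan.n_funct_active + plan.n_seq_cons
    n_gap = plan.n_species_specific + plan.n_decoy_off_dhs
    if len(mappable_slots) < n_mappable:
        raise SimulationError(
            f"only {len(mappable_slots)} mappable slots for {n_mappable} "
            "peaks: binding constraint is mappable sequence / slot pitch")
    if len(gap_slots) < n_gap:
        raise SimulationError(
            f"only {len(gap_slots)} unaligned slots for {n_gap} peaks: "
            "binding constraint is unaligned sequence / slot pitch")

    mi = rng.permutation(len(mappable_slots))
    gi = rng.permutation(len(gap_slots))
    analogs = AnalogTable([(plan.cell_a, plan.cell_b)])
    other_keys = [AssayKey(plan.cell_b, plan.other_tf),
                  AssayKey(plan.other_cell_b, plan.tf)]
    same_key = AssayKey(plan.cell_b, plan.tf)

    peaks_a: list[Peak] = []
    decoys_a: list[Peak] = []
    labels: dict[str, Category] = {}
    compendium: dict[AssayKey, list[Peak]] = {
        same_key: [], other_keys[0]: [], other_keys[1]: []}
    dhs_a: list[GenomicInterval] = []
    dhs_b: list[GenomicInterval] = []

    def base_signal() -> float:
        return float(rng.lognormal(mean=1.0, sigma=plan.signal_sigma))

    def pad(iv: GenomicInterval, sizes: dict[str, int]) -> GenomicInterval:
        return GenomicInterval(iv.chrom,
                               max(0, iv.start - plan.dhs_padding),
                               min(sizes[iv.chrom], iv.end + plan.dhs_padding))

    cursor = 0
    spec_mix = ([Category.FUNCT_CONS] * plan.n_funct_cons
                + [Category.FUNCT_ACTIVE] * plan.n_funct_active
                + [Category.SEQ_CONS] * plan.n_seq_cons)
    for idx, cat in enumerate(spec_mix):
        seg, pos = mappable_slots[mi[cursor]]
        cursor += 1
        name = f"pk{cat.name[:2]}{idx:05d}"
        iv = GenomicInterval(seg.ref_chrom, pos, pos + plan.peak_length,
                             name=name)
        sig = base_signal()
        if cat is not Category.SEQ_CONS:
            sig *= plan.signal_shift
        peaks_a.append(Peak(iv, cell=plan.cell_a, tf=plan.tf, signal=sig,
                            species=plan.species_a))
        labels[name] = cat
        dhs_a.append(pad(iv, truth.sizes_a))
        q0, q1 = seg.project(pos, pos + plan.peak_length)
        target = GenomicInterval(seg.qry_chrom, q0, q1, name=f"{name}_b")
        if cat is Category.FUNCT_CONS:
            key = same_key
        elif cat is Category.FUNCT_ACTIVE:
            key = other_keys[int(rng.integers(2))]
        else:
            dhs_b.append(pad(target, truth.sizes_b))
            continue
        compendium[key].append(Peak(target, cell=key.cell, tf=key.tf,
                                    signal=base_signal(),
                                    species=plan.species_b))
        dhs_b.append(pad(target, truth.sizes_b))

    gcursor = 0
    for idx in range(plan.n_species_specific):
        chrom, pos = gap_slots[gi[gcursor]]
        gcursor += 1
        name = f"pkSS{idx:05d}"
        iv = GenomicInterval(chrom, pos, pos + plan.peak_length, name=name)
        peaks_a.append(Peak(iv, cell=plan.cell_a, tf=plan.tf,
                            signal=base_signal(), species=plan.species_a))
        labels[name] = Category.SPECIES_SPECIFIC
        dhs_a.append(pad(iv, truth.sizes_a))
    for idx in range(plan.n_decoy_off_dhs):
        chrom, pos = gap_slots[gi[gcursor]]
        gcursor += 1
        name = f"pkDECOY{idx:05d}"
        iv = GenomicInterval(chrom, pos, pos + plan.peak_length, name=name)
        decoys_a.append(Peak(iv, cell=plan.cell_a, tf=plan.tf,
                             signal=base_signal(), species=plan.species_a))

    truth.peak_labels.update(labels)
    return PlantedPeaks(peaks_a, decoys_a, labels, compendium,
                        dhs_a, dhs_b, analogs)


# --------------------------------------------------------------------------
# turnover planting


@dataclass(frozen=True)
class TurnoverPlan:
    """Planted TFBS displacement offsets.

    Offsets must be positive (0 would be conserved placement, not
    turnover); the defaults put half the offsets inside the 150 bp
    window and half at or beyond it.
    """

    # half strictly inside the window, half at or beyond it
    offsets: tuple[int, ...] = tuple(range(10, 150, 10)) + tuple(range(150, 290, 10))
    tfbs_length: int = 12
    window: int = 150
    slot_pitch: int = 1_300  # > one exclusion hull so same-segment slots clear

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.offsets):
            raise SimulationError(
                "offset 0 (or negative) requested: overlap is conserved "
                "placement, not turnover")


@dataclass
class PlantedTurnover:
    tfbs_a: list[GenomicInterval]
    tfbs_b: list[GenomicInterval]
    offsets: dict[str, int]
    window: int


def plant_turnover(truth: SyntheticTruth, plan: TurnoverPlan,
                   rng: np.random.Generator) -> PlantedTurnover:
    """Plant TFBS pairs: the comparison-species partner of each site is
    displaced from the homologous span by the planted offset, so the
    turnover scan must report exactly those distances.

    Slots are accepted only if the displaced partner stays clear (by
    more than the largest offset plus the window) of every previously
    placed partner; a plan that cannot be placed raises after the
    candidate slots are exhausted.
    """
    max_off = max(plan.offsets)
    if plan.slot_pitch < 2 * max_off + plan.window:
        raise SimulationError("slot_pitch too small for the offsets")
    slots: list[tuple[TruthSegment, int]] = []
    for s in truth.segments:
        if s.orientation != "same":
            continue
        pos = s.ref_start + 1
        while pos + plan.tfbs_length + max_off + 1 <= s.ref_end:
            slots.append((s, pos))
            pos += plan.slot_pitch
    order = rng.permutation(len(slots))
    placed_b: list[GenomicInterval] = []
    tfbs_a: list[GenomicInterval] = []
    offsets: dict[str, int] = {}
    # exclusion hull around (homologous span .. displaced partner): any
    # other planted partner this far away cannot beat the planted one
    safety = max_off + plan.window + plan.tfbs_length + 1
    occupied: list[tuple[str, int, int]] = []
    si = 0
    for i, off in enumerate(plan.offsets):
        name = f"tfbs{i:04d}"
        placed = False
        while si < len(order):
            seg, pos = slots[order[si]]
            si += 1
            q0, q1 = seg.project(pos, pos + plan.tfbs_length)
            b_iv = GenomicInterval(seg.qry_chrom, q1 + off,
                                   q1 + off + plan.tfbs_length,
                                   name=f"{name}_b")
            if b_iv.end > truth.sizes_b[seg.qry_chrom]:
                continue
            lo, hi = max(0, q0 - safety), b_iv.end + safety
            if any(c == seg.qry_chrom and s < hi and lo < e
                   for c, s, e in occupied):
                continue
            tfbs_a.append(GenomicInterval(seg.ref_chrom, pos,
                                          pos + plan.tfbs_length, name=name))
            placed_b.append(b_iv)
            occupied.append((seg.qry_chrom, lo, hi))
            offsets[name] = off
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place TFBS {i} (offset {off}): slots exhausted")
    truth.turnover_offsets.update(offsets)
    return PlantedTurnover(tfbs_a, placed_b, offsets, plan.window)


# --------------------------------------------------------------------------
# target-link planting


@dataclass(frozen=True)
class LinkPlan:
    """How many TFos of each category retain an orthologous target.

    ``retained`` maps a category to (n_with_targets, n_retained):
    n_with_targets elements get an own-genome link; n_retained of those
    also get the orthologous link at the homologous site.
    """

    retained: tuple[tuple[Category, int, int], ...] = (
        (Category.FUNCT_CONS, 60, 54),
        (Category.FUNCT_ACTIVE, 100, 43),
    )


@dataclass
class PlantedLinks:
    links_a: list[EnhancerGeneLink]
    links_b: list[EnhancerGeneLink]
    orthologs: OrthologTable
    retained_flags: dict[str, bool]


def plant_links(truth: SyntheticTruth, planted: PlantedPeaks,
                plan: LinkPlan, rng: np.random.Generator) -> PlantedLinks:
    """Plant enhancer-gene links with known shared-target flags."""
    seg_index = sorted(truth.segments, key=lambda s: (s.ref_chrom, s.ref_start))

    def segment_of(iv: GenomicInterval) -> TruthSegment | None:
        for s in seg_index:
            if s.ref_chrom == iv.chrom and s.ref_start <= iv.start \
                    and iv.end <= s.ref_end:
                return s
        return None

    by_cat: dict[Category, list[Peak]] = {}
    for p in planted.peaks_a:
        by_cat.setdefault(planted.labels[p.interval.name], []).append(p)

    links_a: list[EnhancerGeneLink] = []
    links_b: list[EnhancerGeneLink] = []
    pairs: list[tuple[str, str]] = []
    flags: dict[str, bool] = {}
    gene_n = 0
    for cat, n_with, n_ret in plan.retained:
        pool = by_cat.get(cat, [])
        if len(pool) < n_with:
            raise SimulationError(
                f"only {len(pool)} {cat.name} peaks for {n_with} links")
        if n_ret > n_with:
            raise SimulationError("n_retained exceeds n_with_targets")
        chosen = [pool[i] for i in rng.permutation(len(pool))[:n_with]]
        for j, peak in enumerate(chosen):
            gene_a = f"geneA{gene_n:05d}"
            gene_b = f"geneB{gene_n:05d}"
            gene_n += 1
            links_a.append(EnhancerGeneLink(peak.interval, gene_a,
                                            species="A"))
            pairs.append((gene_a, gene_b))
            retain = j < n_ret
            flags[peak.interval.name] = retain
            if retain:
                seg = segment_of(peak.interval)
                if seg is None:
                    raise SimulationError(
                        f"{peak.interval.name} does not sit in one segment")
                q0, q1 = seg.project(peak.interval.start, peak.interval.end)
                links_b.append(EnhancerGeneLink(
                    GenomicInterval(seg.qry_chrom, q0, q1), gene_b,
                    species="B"))
    truth.link_truth.update(flags)
    return PlantedLinks(links_a, links_b, OrthologTable(pairs), flags)
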