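"""Build a symmetric, bijective base-level map from alignment chains.

Pairwise chains from one genome against another overlap each other; a
reciprocal one-to-one map requires resolving those overlaps.  We do this
with greedy score-descending claim-and-trim on BOTH genomes at once:
chains are visited from highest to lowest score and each gapless block
keeps only the base pairs whose reference AND query bases are still
unclaimed.  Trimming is symmetric — dropping a base on one genome drops
its partner — so the result is bijective by construction, playing the
role of the "first net layer, re-chained" reciprocal alignments.

Ties in score are broken by larger aligned-base count, then by smaller
chain id, so the map is a deterministic function of the chain *set*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

from intervaltree import IntervalTree

from tfosmap.formats import Chain, GenomicInterval


class MapBuildError(ValueError):
    pass


@dataclass(frozen=True)
class PairedBlock:
    """A gapless run of partnered bases between the two genomes.

    ``ref`` lives on genome A, ``qry`` on genome B; both are the same
    length.  For ``orientation == "inverted"`` the pairing is
    antiparallel: ``ref.start + i`` partners ``qry.end - 1 - i``.
    """

    ref: GenomicInterval
    qry: GenomicInterval
    orientation: str
    chain_id: str

    def __post_init__(self) -> None:
        if len(self.ref) != len(self.qry):
            raise MapBuildError(
                f"paired block sides differ in length: {self.ref} / {self.qry}")
        if self.orientation not in ("same", "inverted"):
            raise MapBuildError(f"bad orientation {self.orientation!r}")

    def partner_of_ref(self, pos: int) -> int:
        """Query coordinate paired with reference base ``pos``."""
        off = pos - self.ref.start
        if self.orientation == "same":
            return self.qry.start + off
        return self.qry.end - 1 - off

    def partner_of_qry(self, pos: int) -> int:
        off = pos - self.qry.start
        if self.orientation == "same":
            return self.ref.start + off
        return self.ref.end - 1 - off

    def project_ref(self, start: int, end: int) -> tuple[int, int]:
        """Project a reference sub-interval (within ``ref``) to query coords."""
        if self.orientation == "same":
            return (self.qry.start + (start - self.ref.start),
                    self.qry.start + (end - self.ref.start))
        return (self.qry.end - (end - self.ref.start),
                self.qry.end - (start - self.ref.start))

    def project_qry(self, start: int, end: int) -> tuple[int, int]:
        if self.orientation == "same":
            return (self.ref.start + (start - self.qry.start),
                    self.ref.start + (end - self.qry.start))
        return (self.ref.end - (end - self.qry.start),
                self.ref.end - (start - self.qry.start))


class OneToOneMap:
    """The bijective base-level correspondence between two genomes.

    Stores non-overlapping :class:`PairedBlock` records, indexed per
    chromosome on both genomes so intervals can be queried in either
    direction.
    """

    def __init__(self, blocks: Iterable[PairedBlock],
                 sizes_a: dict[str, int], sizes_b: dict[str, int]):
        self.blocks: list[PairedBlock] = sorted(
            blocks, key=lambda b: (b.ref.chrom, b.ref.start))
        self.sizes_a = dict(sizes_a)
        self.sizes_b = dict(sizes_b)
        self._tree_a: dict[str, IntervalTree] = {}
        self._tree_b: dict[str, IntervalTree] = {}
        for blk in self.blocks:
            if blk.ref.chrom not in self.sizes_a:
                raise MapBuildError(f"unknown A chromosome {blk.ref.chrom!r}")
            if blk.qry.chrom not in self.sizes_b:
                raise MapBuildError(f"unknown B chromosome {blk.qry.chrom!r}")
            self._tree_a.setdefault(blk.ref.chrom, IntervalTree()).addi(
                blk.ref.start, blk.ref.end, blk)
            self._tree_b.setdefault(blk.qry.chrom, IntervalTree()).addi(
                blk.qry.start, blk.qry.end, blk)

    def tree(self, which: str) -> dict[str, IntervalTree]:
        if which == "A":
            return self._tree_a
        if which == "B":
            return self._tree_b
        raise ValueError(f"which must be 'A' or 'B', got {which!r}")

    def sizes(self, which: str) -> dict[str, int]:
        return self.sizes_a if which == "A" else self.sizes_b

    def overlapping(self, which: str, chrom: str, start: int,
                    end: int) -> list[PairedBlock]:
        trees = self.tree(which)
        if chrom not in trees:
            return []
        return sorted((iv.data for iv in trees[chrom].overlap(start, end)),
                      key=lambda b: (b.ref.chrom, b.ref.start))

    @property
    def mapped_bases(self) -> int:
        return sum(len(b.ref) for b in self.blocks)

    def pairs(self) -> Iterator[tuple[tuple[str, int], tuple[str, int]]]:
        """Yield every (A base, B base) partner pair. For small genomes/tests."""
        for blk in self.blocks:
            for pos in range(blk.ref.start, blk.ref.end):
                yield ((blk.ref.chrom, pos),
                       (blk.qry.chrom, blk.partner_of_ref(pos)))

    def write_pbl(self, stream: TextIO) -> None:
        """Write the documented 7-column TSV, sorted by genome A position."""
        stream.write("#chromA\tstartA\tendA\tchromB\tstartB\tendB\torientation\n")
        for b in self.blocks:
            stream.write(
                f"{b.ref.chrom}\t{b.ref.start}\t{b.ref.end}\t"
                f"{b.qry.chrom}\t{b.qry.start}\t{b.qry.end}\t{b.orientation}\n")

    @classmethod
    def read_pbl(cls, stream: TextIO, sizes_a: dict[str, int],
                 sizes_b: dict[str, int]) -> "OneToOneMap":
        blocks = []
        for i, raw in enumerate(stream):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            blocks.append(PairedBlock(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                GenomicInterval(f[3], int(f[4]), int(f[5])),
                f[6], chain_id=str(i)))
        return cls(blocks, sizes_a, sizes_b)


def _subtract(start: int, end: int, claimed: IntervalTree) -> list[tuple[int, int]]:
    """Portions of [start, end) not covered by any claimed interval."""
    hits = sorted(claimed.overlap(start, end))
    out: list[tuple[int, int]] = []
    cur = start
    for h in hits:
        if h.begin > cur:
            out.append((cur, min(h.begin, end)))
        cur = max(cur, h.end)
        if cur >= end:
            break
    if cur < end:
        out.append((cur, end))
    return out


def _chain_sort_key(chain: Chain):
    # Descending score, then descending aligned bases, then ascending id
    # (numeric when possible) — a deterministic total order.
    try:
        cid: tuple = (0, int(chain.id), "")
    except ValueError:
        cid = (1, 0, chain.id)
    return (-chain.score, -chain.aligned_bases, cid)


def build_bijective_map(
    chains: Sequence[Chain],
    sizes_a: dict[str, int],
    sizes_b: dict[str, int],
) -> OneToOneMap:
    """Greedily resolve overlapping chains into a one-to-one map.

    Chains are visited in descending score order (ties: larger aligned
    base count, then smaller id); each gapless block keeps only base
    pairs free on both genomes, then claims them.  Trimming can split a
    block into several :class:`PairedBlock` pieces; single-base pieces
    are kept.
    """
    for chain in chains:
        if chain.ref.name not in sizes_a:
            raise MapBuildError(
                f"chain {chain.id}: unknown reference chromosome "
                f"{chain.ref.name!r}")
        if chain.qry.name not in sizes_b:
            raise MapBuildError(
                f"chain {chain.id}: unknown query chromosome "
                f"{chain.qry.name!r}")
        if sizes_a[chain.ref.name] != chain.ref.size:
            raise MapBuildError(
                f"chain {chain.id}: {chain.ref.name} size {chain.ref.size} "
                f"!= declared {sizes_a[chain.ref.name]}")
        if sizes_b[chain.qry.name] != chain.qry.size:
            raise MapBuildError(
                f"chain {chain.id}: {chain.qry.name} size {chain.qry.size} "
                f"!= declared {sizes_b[chain.qry.name]}")

    claimed_a: dict[str, IntervalTree] = {c: IntervalTree() for c in sizes_a}
    claimed_b: dict[str, IntervalTree] = {c: IntervalTree() for c in sizes_b}
    out: list[PairedBlock] = []

    for chain in sorted(chains, key=_chain_sort_key):
        for seg in chain.paired_segments():
            blk = PairedBlock(
                GenomicInterval(seg.ref_chrom, seg.ref_start, seg.ref_end),
                GenomicInterval(seg.qry_chrom, seg.qry_start, seg.qry_end),
                seg.orientation, chain.id)
            for r0, r1 in _subtract(seg.ref_start, seg.ref_end,
                                    claimed_a[seg.ref_chrom]):
                q0, q1 = blk.project_ref(r0, r1)
                for qq0, qq1 in _subtract(q0, q1, claimed_b[seg.qry_chrom]):
                    rr0, rr1 = blk.project_qry(qq0, qq1)
                    out.append(PairedBlock(
                        GenomicInterval(seg.ref_chrom, rr0, rr1),
                        GenomicInterval(seg.qry_chrom, qq0, qq1),
                        seg.orientation, chain.id))
                    claimed_a[seg.ref_chrom].addi(rr0, rr1)
                    claimed_b[seg.qry_chrom].addi(qq0, qq1)

    return OneToOneMap(out, sizes_a, sizes_b)


def mapped_coverage(one_map: OneToOneMap, which: str = "A") -> float:
    """Fraction of genome ``which`` covered by the map (same base count
    on both genomes — the map is bijective)."""
    total = sum(one_map.sizes(which).values())
    if total == 0:
        return 0.0
    return one_map.mapped_bases / total


def swap_chain(chain: Chain) -> Chain:
    """Exchange the roles of the two genomes in a chain.

    The chain format requires the reference on '+', so for a '-' strand
    query the swapped chain is expressed with the old reference on the
    reverse complement and the block list reversed.  Score, id and the
    base pairing are preserved exactly.
    """
    from tfosmap.formats import ChainBlock, ChainSide

    if chain.qry.strand == "+":
        new_ref = ChainSide(chain.qry.name, chain.qry.size, "+",
                            chain.qry.start, chain.qry.end)
        new_qry = ChainSide(chain.ref.name, chain.ref.size, "+",
                            chain.ref.start, chain.ref.end)
        blocks = tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks)
    else:
        # Old qry coords are on its reverse complement and descend on '+'
        # as the old ref ascends; reversing block order makes the new
        # reference ('+', old qry) ascend, and the new query (old ref)
        # is then expressed on ITS reverse complement.
        new_ref = ChainSide(chain.qry.name, chain.qry.size, "+",
                            chain.qry.size - chain.qry.end,
                            chain.qry.size - chain.qry.start)
        new_qry = ChainSide(chain.ref.name, chain.ref.size, "-",
                            chain.ref.size - chain.ref.end,
                            chain.ref.size - chain.ref.start)
        n = len(chain.blocks)
        blocks = tuple(
            ChainBlock(
                chain.blocks[n - 1 - j].size,
                # the gap following swapped block j is the gap PRECEDING
                # original block n-1-j, with dt/dq roles exchanged
                chain.blocks[n - 2 - j].dq if j < n - 1 else 0,
                chain.blocks[n - 2 - j].dt if j < n - 1 else 0,
            )
            for j in range(n))
    swapped = Chain(score=chain.score, ref=new_ref, qry=new_qry,
                    id=chain.id, blocks=blocks)
    swapped.validate()
    return swapped
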