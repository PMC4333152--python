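"""Domain types and readers/writers for the standard file formats.

All in-memory coordinates are 0-based, half-open, on the '+' strand.
Minus-strand chain query coordinates (which the chain format expresses on
the reverse complement) are converted to '+' coordinates when pairing
blocks; the original strand is retained on the :class:`Chain`.

Chromosome names are compared as exact strings — no ``chr`` aliasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, TextIO


class FormatError(ValueError):
    """Malformed record in an input file."""


class ChainParseError(FormatError):
    """Malformed chain header or block line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ChainConsistencyError(FormatError):
    """Chain block arithmetic disagrees with the header span."""

    def __init__(self, message: str, chain_id: str):
        super().__init__(f"chain {chain_id}: {message}")
        self.chain_id = chain_id


class RecordError(FormatError):
    """A BED/narrowPeak record violates an invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RecordError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Shared-base test; half-open, so touching intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak (TFos), DHS, or TFBS interval with its assay labels.

    ``signal`` is the ENCODE narrowPeak signalValue (enrichment); BED
    inputs without a signal column get 0.
    """

    interval: GenomicInterval
    cell: str
    tf: str
    signal: float = 0.0
    species: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise RecordError(f"negative signal {self.signal}")
        if not self.cell or not self.tf:
            raise RecordError("cell and tf labels must be non-empty")


class ChainSide(NamedTuple):
    """One genome's half of a chain header."""

    name: str
    size: int
    strand: str
    start: int
    end: int


class ChainBlock(NamedTuple):
    """A gapless aligned block: ``size`` bases, then ``dt``/``dq`` gaps."""

    size: int
    dt: int
    dq: int


class PairedSegment(NamedTuple):
    """A gapless block expressed in '+' coordinates on both genomes.

    For ``orientation == "inverted"`` the pairing runs antiparallel:
    reference base ``ref_start + i`` partners query base
    ``qry_end - 1 - i``.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str  # "same" | "inverted"


@dataclass(frozen=True)
class Chain:
    """One UCSC pairwise alignment chain.

    ``ref`` is always on '+' (format convention). ``qry`` start/end are
    kept as written in the file: for a '-' strand query they are
    coordinates on the reverse complement.
    """

    score: float
    ref: ChainSide
    qry: ChainSide
    id: str
    blocks: tuple[ChainBlock, ...]

    @property
    def aligned_bases(self) -> int:
        return sum(b.size for b in self.blocks)

    def paired_segments(self) -> Iterator[PairedSegment]:
        """Yield gapless blocks with query coordinates converted to '+'."""
        inverted = self.qry.strand == "-"
        t = self.ref.start
        q = self.qry.start  # reverse-complement coords when inverted
        for b in self.blocks:
            if inverted:
                q_plus_start = self.qry.size - (q + b.size)
                q_plus_end = self.qry.size - q
            else:
                q_plus_start, q_plus_end = q, q + b.size
            yield PairedSegment(
                self.ref.name, t, t + b.size,
                self.qry.name, q_plus_start, q_plus_end,
                "inverted" if inverted else "same",
            )
            t += b.size + b.dt
            q += b.size + b.dq

    def validate(self) -> None:
        if not self.blocks:
            raise ChainConsistencyError("chain has no blocks", self.id)
        if self.blocks[-1].dt != 0 or self.blocks[-1].dq != 0:
            raise ChainConsistencyError("last block must have zero gaps", self.id)
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.ref.end - self.ref.start:
            raise ChainConsistencyError(
                f"block sum {t_span} != reference span "
                f"{self.ref.end - self.ref.start}", self.id)
        if q_span != self.qry.end - self.qry.start:
            raise ChainConsistencyError(
                f"block sum {q_span} != query span "
                f"{self.qry.end - self.qry.start}", self.id)
        if self.ref.strand != "+":
            raise ChainConsistencyError("reference strand must be '+'", self.id)
        if self.qry.strand not in ("+", "-"):
            raise ChainConsistencyError(
                f"bad query strand {self.qry.strand!r}", self.id)
        for side in (self.ref, self.qry):
            if not (0 <= side.start < side.end <= side.size):
                raise ChainConsistencyError(
                    f"span {side.start}-{side.end} outside [0, {side.size}] "
                    f"on {side.name}", self.id)
        if any(b.size <= 0 or b.dt < 0 or b.dq < 0 for b in self.blocks):
            raise ChainConsistencyError("invalid block sizes/gaps", self.id)


def read_chains(stream: TextIO | str) -> list[Chain]:
    """Parse UCSC chain records from a text stream (or a string).

    Raises :class:`ChainParseError` on malformed lines and
    :class:`ChainConsistencyError` when block sums disagree with the
    header span.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    chains: list[Chain] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[ChainBlock] = []

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1].dt != 0 or blocks[-1].dq != 0:
            raise ChainParseError(
                "chain must end with a bare size line", lineno)
        chain = Chain(
            score=float(header[1]),
            ref=ChainSide(header[2], int(header[3]), header[4],
                          int(header[5]), int(header[6])),
            qry=ChainSide(header[7], int(header[8]), header[9],
                          int(header[10]), int(header[11])),
            id=header[12],
            blocks=tuple(blocks),
        )
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            finish(lineno)
            fields = line.split()
            if len(fields) != 13:
                raise ChainParseError(
                    f"chain header has {len(fields)} fields, expected 13",
                    lineno)
            try:
                float(fields[1])
                for i in (3, 5, 6, 8, 10, 11):
                    int(fields[i])
            except ValueError as exc:
                raise ChainParseError(f"non-numeric header field: {exc}",
                                      lineno) from None
            header = fields
            header_line = lineno
        else:
            if header is None:
                raise ChainParseError("block line outside a chain record",
                                      lineno)
            fields = line.split()
            try:
                nums = [int(f) for f in fields]
            except ValueError:
                raise ChainParseError(f"non-integer block line {line!r}",
                                      lineno) from None
            if len(nums) == 3:
                blocks.append(ChainBlock(nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append(ChainBlock(nums[0], 0, 0))
            else:
                raise ChainParseError(
                    f"block line has {len(nums)} fields, expected 1 or 3",
                    lineno)
    finish(lineno + 1)
    if header is not None:
        raise ChainParseError("unterminated chain record", header_line)
    return chains


def write_chains(chains: Iterable[Chain], stream: TextIO) -> None:
    """Write chains in UCSC chain format (score written as an integer
    when it is one)."""
    for c in chains:
        score = int(c.score) if float(c.score).is_integer() else c.score
        stream.write(
            f"chain {score} {c.ref.name} {c.ref.size} {c.ref.strand} "
            f"{c.ref.start} {c.ref.end} {c.qry.name} {c.qry.size} "
            f"{c.qry.strand} {c.qry.start} {c.qry.end} {c.id}\n")
        for b in c.blocks[:-1]:
            stream.write(f"{b.size} {b.dt} {b.dq}\n")
        stream.write(f"{c.blocks[-1].size}\n\n")


_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_peaks(
    stream: TextIO | str,
    dialect: str = "narrowPeak",
    cell: str = "NA",
    tf: str = "NA",
    species: str = "",
) -> list[Peak]:
    """Read peaks from BED3/BED6/narrowPeak text.

    narrowPeak column 7 (signalValue) populates :attr:`Peak.signal`;
    BED6 uses the score column; BED3 peaks get signal 0.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    want = _DIALECT_COLUMNS[dialect]
    peaks: list[Peak] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < want:
            raise RecordError(
                f"line {lineno}: {len(fields)} columns, {dialect} needs {want}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise RecordError(f"line {lineno}: non-integer coordinates") from None
        if start >= end:
            raise RecordError(f"line {lineno}: start {start} >= end {end}")
        name = fields[3] if want >= 6 and fields[3] != "." else ""
        strand = fields[5] if want >= 6 and fields[5] in ("+", "-") else "+"
        if dialect == "narrowPeak":
            try:
                signal = float(fields[6])
            except ValueError:
                raise RecordError(
                    f"line {lineno}: non-numeric signalValue {fields[6]!r}"
                ) from None
        elif dialect == "bed6":
            try:
                signal = float(fields[4])
            except ValueError:
                raise RecordError(
                    f"line {lineno}: non-numeric score {fields[4]!r}") from None
        else:
            signal = 0.0
        peaks.append(Peak(GenomicInterval(chrom, start, end, strand, name),
                          cell=cell, tf=tf, signal=signal, species=species))
    return peaks


def write_bed(features: Iterable[Peak | GenomicInterval], stream: TextIO,
              dialect: str = "bed6") -> None:
    """Write features as tab-separated BED (0-based half-open).

    For ``bed6`` the score column carries the peak signal, so
    ``read_peaks(dialect="bed6")`` round-trips :class:`Peak` coordinates,
    names and signals exactly.
    """
    for f in features:
        iv = f.interval if isinstance(f, Peak) else f
        if dialect == "bed3":
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            signal = f.signal if isinstance(f, Peak) else 0.0
            sig = repr(signal) if signal != int(signal) else str(int(signal))
            stream.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{sig}\t{iv.strand}\n")


def read_chrom_sizes(stream: TextIO | str) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` table."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sizes: dict[str, int] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise RecordError(f"line {lineno}: need chrom and size")
        sizes[fields[0]] = int(fields[1])
    return sizes
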