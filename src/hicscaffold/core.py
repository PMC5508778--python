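"""Core domain types shared across the scaffolding pipeline.

A draft assembly is a :class:`ContigSet`; Hi-C evidence enters as a stream of
:class:`PairedAlignment` records (one per read pair with both mates mapped);
the scaffolder's intermediate products are :class:`BreakCall` intervals,
:class:`EndNode`/:class:`LinkEdge` graph elements, and ordered/oriented
:class:`ScaffoldLayout` results.

All coordinates are 0-based half-open throughout the package.  SAM's 1-based
positions are converted at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """One assembly contig: a name, a length and (optionally) its sequence."""

    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.name!r}: length must be > 0, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


class ContigSet:
    """Ordered collection of uniquely named contigs."""

    def __init__(self, contigs: Iterable[Contig] = ()) -> None:
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.name in self._contigs:
            raise ValueError(f"duplicate contig name {contig.name!r}")
        self._contigs[contig.name] = contig

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __getitem__(self, name: str) -> Contig:
        return self._contigs[name]

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    def total_bases(self) -> int:
        return sum(c.length for c in self)


class PairedAlignment(NamedTuple):
    """One Hi-C read pair: both mates mapped, coordinates 0-based half-open."""

    read_id: str
    contig1: str
    pos1: int
    end1: int
    strand1: str
    mapq1: int
    contig2: str
    pos2: int
    end2: int
    strand2: str
    mapq2: int

    @property
    def is_intra(self) -> bool:
        return self.contig1 == self.contig2


@dataclass(frozen=True)
class BreakCall:
    """A low-physical-coverage interval on a contig flagged as a misjoin.

    ``score`` is the (negative) summed coverage deficit of the interval
    relative to the expected level; deeper deficits are more negative.
    """

    contig: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid break interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class EndNode(NamedTuple):
    """A contig end: tag ``B`` is the contig's beginning, ``E`` its end."""

    contig: str
    tag: str


CONTIG_EDGE = "CONTIG"


def edge_key(u: EndNode, v: EndNode) -> tuple[EndNode, EndNode]:
    """Canonical (sorted) key for an unordered pair of end nodes."""
    return (u, v) if u <= v else (v, u)


def edge_kind(u: EndNode, v: EndNode) -> str:
    """BB/BE/EB/EE for Hi-C edges (on the canonical node order), or CONTIG."""
    if u.contig == v.contig:
        return CONTIG_EDGE
    a, b = edge_key(u, v)
    return a.tag + b.tag


@dataclass(frozen=True)
class LinkEdge:
    """A candidate or accepted scaffold-graph edge between two contig ends."""

    u: EndNode
    v: EndNode
    raw_links: int
    weight: float
    kind: str = field(default="")

    def __post_init__(self) -> None:
        if not self.kind:
            object.__setattr__(self, "kind", edge_kind(self.u, self.v))
        if self.kind == CONTIG_EDGE:
            if self.u.contig != self.v.contig or {self.u.tag, self.v.tag} != {"B", "E"}:
                raise ValueError("CONTIG edge must join B and E of the same contig")
        elif self.u.contig == self.v.contig:
            raise ValueError("Hi-C edge must join ends of different contigs")

    @property
    def key(self) -> tuple[EndNode, EndNode]:
        return edge_key(self.u, self.v)


class Placement(NamedTuple):
    """One oriented contig within a scaffold layout."""

    contig: str
    orientation: str  # FORWARD or REVERSE


@dataclass
class ScaffoldLayout:
    """An ordered list of oriented contigs forming one scaffold."""

    id: str
    placements: list[Placement]
    is_seed: bool = False

    def __post_init__(self) -> None:
        names = [p.contig for p in self.placements]
        if len(set(names)) != len(names):
            raise ValueError(f"layout {self.id!r}: duplicate contig placement")

    @property
    def contigs(self) -> list[str]:
        return [p.contig for p in self.placements]

    def reversed_copy(self) -> "ScaffoldLayout":
        flipped = [
            Placement(p.contig, REVERSE if p.orientation == FORWARD else FORWARD)
            for p in reversed(self.placements)
        ]
        return ScaffoldLayout(self.id, flipped, self.is_seed)
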