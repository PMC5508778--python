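"""Scaffold layout: path extraction, seed classification, small-contig insertion.

The scaffold graph is a union of simple paths, so each connected component
has a unique path between its two degree-1 nodes.  Traversing that path and
reading each contig's B–E edge direction gives the contig order and
orientation: crossing a contig B→E places it forward, E→B reversed.

Components with more than ``n_th`` contigs become *seed* scaffolds; the rest
are small scaffolds.  Because weight normalization cannot remove all length
bias, contigs from small scaffolds are then re-inserted into seeds: each
contig is assigned to the single seed it shares the most total edge weight
with (summed over the pre-pruning candidate edge set), and is placed at the
(gap position, orientation) that maximizes the seed's total adjacent-pair
weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from .core import (
    CONTIG_EDGE,
    FORWARD,
    REVERSE,
    ContigSet,
    EndNode,
    LinkEdge,
    Placement,
    ScaffoldLayout,
    edge_key,
)


class GraphStructureError(AssertionError):
    """The scaffold graph violated the path-union structure (builder bug)."""


@dataclass
class LinkIndex:
    """Weight lookup over the original (pre-pruning) candidate edge set."""

    weights: dict[tuple[EndNode, EndNode], float]

    @classmethod
    def from_edges(cls, edges: Iterable[LinkEdge]) -> "LinkIndex":
        return cls({e.key: e.weight for e in edges})

    def weight(self, u: EndNode, v: EndNode) -> float:
        return self.weights.get(edge_key(u, v), 0.0)

    def contig_to_contigs_weight(self, contig: str, others: set[str]) -> float:
        """Total weight of original edges joining ``contig`` to any of ``others``."""
        total = 0.0
        for (u, v), w in self.weights.items():
            if u.contig == contig and v.contig in others:
                total += w
            elif v.contig == contig and u.contig in others:
                total += w
        return total


def _right_end(p: Placement) -> EndNode:
    return EndNode(p.contig, "E" if p.orientation == FORWARD else "B")


def _left_end(p: Placement) -> EndNode:
    return EndNode(p.contig, "B" if p.orientation == FORWARD else "E")


def adjacency_weight(a: Placement, b: Placement, links: LinkIndex) -> float:
    """Link weight between the facing ends of two consecutive placements."""
    return links.weight(_right_end(a), _left_end(b))


def layout_total_weight(placements: list[Placement], links: LinkIndex) -> float:
    """Sum of adjacent-pair link weights along a layout."""
    return sum(
        adjacency_weight(a, b, links) for a, b in zip(placements, placements[1:])
    )


def _canonicalize(layout: ScaffoldLayout) -> ScaffoldLayout:
    # a scaffold read backwards with all orientations flipped is the same
    # scaffold; pick the direction with the lexicographically smaller
    # terminal contig so output is deterministic
    first, last = layout.placements[0].contig, layout.placements[-1].contig
    if last < first:
        return layout.reversed_copy()
    return layout


def extract_paths(graph, n_th: int = 3) -> list[ScaffoldLayout]:
    """One layout per connected component, plus singletons for isolated contigs.

    ``graph`` is a :class:`~hicscaffold.scaffold_graph.ScaffoldGraph`.  Raises
    :class:`GraphStructureError` if a component is not a simple path.
    Layouts are sorted by decreasing contig count (ties: first contig name)
    and given ids ``layout_0000``, ``layout_0001``, ...
    """
    g: nx.Graph = graph.graph
    layouts: list[ScaffoldLayout] = []
    degs = dict(g.degree())
    for comp in nx.connected_components(g):
        ends = sorted(n for n in comp if degs[n] == 1)
        if len(ends) != 2 or any(degs[n] > 2 for n in comp):
            raise GraphStructureError(
                f"component containing {sorted(comp)[0]} is not a simple path"
            )
        path = nx.shortest_path(g, ends[0], ends[1])
        if len(path) != len(comp):
            raise GraphStructureError("path does not visit every node of its component")
        placements = []
        for a, b in zip(path, path[1:]):
            if g.edges[a, b]["kind"] != CONTIG_EDGE:
                continue
            if a.tag == "B" and b.tag == "E":
                placements.append(Placement(a.contig, FORWARD))
            else:
                placements.append(Placement(a.contig, REVERSE))
        layouts.append(_canonicalize(ScaffoldLayout("", placements)))

    in_graph = {n.contig for n in g.nodes}
    for contig in graph.contigs:
        if contig.name not in in_graph:
            layouts.append(ScaffoldLayout("", [Placement(contig.name, FORWARD)]))

    layouts.sort(key=lambda s: (-len(s.placements), s.placements[0].contig))
    for i, layout in enumerate(layouts):
        layout.id = f"layout_{i:04d}"
        layout.is_seed = len(layout.placements) > n_th
    return layouts


def assign_to_seed(
    contig: str,
    links: LinkIndex,
    seeds: list[ScaffoldLayout],
) -> Optional[str]:
    """Seed scaffold sharing the most original edge weight with ``contig``.

    Returns the seed's id, or ``None`` when the contig has zero weight to
    every seed.  Ties go to the lexicographically smallest seed id.
    """
    best: tuple[float, str] | None = None
    for seed in sorted(seeds, key=lambda s: s.id):
        w = links.contig_to_contigs_weight(contig, set(seed.contigs))
        if w > 0 and (best is None or w > best[0]):
            best = (w, seed.id)
    return best[1] if best else None


def score_insertion(
    seed: ScaffoldLayout,
    contig: str,
    position: int,
    orientation: str,
    links: LinkIndex,
) -> float:
    """Total adjacent-pair weight of the seed with ``contig`` inserted.

    ``position`` is a gap index from 0 (before the first placement) to
    ``len(placements)`` (after the last).  Computed incrementally: the seed's
    current total, minus the adjacency the insertion splits, plus the one or
    two new adjacencies the inserted contig creates.
    """
    n = len(seed.placements)
    if not 0 <= position <= n:
        raise ValueError(f"position {position} outside [0, {n}]")
    new = Placement(contig, orientation)
    total = layout_total_weight(seed.placements, links)
    if 0 < position < n:
        total -= adjacency_weight(
            seed.placements[position - 1], seed.placements[position], links
        )
    if position > 0:
        total += adjacency_weight(seed.placements[position - 1], new, links)
    if position < n:
        total += adjacency_weight(new, seed.placements[position], links)
    return total


def best_insertion(
    seed: ScaffoldLayout, contig: str, links: LinkIndex
) -> tuple[int, str, float]:
    """Argmax (position, orientation) over all slots; ties prefer the
    smallest position, then forward orientation."""
    best = None
    for position in range(len(seed.placements) + 1):
        for orientation in (FORWARD, REVERSE):
            s = score_insertion(seed, contig, position, orientation, links)
            if best is None or s > best[2]:
                best = (position, orientation, s)
    assert best is not None
    return best


def insert_small_contigs(
    layouts: list[ScaffoldLayout],
    links: LinkIndex,
) -> list[ScaffoldLayout]:
    """Dissolve small scaffolds and insert their contigs into seed scaffolds.

    Contigs are inserted in decreasing order of total weight to their
    assigned seed, so strongly supported contigs claim slots first; each
    insertion is scored against the seed's current (growing) layout.  Contigs
    with no weight to any seed are emitted as singleton layouts — except
    that a small scaffold none of whose contigs could be assigned is emitted
    intact.  The contig multiset is conserved.
    """
    seeds = [s for s in layouts if s.is_seed]
    smalls = [s for s in layouts if not s.is_seed]
    if not seeds:
        return list(layouts)

    seed_by_id = {s.id: s for s in seeds}
    assignments: list[tuple[float, str, str, str]] = []  # (-weight, contig, seed, small id)
    unassigned: dict[str, list[str]] = {s.id: [] for s in smalls}
    for small in smalls:
        for contig in small.contigs:
            seed_id = assign_to_seed(contig, links, seeds)
            if seed_id is None:
                unassigned[small.id].append(contig)
            else:
                w = links.contig_to_contigs_weight(
                    contig, set(seed_by_id[seed_id].contigs)
                )
                assignments.append((-w, contig, seed_id, small.id))

    assignments.sort()
    for _, contig, seed_id, _ in assignments:
        seed = seed_by_id[seed_id]
        position, orientation, _score = best_insertion(seed, contig, links)
        seed.placements.insert(position, Placement(contig, orientation))

    out = list(seeds)
    for small in smalls:
        left = unassigned[small.id]
        if len(left) == len(small.placements) and left:
            out.append(small)  # nothing assignable: keep the small scaffold intact
        else:
            for contig in left:
                out.append(ScaffoldLayout(f"{small.id}:{contig}", [Placement(contig, FORWARD)]))
    return out


def layouts_to_tsv(layouts: Iterable[ScaffoldLayout]) -> str:
    """Plain TSV: scaffold, rank, contig, orientation (+/-)."""
    lines = ["scaffold\trank\tcontig\torientation"]
    for layout in layouts:
        for rank, p in enumerate(layout.placements):
            sym = "+" if p.orientation == FORWARD else "-"
            lines.append(f"{layout.id}\t{rank}\t{p.contig}\t{sym}")
    return "\n".join(lines) + "\n"
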