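"""Scaffold-graph construction from Hi-C link counts.

Each contig contributes two nodes, its beginning (``B``) and end (``E``).
Read pairs whose mates fall in the terminal windows of two different contigs
are counted as links between those ends, giving the four Hi-C edge kinds BB,
BE, EB and EE that encode relative orientation.  Raw link counts are biased
by contig length and restriction-site density, so edge weights are
normalized by the number of restriction-enzyme cut sites in the two end
windows::

    W = links(C1, C2) / (RE(C1) + RE(C2))

The graph is then built greedily: candidate edges below ``min_links`` raw
pairs are discarded, survivors are scanned in decreasing weight order and an
edge is kept only when neither of its end nodes is already in the graph (so
the kept Hi-C edges form a matching on contig ends).  Adding the implicit
B–E edge of every linked contig completes the graph; any cycle that arises
is broken at its lightest Hi-C edge.  The result is a union of simple paths:
no node has degree above two and every connected component has exactly two
degree-1 nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .core import (
    CONTIG_EDGE,
    Contig,
    ContigSet,
    EndNode,
    LinkEdge,
    PairedAlignment,
    edge_key,
    reverse_complement,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def end_window(contig_length: int, l: int) -> int:
    """Effective end-window width: ``min(l, length // 2)``.

    Capping at half the contig length keeps the B and E windows disjoint on
    contigs shorter than ``2 * l``.
    """
    if l <= 0:
        raise ValueError("end window length l must be > 0")
    return min(l, contig_length // 2)


def assign_read_to_end(
    pos: int, read_end: int, contig: Contig, l: int
) -> Optional[str]:
    """Which end window a read interval [pos, read_end) falls in: B, E or None."""
    if not 0 <= pos < contig.length:
        raise ValueError(f"position {pos} outside contig {contig.name!r}")
    w = end_window(contig.length, l)
    if read_end <= w:
        return "B"
    if pos >= contig.length - w:
        return "E"
    return None


def count_links(
    pairs: Iterable[PairedAlignment], contigs: ContigSet, l: int
) -> dict[tuple[EndNode, EndNode], int]:
    """Raw Hi-C link counts between contig-end pairs.

    Pairs must be inter-contig and already MAPQ-filtered.  A pair contributes
    one link when both mates assign to an end window; pairs with a mid-contig
    mate are ignored.
    """
    counts: dict[tuple[EndNode, EndNode], int] = {}
    for p in pairs:
        if p.contig1 == p.contig2:
            continue
        t1 = assign_read_to_end(p.pos1, p.end1, contigs[p.contig1], l)
        if t1 is None:
            continue
        t2 = assign_read_to_end(p.pos2, p.end2, contigs[p.contig2], l)
        if t2 is None:
            continue
        key = edge_key(EndNode(p.contig1, t1), EndNode(p.contig2, t2))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _motif_pattern(motif: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character in motif {motif!r}: {exc}") from exc
    # lookahead so overlapping occurrences are all counted
    return re.compile(f"(?=({body}))")


def _is_palindromic(motif: str) -> bool:
    return motif.upper() == reverse_complement(motif.upper())


def count_restriction_sites(
    contig: Contig, tag: str, l: int, motifs: Iterable[str]
) -> int:
    """Number of enzyme cut sites starting in an end window, plus a pseudocount.

    Counts forward-strand occurrences of each motif; for non-palindromic
    motifs the reverse complement is scanned as well.  The +1 pseudocount
    keeps normalized weights finite on windows with no site.
    """
    if contig.sequence is None:
        raise ValueError(
            f"contig {contig.name!r} has no sequence: supply the assembly FASTA "
            "or use raw-count mode (no enzyme normalization)"
        )
    motifs = list(motifs)
    if not motifs:
        raise ValueError("at least one restriction motif is required")
    w = end_window(contig.length, l)
    if tag == "B":
        win_start, win_end = 0, w
    elif tag == "E":
        win_start, win_end = contig.length - w, contig.length
    else:
        raise ValueError(f"tag must be 'B' or 'E', got {tag!r}")

    count = 0
    for motif in motifs:
        variants = [motif.upper()]
        if not _is_palindromic(motif):
            variants.append(reverse_complement(motif.upper()))
        for variant in variants:
            # slice extends past the window so sites *starting* inside it
            # but ending beyond still match
            chunk = contig.sequence[win_start : min(win_end + len(variant) - 1, contig.length)]
            for m in _motif_pattern(variant).finditer(chunk):
                if m.start() < win_end - win_start:
                    count += 1
    return count + 1


def normalize_weight(raw_links: int, re_u: int, re_v: int) -> float:
    """Restriction-site-normalized edge weight: links / (RE(C1) + RE(C2))."""
    if re_u < 1 or re_v < 1:
        raise ValueError("restriction-site counts must be >= 1 (pseudocounted)")
    return raw_links / (re_u + re_v)


def make_candidate_edges(
    link_counts: Mapping[tuple[EndNode, EndNode], int],
    contigs: ContigSet,
    l: int,
    motifs: Optional[Iterable[str]] = None,
) -> list[LinkEdge]:
    """Candidate Hi-C edges with normalized weights.

    With ``motifs=None`` (raw-count mode) the weight equals the raw link
    count; otherwise restriction sites are counted once per contig end and
    the weight is ``links / (RE(u) + RE(v))``.
    """
    re_cache: dict[EndNode, int] = {}
    motifs = list(motifs) if motifs is not None else None

    def re_count(node: EndNode) -> int:
        if node not in re_cache:
            re_cache[node] = count_restriction_sites(
                contigs[node.contig], node.tag, l, motifs
            )
        return re_cache[node]

    edges = []
    for (u, v), raw in sorted(link_counts.items()):
        if motifs is None:
            weight = float(raw)
        else:
            weight = normalize_weight(raw, re_count(u), re_count(v))
        edges.append(LinkEdge(u, v, raw, weight))
    return edges


@dataclass
class ScaffoldGraph:
    """The scaffold graph plus the parameters it was built with.

    ``graph`` is an undirected networkx graph on :class:`EndNode` keys; each
    edge carries ``kind``, ``raw_links`` and ``weight`` attributes.
    ``contigs`` is the (post-break) contig set, retained so path extraction
    can emit singleton layouts for contigs with no Hi-C edge.
    """

    graph: nx.Graph
    contigs: ContigSet
    params: dict = field(default_factory=dict)

    def hic_edges(self) -> list[tuple[EndNode, EndNode, dict]]:
        return [
            (u, v, d) for u, v, d in self.graph.edges(data=True)
            if d["kind"] != CONTIG_EDGE
        ]

    def check_path_properties(self) -> None:
        """Raise if the graph violates the path-union structure.

        After construction no node may have degree above 2, the graph must be
        acyclic, and every connected component must have exactly two degree-1
        nodes.
        """
        degs = dict(self.graph.degree())
        bad = [n for n, d in degs.items() if d > 2]
        if bad:
            raise AssertionError(f"nodes with degree > 2: {bad[:5]}")
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise AssertionError(f"graph has a cycle: {cycle[:4]}")
        for comp in nx.connected_components(self.graph):
            deg1 = [n for n in comp if degs[n] == 1]
            if len(deg1) != 2:
                raise AssertionError(
                    f"component {sorted(comp)[:4]}... has {len(deg1)} degree-1 nodes"
                )


def _sort_key(edge: LinkEdge) -> tuple:
    return (-edge.weight, -edge.raw_links, edge.u, edge.v)


def build_graph(
    candidates: Iterable[LinkEdge],
    contigs: ContigSet,
    min_links: int = 5,
    params: Optional[dict] = None,
) -> ScaffoldGraph:
    """Greedy scaffold-graph construction.

    1. Drop candidates with ``raw_links < min_links`` (sequencing noise).
    2. Sort survivors by decreasing weight (ties: more raw links, then
       lexicographic node names, for deterministic output).
    3. Scan in order; add an edge only when *neither* endpoint is already a
       node of the graph.
    4. Add the B–E edge of every contig that received a Hi-C edge.
    5. Remove any cycles (:func:`remove_cycles`).
    """
    g = nx.Graph()
    kept = 0
    for edge in sorted(candidates, key=_sort_key):
        if edge.raw_links < min_links:
            continue
        if edge.u in g or edge.v in g:
            continue
        g.add_edge(edge.u, edge.v, kind=edge.kind, raw_links=edge.raw_links,
                   weight=edge.weight)
        kept += 1
    for name in sorted({n.contig for n in g.nodes}):
        g.add_edge(EndNode(name, "B"), EndNode(name, "E"),
                   kind=CONTIG_EDGE, raw_links=0, weight=0.0)
    sg = ScaffoldGraph(g, contigs, dict(params or {}, min_links=min_links))
    sg.params["hic_edges_kept"] = kept
    remove_cycles(sg)
    return sg


def remove_cycles(sg: ScaffoldGraph) -> ScaffoldGraph:
    """Break every cycle at its minimum-weight Hi-C edge (in place).

    The canonical case is the 4-cycle formed when both the BB and EE edges of
    two contigs were kept and their contig edges close the loop; the lighter
    of the two Hi-C edges is deleted.  Longer cycles (whole components that
    close on themselves) are handled the same way, iterating until acyclic.
    Contig B–E edges are never deleted.
    """
    g = sg.graph
    removed = 0
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        hic = [
            (u, v) for u, v in cycle if g.edges[u, v]["kind"] != CONTIG_EDGE
        ]
        if not hic:  # cannot happen: contig edges alone cannot close a cycle
            raise AssertionError("cycle consisting solely of contig edges")
        u, v = min(hic, key=lambda e: (g.edges[e]["weight"], edge_key(*e)))
        g.remove_edge(u, v)
        removed += 1
    sg.params["cycles_broken"] = sg.params.get("cycles_broken", 0) + removed
    return sg


def edges_to_tsv(sg: ScaffoldGraph) -> str:
    """TSV dump: u_contig, u_tag, v_contig, v_tag, kind, raw_links, weight."""
    lines = ["u_contig\tu_tag\tv_contig\tv_tag\tkind\traw_links\tweight"]
    rows = sorted(
        (edge_key(u, v), d) for u, v, d in sg.graph.edges(data=True)
    )
    for (u, v), d in rows:
        lines.append(
            f"{u.contig}\t{u.tag}\t{v.contig}\t{v.tag}\t{d['kind']}\t"
            f"{d['raw_links']}\t{d['weight']:.6g}"
        )
    return "\n".join(lines) + "\n"


def to_dot(sg: ScaffoldGraph) -> str:
    """GraphViz DOT rendering for manual inspection."""
    out = ["graph scaffold {"]
    for (u, v), d in sorted((edge_key(u, v), d) for u, v, d in sg.graph.edges(data=True)):
        style = 'style="dashed"' if d["kind"] == CONTIG_EDGE else f'label="{d["weight"]:.3g}"'
        out.append(f'  "{u.contig}:{u.tag}" -- "{v.contig}:{v.tag}" [{style}];')
    out.append("}")
    return "\n".join(out) + "\n"
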