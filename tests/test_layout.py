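"""Path extraction, seed assignment and small-contig insertion."""

import itertools

import numpy as np
import pytest

from hicscaffold import (
    Contig,
    ContigSet,
    EndNode,
    FORWARD,
    LinkEdge,
    LinkIndex,
    Placement,
    REVERSE,
    ScaffoldLayout,
    assign_to_seed,
    build_graph,
    extract_paths,
    insert_small_contigs,
    score_insertion,
)
from hicscaffold.layout import adjacency_weight, best_insertion


def node(s):
    contig, tag = s.split(":")
    return EndNode(contig, tag)


def edge(u, v, w):
    return LinkEdge(node(u), node(v), int(max(w, 1)), float(w))


def contig_set(names):
    return ContigSet([Contig(n, 1000) for n in names])


def graph_of(candidates, names, min_links=1):
    return build_graph(candidates, contig_set(names), min_links=min_links)


class TestExtractPaths:
    def test_forward_forward_path(self):
        g = graph_of([edge("a:E", "b:B", 5)], ["a", "b"])
        (layout,) = extract_paths(g, n_th=1)
        assert layout.placements == [Placement("a", FORWARD), Placement("b", FORWARD)]
        assert layout.is_seed  # 2 contigs > n_th=1

    def test_reverse_orientation_from_e_to_b_traversal(self):
        g = graph_of([edge("a:E", "b:E", 5)], ["a", "b"])
        (layout,) = extract_paths(g, n_th=2)
        assert layout.placements == [Placement("a", FORWARD), Placement("b", REVERSE)]
        assert not layout.is_seed

    def test_isolated_contig_becomes_singleton_non_seed(self):
        g = graph_of([edge("a:E", "b:B", 5)], ["a", "b", "lonely"])
        layouts = extract_paths(g, n_th=2)
        singles = [s for s in layouts if len(s.placements) == 1]
        assert [s.placements[0] for s in singles] == [Placement("lonely", FORWARD)]
        assert not singles[0].is_seed

    def test_canonical_direction_smaller_terminal_contig_first(self):
        g = graph_of([edge("z:E", "a:B", 5)], ["a", "z"])
        (layout,) = extract_paths(g, n_th=0)
        # traversing from "a" reverses both contigs
        assert layout.placements == [Placement("a", REVERSE), Placement("z", REVERSE)]

    def test_reversed_layout_is_equivalent(self):
        g = graph_of([edge("a:E", "b:B", 5), edge("b:E", "c:E", 4)], ["a", "b", "c"])
        (layout,) = extract_paths(g, n_th=0)
        double = layout.reversed_copy().reversed_copy()
        assert double.placements == layout.placements

    def test_every_contig_appears_exactly_once(self):
        rng = np.random.default_rng(9)
        names = [f"c{i}" for i in range(20)]
        candidates = []
        for i in range(19):
            candidates.append(edge(f"c{i}:E", f"c{i+1}:B", int(rng.integers(5, 50))))
        g = graph_of(candidates, names)
        layouts = extract_paths(g, n_th=3)
        placed = [p.contig for s in layouts for p in s.placements]
        assert sorted(placed) == sorted(names)


def seed_layout(sid, names, orientations=None):
    orientations = orientations or [FORWARD] * len(names)
    return ScaffoldLayout(sid, [Placement(n, o) for n, o in zip(names, orientations)], is_seed=True)


class TestAssignToSeed:
    def links(self):
        return LinkIndex.from_edges(
            [
                edge("x:E", "a:B", 3.0),
                edge("x:B", "b:E", 1.0),
                edge("x:E", "p:B", 1.5),
            ]
        )

    def test_argmax_over_total_seed_weight(self):
        seeds = [seed_layout("s1", ["a", "b"]), seed_layout("s2", ["p", "q"])]
        assert assign_to_seed("x", self.links(), seeds) == "s1"

    def test_no_links_gives_none(self):
        seeds = [seed_layout("s1", ["m", "n"])]
        assert assign_to_seed("x", self.links(), seeds) is None

    def test_tie_breaks_by_seed_id(self):
        links = LinkIndex.from_edges(
            [edge("x:E", "a:B", 2.0), edge("x:B", "p:B", 2.0)]
        )
        seeds = [seed_layout("s2", ["p"]), seed_layout("s1", ["a"])]
        assert assign_to_seed("x", links, seeds) == "s1"


def brute_force_insertion_score(seed, contig, position, orientation, links):
    """Independent scorer: rebuild the hypothetical layout and sum the
    facing-end weights of every consecutive pair from scratch."""
    placements = list(seed.placements)
    placements.insert(position, Placement(contig, orientation))
    total = 0.0
    for a, b in zip(placements, placements[1:]):
        ra = EndNode(a.contig, "E" if a.orientation == FORWARD else "B")
        lb = EndNode(b.contig, "B" if b.orientation == FORWARD else "E")
        total += links.weight(ra, lb)
    return total


class TestScoreInsertion:
    def test_strong_double_linkage_dominates(self):
        seed = seed_layout("s1", ["a", "b", "c"])
        links = LinkIndex.from_edges(
            [
                edge("a:E", "b:B", 5.0),
                edge("b:E", "c:B", 5.0),
                edge("a:E", "x:B", 9.0),
                edge("x:E", "b:B", 9.0),
            ]
        )
        scores = {
            (pos, o): score_insertion(seed, "x", pos, o, links)
            for pos in range(4)
            for o in (FORWARD, REVERSE)
        }
        assert max(scores, key=scores.get) == (1, FORWARD)

    def test_zero_linkage_scores_equal_everywhere(self):
        seed = seed_layout("s1", ["a", "b", "c"])
        links = LinkIndex.from_edges([edge("a:E", "b:B", 5.0), edge("b:E", "c:B", 5.0)])
        base = 10.0
        for pos in range(4):
            for o in (FORWARD, REVERSE):
                assert score_insertion(seed, "x", pos, o, links) == base - (
                    5.0 if 0 < pos < 3 else 0.0
                )

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            names = [f"c{i}" for i in range(n)]
            orientations = [FORWARD if rng.random() < 0.5 else REVERSE for _ in names]
            seed = seed_layout("s", names, orientations)
            edges = []
            for a, b in itertools.combinations(names + ["x"], 2):
                for ta in "BE":
                    for tb in "BE":
                        if rng.random() < 0.4:
                            edges.append(
                                LinkEdge(EndNode(a, ta), EndNode(b, tb), 1, float(rng.integers(1, 20)))
                            )
            links = LinkIndex.from_edges(edges)
            for pos in range(n + 1):
                for o in (FORWARD, REVERSE):
                    assert score_insertion(seed, "x", pos, o, links) == pytest.approx(
                        brute_force_insertion_score(seed, "x", pos, o, links)
                    )
            # and the argmax agrees with exhaustive search
            pos, orient, score = best_insertion(seed, "x", links)
            best_bf = max(
                (
                    (brute_force_insertion_score(seed, "x", p, o, links), p, o)
                    for p in range(n + 1)
                    for o in (FORWARD, REVERSE)
                ),
            )
            assert score == pytest.approx(best_bf[0])


class TestInsertSmallContigs:
    def test_unique_best_slot_grows_seed(self):
        seed = seed_layout("s1", ["a", "b"])
        small = ScaffoldLayout("s2", [Placement("x", FORWARD)])
        links = LinkIndex.from_edges(
            [edge("a:E", "b:B", 5.0), edge("b:E", "x:B", 7.0)]
        )
        out = insert_small_contigs([seed, small], links)
        assert [s.contigs for s in out] == [["a", "b", "x"]]

    def test_no_seeds_passes_layouts_through(self):
        layouts = [
            ScaffoldLayout("s1", [Placement("a", FORWARD)]),
            ScaffoldLayout("s2", [Placement("b", REVERSE)]),
        ]
        links = LinkIndex.from_edges([])
        assert insert_small_contigs(layouts, links) == layouts

    def test_contig_multiset_is_conserved(self):
        rng = np.random.default_rng(3)
        seeds = [
            seed_layout("s1", ["a", "b", "c", "d"]),
            seed_layout("s2", ["e", "f", "g", "h"]),
        ]
        smalls = [
            ScaffoldLayout("t1", [Placement("x", FORWARD), Placement("y", FORWARD)]),
            ScaffoldLayout("t2", [Placement("z", FORWARD)]),
            ScaffoldLayout("t3", [Placement("w", FORWARD), Placement("v", REVERSE)]),
        ]
        edges = []
        for small_contig in ["x", "y", "z"]:
            target = rng.choice(["a", "c", "f", "h"])
            edges.append(
                LinkEdge(
                    EndNode(small_contig, "B"),
                    EndNode(str(target), "E"),
                    1,
                    float(rng.integers(1, 9)),
                )
            )
        links = LinkIndex.from_edges(edges)
        out = insert_small_contigs(seeds + smalls, links)
        placed = sorted(p.contig for s in out for p in s.placements)
        assert placed == sorted("abcdefgh") + sorted(["v", "w", "x", "y", "z"])

    def test_fully_unassignable_small_scaffold_kept_intact(self):
        seed = seed_layout("s1", ["a", "b", "c", "d"])
        small = ScaffoldLayout("t1", [Placement("x", FORWARD), Placement("y", REVERSE)])
        links = LinkIndex.from_edges([edge("a:E", "b:B", 5.0)])
        out = insert_small_contigs([seed, small], links)
        assert small in out
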