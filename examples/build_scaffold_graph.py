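"""Build a scaffold graph by hand on a four-contig toy example.

Shows the core mechanics: end-window link counting, restriction-site
weight normalization W = links/(RE1+RE2), greedy edge selection (an edge is
skipped when a contig end is already used) and path extraction.
"""

import numpy as np

from hicscaffold import (
    Contig,
    ContigSet,
    PairedAlignment,
    build_graph,
    count_links,
    extract_paths,
    make_candidate_edges,
)

# four 100-kb contigs of random sequence (GATC occurs naturally ~1/256 bp)
rng = np.random.default_rng(0)
bases = np.frombuffer(b"ACGT", dtype=np.uint8)
contigs = ContigSet(
    [
        Contig(f"c{i}", 100_000, bases[rng.integers(0, 4, 100_000)].tobytes().decode())
        for i in range(1, 5)
    ]
)

# Hi-C pairs implying the chain c1 -> c2 -> c3 -> c4 (end-to-begin links),
# plus a weaker spurious c1:E ~ c3:B signal
def pair(i, c1, p1, c2, p2):
    return PairedAlignment(f"r{i}", c1, p1, p1 + 100, "+", 60, c2, p2, p2 + 100, "-", 60)

pairs = []
i = 0
for a, b, n in (("c1", "c2", 40), ("c2", "c3", 35), ("c3", "c4", 45)):
    for _ in range(n):  # mate near the E end of a, mate near the B end of b
        pairs.append(pair(i, a, 99_000 - i % 500, b, 500 + i % 500)); i += 1
for _ in range(8):  # spurious long-range signal
    pairs.append(pair(i, "c1", 98_000, "c3", 1_200)); i += 1

counts = count_links(pairs, contigs, l=50_000)
candidates = make_candidate_edges(counts, contigs, l=50_000, motifs=["GATC"])
for e in sorted(candidates, key=lambda e: -e.weight):
    print(f"{e.u.contig}:{e.u.tag} -- {e.v.contig}:{e.v.tag}  links={e.raw_links}  W={e.weight:.3f}")

graph = build_graph(candidates, contigs, min_links=5)
print(f"\nkept {len(graph.hic_edges())} Hi-C edges (the spurious c1:E~c3:B lost: its ends were taken)")
for layout in extract_paths(graph, n_th=3):
    chain = " -> ".join(f"{p.contig}({p.orientation[0]})" for p in layout.placements)
    print(f"{layout.id} (seed={layout.is_seed}): {chain}")
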