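"""Simulate a small genome, scaffold it end to end, and score the result.

Builds a 4-chromosome genome, fragments it into ~60 contigs, generates
200,000 Hi-C pairs, runs the full scaffolding pipeline (GATC-normalized
edge weights) and compares the layouts with the known truth.
"""

import os
import tempfile

import pandas as pd

from hicscaffold import (
    FORWARD,
    Placement,
    REVERSE,
    RunConfig,
    ScaffoldLayout,
    SimConfig,
    layout_accuracy,
    run_scaffold,
    simulate_all,
)
from hicscaffold.simulator import write_fixture

with tempfile.TemporaryDirectory() as workdir:
    sim = simulate_all(SimConfig(p_inter=0.05, seed=11))
    paths = write_fixture(sim, os.path.join(workdir, "fixture"))
    print(f"simulated {len(sim.contigs)} contigs over {sim.cfg.n_chromosomes} chromosomes")

    cfg = RunConfig(
        contigs_fasta=paths["contigs"],
        alignments=paths["pairs"],
        out_dir=os.path.join(workdir, "run"),
        enzyme=["GATC"],
    )
    stats = run_scaffold(cfg)
    print(f"kept {stats['hic_edges_kept']} Hi-C edges -> {stats['scaffolds_out']} scaffolds")

    df = pd.read_csv(os.path.join(cfg.out_dir, "layout.tsv"), sep="\t")
    layouts = [
        ScaffoldLayout(
            str(sid),
            [
                Placement(r.contig, FORWARD if r.orientation == "+" else REVERSE)
                for r in grp.sort_values("rank").itertuples(index=False)
            ],
        )
        for sid, grp in df.groupby("scaffold")
    ]
    acc = layout_accuracy(layouts, sim.truth.order)
    print(
        f"adjacency recall {acc.n_recovered}/{acc.n_true_adjacencies} "
        f"= {acc.adjacency_recall:.1%}; orientation accuracy {acc.orientation_accuracy:.1%}"
    )
    # recall counts true neighbouring contig pairs reunited in a scaffold;
    # orientation accuracy checks their relative strand among those pairs
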