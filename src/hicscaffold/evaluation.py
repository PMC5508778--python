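"""Truth-based evaluation of scaffolding and misassembly-detection results.

Used with the simulator's truth tables: adjacency recall asks how many pairs
of contigs that are neighbours on a true chromosome end up adjacent in some
scaffold; orientation accuracy asks, among those recovered adjacencies,
whether the two contigs' relative orientation matches the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import BreakCall, FORWARD, ScaffoldLayout


@dataclass
class LayoutAccuracy:
    n_true_adjacencies: int
    n_recovered: int
    n_orientation_correct: int

    @property
    def adjacency_recall(self) -> float:
        return self.n_recovered / self.n_true_adjacencies if self.n_true_adjacencies else float("nan")

    @property
    def orientation_accuracy(self) -> float:
        return self.n_orientation_correct / self.n_recovered if self.n_recovered else float("nan")


def _effective_strand(placement_orientation: str, stored_strand: str) -> str:
    """Strand of the underlying chromosome fragment as laid out.

    ``stored_strand`` is the truth orientation of the contig as stored
    ('+' = fragment kept forward); a reverse placement flips it.
    """
    flip = placement_orientation != FORWARD
    if stored_strand == "+":
        return "-" if flip else "+"
    return "+" if flip else "-"


def layout_accuracy(
    layouts: Iterable[ScaffoldLayout], order_truth: pd.DataFrame
) -> LayoutAccuracy:
    """Compare scaffold layouts against the simulator's order truth table.

    ``order_truth`` columns: chrom, rank, contig, orientation.  True
    adjacencies are consecutive ranks on a chromosome (rank gaps — e.g.
    fragments consumed by chimeras — break adjacency).  A true adjacency
    (a, b) is recovered when a and b are consecutive in some layout, in
    either order; its orientation is correct when both contigs' effective
    strands reproduce the chromosome read in one direction.
    """
    truth_adj: dict[frozenset, tuple[str, str, str, str]] = {}
    for _, grp in order_truth.groupby("chrom"):
        grp = grp.sort_values("rank")
        rows = list(grp.itertuples(index=False))
        for r1, r2 in zip(rows, rows[1:]):
            if r2.rank == r1.rank + 1:
                truth_adj[frozenset((r1.contig, r2.contig))] = (
                    r1.contig, r1.orientation, r2.contig, r2.orientation
                )

    recovered = 0
    orient_ok = 0
    for layout in layouts:
        for p, q in zip(layout.placements, layout.placements[1:]):
            key = frozenset((p.contig, q.contig))
            adj = truth_adj.get(key)
            if adj is None:
                continue
            recovered += 1
            a, sa, b, sb = adj
            if p.contig == a:  # layout order matches chromosome order
                ok = (
                    _effective_strand(p.orientation, sa) == "+"
                    and _effective_strand(q.orientation, sb) == "+"
                )
            else:  # layout runs against the chromosome
                ok = (
                    _effective_strand(p.orientation, sb) == "-"
                    and _effective_strand(q.orientation, sa) == "-"
                )
            if ok:
                orient_ok += 1
    return LayoutAccuracy(len(truth_adj), recovered, orient_ok)


@dataclass
class BreakAccuracy:
    n_junctions: int
    n_detected: int
    n_false_breaks: int
    n_clean_contigs: int

    @property
    def recall(self) -> float:
        return self.n_detected / self.n_junctions if self.n_junctions else float("nan")

    @property
    def false_breaks_per_10_clean(self) -> float:
        if not self.n_clean_contigs:
            return float("nan")
        return 10.0 * self.n_false_breaks / self.n_clean_contigs


def break_accuracy(
    calls: Sequence[BreakCall],
    chimera_truth: pd.DataFrame,
    n_contigs_total: int,
    tolerance: int = 5000,
) -> BreakAccuracy:
    """Score break calls against known chimera junctions.

    A junction counts as detected when some call on its contig has a
    midpoint within ``tolerance`` bases.  Any call that does not match a
    junction within tolerance is a false break; ``n_contigs_total`` minus the
    chimeric contigs gives the clean-contig denominator for the false-break
    rate.
    """
    junctions = {
        (row.contig, int(row.junction)) for row in chimera_truth.itertuples(index=False)
    }
    detected = set()
    false_breaks = 0
    for call in calls:
        hit = None
        for contig, junction in junctions:
            if call.contig == contig and abs(call.midpoint - junction) <= tolerance:
                hit = (contig, junction)
                break
        if hit is None:
            false_breaks += 1
        else:
            detected.add(hit)
    n_chim_contigs = len({c for c, _ in junctions})
    return BreakAccuracy(
        n_junctions=len(junctions),
        n_detected=len(detected),
        n_false_breaks=false_breaks,
        n_clean_contigs=n_contigs_total - n_chim_contigs,
    )
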