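"""End-to-end scaffolding pipeline with deterministic artifacts.

Stages, in order: parse and MAPQ-filter the alignments; detect and break
misassemblies from physical coverage (optional); count Hi-C links between
contig-end windows and normalize by restriction-site counts; build the
scaffold graph greedily; extract paths, classify seed scaffolds and insert
small-scaffold contigs; write FASTA/AGP and reports.  Identical inputs and
configuration produce byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import alignment_io, assembly_io, layout as layout_mod, misassembly, scaffold_graph
from .core import ContigSet, PairedAlignment
from .simulator import SimConfig, simulate_all, write_fixture


@dataclass
class RunConfig:
    """Parameters of one scaffolding run; echoed verbatim to the output dir."""

    contigs_fasta: str
    alignments: str
    out_dir: str
    dialect: str = "auto"  # sam | bed_pairs | auto (by extension)
    enzyme: Optional[list[str]] = None  # IUPAC motifs; None => raw-count mode
    raw_counts: bool = False
    end_window: int = 500_000  # link/RE counting window at each contig end
    mapq_threshold: int = 30
    min_links: int = 5
    n_th: int = 3  # contigs above which a scaffold seeds insertions
    gap_size: int = 500
    do_break: bool = True
    break_delta: Optional[float] = None  # None => per-contig auto level
    min_drop_span: int = 1000  # bases of total dropout a break must amount to
    edge_margin: int = 10_000
    dedup: bool = False
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def validate(self) -> None:
        if self.end_window <= 0:
            raise ValueError("end_window must be > 0")
        if self.mapq_threshold < 0:
            raise ValueError("mapq_threshold must be >= 0")
        if self.min_links < 0:
            raise ValueError("min_links must be >= 0")
        if self.n_th < 0:
            raise ValueError("n_th must be >= 0")
        if self.gap_size < 0:
            raise ValueError("gap_size must be >= 0")
        if self.edge_margin < 0 or self.min_drop_span <= 0:
            raise ValueError("edge_margin must be >= 0 and min_drop_span > 0")
        if not self.raw_counts and not self.enzyme:
            raise ValueError(
                "no restriction enzyme motif given: pass enzyme motifs for "
                "normalized weights, or enable raw_counts (--raw-counts) to "
                "weight edges by raw link counts"
            )


def run_scaffold(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a stats dict (also written to the log)."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    stats: dict[str, object] = {}

    contigs = assembly_io.read_fasta(cfg.contigs_fasta)
    stats["contigs_in"] = len(contigs)
    stats["bases_in"] = contigs.total_bases()

    pairs = list(alignment_io.read_alignments(cfg.alignments, cfg.dialect, contigs))
    stats["pairs_read"] = len(pairs)
    pairs = list(alignment_io.filter_by_mapq(pairs, cfg.mapq_threshold))
    stats["pairs_passing_mapq"] = len(pairs)
    if cfg.dedup:
        pairs = list(alignment_io.deduplicate(pairs))
        stats["pairs_after_dedup"] = len(pairs)

    calls: list[misassembly.BreakCall] = []
    if cfg.do_break:
        by_contig: dict[str, list[PairedAlignment]] = {}
        for p in pairs:
            if p.is_intra:
                by_contig.setdefault(p.contig1, []).append(p)
        for name in sorted(by_contig):
            calls.extend(
                misassembly.detect_breaks(
                    contigs[name],
                    by_contig[name],
                    delta=cfg.break_delta,
                    min_drop_span=cfg.min_drop_span,
                    edge_margin=cfg.edge_margin,
                )
            )
        contigs, remap = misassembly.break_contigs(contigs, calls)
        pairs = [remap.map_pair(p) for p in pairs]
        _write(cfg.out_dir, "remap.tsv", _remap_tsv(remap))
    stats["breaks_applied"] = len(calls)
    stats["contigs_after_break"] = len(contigs)
    _write(cfg.out_dir, "breaks.bed", misassembly.breaks_to_bed(calls))

    inter = [p for p in pairs if not p.is_intra]
    stats["inter_contig_pairs"] = len(inter)
    counts = scaffold_graph.count_links(inter, contigs, cfg.end_window)
    stats["end_pairs_linked"] = len(counts)
    motifs = None if cfg.raw_counts else cfg.enzyme
    candidates = scaffold_graph.make_candidate_edges(
        counts, contigs, cfg.end_window, motifs
    )
    graph = scaffold_graph.build_graph(
        candidates, contigs, cfg.min_links, params={"end_window": cfg.end_window}
    )
    graph.check_path_properties()
    stats["hic_edges_kept"] = graph.params["hic_edges_kept"]
    stats["cycles_broken"] = graph.params["cycles_broken"]
    _write(cfg.out_dir, "graph_edges.tsv", scaffold_graph.edges_to_tsv(graph))

    layouts = layout_mod.extract_paths(graph, cfg.n_th)
    stats["seed_scaffolds"] = sum(1 for s in layouts if s.is_seed)
    links = layout_mod.LinkIndex.from_edges(candidates)
    final = layout_mod.insert_small_contigs(layouts, links)
    stats["scaffolds_out"] = len(final)
    stats["contigs_placed"] = sum(len(s.placements) for s in final)
    _write(cfg.out_dir, "layout.tsv", layout_mod.layouts_to_tsv(final))

    assembly_io.write_scaffolds(
        final,
        contigs,
        cfg.gap_size,
        os.path.join(cfg.out_dir, "scaffolds.fasta"),
        os.path.join(cfg.out_dir, "scaffolds.agp"),
    )

    _write(
        cfg.out_dir,
        "config.json",
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n",
    )
    _write(
        cfg.out_dir,
        "run.log",
        "".join(f"{k}\t{stats[k]}\n" for k in sorted(stats)),
    )
    return stats


def run_simulate(cfg: SimConfig, out_dir: str) -> dict[str, str]:
    """Generate a simulation fixture directory (seeded-deterministic)."""
    result = simulate_all(cfg)
    return write_fixture(result, out_dir)


def run_break_only(cfg: RunConfig) -> list[misassembly.BreakCall]:
    """Misassembly detection alone: writes breaks.bed, broken FASTA and remap."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    contigs = assembly_io.read_fasta(cfg.contigs_fasta)
    pairs = alignment_io.filter_by_mapq(
        alignment_io.read_alignments(cfg.alignments, cfg.dialect, contigs),
        cfg.mapq_threshold,
    )
    by_contig: dict[str, list[PairedAlignment]] = {}
    for p in pairs:
        if p.is_intra:
            by_contig.setdefault(p.contig1, []).append(p)
    calls: list[misassembly.BreakCall] = []
    for name in sorted(by_contig):
        calls.extend(
            misassembly.detect_breaks(
                contigs[name],
                by_contig[name],
                delta=cfg.break_delta,
                min_drop_span=cfg.min_drop_span,
                edge_margin=cfg.edge_margin,
            )
        )
    broken, remap = misassembly.break_contigs(contigs, calls)
    _write(cfg.out_dir, "breaks.bed", misassembly.breaks_to_bed(calls))
    _write(cfg.out_dir, "remap.tsv", _remap_tsv(remap))
    assembly_io.write_fasta(
        ((c.name, c.sequence) for c in broken),
        os.path.join(cfg.out_dir, "contigs_broken.fasta"),
    )
    return calls


def _remap_tsv(remap: misassembly.RemapTable) -> str:
    lines = ["orig_contig\torig_start\torig_end\tnew_contig"]
    for orig, lo, hi, name in remap.to_rows():
        lines.append(f"{orig}\t{lo}\t{hi}\t{name}")
    return "\n".join(lines) + "\n"


def _write(out_dir: str, name: str, text: str) -> None:
    with open(os.path.join(out_dir, name), "w") as fh:
        fh.write(text)
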