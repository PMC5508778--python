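"""Synthetic genomes, contig sets and Hi-C read pairs with known truth.

The generator emulates the two properties of proximity-ligation data the
scaffolder relies on: contact probability is far higher within a chromosome
than between chromosomes, and intra-chromosomal contact probability decays
with genomic distance (modelled here as an exponential in the pair's
separation).  Chromosomes are uniform-random DNA, so restriction sites occur
at their natural density (GATC about every 256 bp); no site planting is
needed.

Fragmentation cuts each chromosome into contigs of uniform-random length,
optionally fuses a fraction of contigs from different chromosomes into
chimeras (recording the junction), reverse-complements contigs at random and
shuffles their names.  Read pairs are drawn in genome coordinates and mapped
through the truth tables into contig coordinates, emitted directly as
alignments with MAPQ 60.

All randomness flows from ``SimConfig.seed`` through one generator, so every
product is reproducible bit for bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .alignment_io import write_bed_pairs
from .assembly_io import write_fasta
from .core import Contig, ContigSet, PairedAlignment, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a small multi-chromosome genome: four 2-Mb
    chromosomes fragmented into ~60 contigs of 50–200 kb, 200,000 Hi-C
    pairs of which 10% are inter-chromosomal, and an intra-chromosomal
    contact distance that decays exponentially with a 20-kb scale.
    """

    n_chromosomes: int = 4
    chromosome_length: int = 2_000_000
    contig_length_min: int = 50_000
    contig_length_max: int = 200_000
    intra_decay_scale: float = 20_000.0
    p_inter: float = 0.1
    n_pairs: int = 200_000
    read_length: int = 100
    chimera_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be > 0")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")
        if not 0 < self.contig_length_min <= self.contig_length_max:
            raise ValueError("require 0 < contig_length_min <= contig_length_max")
        if self.contig_length_max > self.chromosome_length:
            raise ValueError("contig_length_max must not exceed chromosome_length")
        if self.intra_decay_scale <= 0:
            raise ValueError("intra_decay_scale must be > 0")
        if not 0.0 <= self.p_inter <= 1.0:
            raise ValueError("p_inter must be in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 0 < self.read_length <= self.contig_length_min:
            raise ValueError("read_length must be in (0, contig_length_min]")


# truth-table column conventions -------------------------------------------
# segments: contig, seg_index, chrom, chrom_start, chrom_end, contig_offset,
#           strand       -- maps genome loci into contig coordinates
# order:    chrom, rank, contig, orientation   -- non-chimeric contigs only
# chimeras: contig, junction, length


def simulate_genome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, str]:
    """Uniform-random DNA chromosomes named chr1..chrN."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    genome = {}
    for i in range(cfg.n_chromosomes):
        idx = rng.integers(0, 4, cfg.chromosome_length)
        genome[f"chr{i + 1}"] = _BASES[idx].tobytes().decode("ascii")
    return genome


@dataclass
class FragmentationTruth:
    """Truth tables produced by :func:`fragment_into_contigs`."""

    segments: pd.DataFrame
    order: pd.DataFrame
    chimeras: pd.DataFrame


def _cut_points(length: int, cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    # cut so every fragment stays within [min, max]; each draw leaves at
    # least contig_length_min for the remainder (requires max >= 2*min for
    # strict adherence; otherwise the last fragment may run slightly long)
    lo, hi_max = cfg.contig_length_min, cfg.contig_length_max
    cuts = [0]
    while length - cuts[-1] > hi_max:
        hi = max(lo, min(hi_max, length - cuts[-1] - lo))
        cuts.append(cuts[-1] + int(rng.integers(lo, hi + 1)))
    cuts.append(length)
    return cuts


def fragment_into_contigs(
    genome: dict[str, str],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ContigSet, FragmentationTruth]:
    """Cut chromosomes into contigs; optionally fuse some into chimeras.

    Each chromosome is cut at random points into fragments whose lengths are
    uniform in [contig_length_min, contig_length_max] (the last fragment
    absorbs the remainder).  ``chimera_rate`` of the fragments are paired —
    preferentially across chromosomes — and each pair concatenated into one
    chimeric contig with the junction recorded.  Every contig is then
    reverse-complemented with probability 1/2 and the name order shuffled.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 1)

    # fragments: (chrom, start, end, rank)
    fragments: list[tuple[str, int, int, int]] = []
    for chrom in genome:
        cuts = _cut_points(len(genome[chrom]), cfg, rng)
        for rank, (s, e) in enumerate(zip(cuts, cuts[1:])):
            fragments.append((chrom, s, e, rank))

    n_chimeras = int(round(cfg.chimera_rate * len(fragments)))
    chim_members: list[tuple[int, int]] = []
    if n_chimeras:
        pool = list(rng.permutation(len(fragments)))
        used: set[int] = set()
        for _ in range(n_chimeras):
            a = next((i for i in pool if i not in used), None)
            if a is None:
                break
            used.add(a)
            b = next(
                (i for i in pool if i not in used and fragments[i][0] != fragments[a][0]),
                None,
            )
            if b is None:
                b = next((i for i in pool if i not in used), None)
            if b is None:
                used.discard(a)
                break
            used.add(b)
            chim_members.append((a, b))
    in_chimera = {i for ab in chim_members for i in ab}

    # assemble contigs: list of (segment list, is_chimera); each segment is
    # a fragment index, kept in concatenation order
    contig_defs: list[tuple[list[int], bool]] = []
    for i, frag in enumerate(fragments):
        if i not in in_chimera:
            contig_defs.append(([i], False))
    for a, b in chim_members:
        contig_defs.append(([a, b], True))

    order = list(rng.permutation(len(contig_defs)))
    flipped = rng.random(len(contig_defs)) < 0.5

    contigs = ContigSet()
    seg_rows, order_rows, chim_rows = [], [], []
    for new_idx, def_idx in enumerate(order):
        seg_ids, is_chim = contig_defs[def_idx]
        name = f"contig_{new_idx:04d}"
        flip = bool(flipped[def_idx])
        seqs = [genome[fragments[i][0]][fragments[i][1] : fragments[i][2]] for i in seg_ids]
        seq = "".join(seqs)
        if flip:
            seq = reverse_complement(seq)
        contigs.add(Contig(name, len(seq), seq))

        # per-segment placement within the (possibly flipped) contig
        lengths = [fragments[i][2] - fragments[i][1] for i in seg_ids]
        placed = list(zip(seg_ids, lengths))
        if flip:
            placed = placed[::-1]
        offset = 0
        for seg_index, (frag_idx, ln) in enumerate(placed):
            chrom, s, e, rank = fragments[frag_idx]
            seg_rows.append(
                dict(
                    contig=name,
                    seg_index=seg_index,
                    chrom=chrom,
                    chrom_start=s,
                    chrom_end=e,
                    contig_offset=offset,
                    strand="-" if flip else "+",
                )
            )
            offset += ln
        if is_chim:
            junction = lengths[1] if flip else lengths[0]
            chim_rows.append(dict(contig=name, junction=junction, length=len(seq)))
        else:
            chrom, s, e, rank = fragments[seg_ids[0]]
            order_rows.append(
                dict(chrom=chrom, rank=rank, contig=name, orientation="-" if flip else "+")
            )

    truth = FragmentationTruth(
        segments=pd.DataFrame(seg_rows),
        order=pd.DataFrame(order_rows).sort_values(["chrom", "rank"]).reset_index(drop=True)
        if order_rows
        else pd.DataFrame(columns=["chrom", "rank", "contig", "orientation"]),
        chimeras=pd.DataFrame(chim_rows)
        if chim_rows
        else pd.DataFrame(columns=["contig", "junction", "length"]),
    )
    return contigs, truth


def _sample_loci(
    n: int, chrom_lengths: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom index, position) pairs uniform over the genome."""
    cum = np.concatenate(([0], np.cumsum(chrom_lengths)))
    g = rng.integers(0, cum[-1], n)
    c = np.searchsorted(cum, g, side="right") - 1
    return c, g - cum[c]


def _reflect(x: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Fold positions into [0, upper] by triangular reflection."""
    period = 2 * upper
    y = np.abs(x) % period
    return np.where(y > upper, period - y, y)


def simulate_hic_pairs(
    genome: dict[str, str],
    truth: FragmentationTruth,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Hi-C read pairs in contig coordinates, with genome-coordinate truth.

    Each pair is inter-chromosomal with probability ``p_inter`` (both loci
    uniform, chromosomes forced distinct); otherwise one locus is uniform
    and its mate lies at a signed exponential distance (scale
    ``intra_decay_scale``), reflected at the chromosome ends.  Loci are
    mapped through the fragmentation truth into contig coordinates; pairs
    landing in one contig are kept (they feed misassembly detection).

    Returns a DataFrame with the PairedAlignment columns plus truth columns
    ``chrom1, gpos1, chrom2, gpos2, is_inter``.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    chroms = list(genome)
    L = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    rl = cfg.read_length
    n = cfg.n_pairs
    max_start = L - rl  # highest valid read start per chromosome

    c1, x1 = _sample_loci(n, L, rng)
    x1 = np.minimum(x1, max_start[c1])
    inter = rng.random(n) < cfg.p_inter

    # intra mates: signed exponential distance, reflected into range
    d = rng.exponential(cfg.intra_decay_scale, n) * rng.choice((-1, 1), n)
    x2 = _reflect(x1 + d.astype(np.int64), max_start[c1])
    c2 = c1.copy()

    # inter mates: uniform locus on a different chromosome
    idx = np.flatnonzero(inter)
    if len(idx) and len(chroms) > 1:
        ci, xi = _sample_loci(len(idx), L, rng)
        for _ in range(100):
            clash = ci == c1[idx]
            if not clash.any():
                break
            ci2, xi2 = _sample_loci(int(clash.sum()), L, rng)
            ci[clash], xi[clash] = ci2, xi2
        else:
            ci[clash] = (ci[clash] + 1) % len(chroms)
        c2[idx] = ci
        x2[idx] = np.minimum(xi, max_start[ci])
    elif len(idx):
        inter[:] = False  # single-chromosome genome has no inter contacts

    contig1, pos1, strand1 = _map_to_contigs(c1, x1, chroms, truth.segments, rl)
    contig2, pos2, strand2 = _map_to_contigs(c2, x2, chroms, truth.segments, rl)

    return pd.DataFrame(
        dict(
            read_id=[f"pair_{i:07d}" for i in range(n)],
            contig1=contig1,
            pos1=pos1,
            end1=pos1 + rl,
            strand1=strand1,
            mapq1=np.full(n, 60, dtype=np.int64),
            contig2=contig2,
            pos2=pos2,
            end2=pos2 + rl,
            strand2=strand2,
            mapq2=np.full(n, 60, dtype=np.int64),
            chrom1=[chroms[i] for i in c1],
            gpos1=x1,
            chrom2=[chroms[i] for i in c2],
            gpos2=x2,
            is_inter=inter,
        )
    )


def _map_to_contigs(
    c: np.ndarray,
    x: np.ndarray,
    chroms: list[str],
    segments: pd.DataFrame,
    read_length: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map genome read-start loci to (contig, contig position, strand).

    Read starts are nudged so the whole read fits inside one truth segment
    (segments are far longer than a read, so the shift is at most the read
    length)."""
    contig_out = np.empty(len(x), dtype=object)
    pos_out = np.zeros(len(x), dtype=np.int64)
    strand_out = np.empty(len(x), dtype=object)
    for ci, chrom in enumerate(chroms):
        seg = segments[segments.chrom == chrom].sort_values("chrom_start")
        starts = seg.chrom_start.to_numpy()
        ends = seg.chrom_end.to_numpy()
        names = seg.contig.to_numpy()
        offs = seg.contig_offset.to_numpy()
        strands = seg.strand.to_numpy()
        mask = c == ci
        if not mask.any():
            continue
        xi = x[mask]
        si = np.searchsorted(starts, xi, side="right") - 1
        # keep the read inside its segment
        xi = np.minimum(xi, ends[si] - read_length)
        xi = np.maximum(xi, starts[si])
        fwd = strands[si] == "+"
        cpos = np.where(
            fwd,
            offs[si] + (xi - starts[si]),
            offs[si] + (ends[si] - xi - read_length),
        )
        contig_out[mask] = names[si]
        pos_out[mask] = cpos
        strand_out[mask] = np.where(fwd, "+", "-")
    return contig_out, pos_out, strand_out


def pairs_to_alignments(df: pd.DataFrame) -> Iterator[PairedAlignment]:
    """Iterate a simulated pair table as PairedAlignment records."""
    cols = [
        "read_id", "contig1", "pos1", "end1", "strand1", "mapq1",
        "contig2", "pos2", "end2", "strand2", "mapq2",
    ]
    for row in df[cols].itertuples(index=False):
        yield PairedAlignment(*row)


def contact_probability_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome intra- vs inter-chromosomal contact probability.

    For each chromosome, of all pairs touching it (either mate), the
    fraction with both mates on it (intra) versus one mate elsewhere
    (inter).
    """
    chroms = sorted(set(df.chrom1) | set(df.chrom2))
    rows = []
    for c in chroms:
        touch = (df.chrom1 == c) | (df.chrom2 == c)
        n_touch = int(touch.sum())
        n_intra = int(((df.chrom1 == c) & (df.chrom2 == c)).sum())
        intra = n_intra / n_touch if n_touch else float("nan")
        rows.append(
            dict(chrom=c, n_touching=n_touch, intra_probability=intra,
                 inter_probability=1.0 - intra if n_touch else float("nan"))
        )
    return pd.DataFrame(rows)


@dataclass
class SimResult:
    """Everything one simulation run produces."""

    cfg: SimConfig
    genome: dict[str, str]
    contigs: ContigSet
    truth: FragmentationTruth
    pairs: pd.DataFrame = field(repr=False)


def simulate_all(cfg: SimConfig) -> SimResult:
    """Genome -> contigs -> Hi-C pairs under a single seeded generator."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg, rng)
    contigs, truth = fragment_into_contigs(genome, cfg, rng)
    pairs = simulate_hic_pairs(genome, truth, cfg, rng)
    return SimResult(cfg, genome, contigs, truth, pairs)


def write_fixture(result: SimResult, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a complete simulation fixture directory; returns file paths."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "genome": os.path.join(out, "genome.fasta"),
        "contigs": os.path.join(out, "contigs.fasta"),
        "pairs": os.path.join(out, "pairs.bed"),
        "truth_order": os.path.join(out, "truth_order.tsv"),
        "truth_segments": os.path.join(out, "truth_segments.tsv"),
        "truth_chimeras": os.path.join(out, "truth_chimeras.tsv"),
        "config": os.path.join(out, "sim_config.json"),
    }
    write_fasta(sorted(result.genome.items()), paths["genome"])
    write_fasta(((c.name, c.sequence) for c in result.contigs), paths["contigs"])
    write_bed_pairs(pairs_to_alignments(result.pairs), paths["pairs"])
    result.truth.order.to_csv(paths["truth_order"], sep="\t", index=False)
    result.truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    result.truth.chimeras.to_csv(paths["truth_chimeras"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(result.cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
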