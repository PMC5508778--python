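"""FASTA input and scaffold FASTA/AGP output.

Scaffold records concatenate the oriented contig sequences (reverse
placements reverse-complemented) separated by runs of ``N`` of a fixed gap
size; the AGP file describes the identical structure in AGP v2.1 terms, so
the two outputs can always be cross-reconstructed.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .core import Contig, ContigSet, FORWARD, ScaffoldLayout, reverse_complement

FASTA_WIDTH = 60

AGP_GAP_TYPE = "scaffold"
AGP_LINKAGE = "yes"
AGP_EVIDENCE = "proximity_ligation"


def read_fasta(path: str | os.PathLike) -> ContigSet:
    """Load a contig FASTA; names are the first whitespace token, sequences
    uppercased.  Duplicate names raise."""
    contigs = ContigSet()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper()
        contigs.add(Contig(rec.id, len(seq), seq))
    return contigs


def write_fasta(contigs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence) records at fixed line width."""
    with open(path, "w") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def scaffold_sequence(
    layout: ScaffoldLayout, contigs: ContigSet, gap_size: int
) -> str:
    """Concatenated oriented contig sequences separated by N runs."""
    parts = []
    for p in layout.placements:
        contig = contigs[p.contig]
        if contig.sequence is None:
            raise ValueError(f"contig {p.contig!r} has no sequence")
        seq = contig.sequence if p.orientation == FORWARD else reverse_complement(contig.sequence)
        parts.append(seq)
    return ("N" * gap_size).join(parts)


def _scaffold_names(
    layouts: list[ScaffoldLayout], contigs: ContigSet, gap_size: int
) -> list[tuple[str, ScaffoldLayout]]:
    # deterministic naming: scaffold_<k> by decreasing scaffold length,
    # ties by layout id
    def length(layout: ScaffoldLayout) -> int:
        n = len(layout.placements)
        return sum(contigs[p.contig].length for p in layout.placements) + (n - 1) * gap_size

    ordered = sorted(layouts, key=lambda s: (-length(s), s.id))
    return [(f"scaffold_{k}", s) for k, s in enumerate(ordered, start=1)]


def write_scaffolds(
    layouts: list[ScaffoldLayout],
    contigs: ContigSet,
    gap_size: int,
    fasta_path: str | os.PathLike,
    agp_path: str | os.PathLike,
) -> dict[str, str]:
    """Write scaffold FASTA and the matching AGP v2.1; returns
    {scaffold name: layout id}."""
    named = _scaffold_names(layouts, contigs, gap_size)
    write_fasta(
        ((name, scaffold_sequence(s, contigs, gap_size)) for name, s in named),
        fasta_path,
    )
    with open(agp_path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for name, layout in named:
            fh.write(agp_lines(name, layout, contigs, gap_size))
    return {name: s.id for name, s in named}


def agp_lines(
    scaffold_name: str, layout: ScaffoldLayout, contigs: ContigSet, gap_size: int
) -> str:
    """AGP v2.1 component (W) and gap (N) lines for one scaffold."""
    out = []
    pos = 1  # AGP coordinates are 1-based inclusive
    part = 1
    for i, p in enumerate(layout.placements):
        if i > 0 and gap_size > 0:
            out.append(
                f"{scaffold_name}\t{pos}\t{pos + gap_size - 1}\t{part}\tN\t"
                f"{gap_size}\t{AGP_GAP_TYPE}\t{AGP_LINKAGE}\t{AGP_EVIDENCE}"
            )
            pos += gap_size
            part += 1
        length = contigs[p.contig].length
        strand = "+" if p.orientation == FORWARD else "-"
        out.append(
            f"{scaffold_name}\t{pos}\t{pos + length - 1}\t{part}\tW\t"
            f"{p.contig}\t1\t{length}\t{strand}"
        )
        pos += length
        part += 1
    return "\n".join(out) + "\n"


def reconstruct_from_agp(
    agp_path: str | os.PathLike, contigs: ContigSet
) -> dict[str, str]:
    """Rebuild scaffold sequences from an AGP file and the contig set.

    Used to verify that FASTA and AGP outputs describe the same assembly.
    """
    scaffolds: dict[str, list[str]] = {}
    with open(agp_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            obj, beg, end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            parts = scaffolds.setdefault(obj, [])
            if ctype == "N":
                parts.append("N" * int(f[5]))
            elif ctype == "W":
                comp, cbeg, cend, strand = f[5], int(f[6]), int(f[7]), f[8]
                seq = contigs[comp].sequence[cbeg - 1 : cend]
                if strand == "-":
                    seq = reverse_complement(seq)
                parts.append(seq)
            else:
                raise ValueError(f"unsupported AGP component type {ctype!r}")
            if len(parts[-1]) != end - beg + 1:
                raise ValueError(f"AGP part length mismatch in {obj!r}")
    return {name: "".join(parts) for name, parts in scaffolds.items()}
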