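"""Read, filter and pair Hi-C alignments from SAM/BAM or the bed_pairs dialect.

Only read pairs with *both* mates mapped enter the pipeline; secondary and
supplementary SAM records are ignored entirely.  The MAPQ filter drops a pair
when either mate has mapping quality at or below the threshold, which also
removes multi-mapping reads (aligners assign them MAPQ 0).

The ``bed_pairs`` dialect is a plain tab-separated text format with ten
columns::

    contig1  start1  end1  contig2  start2  end2  read_id  mapq1  mapq2  strands

Coordinates are 0-based half-open; ``strands`` is two characters such as
``+-``; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import pysam

from .core import ContigSet, PairedAlignment

BED_PAIRS_COLUMNS = (
    "contig1",
    "start1",
    "end1",
    "contig2",
    "start2",
    "end2",
    "read_id",
    "mapq1",
    "mapq2",
    "strands",
)


class AlignmentParseError(ValueError):
    """Malformed alignment record; carries the offending line number."""


def read_alignments(
    path: str | os.PathLike,
    dialect: str = "auto",
    contigs: Optional[ContigSet] = None,
) -> Iterator[PairedAlignment]:
    """Yield one :class:`PairedAlignment` per read pair with both mates mapped.

    Parameters
    ----------
    path
        SAM/BAM file or bed_pairs text file.
    dialect
        ``"sam"``, ``"bed_pairs"`` or ``"auto"`` (by file extension:
        ``.sam``/``.bam`` are SAM, anything else bed_pairs).
    contigs
        When given, every referenced contig name is validated against it.
    """
    path = os.fspath(path)
    if dialect == "auto":
        dialect = "sam" if path.endswith((".sam", ".bam", ".cram")) else "bed_pairs"
    if dialect == "sam":
        yield from _read_sam(path, contigs)
    elif dialect == "bed_pairs":
        yield from _read_bed_pairs(path, contigs)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_sam(path: str, contigs: Optional[ContigSet]) -> Iterator[PairedAlignment]:
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            pair = _pair_from_sam(other, rec, contigs)
            if pair is not None:
                yield pair
    # reads left unpaired (mate record absent from the file) are dropped


def _pair_from_sam(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, contigs: Optional[ContigSet]
) -> Optional[PairedAlignment]:
    if a.is_unmapped or b.is_unmapped:
        return None
    if a.is_read2 and not b.is_read2:
        a, b = b, a
    for rec in (a, b):
        if contigs is not None and rec.reference_name not in contigs:
            raise AlignmentParseError(
                f"read {rec.query_name!r} maps to unknown contig {rec.reference_name!r}"
            )
    return PairedAlignment(
        read_id=a.query_name,
        contig1=a.reference_name,
        pos1=a.reference_start,
        end1=a.reference_end,
        strand1="-" if a.is_reverse else "+",
        mapq1=a.mapping_quality,
        contig2=b.reference_name,
        pos2=b.reference_start,
        end2=b.reference_end,
        strand2="-" if b.is_reverse else "+",
        mapq2=b.mapping_quality,
    )


def _read_bed_pairs(path: str, contigs: Optional[ContigSet]) -> Iterator[PairedAlignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BED_PAIRS_COLUMNS):
                raise AlignmentParseError(
                    f"{path}:{lineno}: expected {len(BED_PAIRS_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                c1, s1, e1, c2, s2, e2, rid, q1, q2, strands = fields
                pair = PairedAlignment(
                    read_id=rid,
                    contig1=c1,
                    pos1=int(s1),
                    end1=int(e1),
                    strand1=strands[0],
                    mapq1=int(q1),
                    contig2=c2,
                    pos2=int(s2),
                    end2=int(e2),
                    strand2=strands[1],
                    mapq2=int(q2),
                )
            except (ValueError, IndexError) as exc:
                raise AlignmentParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            for name in (pair.contig1, pair.contig2):
                if contigs is not None and name not in contigs:
                    raise AlignmentParseError(
                        f"{path}:{lineno}: unknown contig {name!r}"
                    )
            if pair.pos1 >= pair.end1 or pair.pos2 >= pair.end2:
                raise AlignmentParseError(
                    f"{path}:{lineno}: empty or inverted mate interval"
                )
            yield pair


def write_bed_pairs(pairs: Iterable[PairedAlignment], path: str | os.PathLike) -> int:
    """Write pairs in the bed_pairs dialect; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BED_PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.contig1}\t{p.pos1}\t{p.end1}\t{p.contig2}\t{p.pos2}\t{p.end2}\t"
                f"{p.read_id}\t{p.mapq1}\t{p.mapq2}\t{p.strand1}{p.strand2}\n"
            )
            n += 1
    return n


def filter_by_mapq(
    pairs: Iterable[PairedAlignment], threshold: int = 30
) -> Iterator[PairedAlignment]:
    """Keep only pairs where both mates exceed the MAPQ threshold.

    The default of 30 discards low-confidence and multi-mapped reads; a pair
    is dropped when *either* mate fails.
    """
    if threshold < 0:
        raise ValueError("mapq threshold must be >= 0")
    for p in pairs:
        if p.mapq1 > threshold and p.mapq2 > threshold:
            yield p


def deduplicate(pairs: Iterable[PairedAlignment]) -> Iterator[PairedAlignment]:
    """Drop coordinate-identical pairs (optional PCR-duplicate removal).

    Two pairs are duplicates when both mates share contig, start and end,
    regardless of mate order.
    """
    seen: set[tuple] = set()
    for p in pairs:
        k1 = (p.contig1, p.pos1, p.end1)
        k2 = (p.contig2, p.pos2, p.end2)
        key = (k1, k2) if k1 <= k2 else (k2, k1)
        if key in seen:
            continue
        seen.add(key)
        yield p
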