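"""Misassembly detection from Hi-C physical coverage.

A read pair's *physical coverage* is the full interval spanned by both mates
and the gap between them.  Per-base physical coverage along a contig counts
how many pairs span each base.  A genuine chimeric join shows up as a
contiguous stretch where physical coverage drops well below its neighbourhood,
because few proximity-ligation pairs bridge two unrelated loci.  We locate the
stretch with the minimum-sum-subarray variant of Kadane's algorithm on the
mean-shifted coverage array and break the contig at the midpoint of the
flagged interval.

Contig ends always ramp down to zero coverage (no pair can span past an end),
so candidate intervals whose midpoint falls within ``edge_margin`` of an end
are rejected rather than broken.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import BreakCall, Contig, ContigSet, PairedAlignment

Span = tuple[int, int]


@dataclass
class PhysicalCoverageProfile:
    """Per-base physical coverage of Hi-C pairs along one contig."""

    contig: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage)
        if self.coverage.ndim != 1:
            raise ValueError("coverage must be one-dimensional")
        if len(self.coverage) and self.coverage.min() < 0:
            raise ValueError("coverage values must be >= 0")


def pair_span(pair: PairedAlignment) -> Span:
    """Interval spanned by both mates and the gap between them."""
    return (min(pair.pos1, pair.pos2), max(pair.end1, pair.end2))


def coverage_from_spans(length: int, spans: Iterable[Span]) -> np.ndarray:
    """Per-base coverage from [start, end) spans, by difference-array sums."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for lo, hi in spans:
        diff[lo] += 1
        diff[hi] -= 1
    return np.cumsum(diff[:-1])


def physical_coverage(
    pairs: Iterable[PairedAlignment], contig: Contig
) -> PhysicalCoverageProfile:
    """Per-base physical coverage of intra-contig pairs on ``contig``.

    Every pair must have both mates on the named contig.
    """
    spans = []
    for p in pairs:
        if p.contig1 != contig.name or p.contig2 != contig.name:
            raise ValueError(
                f"pair {p.read_id!r} references {p.contig1}/{p.contig2}, "
                f"not contig {contig.name!r}"
            )
        spans.append(pair_span(p))
    return PhysicalCoverageProfile(contig.name, coverage_from_spans(contig.length, spans))


def _min_sum_subarray(a: np.ndarray) -> tuple[int, int, float]:
    """Minimum-sum contiguous subarray of ``a``: (start, end, sum).

    Linear-time via prefix sums: the subarray (i, j] minimizing
    ``S[j] - S[i]`` takes, for each j, the running maximum prefix before it.
    First-occurrence argmin/argmax give deterministic tie-breaks.
    """
    s = np.concatenate(([0.0], np.cumsum(a, dtype=np.float64)))
    run_max = np.maximum.accumulate(s[:-1])
    best = s[1:] - run_max
    j = int(np.argmin(best))
    i = int(np.argmax(s[: j + 1]))
    return i, j + 1, float(best[j])


def find_low_coverage_interval(
    profile: PhysicalCoverageProfile, delta: float
) -> Optional[BreakCall]:
    """Deepest coverage-deficit interval relative to expected level ``delta``.

    Returns the contiguous interval minimizing ``sum(coverage[i] - delta)``
    (the minimum-sum-subarray variant of Kadane's algorithm), or ``None``
    when no interval has a negative sum.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if len(profile.coverage) == 0:
        raise ValueError(f"empty coverage profile for contig {profile.contig!r}")
    i, j, total = _min_sum_subarray(profile.coverage.astype(np.float64) - delta)
    if total >= 0:
        return None
    return BreakCall(profile.contig, i, j, total)


def default_delta(coverage: np.ndarray) -> Optional[float]:
    """Expected-coverage level: half the median of the nonzero per-base values."""
    nz = coverage[coverage > 0]
    if len(nz) == 0:
        return None
    return float(np.median(nz)) / 2.0


def detect_breaks(
    contig: Contig,
    pairs: Iterable[PairedAlignment],
    delta: Optional[float] = None,
    min_drop_span: int = 1000,
    edge_margin: int = 10_000,
) -> list[BreakCall]:
    """All accepted misjoin calls on one contig, by iterated deepest-first search.

    The deepest deficit interval is found with
    :func:`find_low_coverage_interval`; if its midpoint clears ``edge_margin``
    from both ends and its deficit magnitude is at least ``delta *
    min_drop_span`` (the deficit a total dropout of ``min_drop_span`` bases
    would produce), the contig is split at the interval midpoint and the
    search recurses on the two halves using only pairs fully contained in
    each.  Intervals rejected by the edge rule are masked and the search
    continues elsewhere on the same (sub)contig.

    ``delta=None`` recomputes the expected level per (sub)contig via
    :func:`default_delta`.  Calls are reported in original-contig
    coordinates, deepest first.
    """
    spans = [pair_span(p) for p in pairs]
    calls: list[BreakCall] = []

    def rec(offset: int, length: int, spans: Sequence[Span]) -> None:
        if length <= 2 * edge_margin:
            return
        cov = coverage_from_spans(length, spans)
        d = delta if delta is not None else default_delta(cov)
        if d is None or d <= 0:
            return
        threshold = d * min_drop_span
        work = cov.astype(np.float64) - d
        while True:
            i, j, total = _min_sum_subarray(work)
            if total >= 0 or -total < threshold:
                return
            mid = (i + j) // 2
            if mid >= edge_margin and length - mid >= edge_margin:
                calls.append(BreakCall(contig.name, offset + i, offset + j, total))
                left = [s for s in spans if s[1] <= mid]
                right = [(lo - mid, hi - mid) for lo, hi in spans if lo >= mid]
                rec(offset, mid, left)
                rec(offset + mid, length - mid, right)
                return
            work[i:j] = 0.0  # edge artefact: neutralize and keep searching

    rec(0, contig.length, spans)
    return sorted(calls, key=lambda c: (c.score, c.start))


@dataclass
class RemapTable:
    """Maps original-contig coordinates to post-break (contig, coordinate).

    ``pieces[name]`` is an ordered list of (orig_start, orig_end, new_name)
    tiling each original contig; contigs never broken map to themselves.
    """

    pieces: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def map(self, contig: str, pos: int) -> tuple[str, int]:
        parts = self.pieces.get(contig)
        if parts is None:
            return contig, pos
        idx = bisect.bisect_right([p[0] for p in parts], pos) - 1
        lo, hi, name = parts[max(idx, 0)]
        if not lo <= pos < hi:
            raise ValueError(f"position {pos} outside contig {contig!r}")
        return name, pos - lo

    def map_pair(self, pair: PairedAlignment) -> PairedAlignment:
        """Remap both mates; mate intervals are clipped at new contig ends."""
        c1, p1 = self.map(pair.contig1, pair.pos1)
        c2, p2 = self.map(pair.contig2, pair.pos2)
        len1 = self._piece_length(pair.contig1, c1)
        len2 = self._piece_length(pair.contig2, c2)
        e1 = min(p1 + (pair.end1 - pair.pos1), len1)
        e2 = min(p2 + (pair.end2 - pair.pos2), len2)
        return pair._replace(contig1=c1, pos1=p1, end1=e1, contig2=c2, pos2=p2, end2=e2)

    def _piece_length(self, orig: str, new: str) -> int:
        parts = self.pieces.get(orig)
        if parts is None:
            return 1 << 62  # unbroken: no clipping needed
        for lo, hi, name in parts:
            if name == new:
                return hi - lo
        raise KeyError(new)

    def to_rows(self) -> list[tuple[str, int, int, str]]:
        rows = []
        for orig in sorted(self.pieces):
            for lo, hi, name in self.pieces[orig]:
                rows.append((orig, lo, hi, name))
        return rows


def break_contigs(
    contigs: ContigSet,
    calls: Iterable[BreakCall],
    min_score_magnitude: float = 0.0,
    edge_margin: int = 0,
) -> tuple[ContigSet, RemapTable]:
    """Split contigs at the midpoints of accepted break calls.

    Calls are applied deepest-deficit first.  A call is accepted when its
    deficit magnitude reaches ``min_score_magnitude`` and its midpoint lies at
    least ``edge_margin`` bases from both ends of the piece that currently
    contains it.  A split replaces piece ``<name>`` with ``<name>_1`` and
    ``<name>_2`` (recursively for further calls).  Total bases are conserved.
    """
    pieces: dict[str, list[tuple[int, int, str]]] = {}
    for call in sorted(calls, key=lambda c: (c.score, c.contig, c.start)):
        if call.contig not in contigs:
            raise ValueError(f"break call references unknown contig {call.contig!r}")
        if abs(call.score) < min_score_magnitude:
            continue
        length = contigs[call.contig].length
        parts = pieces.setdefault(call.contig, [(0, length, call.contig)])
        mid = call.midpoint
        idx = bisect.bisect_right([p[0] for p in parts], mid) - 1
        lo, hi, name = parts[idx]
        if mid - lo < edge_margin or hi - mid < edge_margin or mid <= lo or mid >= hi:
            continue
        parts[idx : idx + 1] = [(lo, mid, f"{name}_1"), (mid, hi, f"{name}_2")]

    remap = RemapTable({k: v for k, v in pieces.items() if len(v) > 1})
    out = ContigSet()
    for contig in contigs:
        parts = remap.pieces.get(contig.name)
        if parts is None:
            out.add(contig)
            continue
        for lo, hi, name in parts:
            seq = contig.sequence[lo:hi] if contig.sequence is not None else None
            out.add(Contig(name, hi - lo, seq))
    return out, remap


def breaks_to_bed(calls: Iterable[BreakCall]) -> str:
    """BED text (contig, start, end, score) for a collection of break calls."""
    lines = [
        f"{c.contig}\t{c.start}\t{c.end}\t{c.score:.6g}"
        for c in sorted(calls, key=lambda c: (c.contig, c.start))
    ]
    return "\n".join(lines) + ("\n" if lines else "")
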