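"""Quadripartite plastome architecture detection.

Land-plant plastomes are circular molecules partitioned into a large
single-copy region (LSC), a small single-copy region (SSC), and two
identical inverted repeats (IRa/IRb) separating them.  This module finds
maximal exact inverted-repeat pairs by k-mer seeding of the genome
against its reverse complement with run merging, takes the longest pair
as IRa/IRb, and normalizes the rotation so the LSC starts at position 1
followed by IRa, SSC, IRb.

Only exact repeats are considered (assembled plastome IRs are typically
identical); detection is invariant under rotation of the circular input
and under reverse complementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import SequenceRecord
from .pcr import reverse_complement


class StructureDetectionError(ValueError):
    """Raised when no quadripartite structure can be detected."""


@dataclass(frozen=True)
class RepeatPair:
    """An exact inverted-repeat pair on a circular genome.

    ``a_start``/``b_start`` are 0-based start positions on the input
    sequence; intervals may wrap the origin (end = start + length mod N).
    """

    a_start: int
    b_start: int
    length: int
    genome_length: int

    @property
    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """0-based half-open intervals; ends may exceed N to denote wrap."""
        return (
            (self.a_start, self.a_start + self.length),
            (self.b_start, self.b_start + self.length),
        )


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRa/SSC/IRb partition, 1-based inclusive on the normalized
    (LSC-first) rotation of the genome."""

    genome_id: str
    total: int
    lsc: tuple[int, int, int]  # (start, end, length)
    ira: tuple[int, int, int]
    ssc: tuple[int, int, int]
    irb: tuple[int, int, int]
    rotation_offset: int
    normalized_sequence: str

    def lengths(self) -> tuple[int, int, int, int]:
        return (self.lsc[2], self.ira[2], self.ssc[2], self.irb[2])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.genome_id, name, *coords)
            for name, coords in zip(
                ("LSC", "IRa", "SSC", "IRb"), (self.lsc, self.ira, self.ssc, self.irb)
            )
        ]
        return pd.DataFrame(rows, columns=["genome", "region", "start", "end", "length"])

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.to_frame().iterrows():
                fh.write(
                    f"{row.genome}\t{row.start - 1}\t{row.end}\t{row.region}\n"
                )


def _circular_overlap(a: int, b: int, length: int, n: int) -> bool:
    """Do circular arcs [a, a+length) and [b, b+length) (mod n) overlap?"""
    return ((b - a) % n) < length or ((a - b) % n) < length


def find_inverted_repeats(
    seq: SequenceRecord,
    min_length: int = 1000,
    k: int = 25,
) -> list[RepeatPair]:
    """Maximal exact inverted-repeat pairs of length >= ``min_length``.

    Seeds k-mers of the (doubled, for circular templates) sequence
    against its reverse complement, merges seed runs along diagonals
    into maximal matches, and reports disjoint pairs longest-first.
    """
    s = seq.seq
    n = len(s)
    if min_length > n or n < k or min_length < k:
        if min_length < k and min_length <= n:
            k = max(4, min_length)  # allow small repeats in small test inputs
        else:
            return []
    text = s + s if seq.circular else s
    lt = len(text)
    rc = reverse_complement(text)

    index: dict[str, list[int]] = {}
    for i in range(lt - k + 1):
        index.setdefault(text[i : i + k], []).append(i)

    # matches between rc and text grouped by diagonal d = i_text - p_rc
    diagonals: dict[int, list[int]] = {}
    for p in range(lt - k + 1):
        for i in index.get(rc[p : p + k], ()):
            diagonals.setdefault(i - p, []).append(p)

    pairs: dict[tuple[frozenset[int], int], RepeatPair] = {}
    for d, ps in diagonals.items():
        ps.sort()
        run_start = prev = ps[0]
        runs = []
        for p in ps[1:]:
            if p == prev + 1:
                prev = p
                continue
            runs.append((run_start, prev))
            run_start = prev = p
        runs.append((run_start, prev))
        for p0, p1 in runs:
            length = p1 - p0 + k
            if length < min_length or length > n:
                continue
            i0 = p0 + d  # match interval in text: [i0, i0+length)
            b0 = lt - (p1 + k)  # partner interval in text coordinates
            a, b = i0 % n, b0 % n
            if _circular_overlap(a, b, length, n) if seq.circular else not (
                a + length <= b or b + length <= a
            ):
                continue
            key = (frozenset((a, b)), length)
            pairs.setdefault(key, RepeatPair(min(a, b), max(a, b), length, n))

    ranked = sorted(pairs.values(), key=lambda r: (-r.length, r.a_start, r.b_start))

    def contained(inner: RepeatPair, outer: RepeatPair) -> bool:
        def arc_in(p: int, lp: int, q: int, lq: int) -> bool:
            return ((p - q) % n) + lp <= lq

        return (
            arc_in(inner.a_start, inner.length, outer.a_start, outer.length)
            and arc_in(inner.b_start, inner.length, outer.b_start, outer.length)
        ) or (
            arc_in(inner.a_start, inner.length, outer.b_start, outer.length)
            and arc_in(inner.b_start, inner.length, outer.a_start, outer.length)
        )

    kept: list[RepeatPair] = []
    for pair in ranked:
        if not any(contained(pair, q) for q in kept):
            kept.append(pair)
    return kept


def partition_quadripartite(
    seq: SequenceRecord,
    min_ir: int = 1000,
    k: int = 25,
) -> QuadripartiteStructure:
    """Partition a circular plastome into LSC/IRa/SSC/IRb.

    The longest exact inverted-repeat pair defines the IRs; of the two
    single-copy arcs between them the longer is the LSC (tie-break: the
    arc clockwise of the first repeat copy).  The template is always
    treated as circular.  Raises :class:`StructureDetectionError` when
    no repeat of at least ``min_ir`` bp exists.
    """
    circular = seq if seq.circular else SequenceRecord(seq.id, seq.seq, circular=True)
    pairs = find_inverted_repeats(circular, min_length=min_ir, k=k)
    if not pairs:
        raise StructureDetectionError(
            f"{seq.id}: no quadripartite structure detected (no inverted repeat "
            f">= {min_ir} bp)"
        )
    ir = pairs[0]
    n = len(seq.seq)
    a, b, L = ir.a_start, ir.b_start, ir.length
    arc_after_a = (b - (a + L)) % n
    arc_after_b = (a - (b + L)) % n
    if arc_after_a >= arc_after_b:
        lsc_len, ssc_len = arc_after_a, arc_after_b
        offset = (a + L) % n
    else:
        lsc_len, ssc_len = arc_after_b, arc_after_a
        offset = (b + L) % n
    normalized = seq.seq[offset:] + seq.seq[:offset]

    lsc = (1, lsc_len, lsc_len)
    ira = (lsc_len + 1, lsc_len + L, L)
    ssc = (lsc_len + L + 1, lsc_len + L + ssc_len, ssc_len)
    irb = (lsc_len + L + ssc_len + 1, n, L)
    assert lsc_len + ssc_len + 2 * L == n
    return QuadripartiteStructure(
        genome_id=seq.id,
        total=n,
        lsc=lsc,
        ira=ira,
        ssc=ssc,
        irb=irb,
        rotation_offset=offset,
        normalized_sequence=normalized,
    )


def structures_to_frame(structures: Sequence[QuadripartiteStructure]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in structures], ignore_index=True)


def write_structures(
    structures: Sequence[QuadripartiteStructure], path: str | Path
) -> None:
    structures_to_frame(structures).to_csv(path, sep="\t", index=False)
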