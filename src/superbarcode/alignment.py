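"""Gapped multiple-sequence alignments and variant extraction.

The substrate of a plastome super-barcoding analysis is a multiple
alignment of whole plastid genomes (or nrDNA units) from several closely
related species.  This module loads such alignments from multi-FASTA,
extracts pairwise and column-wise single-nucleotide polymorphisms (SNPs)
and insertion/deletion (InDel) events, and computes sliding-window SNP
density tracks in the coordinates of a chosen reference row.

Conventions
-----------
* Alignment columns are 0-based half-open internally; every report and
  file output uses 1-based inclusive coordinates.
* An *InDel event* is one maximal contiguous run of gap columns shared by
  an identical set of gapped rows; gap columns are additionally reported
  as *InDel sites* so both conventions are available.
* Ambiguity codes (IUPAC) and ``N`` never count as SNPs: a column holding
  only ``{A, N}`` is monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
DNA_BASES = "ACGT"
#: symbols accepted in an alignment row
ALPHABET = frozenset("ACGTRYSWKMBDHVN" + GAP)

_ACGT_CODES = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)
_GAP_CODE = ord(GAP)


class AlignmentFormatError(ValueError):
    """Raised when an input file violates the alignment invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence, optionally circular (plastomes are)."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


def normalize_sequence(raw: str) -> str:
    """Uppercase a raw sequence and map RNA ``U`` to ``T``."""
    return raw.upper().replace("U", "T")


class Alignment:
    """An ordered set of equal-length gapped sequence rows."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise AlignmentFormatError("alignment needs at least one record")
        length = len(records[0])
        seen: set[str] = set()
        for i, rec in enumerate(records):
            if len(rec) != length:
                raise AlignmentFormatError(
                    f"record {i + 1} ({rec.id!r}) has length {len(rec)}, "
                    f"expected {length}"
                )
            if rec.id in seen:
                raise AlignmentFormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if set(rec.seq) == {GAP}:
                raise AlignmentFormatError(f"record {rec.id!r} is all-gap")
        self.records = records
        self.length = length
        self._index = {rec.id: i for i, rec in enumerate(records)}
        self._matrix: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def row(self, sample_id: str) -> str:
        return self.records[self.index(sample_id)].seq

    def index(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    @property
    def matrix(self) -> np.ndarray:
        """(n_records, length) uint8 array of ASCII codes (cached)."""
        if self._matrix is None:
            buf = "".join(rec.seq for rec in self.records).encode()
            self._matrix = np.frombuffer(buf, dtype=np.uint8).reshape(
                len(self.records), self.length
            )
        return self._matrix

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        return Alignment([self.records[self.index(s)] for s in sample_ids])


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic alignment column (>=2 distinct A/C/G/T symbols)."""

    column: int
    alleles: dict[str, str]
    ref_position: int | None = None

    @property
    def bases(self) -> frozenset[str]:
        return frozenset(b for b in self.alleles.values() if b in DNA_BASES)


@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of gap columns with one constant gapped-sample set."""

    start: int
    end: int
    gapped_samples: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DensityTrack:
    """Sliding-window SNP counts on a reference row's ungapped coordinates."""

    reference_id: str
    window: int
    step: int
    #: (start 1-based, end inclusive, snp_count, density per bp)
    bins: tuple[tuple[int, int, int, float], ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bins, columns=["start", "end", "snp_count", "density"]
        ).assign(reference=self.reference_id)[
            ["reference", "start", "end", "snp_count", "density"]
        ]


# ---------------------------------------------------------------------------
# I/O


def load_alignment(path: str | Path, circular: bool = False) -> Alignment:
    """Load a gapped multi-FASTA alignment.

    Sequences are uppercased and ``U`` is mapped to ``T``.  Unequal row
    lengths or duplicate ids raise :class:`AlignmentFormatError` naming
    the offending record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, normalize_sequence(str(rec.seq)), circular)
        )
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: alignment needs >=2 records")
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records]
    SeqIO.write(bio, str(path), "fasta")


def load_genomes(path: str | Path, circular: bool = True) -> list[SequenceRecord]:
    """Load plain (ungapped) genome FASTA records."""
    return [
        SequenceRecord(rec.id, normalize_sequence(str(rec.seq)), circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genomes(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pairwise variants


def _core_bounds(row: np.ndarray) -> tuple[int, int]:
    """Half-open interval spanned by the first and last non-gap symbol."""
    nongap = np.flatnonzero(row != _GAP_CODE)
    return int(nongap[0]), int(nongap[-1]) + 1


def count_pairwise_variants(
    aln: Alignment,
    a: str,
    b: str,
    ignore_terminal_gaps: bool = True,
) -> tuple[int, int, int]:
    """Count SNPs and InDels between two rows of the alignment.

    Returns ``(snp_count, indel_event_count, indel_site_count)``.  A SNP
    is a column where both symbols are in ``{A,C,G,T}`` and differ.  An
    InDel event is a maximal run of columns gapped in exactly one of the
    two rows; the site count is the number of such gap columns.  Leading
    and trailing gap stretches (alignment-edge artifacts) are excluded
    unless ``ignore_terminal_gaps=False``.
    """
    ra = aln.matrix[aln.index(a)]
    rb = aln.matrix[aln.index(b)]
    lo, hi = 0, aln.length
    if ignore_terminal_gaps:
        fa, la = _core_bounds(ra)
        fb, lb = _core_bounds(rb)
        lo, hi = max(fa, fb), min(la, lb)
        if lo >= hi:
            return 0, 0, 0
    ra, rb = ra[lo:hi], rb[lo:hi]

    va = np.isin(ra, _ACGT_CODES)
    vb = np.isin(rb, _ACGT_CODES)
    snp_count = int(np.count_nonzero(va & vb & (ra != rb)))

    ga = (ra == _GAP_CODE) & (rb != _GAP_CODE)
    gb = (rb == _GAP_CODE) & (ra != _GAP_CODE)
    indel_sites = int(np.count_nonzero(ga) + np.count_nonzero(gb))
    events = _count_runs(ga) + _count_runs(gb)
    return snp_count, events, indel_sites


def _count_runs(mask: np.ndarray) -> int:
    """Number of maximal runs of True in a boolean vector."""
    if not mask.any():
        return 0
    m = mask.astype(np.int8)
    return int(m[0] + np.count_nonzero(np.diff(m) == 1))


# ---------------------------------------------------------------------------
# Column-wise variants


def _polymorphic_mask(matrix: np.ndarray) -> np.ndarray:
    """Columns with at least two distinct A/C/G/T symbols."""
    distinct = np.zeros(matrix.shape[1], dtype=np.int8)
    for code in _ACGT_CODES:
        distinct += (matrix == code).any(axis=0)
    return distinct >= 2


def call_msa_variants(
    aln: Alignment,
    reference_id: str | None = None,
) -> tuple[list[VariantSite], list[IndelEvent]]:
    """Extract all SNP sites and InDel events from the alignment.

    Every column with >=2 distinct ``{A,C,G,T}`` symbols yields a
    :class:`VariantSite`; every maximal run of gap columns with a
    constant gapped-sample set yields one :class:`IndelEvent`.  When a
    ``reference_id`` is given, SNP sites carry a 1-based position on that
    row's ungapped coordinates (``None`` where the reference is gapped).
    """
    M = aln.matrix
    ids = aln.ids
    refpos = _reference_positions(aln, reference_id) if reference_id else None

    sites: list[VariantSite] = []
    for col in np.flatnonzero(_polymorphic_mask(M)):
        col = int(col)
        alleles = {ids[i]: chr(M[i, col]) for i in range(len(ids))}
        rp = None if refpos is None else refpos[col]
        sites.append(VariantSite(column=col, alleles=alleles, ref_position=rp))

    events: list[IndelEvent] = []
    G = M == _GAP_CODE
    anygap = G.any(axis=0)
    if anygap.any():
        L = aln.length
        bounds = np.zeros(L + 1, dtype=bool)
        bounds[0] = bounds[L] = True
        bounds[1:L] = (G[:, 1:] != G[:, :-1]).any(axis=0)
        edges = np.flatnonzero(bounds)
        for s, e in zip(edges[:-1], edges[1:]):
            if anygap[s]:
                gapped = frozenset(ids[i] for i in np.flatnonzero(G[:, s]))
                events.append(IndelEvent(int(s), int(e), gapped))
    return sites, events


def _reference_positions(aln: Alignment, reference_id: str) -> list[int | None]:
    """Per-column 1-based ungapped reference position (None at ref gaps)."""
    row = aln.matrix[aln.index(reference_id)]
    nongap = row != _GAP_CODE
    cum = np.cumsum(nongap)
    return [int(cum[i]) if nongap[i] else None for i in range(len(row))]


# ---------------------------------------------------------------------------
# SNP density


def snp_density_track(
    aln: Alignment,
    reference_id: str,
    window: int = 600,
    step: int = 200,
) -> DensityTrack:
    """Sliding-window SNP density in reference coordinates.

    SNP columns are projected onto the reference row (columns where the
    reference is gapped are dropped).  Windows start at 1, 1+step, ...;
    the final partial windows are included with density normalized by
    their actual span.
    """
    if step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got window={window} step={step}")
    idx = aln.index(reference_id)  # raises for unknown reference
    row = aln.matrix[idx]
    nongap = row != _GAP_CODE
    ref_len = int(np.count_nonzero(nongap))
    cum = np.cumsum(nongap)
    poly = _polymorphic_mask(aln.matrix)
    positions = np.sort(cum[poly & nongap])  # 1-based projected SNP positions

    bins = []
    for start in range(1, ref_len + 1, step):
        end = min(start + window - 1, ref_len)
        count = int(
            np.searchsorted(positions, end, side="right")
            - np.searchsorted(positions, start, side="left")
        )
        span = end - start + 1
        bins.append((start, end, count, count / span))
    return DensityTrack(reference_id, window, step, tuple(bins))


# ---------------------------------------------------------------------------
# Tabular output


def variants_to_frame(
    sites: Sequence[VariantSite], events: Sequence[IndelEvent]
) -> pd.DataFrame:
    """Variants as a tidy table (1-based inclusive columns)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "type": "SNP",
                "column_start": s.column + 1,
                "column_end": s.column + 1,
                "ref_position": s.ref_position,
                "length": 1,
                "alleles": ";".join(f"{k}={v}" for k, v in sorted(s.alleles.items())),
            }
        )
    for e in events:
        rows.append(
            {
                "type": "InDel",
                "column_start": e.start + 1,
                "column_end": e.end,
                "ref_position": None,
                "length": e.length,
                "alleles": ";".join(sorted(e.gapped_samples)) + "=gap",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["type", "column_start", "column_end", "ref_position", "length", "alleles"],
    )
    return frame.sort_values(["column_start", "type"], kind="stable").reset_index(drop=True)


def write_variants(
    sites: Sequence[VariantSite],
    events: Sequence[IndelEvent],
    path: str | Path,
) -> None:
    variants_to_frame(sites, events).to_csv(path, sep="\t", index=False)


def write_density(track: DensityTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)
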