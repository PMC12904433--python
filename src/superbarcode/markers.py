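"""Species-diagnostic SNP/InDel screening from labeled alignments.

A site is *diagnostic* for a target species when it perfectly separates
that species from every other sample in the alignment: the target
samples are fixed for one allele and all non-target samples carry a
different allele.  For InDels the unit is a whole gap-run event whose
gapped-sample set is exactly the target species (or exactly its
complement), with a minimum length threshold (strictly greater than
``min_length`` by default, mirroring the "longer than 10 bp" screening
rule commonly applied to plastome alignments).

Screening strictness:

* ``strict`` (default) — fixation required on both sides; a candidate
  column containing any ``N``/ambiguity/gap is discarded.
* ``relaxed`` — the non-target side need not be fixed, only free of the
  target allele; samples with ambiguous symbols are ignored per column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, _ACGT_CODES, _reference_positions, call_msa_variants

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesLabeling:
    """Sample-id -> species-name mapping used for diagnostic screening."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least two species")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def samples_of(self, species: str) -> tuple[str, ...]:
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}")
        return tuple(s for s, sp in self.labels.items() if sp == species)

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.labels

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesLabeling":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(frame["sample"], frame["species"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.labels.items()), columns=["sample", "species"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DiagnosticSite:
    """A locus that perfectly separates one species from all others."""

    kind: str  # "SNP" | "InDel"
    target_species: str
    start: int  # 0-based alignment column, half-open interval
    end: int
    target_allele: str
    other_allele: str
    ref_start: int | None = None
    ref_end: int | None = None
    annotation: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def position(self) -> int:
        """Best available 1-based sort position (reference, else column)."""
        return self.ref_start if self.ref_start is not None else self.start + 1


@dataclass(frozen=True)
class RegionAnnotation:
    """Named intervals (genes / intergenic spacers) on a reference genome."""

    reference_id: str
    intervals: tuple[tuple[str, int, int, str], ...]  # (name, start 1-based, end incl, kind)

    def __post_init__(self) -> None:
        names = [name for name, *_ in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("interval names must be unique")
        for name, start, end, _ in self.intervals:
            if start < 1 or end < start:
                raise ValueError(f"invalid interval {name!r}: [{start}, {end}]")

    @classmethod
    def from_bed(cls, path: str | Path, reference_id: str | None = None) -> "RegionAnnotation":
        """Read 0-based half-open BED (chrom, start, end, name[, score, kind])."""
        intervals = []
        ref = reference_id
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                kind = parts[5] if len(parts) > 5 else "region"
                if ref is None:
                    ref = chrom
                if chrom == ref:
                    intervals.append((name, start + 1, end, kind))
        return cls(ref or "", tuple(intervals))

    @classmethod
    def from_tsv(cls, path: str | Path, reference_id: str | None = None) -> "RegionAnnotation":
        """Read a 1-based inclusive TSV (columns name, start, end, kind)."""
        frame = pd.read_csv(path, sep="\t")
        intervals = tuple(
            (str(r["name"]), int(r["start"]), int(r["end"]), str(r.get("kind", "region")))
            for _, r in frame.iterrows()
        )
        return cls(reference_id or "", intervals)


def _check_labels(aln: Alignment, labels: SpeciesLabeling) -> None:
    missing = [s for s in aln.ids if s not in labels]
    if missing:
        raise ValueError(f"samples without species label: {missing}")


def _warn_singletons(labels: SpeciesLabeling, target: str) -> None:
    if len(labels.samples_of(target)) == 1:
        logger.warning(
            "species %r has a single sample: fixation is trivially satisfied "
            "and intraspecific variation is unassessed",
            target,
        )


def find_diagnostic_snps(
    aln: Alignment,
    labels: SpeciesLabeling,
    target: str,
    mode: str = "strict",
    reference_id: str | None = None,
) -> list[DiagnosticSite]:
    """Columns where the target species is fixed for a base private to it.

    In strict mode the non-target samples must also be fixed (for a
    different base) and any ambiguity discards the column; in relaxed
    mode non-target samples may vary as long as none carries the target
    base, and ambiguous samples are ignored per column.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_labels(aln, labels)
    _warn_singletons(labels, target)
    target_rows = np.array([aln.index(s) for s in labels.samples_of(target)])
    other_rows = np.array([i for i in range(len(aln)) if i not in set(target_rows)])
    if other_rows.size == 0:
        raise ValueError("no non-target samples present")
    M = aln.matrix
    Mt, Mo = M[target_rows], M[other_rows]

    valid_t = np.isin(Mt, _ACGT_CODES)
    valid_o = np.isin(Mo, _ACGT_CODES)
    fixed_t = valid_t.all(axis=0) & (Mt == Mt[0]).all(axis=0)
    target_base = Mt[0]

    if mode == "strict":
        fixed_o = valid_o.all(axis=0) & (Mo == Mo[0]).all(axis=0)
        hit = fixed_t & fixed_o & (target_base != Mo[0])
    else:
        carries_target = (valid_o & (Mo == target_base)).any(axis=0)
        has_other = valid_o.any(axis=0)
        hit = fixed_t & has_other & ~carries_target

    refpos = _reference_positions(aln, reference_id) if reference_id else None
    sites = []
    for col in map(int, np.flatnonzero(hit)):
        others = sorted({chr(c) for c, v in zip(Mo[:, col], valid_o[:, col]) if v})
        rp = refpos[col] if refpos is not None else None
        sites.append(
            DiagnosticSite(
                kind="SNP",
                target_species=target,
                start=col,
                end=col + 1,
                target_allele=chr(target_base[col]),
                other_allele=",".join(others),
                ref_start=rp,
                ref_end=rp,
            )
        )
    return sites


def find_diagnostic_indels(
    aln: Alignment,
    labels: SpeciesLabeling,
    target: str,
    min_length: int = 10,
    allow_equal: bool = False,
    reference_id: str | None = None,
) -> list[DiagnosticSite]:
    """InDel events whose gapped-sample set is exactly the target species
    (deletion in target) or exactly its complement (insertion in target),
    longer than ``min_length`` (``>=`` with ``allow_equal=True``)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    _check_labels(aln, labels)
    _warn_singletons(labels, target)
    target_set = frozenset(labels.samples_of(target))
    complement = frozenset(aln.ids) - target_set
    _, events = call_msa_variants(aln)
    refpos = _reference_positions(aln, reference_id) if reference_id else None

    sites = []
    for ev in events:
        long_enough = ev.length >= min_length if allow_equal else ev.length > min_length
        if not long_enough:
            continue
        if ev.gapped_samples == target_set:
            t_allele, o_allele = "gap", "present"
        elif ev.gapped_samples == complement:
            t_allele, o_allele = "present", "gap"
        else:
            continue
        rs = re = None
        if refpos is not None:
            inside = [refpos[c] for c in range(ev.start, ev.end) if refpos[c] is not None]
            if inside:
                rs, re = inside[0], inside[-1]
        sites.append(
            DiagnosticSite(
                kind="InDel",
                target_species=target,
                start=ev.start,
                end=ev.end,
                target_allele=t_allele,
                other_allele=o_allele,
                ref_start=rs,
                ref_end=re,
            )
        )
    return sites


def annotate_candidates(
    sites: Sequence[DiagnosticSite], ann: RegionAnnotation
) -> list[DiagnosticSite]:
    """Label each site with the overlapping region name(s).

    Sites without reference coordinates, or overlapping no interval, are
    labeled ``unannotated``.  A site spanning several intervals receives
    all names, joined in coordinate order.
    """
    ordered = sorted(ann.intervals, key=lambda iv: (iv[1], iv[2]))
    out = []
    for site in sites:
        if site.ref_start is None:
            out.append(replace(site, annotation=("unannotated",)))
            continue
        lo = site.ref_start
        hi = site.ref_end if site.ref_end is not None else site.ref_start
        names = tuple(
            name for name, start, end, _ in ordered if start <= hi and lo <= end
        )
        out.append(replace(site, annotation=names or ("unannotated",)))
    return out


def select_marker_candidates(
    sites: Sequence[DiagnosticSite], per_species_max: int
) -> list[DiagnosticSite]:
    """Deterministic ranking of candidate loci, capped per species.

    InDels rank before SNPs; InDels by descending length then ascending
    position, SNPs by ascending position.  Stable under input shuffling.
    """
    if per_species_max < 1:
        raise ValueError("per_species_max must be >= 1")

    def key(site: DiagnosticSite):
        if site.kind == "InDel":
            return (0, -site.length, site.position, site.target_species)
        return (1, 0, site.position, site.target_species)

    ranked = []
    taken: dict[str, int] = {}
    for site in sorted(sites, key=key):
        if taken.get(site.target_species, 0) < per_species_max:
            ranked.append(site)
            taken[site.target_species] = taken.get(site.target_species, 0) + 1
    return ranked


def separates_target(aln: Alignment, labels: SpeciesLabeling, site: DiagnosticSite) -> bool:
    """Genotype a site back against the alignment: does it perfectly
    separate target from non-target samples?"""
    target_set = set(labels.samples_of(site.target_species))
    if site.kind == "SNP":
        col = site.start
        genotypes = {rec.id: rec.seq[col] for rec in aln.records}
        t_alleles = {genotypes[s] for s in target_set}
        o_alleles = {g for s, g in genotypes.items() if s not in target_set}
        return len(t_alleles) == 1 and not (t_alleles & o_alleles)
    gap_state = {
        rec.id: all(c == "-" for c in rec.seq[site.start : site.end])
        for rec in aln.records
    }
    t_states = {gap_state[s] for s in target_set}
    o_states = {g for s, g in gap_state.items() if s not in target_set}
    return len(t_states) == 1 and len(o_states) == 1 and t_states != o_states


def candidates_to_frame(sites: Sequence[DiagnosticSite]) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "species": s.target_species,
            "kind": s.kind,
            "column_start": s.start + 1,
            "column_end": s.end,
            "ref_start": s.ref_start,
            "ref_end": s.ref_end,
            "length": s.length,
            "target_allele": s.target_allele,
            "other_allele": s.other_allele,
            "annotation": ";".join(s.annotation) or "unannotated",
        }
        for i, s in enumerate(sites)
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "rank", "species", "kind", "column_start", "column_end",
            "ref_start", "ref_end", "length", "target_allele", "other_allele",
            "annotation",
        ],
    )
    return frame.astype({"ref_start": "Int64", "ref_end": "Int64"})


def write_candidates(sites: Sequence[DiagnosticSite], path: str | Path) -> None:
    candidates_to_frame(sites).to_csv(path, sep="\t", index=False)
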