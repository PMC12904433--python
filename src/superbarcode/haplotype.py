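"""Multilocus haplotype classification from marker band patterns.

Each species has an expected profile over the marker panel: the pattern
label (``A``/``B``) its allele produces, or ``absent`` for dominant
markers where the species yields no product.  A sample is assigned to a
species only on an exact profile match (Hamming distance 0 over all
markers); anything else is reported as ``novel`` together with the
nearest profiles and the disagreeing markers, so that congeners outside
the reference panel surface as distinct haplotypes rather than being
forced into a species.  Novel profiles are never auto-added — extending
the profile table is an explicit user action.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .markers import SpeciesLabeling
from .pcr import BandPattern, MarkerDefinition

ABSENT = "absent"


@dataclass(frozen=True)
class SpeciesProfileTable:
    """species -> marker -> expected state (pattern label or ``absent``)."""

    profiles: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        marker_sets = {frozenset(p) for p in self.profiles.values()}
        if len(marker_sets) > 1:
            raise ValueError("all species must reference the same marker set")
        seen: dict[tuple, str] = {}
        for species, profile in self.profiles.items():
            key = tuple(sorted(profile.items()))
            if key in seen:
                raise ValueError(
                    f"species {species!r} and {seen[key]!r} have identical profiles"
                )
            seen[key] = species

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.profiles))

    @property
    def markers(self) -> tuple[str, ...]:
        first = next(iter(self.profiles.values()))
        return tuple(sorted(first))

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame.from_dict(
            {sp: dict(p) for sp, p in self.profiles.items()}, orient="index"
        ).rename_axis("species")
        frame[sorted(frame.columns)].to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesProfileTable":
        frame = pd.read_csv(path, sep="\t", index_col="species", dtype=str)
        return cls({str(sp): dict(row) for sp, row in frame.iterrows()})


@dataclass(frozen=True)
class HaplotypeCall:
    """Classification result for one sample."""

    sample_id: str
    call: str  # species name | "novel" | "ambiguous"
    profile_distance: int
    matched: int
    mismatched_markers: tuple[str, ...]
    nearest: tuple[str, ...] = ()


def build_profile_table(
    panel: Sequence[MarkerDefinition],
    labels: SpeciesLabeling | Sequence[str],
) -> SpeciesProfileTable:
    """Derive per-species expected states from a marker panel.

    Each marker's ``classification`` must partition the species; species
    whose expected fragment list is empty (dominant marker non-target
    group) map to ``absent``.
    """
    species = labels.species if isinstance(labels, SpeciesLabeling) else tuple(labels)
    profiles: dict[str, dict[str, str]] = {sp: {} for sp in species}
    for marker in panel:
        for sp in species:
            label = next(
                (lab for lab, group in marker.classification.items() if sp in group),
                None,
            )
            if label is None:
                raise ValueError(
                    f"marker {marker.name!r} does not classify species {sp!r}"
                )
            expected = marker.expected.get(label, ())
            profiles[sp][marker.name] = ABSENT if not expected else label
    return SpeciesProfileTable(profiles)


def _observed_states(
    bands: Sequence[BandPattern], markers: Sequence[str]
) -> dict[str, str]:
    """Collapse band patterns to per-marker states; no fragments = absent,
    markers not covered by any band = absent."""
    states = {m: ABSENT for m in markers}
    known = set(markers)
    for band in bands:
        if band.marker_name not in known:
            raise ValueError(f"marker {band.marker_name!r} unknown to profile table")
        states[band.marker_name] = ABSENT if not band.fragments else band.matched_label
    return states


def classify_sample(
    bands: Sequence[BandPattern], profiles: SpeciesProfileTable
) -> HaplotypeCall:
    """Assign one sample to a species haplotype group.

    Exact match (distance 0) to exactly one species profile gives a
    species call; several exact matches give ``ambiguous`` (impossible
    with pairwise-distinct profiles, kept as a guard); otherwise the call
    is ``novel``, with the nearest species (ties in lexicographic order,
    all reported) and the mismatched markers of the best match listed.
    """
    if not bands:
        sample_id = "?"
    else:
        ids = {b.sample_id for b in bands}
        if len(ids) > 1:
            raise ValueError(f"bands from several samples: {sorted(ids)}")
        sample_id = ids.pop()
    markers = profiles.markers
    states = _observed_states(bands, markers)

    distances: dict[str, list[str]] = {}
    for species in profiles.species:
        profile = profiles.profiles[species]
        distances[species] = [m for m in markers if states[m] != profile[m]]
    exact = [sp for sp, mm in distances.items() if not mm]
    if len(exact) == 1:
        return HaplotypeCall(sample_id, exact[0], 0, len(markers), ())
    if len(exact) > 1:
        return HaplotypeCall(sample_id, "ambiguous", 0, len(markers), (), tuple(exact))
    best = min(len(mm) for mm in distances.values())
    nearest = tuple(sorted(sp for sp, mm in distances.items() if len(mm) == best))
    return HaplotypeCall(
        sample_id,
        "novel",
        best,
        len(markers) - best,
        tuple(distances[nearest[0]]),
        nearest,
    )


def classify_panel(
    patterns: Sequence[BandPattern], profiles: SpeciesProfileTable
) -> list[HaplotypeCall]:
    """Classify every sample appearing in a band-pattern set."""
    by_sample: dict[str, list[BandPattern]] = {}
    for p in patterns:
        by_sample.setdefault(p.sample_id, []).append(p)
    return [classify_sample(bands, profiles) for _, bands in sorted(by_sample.items())]


def profile_distance(
    profiles: SpeciesProfileTable, species_a: str, species_b: str
) -> int:
    """Hamming distance between two species profiles over the panel."""
    pa, pb = profiles.profiles[species_a], profiles.profiles[species_b]
    return sum(pa[m] != pb[m] for m in profiles.markers)


def calls_to_frame(calls: Sequence[HaplotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "call": c.call,
                "distance": c.profile_distance,
                "matched": c.matched,
                "mismatched_markers": ";".join(c.mismatched_markers) or "-",
                "nearest": ";".join(c.nearest) or "-",
            }
            for c in calls
        ]
    )


def write_calls(calls: Sequence[HaplotypeCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
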