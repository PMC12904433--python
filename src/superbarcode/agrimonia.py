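"""The published eight-marker authentication panel for Korean *Agrimonia*.

Four *Agrimonia* species traded as medicinal material in Korea
(*A. pilosa*, *A. coreana*, *A. nipponica*, *A. eupatoria*) are
distinguished by eight plastome loci: four intergenic-spacer InDels
(codominant), two coding-gene SNPs assayed as CAPS (codominant) and two
SNPs assayed with allele-specific primers (dominant).  Each marker
separates one target species (pattern A) from the other three
(pattern B).  This module ships the published primer sequences, marker
types, species classification and expected product/fragment sizes as a
ready-made panel.

The restriction enzymes of the two CAPS assays are laboratory
configuration rather than published data; by default the panel (and the
synthetic genome builder) uses EcoRI, and callers may supply their own
enzymes per marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .pcr import ECORI, Enzyme, MarkerDefinition, PrimerPair

PILOSA = "A. pilosa"
COREANA = "A. coreana"
NIPPONICA = "A. nipponica"
EUPATORIA = "A. eupatoria"
GOROVOII = "A. gorovoii"

#: the four species covered by the panel
SPECIES: tuple[str, ...] = (PILOSA, COREANA, NIPPONICA, EUPATORIA)


@dataclass(frozen=True)
class PublishedMarker:
    """One row of the published marker table."""

    name: str
    locus: str
    kind: str  # codominant_caps | dominant_snp | codominant_indel
    a_species: tuple[str, ...]
    b_species: tuple[str, ...]
    forward: str
    reverse: str
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]


def _others(target: str) -> tuple[str, ...]:
    return tuple(s for s in SPECIES if s != target)


PANEL: tuple[PublishedMarker, ...] = (
    PublishedMarker(
        "AP1", "rps15", "codominant_caps", (PILOSA,), _others(PILOSA),
        "TCCCGAATATTCAACCGATTA", "CCCTTTGTGTATACCTTTTCAAAT",
        (282, 168), (450,),
    ),
    PublishedMarker(
        "AP2", "matK-rps16", "dominant_snp", (PILOSA,), _others(PILOSA),
        "GTTTGTTGATTAAGGCGAAGCAA", "CGTTGCAATTGATGTTCGATCC",
        (201,), (),
    ),
    PublishedMarker(
        "AC1", "ndhA", "codominant_caps", (COREANA,), _others(COREANA),
        "AACCCATCGTTTTTACTTACGAA", "TGCTCCTATCCACCGATTAAA",
        (196, 54), (250,),
    ),
    PublishedMarker(
        "AC2", "ndhF-rpl32", "codominant_indel", (COREANA,), _others(COREANA),
        "GAGCAAGGATAAATAATGACAGAAC", "TGATTGGGAATAAACCGAACAAA",
        (163,), (143,),
    ),
    PublishedMarker(
        "AN1", "rps8-rpl14", "codominant_indel", (NIPPONICA,), _others(NIPPONICA),
        "CCCTCCGAAAGAATGTTGAA", "TTTTGCTTCGGAAAAGGTTC",
        (210,), (182,),
    ),
    PublishedMarker(
        "AN2", "atpB-rbcL", "dominant_snp", (NIPPONICA,), _others(NIPPONICA),
        "GTGCAAGTCTTTTATTTGCCTTAG", "GGCAGAATTCGTCCATAAACAT",
        (260,), (),
    ),
    PublishedMarker(
        "AE1", "psaJ-rpl20", "codominant_indel", (EUPATORIA,), _others(EUPATORIA),
        "CGGCACTTAAAAATCCGAAAT", "TGAAAGAAAGATTTCGTTGCAATA",
        (180,), (124,),
    ),
    PublishedMarker(
        "AE2", "rbcL-accD", "codominant_indel", (EUPATORIA,), _others(EUPATORIA),
        "TGGATCCACAATTAATCCTACG", "GATCCAAAAATGCAGGATCG",
        (188,), (148,),
    ),
)


def agrimonia_panel(
    enzymes: Mapping[str, Enzyme] | None = None,
) -> list[MarkerDefinition]:
    """Build the published panel as :class:`MarkerDefinition` objects.

    ``enzymes`` maps CAPS marker names to enzymes (default: EcoRI for
    both CAPS assays).
    """
    enzymes = dict(enzymes or {})
    panel = []
    for m in PANEL:
        enzyme = None
        if m.kind == "codominant_caps":
            enzyme = enzymes.get(m.name, ECORI)
        panel.append(
            MarkerDefinition(
                name=m.name,
                kind=m.kind,
                primers=PrimerPair(m.name, m.forward, m.reverse),
                expected={"A": m.fragments_a, "B": m.fragments_b},
                classification={"A": m.a_species, "B": m.b_species},
                enzyme=enzyme,
            )
        )
    return panel
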