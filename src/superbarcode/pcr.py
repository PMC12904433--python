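"""In-silico PCR, allele-specific amplification and CAPS digestion.

Emulates the wet-lab genotyping assays used for plastome super-barcoding:

* **codominant InDel markers** — both alleles amplify, products differ in
  size by the InDel length;
* **dominant SNP markers** — the allele-specific primer's 3'-terminal
  base sits on the diagnostic SNP, so only the matching allele yields a
  product (presence/absence scoring);
* **codominant CAPS markers** — both alleles amplify the same product,
  but a SNP creates/destroys a restriction site, so the digestion
  fragment pattern differs.

Product sizes include both primer footprints (standard PCR convention).
Primer matching is exact by default (``max_mismatch=0``); mismatch
tolerance and the length of the 3'-terminal exact-match anchor are
per-primer-pair settings.  Degenerate IUPAC codes are honoured in
primers but treated as mismatches in templates (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MARKER_KINDS = ("codominant_indel", "dominant_snp", "codominant_caps")

# bitmask encodings: template symbols outside ACGT encode as 0 and match nothing
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_TEMPLATE_ENC = np.zeros(256, dtype=np.uint8)
for _b, _v in _BIT.items():
    _TEMPLATE_ENC[ord(_b)] = _v
_PRIMER_ENC = np.zeros(256, dtype=np.uint8)
for _sym, _expansion in IUPAC.items():
    _PRIMER_ENC[ord(_sym)] = sum(_BIT[b] for b in _expansion)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 0
    three_prime_anchor: int = 1

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{self.name}: {label} primer shorter than 10 bp")
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.name}: invalid {label} symbols {sorted(bad)}")
        if self.max_mismatch < 0 or self.three_prime_anchor < 0:
            raise ValueError(f"{self.name}: negative matching parameter")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; coordinates are 1-based inclusive."""

    template_id: str
    start: int
    end: int
    wraps_origin: bool
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme given by its recognition site and cut offset.

    ``cut_offset`` is the top-strand cut position within/after the
    recognition site (0 = cut before the first site base).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid site symbols {sorted(bad)}")


#: EcoRI, the conventional enzyme used by the synthetic genome builder
ECORI = Enzyme("EcoRI", "GAATTC", 1)


@dataclass(frozen=True)
class MarkerDefinition:
    """One marker of a genotyping panel.

    ``expected`` maps a pattern label (``"A"``/``"B"``) to the fragment
    lengths its allele produces (empty tuple = no amplification);
    ``classification`` maps the same labels to the species carrying each
    allele.
    """

    name: str
    kind: str
    primers: PrimerPair
    expected: dict[str, tuple[int, ...]]
    classification: dict[str, tuple[str, ...]] = field(default_factory=dict)
    enzyme: Enzyme | None = None

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"{self.name}: unknown marker kind {self.kind!r}")
        if self.kind == "codominant_caps" and self.enzyme is None:
            raise ValueError(f"{self.name}: CAPS marker requires an enzyme")
        if not self.expected:
            raise ValueError(f"{self.name}: empty expected pattern map")


@dataclass(frozen=True)
class BandPattern:
    """The in-silico gel lane for one sample x marker."""

    sample_id: str
    marker_name: str
    fragments: tuple[int, ...]
    matched_label: str  # "A" | "B" | ... | "none"


# ---------------------------------------------------------------------------
# Primer-site search


def _scan(
    tcodes: np.ndarray,
    pattern: str,
    max_mismatch: int,
    anchor: Iterable[int],
) -> np.ndarray:
    """0-based start positions where ``pattern`` matches ``tcodes``.

    ``anchor`` lists pattern indices that must match exactly regardless
    of ``max_mismatch``.
    """
    L = len(pattern)
    n = len(tcodes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    pcodes = _PRIMER_ENC[np.frombuffer(pattern.encode(), np.uint8)]
    mism = np.zeros(n, dtype=np.int32)
    anchor_bad = np.zeros(n, dtype=bool)
    anchor = set(anchor)
    for j in range(L):
        ok = (tcodes[j : j + n] & pcodes[j]) != 0
        mism += ~ok
        if j in anchor:
            anchor_bad |= ~ok
    return np.flatnonzero((mism <= max_mismatch) & ~anchor_bad)


def _encode(seq: str) -> np.ndarray:
    return _TEMPLATE_ENC[np.frombuffer(seq.encode(), np.uint8)]


def _plus_sites(text: str, primer: str, max_mm: int, anchor_len: int) -> np.ndarray:
    """Plus-strand sites: primer read 5'->3' equals template; anchor at 3' end."""
    L = len(primer)
    anchor = range(max(0, L - anchor_len), L)
    return _scan(_encode(text), primer, max_mm, anchor)

def _minus_sites(text: str, primer: str, max_mm: int, anchor_len: int) -> np.ndarray:
    """Minus-strand sites: reverse complement of the primer on the plus
    strand; the primer's 3' end maps to the leftmost site base."""
    L = len(primer)
    anchor = range(min(anchor_len, L))
    return _scan(_encode(text), reverse_complement(primer), max_mm, anchor)


def find_primer_sites(
    template: SequenceRecord,
    primer: str,
    max_mismatch: int = 0,
    three_prime_anchor: int = 1,
) -> list[tuple[int, str]]:
    """All primer binding sites as ``(position 1-based, strand)`` tuples.

    Minus-strand hits report the leftmost template coordinate of the
    site.  Circular templates are scanned across the origin.
    """
    n = len(template.seq)
    lp = len(primer)
    text = template.seq + template.seq[: lp - 1] if template.circular else template.seq
    hits = []
    for strand, fn in (("+", _plus_sites), ("-", _minus_sites)):
        for p in fn(text, primer, max_mismatch, three_prime_anchor):
            hits.append((int(p) % n + 1, strand))
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# Amplification


def amplify(
    template: SequenceRecord,
    primers: PrimerPair,
    circular: bool | None = None,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Predict all PCR products of a primer pair on one template.

    A product is any forward plus-strand site paired with a downstream
    reverse-primer minus-strand site, with total length (both primers
    included) at most ``max_product``.  On circular templates products
    may wrap the origin; a zero-amplicon result is a valid "no band".
    """
    circ = template.circular if circular is None else circular
    n = len(template.seq)
    lf, lr = len(primers.forward), len(primers.reverse)
    if lf > n or lr > n:
        return []
    text = template.seq * 2 if circ else template.seq
    cap = min(max_product, n - 1) if circ else max_product

    f_hits = _plus_sites(text, primers.forward, primers.max_mismatch, primers.three_prime_anchor)
    r_hits = _minus_sites(text, primers.reverse, primers.max_mismatch, primers.three_prime_anchor)
    if circ:
        f_hits = f_hits[f_hits < n]

    products = []
    for f in f_hits:
        lo = np.searchsorted(r_hits, f + lf)
        for p in r_hits[lo:]:
            e = int(p) + lr  # exclusive end in text coordinates
            length = e - int(f)
            if length > cap:
                break
            products.append(
                Amplicon(
                    template_id=template.id,
                    start=int(f) + 1,
                    end=(e - 1) % n + 1,
                    wraps_origin=bool(circ and e > n),
                    sequence=text[int(f) : e],
                )
            )
    return sorted(products, key=lambda a: (a.start, a.length))


def amplify_dominant(
    template: SequenceRecord,
    primers: PrimerPair,
    circular: bool | None = None,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Allele-specific amplification: enforce a >=1 bp 3'-terminal anchor
    on both primers so a 3' mismatch at the diagnostic SNP abolishes the
    product."""
    anchored = replace(primers, three_prime_anchor=max(1, primers.three_prime_anchor))
    return amplify(template, anchored, circular=circular, max_product=max_product)


# ---------------------------------------------------------------------------
# Restriction digestion


def digest(amplicon: Amplicon | str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths after full digestion of a linear amplicon.

    Cuts at every recognition-site occurrence on either strand; returns
    fragment lengths in descending order (their sum equals the amplicon
    length).  With no site the whole length is returned.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    L = len(seq)
    t = _encode(seq)
    site_len = len(enzyme.recognition)
    cuts: set[int] = set()
    for p in _scan(t, enzyme.recognition, 0, ()):
        cuts.add(int(p) + enzyme.cut_offset)
    rc_site = reverse_complement(enzyme.recognition)
    if rc_site != enzyme.recognition:
        for p in _scan(t, rc_site, 0, ()):
            cuts.add(int(p) + site_len - enzyme.cut_offset)
    cuts = {c for c in cuts if 0 < c < L}
    edges = [0, *sorted(cuts), L]
    return sorted((b - a for a, b in zip(edges[:-1], edges[1:])), reverse=True)


# ---------------------------------------------------------------------------
# Panel evaluation


def _fragments_match(
    observed: Sequence[int], expected: Sequence[int], tolerance: int
) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tolerance for o, e in zip(sorted(observed), sorted(expected)))


def genotype_sample(
    sample: SequenceRecord,
    marker: MarkerDefinition,
    size_tolerance: int = 0,
    max_product: int = 5000,
) -> BandPattern:
    """Run one marker assay on one sample and score the lane."""
    run = amplify_dominant if marker.kind == "dominant_snp" else amplify
    amps = run(sample, marker.primers, max_product=max_product)
    if not amps:
        fragments: tuple[int, ...] = ()
        interpretable = True
    else:
        lengths = {a.length for a in amps}
        if len(lengths) > 1:
            # several products of distinct size: uninterpretable lane
            fragments = tuple(sorted((a.length for a in amps), reverse=True))
            interpretable = False
        else:
            amp = amps[0]
            if marker.kind == "codominant_caps":
                fragments = tuple(digest(amp, marker.enzyme))
            else:
                fragments = (amp.length,)
            interpretable = True
    label = "none"
    if interpretable:
        matches = [
            lab
            for lab, exp in marker.expected.items()
            if _fragments_match(fragments, exp, size_tolerance)
        ]
        if len(matches) == 1:
            label = matches[0]
    return BandPattern(sample.id, marker.name, fragments, label)


def evaluate_panel(
    samples: Sequence[SequenceRecord],
    panel: Sequence[MarkerDefinition],
    size_tolerance: int = 0,
    max_product: int = 5000,
) -> list[BandPattern]:
    """Genotype every sample against every marker of the panel."""
    names = [m.name for m in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in panel")
    return [
        genotype_sample(s, m, size_tolerance=size_tolerance, max_product=max_product)
        for s in samples
        for m in panel
    ]


def band_matrix(patterns: Sequence[BandPattern]) -> pd.DataFrame:
    """Samples x markers matrix with cells like ``"A:282,168"``."""
    rows: dict[str, dict[str, str]] = {}
    for p in patterns:
        cell = f"{p.matched_label}:{','.join(map(str, p.fragments)) or '-'}"
        rows.setdefault(p.sample_id, {})[p.marker_name] = cell
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


def write_band_matrix(patterns: Sequence[BandPattern], path: str | Path) -> None:
    band_matrix(patterns).to_csv(path, sep="\t")


def read_band_matrix(path: str | Path) -> list[BandPattern]:
    frame = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
    patterns = []
    for sample, row in frame.iterrows():
        for marker, cell in row.items():
            label, _, frag_text = str(cell).partition(":")
            fragments = (
                tuple(int(x) for x in frag_text.split(",")) if frag_text not in ("", "-") else ()
            )
            patterns.append(BandPattern(str(sample), str(marker), fragments, label))
    return patterns


# ---------------------------------------------------------------------------
# Panel I/O


def write_panel(panel: Sequence[MarkerDefinition], path: str | Path) -> None:
    rows = []
    for m in panel:
        rows.append(
            {
                "name": m.name,
                "type": m.kind,
                "forward": m.primers.forward,
                "reverse": m.primers.reverse,
                "enzyme": m.enzyme.name if m.enzyme else "-",
                "enzyme_site": m.enzyme.recognition if m.enzyme else "-",
                "enzyme_offset": m.enzyme.cut_offset if m.enzyme else "-",
                "expected_A": ",".join(map(str, m.expected.get("A", ()))) or "-",
                "expected_B": ",".join(map(str, m.expected.get("B", ()))) or "-",
                "species_A": ";".join(m.classification.get("A", ())) or "-",
                "species_B": ";".join(m.classification.get("B", ())) or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[MarkerDefinition]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    panel = []
    for _, row in frame.iterrows():
        enzyme = None
        if row["enzyme_site"] != "-":
            enzyme = Enzyme(row["enzyme"], row["enzyme_site"], int(row["enzyme_offset"]))
        expected = {}
        classification = {}
        for label in ("A", "B"):
            text = row[f"expected_{label}"]
            expected[label] = (
                tuple(int(x) for x in text.split(",")) if text != "-" else ()
            )
            sp = row[f"species_{label}"]
            if sp != "-":
                classification[label] = tuple(sp.split(";"))
        panel.append(
            MarkerDefinition(
                name=row["name"],
                kind=row["type"],
                primers=PrimerPair(row["name"], row["forward"], row["reverse"]),
                expected=expected,
                classification=classification,
                enzyme=enzyme,
            )
        )
    return panel
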