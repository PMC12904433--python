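"""Synthetic mini-plastome species sets with a fully known truth set.

Every stage of the super-barcoding pipeline is testable offline against
genomes generated here.  A simulated set emulates the salient features
of real congeneric plastome panels:

* circular genomes with a quadripartite LSC/IRa/SSC/IRb layout (default
  15 kb, scalable to the ~155 kb of a real plastome);
* species diverged on a fixed pectinate tree, with interspecific SNP
  divergence well above intraspecific divergence (the premise that makes
  super-barcoding work);
* planted species-diagnostic SNP columns and InDel blocks (>=10 bp) in
  mutation-protected windows, so recovery screens have an exact truth;
* planted marker loci reproducing the published panel's primer
  sequences and product sizes, so in-silico genotyping of a synthetic
  sample yields the published banding patterns.

Random substitutions follow a uniform (Jukes–Cantor-like) model; each
mutated alignment column carries exactly one mutation event, which keeps
the derived truth set exact.  The inverted repeats are kept free of
mutations (concerted IR evolution; real IRs are comparatively
conserved).  All randomness flows from one integer seed: a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agrimonia
from .alignment import Alignment, SequenceRecord, write_alignment, write_genomes
from .markers import SpeciesLabeling
from .pcr import (
    ECORI,
    Enzyme,
    MarkerDefinition,
    PrimerPair,
    digest,
    evaluate_panel,
    reverse_complement,
    write_panel,
)

_BASES = "ACGT"
_GAP = ord("-")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(RuntimeError):
    """Raised when a scenario cannot be realised (e.g. genome too small)."""


# ---------------------------------------------------------------------------
# Scenario


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic species set.

    Default rates mirror observed congeneric plastome panels: roughly
    2 substitutions/kb between species against 0.3/kb within species
    (an order-of-magnitude gap).  ``interspecific_snp_rate`` is the
    expected pairwise divergence between sister species;
    ``intraspecific_snp_rate`` the expected divergence between two
    samples of one species.
    """

    seed: int = 0
    genome_length: int = 15_000
    ir_length: int = 2_600
    ssc_length: int = 1_870
    species: tuple[tuple[str, int], ...] = (
        (agrimonia.PILOSA, 2),
        (agrimonia.COREANA, 2),
        (agrimonia.NIPPONICA, 2),
        (agrimonia.EUPATORIA, 2),
    )
    interspecific_snp_rate: float = 0.002
    intraspecific_snp_rate: float = 0.0003
    diagnostic_snps_per_species: int = 3
    diagnostic_indel_lengths: tuple[int, ...] = (12, 20)
    plant_panel: bool = True
    min_spacer: int = 30

    def __post_init__(self) -> None:
        for rate in (self.interspecific_snp_rate, self.intraspecific_snp_rate):
            if not 0 <= rate <= 0.2:
                raise ValueError("substitution rates must lie in [0, 0.2]")
        if self.intraspecific_snp_rate >= self.interspecific_snp_rate:
            raise ValueError(
                "intraspecific rate must be below interspecific rate "
                "(the premise of species-level barcoding)"
            )
        if len(self.species) < 2 or any(n < 1 for _, n in self.species):
            raise ValueError("need >=2 species with >=1 sample each")
        if self.ir_length + self.ssc_length >= self.genome_length / 2:
            raise ValueError("ir_length + ssc_length must be < genome_length / 2")
        if any(l < 1 for l in self.diagnostic_indel_lengths):
            raise ValueError("diagnostic InDel lengths must be >= 1")

    @property
    def lsc_length(self) -> int:
        return self.genome_length - 2 * self.ir_length - self.ssc_length

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.species)

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SimulationScenario":
        """Full plastome dimensions: ~155 kb genomes with 25,958 bp IRs
        and an 18,765 bp SSC, four species, 36 accessions.  The master
        length is chosen so every emitted sample (after its planted
        deletions) keeps LSC/IR/SSC and total lengths inside the ranges
        observed for real congeneric plastome panels."""
        return cls(
            seed=seed,
            genome_length=155_320,
            ir_length=25_958,
            ssc_length=18_765,
            species=(
                (agrimonia.PILOSA, 26),
                (agrimonia.COREANA, 3),
                (agrimonia.NIPPONICA, 4),
                (agrimonia.EUPATORIA, 3),
            ),
        )


# ---------------------------------------------------------------------------
# Marker planting specs


@dataclass(frozen=True)
class MarkerSpec:
    """Blueprint of one marker locus to plant into a synthetic genome.

    ``product_a`` is the full product size of the pattern-A allele;
    ``product_b`` the pattern-B size (``None`` = no amplification, a
    dominant marker).  For CAPS markers both alleles share the product
    size and ``cut_fragments`` gives the digestion fragments of the
    pattern-A allele (two fragments = one planted site).
    """

    name: str
    kind: str
    a_species: tuple[str, ...]
    b_species: tuple[str, ...]
    product_a: int
    product_b: int | None = None
    cut_fragments: tuple[int, ...] | None = None
    forward: str | None = None
    reverse: str | None = None
    primer_length: int = 21
    enzyme: Enzyme | None = None

    def __post_init__(self) -> None:
        if self.kind == "codominant_indel":
            if self.product_b is None or self.product_b >= self.product_a:
                raise ValueError(f"{self.name}: InDel marker needs product_b < product_a")
        elif self.kind == "dominant_snp":
            if self.product_b is not None:
                raise ValueError(f"{self.name}: dominant marker has no B product")
        elif self.kind == "codominant_caps":
            if self.product_b != self.product_a:
                raise ValueError(f"{self.name}: CAPS alleles share the product size")
            if not self.cut_fragments or len(self.cut_fragments) != 2:
                raise ValueError(f"{self.name}: need exactly two CAPS cut fragments")
            if sum(self.cut_fragments) != self.product_a:
                raise ValueError(f"{self.name}: CAPS fragments must sum to product size")
        else:
            raise ValueError(f"{self.name}: unknown marker kind {self.kind!r}")


def agrimonia_marker_specs() -> list[MarkerSpec]:
    """Planting specs reproducing the published panel's primers/sizes."""
    specs = []
    for m in agrimonia.PANEL:
        if m.kind == "codominant_caps":
            product_b = m.fragments_b[0]
            cut = m.fragments_a
        elif m.kind == "codominant_indel":
            product_b = m.fragments_b[0]
            cut = None
        else:
            product_b = None
            cut = None
        specs.append(
            MarkerSpec(
                name=m.name,
                kind=m.kind,
                a_species=m.a_species,
                b_species=m.b_species,
                product_a=m.fragments_a[0] if m.kind != "codominant_caps" else sum(m.fragments_a),
                product_b=product_b,
                cut_fragments=cut,
                forward=m.forward,
                reverse=m.reverse,
                enzyme=ECORI if m.kind == "codominant_caps" else None,
            )
        )
    return specs


@dataclass(frozen=True)
class _PlantedWindow:
    spec: MarkerSpec
    primers: PrimerPair
    enzyme: Enzyme | None
    content_a: str  # pattern-A allele of the whole locus (product-sized)
    b_gap: tuple[int, int] | None  # window offsets gapped in B alleles
    b_snp: tuple[int, str] | None  # (window offset, substituted base) in B alleles

    @property
    def length(self) -> int:
        return len(self.content_a)

    def expected(self) -> dict[str, tuple[int, ...]]:
        spec = self.spec
        if spec.kind == "codominant_caps":
            return {
                "A": tuple(sorted(spec.cut_fragments, reverse=True)),
                "B": (spec.product_a,),
            }
        if spec.kind == "dominant_snp":
            return {"A": (spec.product_a,), "B": ()}
        return {"A": (spec.product_a,), "B": (spec.product_b,)}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(0, len(choices)))]


def _count_occurrences(haystack: str, needle: str) -> int:
    return haystack.count(needle) + reverse_complement(haystack).count(needle)


def _build_window(rng: np.random.Generator, spec: MarkerSpec) -> _PlantedWindow:
    """Construct one marker locus (pattern-A allele + B-allele edit)."""
    forward = spec.forward or _random_seq(rng, spec.primer_length)
    rev = spec.reverse or _random_seq(rng, spec.primer_length)
    lf, lr = len(forward), len(rev)
    interior_len = spec.product_a - lf - lr
    if interior_len < 3:
        raise SimulationError(f"{spec.name}: product too small for primers")

    for _ in range(200):
        window = forward + _random_seq(rng, interior_len) + reverse_complement(rev)
        b_gap = b_snp = None
        if spec.kind == "codominant_indel":
            diff = spec.product_a - spec.product_b
            lo, hi = lf + 1, len(window) - lr - 1 - diff
            if hi < lo:
                raise SimulationError(f"{spec.name}: window too small for InDel block")
            start = int(rng.integers(lo, hi + 1))
            b_gap = (start, start + diff)
            window_b = window[: start] + window[start + diff :]
        elif spec.kind == "dominant_snp":
            off = lf - 1  # 3'-terminal base of the forward primer
            b_snp = (off, _other_base(rng, window[off]))
            window_b = window[:off] + b_snp[1] + window[off + 1 :]
        else:  # codominant_caps
            enzyme = spec.enzyme or ECORI
            site = enzyme.recognition
            if set(site) - set(_BASES):
                raise SimulationError(f"{spec.name}: degenerate enzyme sites unsupported")
            cut = max(spec.cut_fragments)  # cut measured from the forward end
            site_start = cut - enzyme.cut_offset
            if site_start < lf + 1 or site_start + len(site) > len(window) - lr - 1:
                cut = min(spec.cut_fragments)
                site_start = cut - enzyme.cut_offset
            if site_start < lf + 1 or site_start + len(site) > len(window) - lr - 1:
                raise SimulationError(f"{spec.name}: enzyme site does not fit the product")
            window = window[:site_start] + site + window[site_start + len(site) :]
            mut_at = site_start + len(site) // 2
            b_snp = (mut_at, _other_base(rng, window[mut_at]))
            window_b = window[:mut_at] + b_snp[1] + window[mut_at + 1 :]

        # the primers must bind exactly once, on the intended strand,
        # in both alleles (B checked without its abolished site)
        ok = (
            _count_occurrences(window, forward) == 1
            and _count_occurrences(window, rev) == 1
            and window.startswith(forward)
            and window.endswith(reverse_complement(rev))
        )
        if ok and spec.kind == "dominant_snp":
            # the edited allele must no longer carry the forward site
            ok = forward not in window_b and forward not in reverse_complement(window_b)
        elif ok:
            ok = (
                _count_occurrences(window_b, forward) == 1
                and _count_occurrences(window_b, rev) == 1
            )
        if ok and spec.kind == "codominant_caps":
            enzyme = spec.enzyme or ECORI
            ok = digest(window, enzyme) == sorted(spec.cut_fragments, reverse=True) and digest(
                window_b, enzyme
            ) == [len(window_b)]
        if ok:
            return _PlantedWindow(
                spec=spec,
                primers=PrimerPair(spec.name, forward, rev),
                enzyme=spec.enzyme or (ECORI if spec.kind == "codominant_caps" else None),
                content_a=window,
                b_gap=b_gap,
                b_snp=b_snp,
            )
    raise SimulationError(f"{spec.name}: could not realise marker window")


def plant_marker_loci(
    genome: str,
    specs: Sequence[MarkerSpec],
    seed: int = 0,
    position: int | None = None,
    spacer: int = 60,
) -> tuple[dict[str, str], list[MarkerDefinition]]:
    """Insert a marker panel into a genome; return per-species variants.

    All loci are inserted contiguously (separated by random ``spacer``
    sequence) at ``position`` (default: genome midpoint).  Each species
    named by the specs receives the pattern-A allele at its own markers
    and pattern-B elsewhere.  Returns the per-species genome strings and
    the corresponding :class:`MarkerDefinition` panel.
    """
    rng = np.random.default_rng(seed)
    windows = [_build_window(rng, spec) for spec in specs]
    species = sorted({sp for w in windows for sp in (*w.spec.a_species, *w.spec.b_species)})
    pos = len(genome) // 2 if position is None else position

    cassettes: dict[str, list[str]] = {sp: [] for sp in species}
    for w in windows:
        gap_fill = _random_seq(rng, spacer)
        for sp in species:
            if sp in w.spec.a_species:
                allele = w.content_a
            elif w.b_gap is not None:
                allele = w.content_a[: w.b_gap[0]] + w.content_a[w.b_gap[1] :]
            elif w.b_snp is not None:
                off, base = w.b_snp
                allele = w.content_a[:off] + base + w.content_a[off + 1 :]
            else:
                allele = w.content_a
            cassettes[sp].append(allele + gap_fill)

    genomes = {
        sp: genome[:pos] + "".join(parts) + genome[pos:] for sp, parts in cassettes.items()
    }
    defs = [
        MarkerDefinition(
            name=w.spec.name,
            kind=w.spec.kind,
            primers=w.primers,
            expected=w.expected(),
            classification={"A": w.spec.a_species, "B": w.spec.b_species},
            enzyme=w.enzyme,
        )
        for w in windows
    ]
    return genomes, defs


# ---------------------------------------------------------------------------
# Truth set


@dataclass(frozen=True)
class PlantedDiagnostic:
    """One locus known to separate a species from all others.

    ``source`` records how it arose: explicitly planted ("planted"),
    implied by a planted marker allele ("marker"), or created by a
    species-branch substitution ("branch" — equally diagnostic)."""

    species: str
    kind: str  # "SNP" | "InDel"
    start: int  # 0-based alignment columns, half-open
    end: int
    target_allele: str
    other_allele: str
    source: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything the simulator knows about an emitted species set."""

    scenario: SimulationScenario
    tree_newick: str
    alignment: Alignment
    labels: SpeciesLabeling
    genomes: list[SequenceRecord]
    diagnostics: list[PlantedDiagnostic]
    markers: list[MarkerDefinition]
    expected_patterns: dict[str, dict[str, str]]
    region_columns: dict[str, tuple[int, int]]
    quadripartite: dict[str, tuple[int, int, int, int]]

    def diagnostic_loci(self, species: str, kind: str) -> set[tuple[int, int]]:
        """Column intervals of all loci diagnostic for one species."""
        return {
            (d.start, d.end)
            for d in self.diagnostics
            if d.species == species and d.kind == kind
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "alignment.fasta")
        write_genomes(self.genomes, outdir / "genomes.fasta")
        self.labels.to_tsv(outdir / "labels.tsv")
        write_panel(self.markers, outdir / "truth_markers.tsv")
        pd.DataFrame(
            [
                {
                    "species": d.species,
                    "kind": d.kind,
                    "column_start": d.start + 1,
                    "column_end": d.end,
                    "target_allele": d.target_allele,
                    "other_allele": d.other_allele,
                    "source": d.source,
                }
                for d in self.diagnostics
            ]
        ).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"sample": s, "lsc": q[0], "ira": q[1], "ssc": q[2], "irb": q[3]}
                for s, q in sorted(self.quadripartite.items())
            ]
        ).to_csv(outdir / "truth_structure.tsv", sep="\t", index=False)
        (outdir / "tree.nwk").write_text(self.tree_newick + "\n")


# ---------------------------------------------------------------------------
# Simulation


def _sample_code(species: str, seen: dict[str, str]) -> str:
    code = "".join(w[0] for w in species.replace(".", "").split() if w)
    base, i = code, 1
    while code in seen.values():
        i += 1
        code = f"{base}{i}"
    return code


def _species_newick(scn: SimulationScenario, sample_ids: dict[str, list[str]]) -> str:
    t_samp = scn.intraspecific_snp_rate / 2
    t_term = scn.interspecific_snp_rate / 2
    t_int = scn.interspecific_snp_rate / 4

    def clade(species: str) -> str:
        ids = sample_ids[species]
        if len(ids) == 1:
            return ids[0]
        return "(" + ",".join(f"{s}:{t_samp:g}" for s in ids) + ")"

    names = scn.species_names
    acc = f"({clade(names[0])}:{t_term:g},{clade(names[1])}:{t_term:g})"
    for name in names[2:]:
        acc = f"({acc}:{t_int:g},{clade(name)}:{t_term:g})"
    return acc + ";"


def simulate_species_set(scn: SimulationScenario) -> TruthSet:
    """Generate one synthetic species set and its complete truth set.

    Fully deterministic for a given scenario (including the seed).  The
    panel's expected band patterns are verified against the package's
    own in-silico PCR on the emitted genomes before returning.
    """
    rng = np.random.default_rng(scn.seed)
    L, lsc, ir, ssc = scn.genome_length, scn.lsc_length, scn.ir_length, scn.ssc_length

    # --- feature layout inside the LSC -------------------------------------
    windows = (
        [_build_window(rng, spec) for spec in agrimonia_marker_specs()]
        if scn.plant_panel
        else []
    )
    features: list[tuple[str, object, int]] = [("marker", w, w.length) for w in windows]
    for species in scn.species_names:
        for length in scn.diagnostic_indel_lengths:
            features.append(("indel", species, int(length)))
        for _ in range(scn.diagnostic_snps_per_species):
            features.append(("snp", species, 1))
    order = rng.permutation(len(features))
    features = [features[i] for i in order]

    total_feature = sum(f[2] for f in features)
    n_spacers = len(features) + 1
    free = lsc - total_feature - scn.min_spacer * n_spacers
    if free < 0:
        raise SimulationError(
            f"LSC of {lsc} bp cannot hold {total_feature} bp of planted features"
        )
    extras = rng.multinomial(free, np.full(n_spacers, 1 / n_spacers))
    spacer_lengths = [scn.min_spacer + int(e) for e in extras]

    # --- ancestral master genome -------------------------------------------
    parts: list[str] = []
    placed: list[tuple[str, object, int, int]] = []  # (kind, payload, start, end)
    cursor = 0
    for spacer_len, feature in zip(spacer_lengths, features + [None]):
        parts.append(_random_seq(rng, spacer_len))
        cursor += spacer_len
        if feature is None:
            break
        kind, payload, length = feature
        parts.append(
            payload.content_a if kind == "marker" else _random_seq(rng, length)
        )
        placed.append((kind, payload, cursor, cursor + length))
        cursor += length
    assert cursor == lsc
    ira_seq = _random_seq(rng, ir)
    parts.append(ira_seq)
    parts.append(_random_seq(rng, ssc))
    parts.append(reverse_complement(ira_seq))
    master = list("".join(parts))
    assert len(master) == L

    # block IR boundary extension: the flanking bases must not complement
    boundary = {lsc - 1, 0, lsc + ir, L - ir - 1}
    if master[lsc - 1] == _COMP[master[0]]:
        master[lsc - 1] = _other_base(rng, master[lsc - 1])
    if master[lsc + ir] == _COMP[master[L - ir - 1]]:
        master[lsc + ir] = _other_base(rng, master[lsc + ir])
    master = "".join(master)

    # --- mutable columns ----------------------------------------------------
    mutable = np.zeros(L, dtype=bool)
    mutable[:lsc] = True
    mutable[lsc + ir : lsc + ir + ssc] = True
    for _, _, start, end in placed:
        mutable[start:end] = False
    for b in boundary:
        mutable[b] = False
    mut_cols = np.flatnonzero(mutable)

    # --- samples and the mutation plan --------------------------------------
    codes: dict[str, str] = {}
    sample_ids: dict[str, list[str]] = {}
    for species, n in scn.species:
        codes[species] = _sample_code(species, codes)
        sample_ids[species] = [f"{codes[species]}_{i + 1}" for i in range(n)]
    all_samples = [s for species in scn.species_names for s in sample_ids[species]]
    sample_species = {
        s: species for species in scn.species_names for s in sample_ids[species]
    }

    names = scn.species_names
    m_term = round(scn.interspecific_snp_rate * L / 2)
    m_int = round(scn.interspecific_snp_rate * L / 4)
    m_samp = round(scn.intraspecific_snp_rate * L / 2)
    branches: list[tuple[frozenset[str], int]] = [
        (frozenset(names[: j + 1]), m_int) for j in range(1, len(names) - 1)
    ] + [(frozenset((sp,)), m_term) for sp in names]
    events_needed = sum(m for _, m in branches) + m_samp * len(all_samples)
    if events_needed > len(mut_cols):
        raise SimulationError("substitution rates too high for the mutable genome span")
    chosen = rng.choice(mut_cols, size=events_needed, replace=False)

    rows: dict[str, np.ndarray] = {
        s: np.frombuffer(master.encode(), np.uint8).copy() for s in all_samples
    }
    master_arr = np.frombuffer(master.encode(), np.uint8)

    diagnostics: list[PlantedDiagnostic] = []
    recorder = _DiagnosticRecorder(diagnostics, scn.species_names, sample_ids)
    take = 0
    for clade, m in branches:
        cols = chosen[take : take + m]
        take += m
        carriers = {s for s in all_samples if sample_species[s] in clade}
        for col in map(int, cols):
            derived = _other_base(rng, master[col])
            for s in carriers:
                rows[s][col] = ord(derived)
            recorder.snp(carriers, col, derived, master[col], "branch")
    for s in all_samples:
        cols = chosen[take : take + m_samp]
        take += m_samp
        for col in map(int, cols):
            derived = _other_base(rng, chr(rows[s][col]))
            rows[s][col] = ord(derived)
            recorder.snp({s}, col, derived, chr(master_arr[col]), "branch")

    # --- plant explicit diagnostics -----------------------------------------
    for kind, payload, start, end in placed:
        if kind == "snp":
            species = payload
            target = set(sample_ids[species])
            x = master[start]
            y = _other_base(rng, x)
            for s in all_samples:
                rows[s][start] = ord(x if s in target else y)
            recorder.snp(target, start, x, y, "planted")
        elif kind == "indel":
            species = payload
            for s in sample_ids[species]:
                rows[s][start:end] = _GAP
            recorder.indel(set(sample_ids[species]), start, end, "planted")

    # --- plant panel alleles -------------------------------------------------
    markers: list[MarkerDefinition] = []
    for kind, payload, start, end in placed:
        if kind != "marker":
            continue
        w: _PlantedWindow = payload
        b_samples = {s for sp in w.spec.b_species for s in sample_ids.get(sp, [])}
        if w.b_gap is not None:
            g0, g1 = start + w.b_gap[0], start + w.b_gap[1]
            for s in b_samples:
                rows[s][g0:g1] = _GAP
            recorder.indel(b_samples, g0, g1, "marker")
        elif w.b_snp is not None:
            off, base = w.b_snp
            col = start + off
            for s in b_samples:
                rows[s][col] = ord(base)
            recorder.snp(b_samples, col, base, master[col], "marker")
        markers.append(
            MarkerDefinition(
                name=w.spec.name,
                kind=w.spec.kind,
                primers=w.primers,
                expected=w.expected(),
                classification={"A": w.spec.a_species, "B": w.spec.b_species},
                enzyme=w.enzyme,
            )
        )

    # --- assemble records ----------------------------------------------------
    records = [
        SequenceRecord(s, rows[s].tobytes().decode(), circular=False)
        for s in all_samples
    ]
    alignment = Alignment(records)
    genomes = [
        SequenceRecord(s, rows[s].tobytes().decode().replace("-", ""), circular=True)
        for s in all_samples
    ]
    labels = SpeciesLabeling({s: sample_species[s] for s in all_samples})

    region_columns = {
        "LSC": (0, lsc),
        "IRa": (lsc, lsc + ir),
        "SSC": (lsc + ir, lsc + ir + ssc),
        "IRb": (lsc + ir + ssc, L),
    }
    quadripartite = {}
    for s in all_samples:
        row = rows[s]
        lengths = tuple(
            int(np.count_nonzero(row[a:b] != _GAP)) for a, b in region_columns.values()
        )
        quadripartite[s] = lengths

    expected_patterns = {
        species: {
            m.name: ("A" if species in m.classification["A"] else "B") for m in markers
        }
        for species in scn.species_names
    }

    truth = TruthSet(
        scenario=scn,
        tree_newick=_species_newick(scn, sample_ids),
        alignment=alignment,
        labels=labels,
        genomes=genomes,
        diagnostics=diagnostics,
        markers=markers,
        expected_patterns=expected_patterns,
        region_columns=region_columns,
        quadripartite=quadripartite,
    )
    if markers:
        _assert_panel_consistency(truth)
    return truth


class _DiagnosticRecorder:
    """Book-keeps every locus that separates one species from the rest.

    A variant carried by exactly the samples of one species — or by
    exactly everything else — is species-diagnostic, whether it was
    planted on purpose or arose from a species-branch substitution."""

    def __init__(
        self,
        diagnostics: list[PlantedDiagnostic],
        names: tuple[str, ...],
        sample_ids: dict[str, list[str]],
    ):
        self.diagnostics = diagnostics
        self.names = names
        self.sample_sets = {sp: frozenset(sample_ids[sp]) for sp in names}
        self.all_samples = frozenset().union(*self.sample_sets.values())

    def snp(self, carriers: set, col: int, carrier_allele: str, other_allele: str, source: str) -> None:
        carriers = frozenset(carriers)
        for sp in self.names:
            sps = self.sample_sets[sp]
            if carriers == sps:
                self.diagnostics.append(
                    PlantedDiagnostic(sp, "SNP", col, col + 1, carrier_allele, other_allele, source)
                )
            elif carriers == self.all_samples - sps:
                self.diagnostics.append(
                    PlantedDiagnostic(sp, "SNP", col, col + 1, other_allele, carrier_allele, source)
                )

    def indel(self, gapped: set, start: int, end: int, source: str) -> None:
        gapped = frozenset(gapped)
        for sp in self.names:
            sps = self.sample_sets[sp]
            if gapped == sps:
                self.diagnostics.append(
                    PlantedDiagnostic(sp, "InDel", start, end, "gap", "present", source)
                )
            elif gapped == self.all_samples - sps:
                self.diagnostics.append(
                    PlantedDiagnostic(sp, "InDel", start, end, "present", "gap", source)
                )


def _assert_panel_consistency(truth: TruthSet) -> None:
    """Emitted genomes must genotype to the expected patterns exactly."""
    patterns = evaluate_panel(truth.genomes, truth.markers)
    for p in patterns:
        species = truth.labels[p.sample_id]
        want = truth.expected_patterns[species][p.marker_name]
        if p.matched_label != want:
            raise SimulationError(
                f"self-check failed: {p.sample_id} x {p.marker_name} scored "
                f"{p.matched_label!r} (fragments {p.fragments}), expected {want!r}"
            )


# ---------------------------------------------------------------------------
# Divergent pair


def simulate_divergent_pair(
    length: int = 15_000,
    n_snps: int = 64,
    n_indel_events: int = 31,
    max_indel_length: int = 12,
    seed: int = 0,
    ids: tuple[str, str] = ("sample_1", "sample_2"),
) -> Alignment:
    """An aligned genome pair with exact planted variant counts.

    Plants exactly ``n_snps`` substitution columns and
    ``n_indel_events`` separate gap runs (each gapping one of the two
    rows, lengths 1..``max_indel_length``), well separated so every run
    is one event and none touches an alignment edge.
    """
    rng = np.random.default_rng(seed)
    indel_lengths = [int(x) for x in rng.integers(1, max_indel_length + 1, n_indel_events)]
    feature_lengths = [1] * n_snps + indel_lengths
    kinds = ["snp"] * n_snps + ["indel"] * n_indel_events
    order = rng.permutation(len(kinds))
    feature_lengths = [feature_lengths[i] for i in order]
    kinds = [kinds[i] for i in order]

    min_spacer = 2
    n_spacers = len(kinds) + 1
    free = length - sum(feature_lengths) - min_spacer * n_spacers
    if free < 0:
        raise SimulationError("alignment too short for the requested variants")
    extras = rng.multinomial(free, np.full(n_spacers, 1 / n_spacers))
    spacers = [min_spacer + int(e) for e in extras]

    a: list[str] = []
    b: list[str] = []
    for spacer, kind, flen in zip(spacers, kinds + [None], feature_lengths + [0]):
        block = _random_seq(rng, spacer)
        a.append(block)
        b.append(block)
        if kind is None:
            break
        seg = _random_seq(rng, flen)
        if kind == "snp":
            a.append(seg)
            b.append(_other_base(rng, seg))
        else:
            gapped_row = a if rng.integers(0, 2) else b
            other_row = b if gapped_row is a else a
            gapped_row.append("-" * flen)
            other_row.append(seg)
    return Alignment(
        [
            SequenceRecord(ids[0], "".join(a)),
            SequenceRecord(ids[1], "".join(b)),
        ]
    )
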