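"""Primer-site search, amplification, CAPS digestion, panel genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import superbarcode as sb
from superbarcode.agrimonia import PANEL
from superbarcode.pcr import ECORI, read_band_matrix, write_band_matrix, read_panel, write_panel

from conftest import random_dna

AP1_F = "TCCCGAATATTCAACCGATTA"
AP1_R = "CCCTTTGTGTATACCTTTTCAAAT"


def _template(seq: str, circular: bool = False) -> sb.SequenceRecord:
    return sb.SequenceRecord("tmpl", seq, circular=circular)


# ---------------------------------------------------------------------------
# primer sites


def test_exact_plus_strand_site():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 100) + AP1_F + random_dna(rng, 80)
    hits = sb.find_primer_sites(_template(seq), AP1_F)
    assert (101, "+") in hits and len(hits) == 1


def test_absent_primer_no_hits():
    rng = np.random.default_rng(1)
    assert sb.find_primer_sites(_template(random_dna(rng, 200)), AP1_F) == []


def test_minus_strand_site_reports_leftmost_coordinate():
    rng = np.random.default_rng(2)
    seq = random_dna(rng, 50) + sb.reverse_complement(AP1_R) + random_dna(rng, 30)
    hits = sb.find_primer_sites(_template(seq), AP1_R)
    assert hits == [(51, "-")]


def test_degenerate_primer_codes_match_their_sets():
    seq = "AAAACGTACGTAAAA"
    assert sb.find_primer_sites(_template(seq), "ACGTACGTAA") != []
    assert sb.find_primer_sites(_template(seq), "ACRTACRTAA") != []  # R covers G
    assert sb.find_primer_sites(_template(seq), "ACYTACGTAA") == []  # Y cannot be G


def test_circular_site_spanning_origin():
    rng = np.random.default_rng(3)
    filler = random_dna(rng, 120)
    seq = AP1_F[10:] + filler + AP1_F[:10]
    assert sb.find_primer_sites(_template(seq, circular=True), AP1_F) == [
        (len(seq) - 10 + 1, "+")
    ]
    assert sb.find_primer_sites(_template(seq, circular=False), AP1_F) == []


def test_primer_longer_than_template_is_empty():
    assert sb.find_primer_sites(_template("ACGTACGTAA"), "A" * 50) == []


def test_mismatch_tolerance_with_three_prime_anchor():
    rng = np.random.default_rng(4)
    mutated = "G" + AP1_F[1:]  # one 5' mismatch
    seq = random_dna(rng, 40) + mutated + random_dna(rng, 40)
    assert sb.find_primer_sites(_template(seq), AP1_F, max_mismatch=0) == []
    assert sb.find_primer_sites(_template(seq), AP1_F, max_mismatch=1) == [(41, "+")]
    # a 3'-terminal mismatch is never tolerated within the anchor
    mutated3 = AP1_F[:-1] + ("C" if AP1_F[-1] != "C" else "G")
    seq3 = random_dna(rng, 40) + mutated3 + random_dna(rng, 40)
    assert sb.find_primer_sites(_template(seq3), AP1_F, max_mismatch=2, three_prime_anchor=1) == []


# ---------------------------------------------------------------------------
# amplification


def test_amplify_constructed_product():
    rng = np.random.default_rng(5)
    insert = random_dna(rng, 10)
    seq = random_dna(rng, 60) + AP1_F + insert + sb.reverse_complement(AP1_R) + random_dna(rng, 60)
    pair = sb.PrimerPair("AP1", AP1_F, AP1_R)
    amps = sb.amplify(_template(seq), pair)
    assert len(amps) == 1
    amp = amps[0]
    assert amp.length == len(AP1_F) + 10 + len(AP1_R) == 55
    assert amp.sequence.startswith(AP1_F)
    assert amp.sequence.endswith(sb.reverse_complement(AP1_R))


def test_amplify_requires_convergent_orientation():
    rng = np.random.default_rng(6)
    # both primers on the plus strand: no convergent pair, no product
    seq = random_dna(rng, 30) + AP1_F + random_dna(rng, 20) + AP1_R + random_dna(rng, 30)
    assert sb.amplify(_template(seq), sb.PrimerPair("AP1", AP1_F, AP1_R)) == []


def test_amplify_max_product_cap():
    rng = np.random.default_rng(7)
    seq = AP1_F + random_dna(rng, 300) + sb.reverse_complement(AP1_R)
    pair = sb.PrimerPair("AP1", AP1_F, AP1_R)
    assert sb.amplify(_template(seq), pair, max_product=100) == []
    assert len(sb.amplify(_template(seq), pair, max_product=400)) == 1


def test_amplify_wraps_origin_on_circular_template():
    rng = np.random.default_rng(8)
    core = AP1_F + random_dna(rng, 40) + sb.reverse_complement(AP1_R)
    filler = random_dna(rng, 150)
    # rotate so the product spans the origin
    seq = core[60:] + filler + core[:60]
    amps = sb.amplify(_template(seq, circular=True), sb.PrimerPair("AP1", AP1_F, AP1_R))
    assert len(amps) == 1 and amps[0].wraps_origin
    assert amps[0].sequence == core


def test_amplify_rotation_invariance(truth):
    genome = truth.genomes[0]
    marker = truth.markers[0]
    baseline = sorted(a.length for a in sb.amplify(genome, marker.primers))
    rng = np.random.default_rng(9)
    for _ in range(3):
        shift = int(rng.integers(1, len(genome.seq)))
        rotated = sb.SequenceRecord(genome.id, genome.seq[shift:] + genome.seq[:shift], circular=True)
        assert sorted(a.length for a in sb.amplify(rotated, marker.primers)) == baseline


def test_strand_involution():
    rng = np.random.default_rng(10)
    seq = random_dna(rng, 50) + AP1_F + random_dna(rng, 33) + sb.reverse_complement(AP1_R) + random_dna(rng, 50)
    fwd = sb.amplify(_template(seq), sb.PrimerPair("AP1", AP1_F, AP1_R))
    rev = sb.amplify(
        _template(sb.reverse_complement(seq)), sb.PrimerPair("AP1r", AP1_R, AP1_F)
    )
    assert [a.length for a in fwd] == [a.length for a in rev] != []


def test_dominant_three_prime_ablation():
    rng = np.random.default_rng(11)
    ap2 = next(m for m in PANEL if m.name == "AP2")
    core = ap2.forward + random_dna(rng, 50) + sb.reverse_complement(ap2.reverse)
    pair = sb.PrimerPair("AP2", ap2.forward, ap2.reverse)
    assert len(sb.amplify_dominant(_template(core), pair)) == 1
    off = len(ap2.forward) - 1
    base = core[off]
    mutated = core[:off] + ("A" if base != "A" else "C") + core[off + 1 :]
    assert sb.amplify_dominant(_template(mutated), pair) == []


# ---------------------------------------------------------------------------
# digestion


def test_digest_single_site():
    assert sb.digest("AAGAATTCTT", ECORI) == [7, 3]


def test_digest_no_site_returns_whole_length():
    assert sb.digest("A" * 37, ECORI) == [37]


def test_digest_minus_strand_site_of_asymmetric_enzyme():
    enzyme = sb.Enzyme("toy", "GACGT", 1)
    # plus strand lacks the site; the reverse complement carries it
    assert sb.digest("AAACGTCAA", enzyme) == [6, 3]


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=6, max_size=400))
def test_digest_conserves_length(seq):
    fragments = sb.digest(seq, ECORI)
    assert sum(fragments) == len(seq)
    assert fragments == sorted(fragments, reverse=True)
    assert all(f >= 1 for f in fragments)


# ---------------------------------------------------------------------------
# panel genotyping


def test_synthetic_pilosa_sample_matches_published_patterns(truth):
    pilosa = next(g for g in truth.genomes if truth.labels[g.id] == "A. pilosa")
    got = {
        p.marker_name: p.matched_label
        for p in sb.evaluate_panel([pilosa], truth.markers)
    }
    assert got == {
        "AP1": "A", "AP2": "A", "AC1": "B", "AC2": "B",
        "AN1": "B", "AN2": "B", "AE1": "B", "AE2": "B",
    }
    # the dominant non-target lane is an empty lane
    (an2,) = [p for p in sb.evaluate_panel([pilosa], truth.markers) if p.marker_name == "AN2"]
    assert an2.fragments == ()


def test_codominant_indel_size_difference(truth):
    ac2 = next(m for m in truth.markers if m.name == "AC2")
    by_species = {}
    for g in truth.genomes:
        (amp,) = sb.amplify(g, ac2.primers)
        by_species[truth.labels[g.id]] = amp.length
    assert by_species["A. coreana"] - by_species["A. pilosa"] == 20


def test_empty_sample_list_gives_empty_matrix(truth):
    assert sb.evaluate_panel([], truth.markers) == []


def test_duplicate_marker_names_error(truth):
    with pytest.raises(ValueError, match="duplicate"):
        sb.evaluate_panel(truth.genomes[:1], [truth.markers[0], truth.markers[0]])


def test_band_matrix_round_trip(tmp_path, truth):
    patterns = sb.evaluate_panel(truth.genomes[:3], truth.markers)
    path = tmp_path / "bands.tsv"
    write_band_matrix(patterns, path)
    again = read_band_matrix(path)
    assert {(p.sample_id, p.marker_name, p.fragments, p.matched_label) for p in again} == {
        (p.sample_id, p.marker_name, p.fragments, p.matched_label) for p in patterns
    }


def test_panel_tsv_round_trip(tmp_path, truth):
    path = tmp_path / "panel.tsv"
    write_panel(truth.markers, path)
    again = read_panel(path)
    assert [m.name for m in again] == [m.name for m in truth.markers]
    for a, b in zip(again, truth.markers):
        assert a.kind == b.kind
        assert a.primers.forward == b.primers.forward
        assert a.expected == b.expected
        assert a.classification == b.classification
        assert (a.enzyme is None) == (b.enzyme is None)
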