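"""Alignment loading, pairwise/column variant extraction, SNP density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import superbarcode as sb
from superbarcode.alignment import AlignmentFormatError, write_alignment

from conftest import make_alignment


# ---------------------------------------------------------------------------
# loading


def test_load_minimal_alignment(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">s1\nAC-GT\n>s2\naccgu\n")
    aln = sb.load_alignment(p)
    assert aln.length == 5 and len(aln) == 2
    # lowercase is uppercased, RNA U becomes T
    assert aln.row("s2") == "ACCGT"


def test_unequal_lengths_error_names_record(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">s1\nACGTA\n>s2\nACGTAC\n")
    with pytest.raises(AlignmentFormatError, match="record 2.*s2"):
        sb.load_alignment(p)


def test_duplicate_ids_error(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">s1\nACGT\n>s1\nACGT\n")
    with pytest.raises(AlignmentFormatError, match="duplicate"):
        sb.load_alignment(p)


def test_round_trip(tmp_path, truth):
    p = tmp_path / "rt.fasta"
    write_alignment(truth.alignment, p)
    again = sb.load_alignment(p)
    assert again.ids == truth.alignment.ids
    assert all(
        again.row(s) == truth.alignment.row(s) for s in truth.alignment.ids
    )


# ---------------------------------------------------------------------------
# pairwise variants


def test_pairwise_example():
    aln = make_alignment({"a": "ACGTACGT--AC", "b": "ACCTACGTGGAC"})
    assert sb.count_pairwise_variants(aln, "a", "b") == (1, 1, 2)


def test_pairwise_identity():
    aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT"})
    assert sb.count_pairwise_variants(aln, "a", "b") == (0, 0, 0)


def test_pairwise_unknown_id():
    aln = make_alignment({"a": "ACGT", "b": "ACGT"})
    with pytest.raises(KeyError):
        sb.count_pairwise_variants(aln, "a", "zzz")


def test_terminal_gaps_excluded_by_default():
    aln = make_alignment({"a": "--ACGT", "b": "CCACGA"})
    assert sb.count_pairwise_variants(aln, "a", "b") == (1, 0, 0)
    assert sb.count_pairwise_variants(aln, "a", "b", ignore_terminal_gaps=False) == (
        1,
        1,
        2,
    )


def _brute_force_pair(sa: str, sb_: str, ignore_terminal: bool = True):
    """Independent per-column scan used as the counting oracle."""
    n = len(sa)

    def core(s):
        i = 0
        while s[i] == "-":
            i += 1
        j = n
        while s[j - 1] == "-":
            j -= 1
        return i, j

    lo, hi = 0, n
    if ignore_terminal:
        a0, a1 = core(sa)
        b0, b1 = core(sb_)
        lo, hi = max(a0, b0), min(a1, b1)
        if lo >= hi:
            return (0, 0, 0)
    snp = sites = events = 0
    prev = None
    for i in range(lo, hi):
        x, y = sa[i], sb_[i]
        state = None
        if x == "-" and y != "-":
            state = "a"
        elif y == "-" and x != "-":
            state = "b"
        if x in "ACGT" and y in "ACGT" and x != y:
            snp += 1
        if state:
            sites += 1
            if state != prev:
                events += 1
        prev = state
    return snp, events, sites


@st.composite
def _gapped_pairs(draw):
    length = draw(st.integers(2, 80))
    alphabet = "ACGT" + "N-"

    def row():
        s = draw(st.text(alphabet=alphabet, min_size=length, max_size=length))
        return s

    a, b = row(), row()
    for s in (a, b):
        if set(s) == {"-"}:
            a, b = a[:-1] + "A", b[:-1] + "A"
    return a[:-1] + "A", b[:-1] + "A"  # guarantee a non-gap symbol per row


@settings(max_examples=150, derandomize=True, deadline=None)
@given(_gapped_pairs(), st.booleans())
def test_pairwise_matches_brute_force_and_is_symmetric(pair, ignore_terminal):
    a, b = pair
    aln = make_alignment({"a": a, "b": b})
    got = sb.count_pairwise_variants(aln, "a", "b", ignore_terminal_gaps=ignore_terminal)
    assert got == _brute_force_pair(a, b, ignore_terminal)
    assert got == sb.count_pairwise_variants(
        aln, "b", "a", ignore_terminal_gaps=ignore_terminal
    )


def test_ambiguity_never_counts_as_snp():
    aln = make_alignment({"a": "ANRA", "b": "AARA"})
    assert sb.count_pairwise_variants(aln, "a", "b") == (0, 0, 0)


# ---------------------------------------------------------------------------
# column-wise variants


def test_msa_monomorphic():
    aln = make_alignment({"a": "AAA", "b": "AAA", "c": "AAA"})
    assert sb.call_msa_variants(aln) == ([], [])


def test_msa_single_indel_event():
    aln = make_alignment({"r1": "A-A", "r2": "ACA", "r3": "ACA"})
    sites, events = sb.call_msa_variants(aln)
    assert sites == []
    assert len(events) == 1
    (ev,) = events
    assert ev.length == 1 and ev.gapped_samples == frozenset({"r1"})


def test_msa_events_split_by_gapped_set():
    aln = make_alignment({"r1": "A--A", "r2": "AA-A", "r3": "AAAA"})
    _, events = sb.call_msa_variants(aln)
    assert {(e.start, e.end, e.gapped_samples) for e in events} == {
        (1, 2, frozenset({"r1"})),
        (2, 3, frozenset({"r1", "r2"})),
    }


def test_msa_consistent_with_pairwise(truth):
    pair = truth.alignment.subset(["Ap_1", "Ae_1"])
    sites, events = sb.call_msa_variants(pair)
    snps, n_events, _ = sb.count_pairwise_variants(
        truth.alignment, "Ap_1", "Ae_1", ignore_terminal_gaps=False
    )
    assert len(sites) == snps
    single = [e for e in events if len(e.gapped_samples) == 1]
    assert len(single) == n_events


def test_msa_recovers_planted_snp_columns(truth):
    sites, _ = sb.call_msa_variants(truth.alignment)
    found = {s.column for s in sites}
    planted = {
        d.start
        for d in truth.diagnostics
        if d.kind == "SNP" and d.source == "planted"
    }
    assert planted <= found


# ---------------------------------------------------------------------------
# density track


def test_density_no_snps_all_zero():
    aln = make_alignment({"a": "A" * 1000, "b": "A" * 1000})
    track = sb.snp_density_track(aln, "a")
    assert all(b[2] == 0 and b[3] == 0.0 for b in track.bins)


def test_density_example_bins():
    ref = list("A" * 1000)
    other = list(ref)
    other[9] = "C"  # ref position 10
    other[699] = "C"  # ref position 700
    aln = make_alignment({"ref": "".join(ref), "alt": "".join(other)})
    track = sb.snp_density_track(aln, "ref", window=600, step=200)
    bins = {(b[0], b[1]): b[2] for b in track.bins}
    assert bins[(1, 600)] == 1
    assert bins[(601, 1000)] == 1
    assert bins[(801, 1000)] == 0
    # the final partial bin is normalized by its actual span
    last = track.bins[-1]
    assert last[3] == pytest.approx(last[2] / (last[1] - last[0] + 1))


def test_density_reference_gap_columns_dropped():
    aln = make_alignment({"ref": "AA--AA", "alt": "AACCAC"})
    track = sb.snp_density_track(aln, "ref", window=4, step=4)
    assert sum(b[2] for b in track.bins) == 1  # only the projected SNP counts


def test_density_bin_sum_identity(truth):
    ref = truth.alignment.ids[0]
    track = sb.snp_density_track(truth.alignment, ref, window=500, step=500)
    sites, _ = sb.call_msa_variants(truth.alignment, reference_id=ref)
    projected = sum(1 for s in sites if s.ref_position is not None)
    assert sum(b[2] for b in track.bins) == projected


def test_density_interior_snp_membership_count(truth):
    ref = truth.alignment.ids[0]
    window, step = 600, 200
    track = sb.snp_density_track(truth.alignment, ref, window=window, step=step)
    sites, _ = sb.call_msa_variants(truth.alignment, reference_id=ref)
    ref_len = len(truth.alignment.row(ref).replace("-", ""))
    interior = [
        s.ref_position
        for s in sites
        if s.ref_position is not None and window <= s.ref_position <= ref_len - window
    ]
    memberships = sum(
        sum(1 for p in interior if b[0] <= p <= b[1]) for b in track.bins
    )
    assert memberships == len(interior) * (window // step)


def test_density_errors(truth):
    with pytest.raises(ValueError):
        sb.snp_density_track(truth.alignment, truth.alignment.ids[0], window=100, step=200)
    with pytest.raises(KeyError):
        sb.snp_density_track(truth.alignment, "no-such-sample")
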