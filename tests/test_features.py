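"""Unit and property tests for the W/S entropy feature model."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucpos import (
    DnaSequence,
    EntropyParams,
    InvalidParameterError,
    InvalidSequenceError,
    conservation_coefficient,
    count_duplex_kmers,
    geometric_entropy_component,
    index_vector_u,
    index_vector_v,
    nucleotide_frequencies,
    positioning_feature_vector,
    reverse_complement,
    structural_average,
    tsallis_entropy,
    ws_encode,
)
from nucpos.features import window_feature_matrix

dna_strings = st.text(alphabet="ACGTN", min_size=0, max_size=40)


# ---------------------------------------------------------------------------
# alphabet
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "WSSW"), ("AATT", "WWWW"), ("ANG", "WNS"), ("", "")],
)
def test_ws_encode_maps_letter_classes(seq, expected):
    assert ws_encode(seq).symbols == expected


def test_ws_encode_reports_offending_position():
    with pytest.raises(InvalidSequenceError, match="position 3"):
        ws_encode("ACXGT")


@pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("AN", "NT")])
def test_reverse_complement(seq, expected):
    assert reverse_complement(DnaSequence("t", seq)).seq == expected


@settings(derandomize=True, max_examples=200)
@given(dna_strings)
def test_ws_image_of_reverse_complement_is_reversal(seq):
    d = DnaSequence("t", seq)
    assert ws_encode(reverse_complement(d)).symbols == ws_encode(d).symbols[::-1]


# ---------------------------------------------------------------------------
# duplex k-mer counting
# ---------------------------------------------------------------------------

def brute_force_duplex_counts(seq: str, k: int) -> dict:
    """Independent oracle: enumerate k-windows on the strand and its
    reverse complement, count their W/S images, skipping N windows."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    counts = {"".join(m): 0 for m in product("WS", repeat=k)}
    for strand in (seq, rc):
        for i in range(len(strand) - k + 1):
            win = strand[i : i + k]
            if "N" in win:
                continue
            counts[ws_encode(win).symbols] += 1
    return counts


def test_duplex_kmer_counts_exhaustive_small_sequences():
    """Implementation equals window enumeration for every DNA string of
    length <= 6 and every k."""
    for L in range(1, 7):
        for tup in product("ACGT", repeat=L):
            seq = "".join(tup)
            for k in (1, 2, 3):
                if L < k:
                    continue
                got = count_duplex_kmers(seq, k)
                assert got.counts == brute_force_duplex_counts(seq, k), (seq, k)


@settings(derandomize=True, max_examples=150)
@given(dna_strings, st.sampled_from([1, 2, 3]))
def test_duplex_kmer_counts_match_oracle_with_N(seq, k):
    got = count_duplex_kmers(seq, k)
    assert got.counts == brute_force_duplex_counts(seq, k)
    # duplex complementation symmetry: counts[m] == counts[reverse(m)]
    for m, v in got.counts.items():
        assert v == got.counts[m[::-1]]


def test_duplex_kmer_totals_for_n_free_sequences(random_dna):
    seq = random_dna(60)
    for k in (1, 2, 3):
        assert count_duplex_kmers(seq, k).total() == 2 * (60 - k + 1)


@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("AAAA", 3, {"WWW": 4}),
        ("AATT", 2, {"WW": 6, "WS": 0, "SW": 0, "SS": 0}),
    ],
)
def test_duplex_kmer_examples(seq, k, expected):
    counts = count_duplex_kmers(seq, k).counts
    for m, v in expected.items():
        assert counts[m] == v


def test_short_sequence_yields_empty_counts():
    got = count_duplex_kmers("AC", 3)
    assert got.total() == 0 and got.valid_positions == 0


def test_k_out_of_range_rejected():
    with pytest.raises(InvalidParameterError):
        count_duplex_kmers("ACGT", 4)


# ---------------------------------------------------------------------------
# index vectors
# ---------------------------------------------------------------------------

def test_index_vector_u_examples():
    u = index_vector_u(count_duplex_kmers("AAAA", 2))
    assert (u.u_ww, u.u_ss) == pytest.approx((1.0, 0.0))
    u = index_vector_u(count_duplex_kmers("GGGG", 2))
    assert (u.u_ww, u.u_ss) == pytest.approx((0.0, 1.0))
    # W/S image WWSS: duplex dimers {WW:2, WS:1, SW:1, SS:2}
    u = index_vector_u(count_duplex_kmers("ATGC", 2))
    assert (u.u_ww, u.u_ss) == pytest.approx((2 / 6, 2 / 6))


def test_index_vector_u_degenerate_input():
    u = index_vector_u(count_duplex_kmers("NN", 2))
    assert (u.u_ww, u.u_ss) == (0.0, 0.0)


def test_index_vector_v_examples():
    v = index_vector_v(count_duplex_kmers("AAAA", 1), count_duplex_kmers("AAAA", 3))
    assert v.v_www == pytest.approx(4 / 8)
    v = index_vector_v(count_duplex_kmers("GGG", 1), count_duplex_kmers("GGG", 3))
    assert v.v_sss == pytest.approx(2 / 6)
    v = index_vector_v(count_duplex_kmers("CCC", 1), count_duplex_kmers("CCC", 3))
    assert v.v_www == 0.0  # N_W == 0 -> defined 0


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def test_tsallis_entropy_closed_forms():
    assert tsallis_entropy((1.0, 0.0), 2.0) == pytest.approx(0.0)
    assert tsallis_entropy((0.5, 0.5), 2.0) == pytest.approx(0.5)
    assert tsallis_entropy((0.5, 0.5), 1 + 1e-6) == pytest.approx(math.log(2), abs=1e-4)


def test_tsallis_entropy_rejects_bad_input():
    with pytest.raises(InvalidParameterError):
        tsallis_entropy((0.5, 0.5), 1.0)
    with pytest.raises(InvalidSequenceError):
        tsallis_entropy((0.5, 0.4), 2.0)


def test_geometric_component_closed_form(params):
    assert geometric_entropy_component(0.5, params, 147, 1) == pytest.approx(0.5)
    assert geometric_entropy_component(0.0, params, 147, 3) == 0.0
    assert geometric_entropy_component(1.0, params, 147, 3) == 0.0


@pytest.mark.parametrize("q", [0.5, 1.5, 2.0, 3.0])
def test_geometric_component_symmetric_and_nonnegative(q):
    p_grid = np.linspace(0, 1, 21)
    params = EntropyParams(q=q)
    vals = [geometric_entropy_component(p, params, 120, 3) for p in p_grid]
    assert all(v >= 0 for v in vals)
    assert vals == pytest.approx(vals[::-1])


def test_geometric_component_length_validation(params):
    with pytest.raises(InvalidSequenceError):
        geometric_entropy_component(0.5, params, 2, 3)


def test_conservation_coefficient_full_map():
    expected = {
        "WWW": 1, "SSS": 1, "WSW": 1, "SWS": 1,
        "WWS": 2, "SWW": 2, "WSS": 2, "SSW": 2,
    }
    for m, c in expected.items():
        assert conservation_coefficient(m) == c
    with pytest.raises(InvalidSequenceError):
        conservation_coefficient("WXS")


# ---------------------------------------------------------------------------
# the positioning feature vector
# ---------------------------------------------------------------------------

def test_feature_vector_reverse_complement_invariant(random_dna, params):
    for _ in range(100):
        d = DnaSequence("t", random_dna(147))
        a = positioning_feature_vector(d, params).s
        b = positioning_feature_vector(reverse_complement(d), params).s
        assert np.array_equal(a, b)


def test_feature_vector_structural_symmetry(random_dna, params):
    """S(2)==S(4) and S(6)==S(8) on random 147-mers, including N-bearing."""
    for i in range(200):
        d = random_dna(147, n_frac=0.05 if i % 4 == 0 else 0.0)
        s = positioning_feature_vector(d, params).s
        assert s[1] == s[3] and s[5] == s[7]
        assert np.all(s >= 0)


def test_feature_vector_all_A_boundary(params):
    """With no G/C the S-motif probabilities are degenerate (0 or the
    denominator vanishes) and components 5-8 sit at the boundary value 0."""
    s = positioning_feature_vector("A" * 147, params).s
    assert np.array_equal(s[4:], np.zeros(4))


def test_feature_vector_input_validation(params):
    with pytest.raises(InvalidSequenceError):
        positioning_feature_vector("AC", params)
    with pytest.raises(InvalidSequenceError):
        positioning_feature_vector("N" * 10, params)


def test_window_feature_matrix_matches_per_window_vectors(random_dna, params):
    seq = random_dna(400)
    starts, feats, n_frac = window_feature_matrix(seq, params, window=147, step=1)
    assert starts[0] == 1 and len(starts) == 400 - 147 + 1
    for idx in (0, 57, 130, 253):
        expected = positioning_feature_vector(seq[idx : idx + 147], params).s
        assert feats[idx] == pytest.approx(expected, abs=1e-12)
    assert n_frac == pytest.approx(np.zeros(len(starts)))


def test_window_feature_matrix_handles_N(params):
    seq = "ACGT" * 50 + "N" * 30 + "GGCC" * 30
    starts, feats, n_frac = window_feature_matrix(seq, params, window=147, step=10)
    assert n_frac.max() > 0
    i = int(np.argmax(n_frac))
    expected = positioning_feature_vector(
        seq[starts[i] - 1 : starts[i] - 1 + 147], params
    ).s
    assert feats[i] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# auxiliary statistics
# ---------------------------------------------------------------------------

def _full_scale(default=0.0, **overrides):
    scale = {"".join(d): default for d in product("ACGT", repeat=2)}
    scale.update(overrides)
    return scale


def test_structural_average_examples():
    assert structural_average("ACGTAC", _full_scale(3.2)) == pytest.approx(3.2)
    assert structural_average("AA", _full_scale(AA=1.0, TT=5.0)) == pytest.approx(3.0)
    scale = _full_scale(**{k: float(i) for i, k in enumerate(_full_scale())})
    assert structural_average("AC", scale) == pytest.approx(structural_average("GT", scale))


def test_structural_average_missing_dinucleotide():
    scale = _full_scale(3.0)
    del scale["CG"]
    with pytest.raises(InvalidParameterError, match="CG"):
        structural_average("ACGT", scale)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGT", (0.25, 0.25, 0.25, 0.25)),
        ("AAAN", (1.0, 0.0, 0.0, 0.0)),
        ("GGC", (0.0, 0.0, 2 / 3, 1 / 3)),
    ],
)
def test_nucleotide_frequencies(seq, expected):
    assert nucleotide_frequencies(seq) == pytest.approx(expected)


def test_nucleotide_frequencies_all_N_rejected():
    with pytest.raises(InvalidSequenceError):
        nucleotide_frequencies("NNN")
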