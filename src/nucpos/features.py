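"""Sequence features for nucleosome positioning.

A DNA duplex is reduced to the two-letter W/S alphabet (W = A or T, S = C
or G; complementation is the identity on W/S, so the reverse complement of
a W/S string is its plain reversal).  k-mers (k = 1, 2, 3) are counted over
both strands read 5'->3'.  From the duplex counts two index vectors are
formed -- the dimer frequencies (u_WW, u_SS) and the conditional trimer
frequencies (v_WWW = N_WWW / N_W, v_SSS = N_SSS / N_S) -- and each of the
eight W/S trinucleotides contributes one component of the positioning
feature vector

    S(j) = c_j * E_q( N_mj / N_X ),   j = 1..8,

where m_1..m_8 = (WWW, WWS, WSW, SWW, SSS, SSW, SWS, WSS), N_X is the
duplex count of the majority letter of m_j, c_j is the conservation
coefficient (1 for W/S palindromes, whose strand distribution determines
the complementary strand completely; 2 for the independent pairs), and

    E_q(p) = [standard_length / (L - k + 1)] * (1 - p^q - (1-p)^q) / (q - 1)

is the length-standardised binary Tsallis entropy (entropic index q != 1,
147 bp standard).  Duplex counting makes the vector exactly invariant
under reverse complementation and forces S(2) == S(4) and S(6) == S(8)
(N_WWS == N_SWW and N_SSW == N_WSS on a duplex).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_WS_TABLE = str.maketrans("ATCGN", "WWSSN")

#: canonical component order of the positioning feature vector: the four
#: W-majority trimers (A/T-riched motifs) then the four S-majority ones.
TRIMER_ORDER: Tuple[str, ...] = (
    "WWW", "WWS", "WSW", "SWW", "SSS", "SSW", "SWS", "WSS",
)

DEFAULT_STANDARD_LENGTH = 147


class InvalidSequenceError(ValueError):
    """Raised for sequences outside the {A,C,G,T,N} alphabet or degenerate input."""


class InvalidParameterError(ValueError):
    """Raised for parameter values outside an operation's domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise InvalidSequenceError(
                f"sequence {self.id!r}: invalid character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class WsSequence:
    """W/S reduction of a DNA sequence; N positions are kept as N."""

    symbols: str
    source_length: int


@dataclass(frozen=True)
class DuplexKmerCounts:
    """k-mer counts summed over a strand and its reverse complement.

    ``valid_positions`` is the number of N-free k-windows on one strand;
    the duplex total over all k-mers is twice that.
    """

    k: int
    counts: Dict[str, int]
    valid_positions: int

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class IndexVectorU:
    """Duplex frequencies of the WW and SS dimeric motifs."""

    u_ww: float
    u_ss: float


@dataclass(frozen=True)
class IndexVectorV:
    """Conditional duplex frequencies of the WWW and SSS trimeric motifs."""

    v_www: float
    v_sss: float


@dataclass(frozen=True)
class EntropyParams:
    """Entropic index and length standard of the entropy transform."""

    q: float = 2.0
    standard_length: int = DEFAULT_STANDARD_LENGTH

    def __post_init__(self) -> None:
        if self.q == 1:
            raise InvalidParameterError(
                "entropic index q must differ from 1 (q -> 1 is the Shannon limit)"
            )
        if self.standard_length <= 0:
            raise InvalidParameterError("standard_length must be positive")


@dataclass(frozen=True)
class PositioningFeatureVector:
    """The 8-component positioning feature vector S(1..8) for one duplex."""

    s: np.ndarray
    u: IndexVectorU = field(compare=False, default=None)  # type: ignore[assignment]
    v: IndexVectorV = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.s, dtype=float)
        if arr.shape != (8,):
            raise InvalidParameterError("feature vector must have 8 components")
        object.__setattr__(self, "s", arr)


# ---------------------------------------------------------------------------
# alphabet operations
# ---------------------------------------------------------------------------

def ws_encode(seq: DnaSequence | str) -> WsSequence:
    """Map A,T -> W and C,G -> S position-wise; N passes through."""
    s = seq.seq if isinstance(seq, DnaSequence) else str(seq)
    bad = set(s) - DNA_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise InvalidSequenceError(
            f"invalid character {s[pos]!r} at position {pos + 1}"
        )
    return WsSequence(symbols=s.translate(_WS_TABLE), source_length=len(s))


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    """Watson-Crick reverse complement (N maps to N)."""
    return DnaSequence(id=seq.id, seq=seq.seq.translate(_COMPLEMENT)[::-1])


def _ws_kmer_strand_counts(symbols: str, k: int) -> Tuple[Dict[str, int], int]:
    """N-free k-window counts on one strand of a W/S string."""
    counts = {"".join(m): 0 for m in product("WS", repeat=k)}
    valid = 0
    for i in range(len(symbols) - k + 1):
        mer = symbols[i : i + k]
        if "N" in mer:
            continue
        counts[mer] += 1
        valid += 1
    return counts, valid


def count_duplex_kmers(seq: DnaSequence | str, k: int) -> DuplexKmerCounts:
    """Count W/S k-mers over the strand and its reverse complement.

    On the W/S alphabet the reverse complement is the reversed string, so
    the duplex count of motif m is the strand count of m plus the strand
    count of reverse(m).  Windows containing N are skipped.
    """
    if k not in (1, 2, 3):
        raise InvalidParameterError(f"k must be in {{1,2,3}}, got {k}")
    ws = ws_encode(seq)
    strand, valid = _ws_kmer_strand_counts(ws.symbols, k)
    duplex = {m: strand[m] + strand[m[::-1]] for m in strand}
    return DuplexKmerCounts(k=k, counts=duplex, valid_positions=valid)


# ---------------------------------------------------------------------------
# index vectors
# ---------------------------------------------------------------------------

def index_vector_u(counts2: DuplexKmerCounts) -> IndexVectorU:
    """Frequencies of WW and SS among all duplex dimer positions."""
    if counts2.k != 2:
        raise InvalidParameterError("index_vector_u requires k=2 counts")
    total = counts2.total()
    if total == 0:
        logger.warning("no valid dimer positions; index vector u set to (0, 0)")
        return IndexVectorU(0.0, 0.0)
    return IndexVectorU(counts2.counts["WW"] / total, counts2.counts["SS"] / total)


def index_vector_v(counts1: DuplexKmerCounts, counts3: DuplexKmerCounts) -> IndexVectorV:
    """Relative frequency of WWW (SSS) given an occurrence of W (S).

    A zero denominator (the letter never occurs) yields component 0.
    """
    if counts1.k != 1 or counts3.k != 3:
        raise InvalidParameterError("index_vector_v requires k=1 and k=3 counts")
    n_w, n_s = counts1.counts["W"], counts1.counts["S"]
    v_www = counts3.counts["WWW"] / n_w if n_w else 0.0
    v_sss = counts3.counts["SSS"] / n_s if n_s else 0.0
    return IndexVectorV(v_www, v_sss)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def tsallis_entropy(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Tsallis entropy (1 - sum p_i^q) / (q - 1) of a discrete distribution."""
    if q == 1:
        raise InvalidParameterError(
            "q=1 is the Shannon limit; use q close to 1 or scipy.stats.entropy"
        )
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise InvalidSequenceError("probabilities must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise InvalidSequenceError(f"probabilities sum to {arr.sum()}, not 1")
    arr = np.clip(arr, 0.0, 1.0)
    return float((1.0 - np.sum(arr**q)) / (q - 1.0))


def geometric_entropy_component(
    p: float, params: EntropyParams, length_bp: int, k: int
) -> float:
    """Length-standardised binary Tsallis entropy of the motif probability p.

    The multiplicative coefficient standard_length/(L - k + 1) removes the
    effect of sequence-length differences and is the identity at the
    147-bp standard.
    """
    if length_bp < k:
        raise InvalidSequenceError(
            f"sequence length {length_bp} shorter than k={k}"
        )
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p must be in [0, 1], got {p}")
    coeff = params.standard_length / (length_bp - k + 1)
    return coeff * tsallis_entropy((p, 1.0 - p), params.q)


def conservation_coefficient(trimer: str) -> int:
    """1 for W/S palindromes (duplex-self-determining trimers), else 2.

    On the W/S alphabet complementation is the identity, so the reverse
    complement of a trimer is its reversal; the strand distribution of a
    palindromic trimer fixes its distribution on the other strand.
    """
    if len(trimer) != 3 or set(trimer) - {"W", "S"}:
        raise InvalidSequenceError(f"not a W/S trimer: {trimer!r}")
    return 1 if trimer == trimer[::-1] else 2


_CONSERVATION = {m: conservation_coefficient(m) for m in TRIMER_ORDER}


# ---------------------------------------------------------------------------
# the positioning feature vector
# ---------------------------------------------------------------------------

def _trimer_probabilities(counts1: DuplexKmerCounts, counts3: DuplexKmerCounts) -> np.ndarray:
    """N_mj / N_X for the eight ordered trimers (0 when the letter is absent)."""
    n_w, n_s = counts1.counts["W"], counts1.counts["S"]
    probs = np.empty(8)
    for j, m in enumerate(TRIMER_ORDER):
        denom = n_w if m.count("W") >= 2 else n_s
        probs[j] = counts3.counts[m] / denom if denom else 0.0
    return probs


def positioning_feature_vector(
    seq: DnaSequence | str, params: EntropyParams | None = None
) -> PositioningFeatureVector:
    """Compute S(1..8) for one DNA duplex.

    Components 1-4 describe the A/T-riched (W-majority) trimeric motifs,
    components 5-8 the G/C-riched ones.  Exactly reverse-complement
    invariant; S(2)==S(4) and S(6)==S(8) hold identically.
    """
    params = params or EntropyParams()
    d = seq if isinstance(seq, DnaSequence) else DnaSequence("seq", str(seq))
    if len(d.seq) < 3:
        raise InvalidSequenceError("need at least 3 bp for trimer features")
    if set(d.seq) == {"N"}:
        raise InvalidSequenceError("all-N sequence carries no information")
    c1 = count_duplex_kmers(d, 1)
    c2 = count_duplex_kmers(d, 2)
    c3 = count_duplex_kmers(d, 3)
    probs = _trimer_probabilities(c1, c3)
    s = np.array(
        [
            _CONSERVATION[m]
            * geometric_entropy_component(probs[j], params, d.length, 3)
            for j, m in enumerate(TRIMER_ORDER)
        ]
    )
    return PositioningFeatureVector(
        s=s, u=index_vector_u(c2), v=index_vector_v(c1, c3)
    )


# ---------------------------------------------------------------------------
# vectorised window scanning (same model, cumulative-sum counting)
# ---------------------------------------------------------------------------

_TRIMER_CODE = {m: (("WS".index(m[0]) << 2) | ("WS".index(m[1]) << 1) | "WS".index(m[2]))
                for m in ("".join(t) for t in product("WS", repeat=3))}


def window_feature_matrix(
    seq: DnaSequence | str,
    params: EntropyParams | None = None,
    window: int = 147,
    step: int = 1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """S(1..8) for every length-`window` window of `seq` at stride `step`.

    Returns (starts, features, n_fraction): 1-based window starts, an
    (n_windows, 8) matrix identical to per-window
    :func:`positioning_feature_vector`, and the N fraction of each window.
    Implemented with cumulative sums so chromosome-scale scans stay cheap.
    """
    params = params or EntropyParams()
    s = seq.seq if isinstance(seq, DnaSequence) else str(seq)
    L = len(s)
    if L < window:
        raise InvalidSequenceError(f"sequence length {L} < window {window}")
    ws = ws_encode(s).symbols
    code = np.frombuffer(ws.encode(), dtype=np.uint8)
    a = np.where(code == ord("S"), 1, np.where(code == ord("W"), 0, -1)).astype(np.int64)
    valid = a >= 0

    # monomer cumulative counts
    cum_w = np.concatenate(([0], np.cumsum((a == 0).astype(np.int64))))
    cum_s = np.concatenate(([0], np.cumsum((a == 1).astype(np.int64))))

    # trimer codes at each start position (or -1 if any N inside)
    t_valid = valid[:-2] & valid[1:-1] & valid[2:]
    t_code = (a[:-2] << 2) | (a[1:-1] << 1) | a[2:]
    cums = {}
    for m, c in _TRIMER_CODE.items():
        ind = ((t_code == c) & t_valid).astype(np.int64)
        cums[m] = np.concatenate(([0], np.cumsum(ind)))

    starts0 = np.arange(0, L - window + 1, step)
    # strand trimer counts per window: windows of trimer starts [s, s+window-3]
    def wsum(cum: np.ndarray, width: int) -> np.ndarray:
        return cum[starts0 + width] - cum[starts0]

    strand = {m: wsum(cums[m], window - 2) for m in _TRIMER_CODE}
    n_w = 2 * wsum(cum_w, window)
    n_s = 2 * wsum(cum_s, window)

    coeff = params.standard_length / (window - 3 + 1)
    q = params.q
    feats = np.empty((len(starts0), 8))
    for j, m in enumerate(TRIMER_ORDER):
        duplex = strand[m] + strand[m[::-1]]
        denom = n_w if m.count("W") >= 2 else n_s
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, duplex / np.maximum(denom, 1), 0.0)
        ent = (1.0 - p**q - (1.0 - p) ** q) / (q - 1.0)
        feats[:, j] = _CONSERVATION[m] * coeff * ent

    n_frac = 1.0 - (wsum(cum_w, window) + wsum(cum_s, window)) / window
    return starts0 + 1, feats, n_frac


# ---------------------------------------------------------------------------
# auxiliary per-sequence statistics
# ---------------------------------------------------------------------------

def structural_average(seq: DnaSequence | str, scale: Mapping[str, float]) -> float:
    """Mean duplex value of a dinucleotide structural property.

    Each dinucleotide step contributes the average of the property value
    on the strand and at the corresponding step of the reverse complement.
    The scale must define all 16 dinucleotides; steps containing N are
    skipped.
    """
    s = seq.seq if isinstance(seq, DnaSequence) else str(seq)
    missing = [
        "".join(d) for d in product("ACGT", repeat=2) if "".join(d) not in scale
    ]
    if missing:
        raise InvalidParameterError(f"scale missing dinucleotides: {missing}")
    if len(s) < 2:
        raise InvalidSequenceError("need at least one dinucleotide step")
    vals = []
    for i in range(len(s) - 1):
        di = s[i : i + 2]
        if "N" in di:
            continue
        rc = di.translate(_COMPLEMENT)[::-1]
        vals.append(0.5 * (scale[di] + scale[rc]))
    if not vals:
        raise InvalidSequenceError("no N-free dinucleotide step in sequence")
    return float(np.mean(vals))


def nucleotide_frequencies(seq: DnaSequence | str) -> Tuple[float, float, float, float]:
    """(A, T, G, C) fractions over non-N positions."""
    s = seq.seq if isinstance(seq, DnaSequence) else str(seq)
    n_valid = sum(s.count(b) for b in "ACGT")
    if n_valid == 0:
        raise InvalidSequenceError("sequence has no non-N base")
    return tuple(s.count(b) / n_valid for b in "ATGC")  # type: ignore[return-value]


def feature_table(
    seqs: Iterable[DnaSequence], params: EntropyParams | None = None
) -> pd.DataFrame:
    """Per-sequence feature table: S1..S8, index vectors, base fractions."""
    params = params or EntropyParams()
    rows = []
    for d in seqs:
        fv = positioning_feature_vector(d, params)
        fa, ft, fg, fc = nucleotide_frequencies(d)
        row = {"id": d.id}
        row.update({f"S{j + 1}": fv.s[j] for j in range(8)})
        row.update(
            {
                "u_ww": fv.u.u_ww,
                "u_ss": fv.u.u_ss,
                "v_www": fv.v.v_www,
                "v_sss": fv.v.v_sss,
                "fA": fa,
                "fT": ft,
                "fG": fg,
                "fC": fc,
                "len": d.length,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(
    seqs: Iterable[DnaSequence], params: EntropyParams | None = None
) -> np.ndarray:
    """(n, 8) array of positioning feature vectors."""
    return np.array([positioning_feature_vector(d, params).s for d in seqs])
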