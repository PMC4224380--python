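"""Relative-distance nucleosome occupancy model.

Two training centers are built by featurizing the highest- and
lowest-scoring 50-bp fragments of a scored pool (the geometric centers of
the nucleosome-forming and nucleosome-inhibiting feature clouds).  Every
147-bp window of a genomic sequence is then scored by the relative
distance

    d(x) = ||x - c_neg|| / (||x - c_pos|| + ||x - c_neg||)

which lies in [0,1], equals 1 at the positive center, 0 at the negative
one and 0.5 on the perpendicular bisector (the random level).  The raw
track is range-normalised per scanned sequence and converted to a
per-basepair occupancy: P(i) is the mean normalised score of every window
covering basepair i (window starts i-146..i, clipped at the sequence
edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .features import (
    DnaSequence,
    EntropyParams,
    InvalidParameterError,
    InvalidSequenceError,
    window_feature_matrix,
)

logger = logging.getLogger(__name__)

NUCLEOSOME_BP = 147
#: windows with more than this fraction of N get the neutral score 0.5
MAX_N_FRACTION = 0.5


def _native_params(params: EntropyParams, length: int, k: int = 3) -> EntropyParams:
    """Entropy parameters with a unit length coefficient for `length`.

    Distance geometry needs the training fragments (one fixed length) and
    the scan windows (another fixed length) expressed with a common
    coefficient; the motif probabilities are already length-free, so both
    point sets are featurized at their native scale (coefficient exactly
    1) and only the entropic index is carried over.
    """
    return EntropyParams(q=params.q, standard_length=length - k + 1)


@dataclass(frozen=True)
class TrainingCenters:
    """Geometric centers of the positive/negative training feature clouds."""

    c_pos: np.ndarray
    c_neg: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        cp = np.asarray(self.c_pos, dtype=float)
        cn = np.asarray(self.c_neg, dtype=float)
        if cp.shape != (8,) or cn.shape != (8,):
            raise InvalidParameterError("centers must be 8-component vectors")
        if np.array_equal(cp, cn):
            raise InvalidParameterError(
                "positive and negative centers coincide; the model is degenerate"
            )
        object.__setattr__(self, "c_pos", cp)
        object.__setattr__(self, "c_neg", cn)


@dataclass
class WindowScoreTrack:
    """Raw and range-normalised window scores along one scanned sequence."""

    start_coords: np.ndarray  # 1-based window starts
    raw: np.ndarray
    normalized: np.ndarray
    window: int = NUCLEOSOME_BP
    n_flagged: int = 0  # windows neutralised for excess N


@dataclass
class OccupancyProfile:
    """Per-basepair occupancy probabilities in [0, 1]."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)

    def __len__(self) -> int:
        return len(self.p)


def geometric_center(vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Component-wise arithmetic mean of a non-empty set of vectors."""
    arr = np.asarray(vectors, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("cannot take the center of an empty set")
    return arr.mean(axis=0)


def _featurize_native(seq: str, params: EntropyParams) -> np.ndarray:
    """Positioning feature vector at the sequence's native entropy scale."""
    from .features import positioning_feature_vector

    return positioning_feature_vector(
        DnaSequence("frag", seq), _native_params(params, len(seq))
    ).s


def build_training_centers(
    scored_fragments: Sequence[Tuple[str, float]],
    n_top: int,
    params: EntropyParams | None = None,
) -> TrainingCenters:
    """Centers from the n_top highest- and lowest-scoring fragments.

    `scored_fragments` is a sequence of (sequence, score); ties are broken
    by input order (stable sort).
    """
    if n_top < 1:
        raise InvalidParameterError("n_top must be positive")
    if len(scored_fragments) < 2 * n_top:
        raise InvalidParameterError(
            f"need at least {2 * n_top} fragments, got {len(scored_fragments)}"
        )
    scores = np.array([s for _, s in scored_fragments], dtype=float)
    asc = np.argsort(scores, kind="stable")
    desc = np.argsort(-scores, kind="stable")
    top = [scored_fragments[i][0] for i in desc[:n_top]]
    bottom = [scored_fragments[i][0] for i in asc[:n_top]]
    params = params or EntropyParams()
    pos = np.array([_featurize_native(s, params) for s in top])
    neg = np.array([_featurize_native(s, params) for s in bottom])
    return TrainingCenters(
        c_pos=geometric_center(pos),
        c_neg=geometric_center(neg),
        n_pos=n_top,
        n_neg=n_top,
    )


def relative_distance(x: np.ndarray, centers: TrainingCenters) -> float:
    """Two-center relative distance in [0, 1]; larger = more nucleosome-like."""
    x = np.asarray(x, dtype=float)
    d_pos = float(np.linalg.norm(x - centers.c_pos))
    d_neg = float(np.linalg.norm(x - centers.c_neg))
    return d_neg / (d_pos + d_neg)


def range_normalize(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant track maps to 0.5 everywhere."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("constant score track; normalised to the neutral 0.5")
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def scan_window_scores(
    genome_seq: DnaSequence,
    centers: TrainingCenters,
    params: EntropyParams | None = None,
    window: int = NUCLEOSOME_BP,
    step: int = 1,
) -> WindowScoreTrack:
    """Relative-distance score for every window, then range normalisation.

    Windows with more than 50% N are assigned the neutral raw score 0.5.
    """
    params = params or EntropyParams()
    if genome_seq.length < window:
        raise InvalidSequenceError(
            f"sequence {genome_seq.id!r} shorter than the {window}-bp window"
        )
    starts, feats, n_frac = window_feature_matrix(
        genome_seq, _native_params(params, window), window, step
    )
    d_pos = np.linalg.norm(feats - centers.c_pos, axis=1)
    d_neg = np.linalg.norm(feats - centers.c_neg, axis=1)
    with np.errstate(invalid="ignore"):
        raw = d_neg / (d_pos + d_neg)
    raw = np.where(d_pos + d_neg == 0, 0.5, raw)
    flagged = n_frac > MAX_N_FRACTION
    raw[flagged] = 0.5
    if flagged.any():
        logger.warning("%d windows neutralised for >50%% N content", int(flagged.sum()))
    return WindowScoreTrack(
        start_coords=starts,
        raw=raw,
        normalized=range_normalize(raw),
        window=window,
        n_flagged=int(flagged.sum()),
    )


def per_bp_occupancy(
    track: WindowScoreTrack, seq_length: int, window: int | None = None
) -> OccupancyProfile:
    """P(i) = mean normalised score of all windows covering basepair i.

    A window starting at s (1-based) covers basepairs s..s+window-1, so
    the covering starts for basepair i are max(1, i-window+1)..min(n_win,
    i); edge basepairs average over the fewer available windows.  Requires
    a 1-bp-step track.
    """
    window = window or track.window
    n_win = seq_length - window + 1
    if len(track.normalized) != n_win:
        raise InvalidParameterError(
            f"track has {len(track.normalized)} windows, expected {n_win} "
            f"for length {seq_length} (1-bp step)"
        )
    cum = np.concatenate(([0.0], np.cumsum(track.normalized)))
    i = np.arange(1, seq_length + 1)
    lo = np.maximum(1, i - window + 1)
    hi = np.minimum(n_win, i)
    p = (cum[hi] - cum[lo - 1]) / (hi - lo + 1)
    return OccupancyProfile(p=p)


def occupancy_profile(
    genome_seq: DnaSequence,
    centers: TrainingCenters,
    params: EntropyParams | None = None,
    window: int = NUCLEOSOME_BP,
) -> OccupancyProfile:
    """Convenience: scan at 1-bp step and average into a per-bp profile."""
    track = scan_window_scores(genome_seq, centers, params, window=window, step=1)
    return per_bp_occupancy(track, genome_seq.length, window)
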