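"""Two-step peak filtration turning an occupancy profile into isolated
nucleosome calls.

Candidate peaks are profile positions that are the (leftmost) maximum of
their centered 147-bp neighbourhood, discovered by scanning 147-bp
windows at a 10-bp stride.  Filtration then (1) enforces a minimum
peak-to-peak spacing of 147 bp -- of any two closer peaks the smaller is
removed -- and (2) drops "dummy peaks" below the 0.5 cutoff, the random
level of the relative-distance score.  Each surviving peak becomes a
147-bp call spanning center +/- 73; calls that would extend past the
sequence ends are dropped so every call is exactly one nucleosome
footprint, and the spacing filter guarantees the calls never overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .features import InvalidParameterError
from .occupancy import NUCLEOSOME_BP, OccupancyProfile

logger = logging.getLogger(__name__)

HALF_NUCLEOSOME = NUCLEOSOME_BP // 2  # 73


@dataclass(frozen=True, order=True)
class Peak:
    """A local occupancy maximum: 1-based position and profile value."""

    position: int
    value: float


@dataclass(frozen=True)
class NucleosomeCall:
    """One isolated nucleosome: 147-bp span centered on a peak."""

    center: int
    score: float

    @property
    def start(self) -> int:
        return self.center - HALF_NUCLEOSOME

    @property
    def end(self) -> int:
        return self.center + HALF_NUCLEOSOME


def _neighbourhood_peak(p: np.ndarray, pos0: int, half: int) -> bool:
    """Is 0-based index pos0 the leftmost maximum of its centered
    neighbourhood, with the neighbourhood not constant?"""
    lo = max(0, pos0 - half)
    hi = min(len(p), pos0 + half + 1)
    neigh = p[lo:hi]
    v = p[pos0]
    if v < neigh.max() or neigh.min() == neigh.max():
        return False
    # leftmost attaining the maximum within the neighbourhood
    return int(np.argmax(neigh)) == pos0 - lo


def detect_candidate_peaks(
    profile: OccupancyProfile | np.ndarray,
    window: int = NUCLEOSOME_BP,
    step: int = 10,
) -> List[Peak]:
    """Scan 147-bp windows at a 10-bp stride and keep positions that are
    the leftmost maximum of their centered 147-bp neighbourhood.

    Flat stretches yield no peaks (the neighbourhood must not be
    constant); on a plateau the leftmost index is the peak position.
    """
    p = profile.p if isinstance(profile, OccupancyProfile) else np.asarray(profile, float)
    n = len(p)
    if n < window:
        raise InvalidParameterError(f"profile length {n} < window {window}")
    half = window // 2
    found = {}
    for s in range(0, n - window + 1, step):
        w = p[s : s + window]
        pos0 = s + int(np.argmax(w))
        if pos0 in found:
            continue
        if _neighbourhood_peak(p, pos0, half):
            found[pos0] = p[pos0]
    return [Peak(position=pos0 + 1, value=float(v)) for pos0, v in sorted(found.items())]


def enforce_min_spacing(
    peaks: Sequence[Peak], min_dist: int = NUCLEOSOME_BP
) -> List[Peak]:
    """Remove the smaller of any two peaks closer than min_dist.

    Greedy by descending value (ties: leftmost first): a peak is kept iff
    it lies at least min_dist from every already-kept peak.  Exactly
    min_dist apart is allowed.  Idempotent; output sorted by position.
    """
    order = sorted(peaks, key=lambda pk: (-pk.value, pk.position))
    kept: List[Peak] = []
    for pk in order:
        if all(abs(pk.position - other.position) >= min_dist for other in kept):
            kept.append(pk)
    return sorted(kept, key=lambda pk: pk.position)


def apply_threshold(peaks: Sequence[Peak], cutoff: float = 0.5) -> List[Peak]:
    """Drop dummy peaks with value below the cutoff (boundary kept)."""
    return [pk for pk in peaks if pk.value >= cutoff]


def peaks_to_nucleosomes(
    peaks: Sequence[Peak], profile_length: int
) -> List[NucleosomeCall]:
    """center +/- 73 spans; calls extending past the sequence are dropped."""
    calls = []
    for pk in peaks:
        call = NucleosomeCall(center=pk.position, score=pk.value)
        if call.start < 1 or call.end > profile_length:
            logger.warning(
                "dropping peak at %d: %d-bp span exceeds sequence bounds",
                pk.position,
                NUCLEOSOME_BP,
            )
            continue
        calls.append(call)
    return calls


def call_nucleosomes(
    profile: OccupancyProfile,
    cutoff: float = 0.5,
    min_dist: int = NUCLEOSOME_BP,
    window: int = NUCLEOSOME_BP,
    step: int = 10,
) -> List[NucleosomeCall]:
    """Full peak-detection pipeline: detect, space, threshold, call."""
    peaks = detect_candidate_peaks(profile, window=window, step=step)
    peaks = enforce_min_spacing(peaks, min_dist=min_dist)
    peaks = apply_threshold(peaks, cutoff=cutoff)
    return peaks_to_nucleosomes(peaks, len(profile))
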