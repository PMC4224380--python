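"""Seeded synthetic inputs with the statistical structure the method
assumes.

Nucleosome-like sequences are 147 bp, G+C-elevated, and carry the ~10-bp
WW/SS dinucleotide periodicity of nucleosomal DNA (a WW dinucleotide is
planted at every period multiple and an SS dinucleotide half a period
later, each with probability `periodic_boost`; the background G+C is
solved so the sequence-wide expectation equals `nuc_gc` exactly).
Linker-like sequences are A/T-rich, aperiodic and of variable length,
mimicking the nucleosome-free AT-rich intergenic regions of yeast.  Toy
genomes alternate linkers with planted 147-bp nucleosomes at recorded
centers, and scored 50-bp fragment pools emulate microarray-scored
fragments with high (nucleosome-forming) and low (nucleosome-inhibiting)
tails.

All generators are bit-reproducible: a single global seed derives an
independent substream per generator, so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .features import DnaSequence, InvalidParameterError
from .occupancy import NUCLEOSOME_BP
from .peaks import HALF_NUCLEOSOME, NucleosomeCall

_STREAMS = {"nucleosomal": 0, "linker": 1, "genome": 2, "fragments": 3}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions; defaults are the study conditions of the
    desk-scale benchmark."""

    seed: int
    n_nuc: int = 200
    n_link: int = 200
    nuc_gc: float = 0.55
    link_gc: float = 0.30
    period: int = 10
    periodic_boost: float = 0.8
    link_len_range: Tuple[int, int] = (100, 200)
    genome_n_nucleosomes: int = 20
    genome_linker_len_range: Tuple[int, int] = (30, 100)

    def __post_init__(self) -> None:
        for name, frac in (("nuc_gc", self.nuc_gc), ("link_gc", self.link_gc)):
            if not 0.0 < frac < 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1)")
        for name, rng in (
            ("link_len_range", self.link_len_range),
            ("genome_linker_len_range", self.genome_linker_len_range),
        ):
            if rng[0] > rng[1] or rng[0] < 1:
                raise InvalidParameterError(f"{name} must be an ordered positive range")
        if not 0.0 <= self.periodic_boost <= 1.0:
            raise InvalidParameterError("periodic_boost must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass(frozen=True)
class ToyGenome:
    """A synthetic sequence with planted, non-overlapping nucleosomes."""

    seq: DnaSequence
    planted_centers: List[int]
    planted_calls: List[NucleosomeCall]


def _draw_bases(rng: np.random.Generator, ws: np.ndarray) -> str:
    """Resolve a W/S pattern (0=W, 1=S) into concrete bases."""
    w_choice = rng.integers(0, 2, size=len(ws))
    bases = np.where(
        ws == 0,
        np.where(w_choice == 0, ord("A"), ord("T")),
        np.where(w_choice == 0, ord("C"), ord("G")),
    ).astype(np.uint8)
    return bases.tobytes().decode()


def _periodic_ws_pattern(
    rng: np.random.Generator, length: int, gc: float, period: int, boost: float
) -> np.ndarray:
    """W/S pattern with WW planted at period multiples and SS half a
    period later; background G+C solved so E[G+C] == gc exactly."""
    ww_sites = [s for s in range(0, length, period) if s + 1 < length]
    ss_sites = [s for s in range(period // 2, length, period) if s + 1 < length]
    n_sites = len(ww_sites) + len(ss_sites)
    denom = length - 2 * boost * n_sites
    g_bg = (length * gc - 2 * boost * len(ss_sites)) / denom
    if not 0.0 < g_bg < 1.0:
        raise InvalidParameterError(
            f"periodic planting incompatible with gc={gc}: background {g_bg:.3f}"
        )
    ws = (rng.random(length) < g_bg).astype(np.int8)  # 1 = S
    for s in ww_sites:
        if rng.random() < boost:
            ws[s : s + 2] = 0
    for s in ss_sites:
        if rng.random() < boost:
            ws[s : s + 2] = 1
    return ws


def gen_nucleosomal_like(
    spec: SyntheticSpec, length: int = NUCLEOSOME_BP, rng: Optional[np.random.Generator] = None
) -> List[DnaSequence]:
    """n_nuc G+C-elevated, 10-bp-periodic sequences of fixed length."""
    rng = rng or spec.rng("nucleosomal")
    out = []
    for i in range(spec.n_nuc):
        ws = _periodic_ws_pattern(
            rng, length, spec.nuc_gc, spec.period, spec.periodic_boost
        )
        out.append(DnaSequence(f"nuc_{i + 1:04d}", _draw_bases(rng, ws)))
    return out


def gen_linker_like(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> List[DnaSequence]:
    """n_link A/T-rich aperiodic sequences, lengths uniform in link_len_range."""
    rng = rng or spec.rng("linker")
    lo, hi = spec.link_len_range
    out = []
    for i in range(spec.n_link):
        length = int(rng.integers(lo, hi + 1))
        ws = (rng.random(length) < spec.link_gc).astype(np.int8)
        out.append(DnaSequence(f"link_{i + 1:04d}", _draw_bases(rng, ws)))
    return out


def _one_nucleosomal(spec: SyntheticSpec, rng: np.random.Generator, length: int) -> str:
    ws = _periodic_ws_pattern(rng, length, spec.nuc_gc, spec.period, spec.periodic_boost)
    return _draw_bases(rng, ws)


def _one_linker(spec: SyntheticSpec, rng: np.random.Generator, length: int) -> str:
    ws = (rng.random(length) < spec.link_gc).astype(np.int8)
    return _draw_bases(rng, ws)


def gen_toy_genome(
    spec: SyntheticSpec, total_length: Optional[int] = None
) -> ToyGenome:
    """Alternate linker and nucleosome segments; record the planted calls.

    Linker lengths are uniform in genome_linker_len_range; when
    total_length exceeds the resulting size, the surplus is spread
    uniformly over the linkers so the planted nucleosomes span the whole
    sequence.
    """
    rng = spec.rng("genome")
    n = spec.genome_n_nucleosomes
    lo, hi = spec.genome_linker_len_range
    linker_lens = [int(rng.integers(lo, hi + 1)) for _ in range(n + 1)]
    base_total = sum(linker_lens) + n * NUCLEOSOME_BP
    if total_length is not None:
        if total_length < base_total:
            raise InvalidParameterError(
                f"total_length {total_length} < minimal layout {base_total}"
            )
        extra = total_length - base_total
        add, rem = divmod(extra, n + 1)
        linker_lens = [l + add for l in linker_lens]
        linker_lens[-1] += rem

    parts, centers, calls = [], [], []
    pos = 0  # 0-based running length
    for i in range(n):
        parts.append(_one_linker(spec, rng, linker_lens[i]))
        pos += linker_lens[i]
        parts.append(_one_nucleosomal(spec, rng, NUCLEOSOME_BP))
        start = pos + 1  # 1-based nucleosome start
        center = start + HALF_NUCLEOSOME
        centers.append(center)
        calls.append(NucleosomeCall(center=center, score=1.0))
        pos += NUCLEOSOME_BP
    parts.append(_one_linker(spec, rng, linker_lens[n]))
    seq = DnaSequence("toy_genome", "".join(parts))
    return ToyGenome(seq=seq, planted_centers=centers, planted_calls=calls)


@dataclass(frozen=True)
class ScoredFragment:
    id: str
    seq: str
    score: float


def gen_scored_fragments(
    spec: SyntheticSpec,
    n_fragments: int = 4000,
    fragment_length: int = 50,
    noise_sd: float = 0.3,
) -> List[ScoredFragment]:
    """50-bp fragments from the two compositional regimes with scores =
    regime mean (+1 nucleosome-forming / -1 inhibiting) + Gaussian noise,
    presented in shuffled order."""
    if n_fragments % 2:
        raise InvalidParameterError("n_fragments must be even")
    rng = spec.rng("fragments")
    half = n_fragments // 2
    frags = []
    for i in range(half):
        seq = _one_nucleosomal(spec, rng, fragment_length)
        frags.append(("pos", seq, 1.0 + noise_sd * rng.standard_normal()))
    for i in range(half):
        seq = _one_linker(spec, rng, fragment_length)
        frags.append(("neg", seq, -1.0 + noise_sd * rng.standard_normal()))
    order = rng.permutation(n_fragments)
    return [
        ScoredFragment(f"frag_{k + 1:05d}_{frags[j][0]}", frags[j][1], float(frags[j][2]))
        for k, j in enumerate(order)
    ]
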