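"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based inclusive; BED output is 0-based
half-open (a call [927, 1073] emits start 926, end 1073).  Profiles are
written as fixedStep wiggle (step 1, 6 decimals), fragments and feature
tables as TSV, training centers and reports as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import DnaSequence, InvalidSequenceError
from .occupancy import OccupancyProfile, TrainingCenters
from .peaks import NucleosomeCall
from .synthetic import ScoredFragment

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> List[DnaSequence]:
    """Read a (multi-record) FASTA file; sequences are uppercased and IDs
    taken from the header up to the first whitespace."""
    records = [
        DnaSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(seqs: Sequence[DnaSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for d in seqs:
            fh.write(f">{d.id}\n")
            for i in range(0, len(d.seq), width):
                fh.write(d.seq[i : i + width] + "\n")


def write_bed(
    calls: Sequence[NucleosomeCall], chrom: str, path: str | Path
) -> None:
    """BED6: 0-based half-open, name nuc_k, score = peak value x1000."""
    with open(path, "w") as fh:
        for k, c in enumerate(calls, start=1):
            fh.write(
                f"{chrom}\t{c.start - 1}\t{c.end}\tnuc_{k}\t"
                f"{round(c.score * 1000)}\t.\n"
            )


def read_bed(path: str | Path) -> Tuple[str, List[NucleosomeCall]]:
    """Read BED calls back to 1-based inclusive NucleosomeCall objects."""
    chrom = ""
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            chrom = parts[0]
            start0, end = int(parts[1]), int(parts[2])
            score = float(parts[4]) / 1000 if len(parts) > 4 else 0.0
            start1 = start0 + 1
            center = (start1 + end) // 2
            calls.append(NucleosomeCall(center=center, score=score))
    return chrom, calls


def write_wiggle(profile: OccupancyProfile, chrom: str, path: str | Path) -> None:
    """fixedStep wiggle, step 1, one 6-decimal value per line."""
    if len(profile) == 0:
        raise InvalidSequenceError("cannot write an empty profile")
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
        fh.writelines(f"{v:.6f}\n" for v in profile.p)


def read_wiggle(path: str | Path) -> Tuple[str, OccupancyProfile]:
    chrom = ""
    values: List[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields.get("chrom", "")
            elif line:
                values.append(float(line))
    return chrom, OccupancyProfile(p=np.array(values))


def write_fragments_tsv(frags: Sequence[ScoredFragment], path: str | Path) -> None:
    pd.DataFrame(
        {"id": [f.id for f in frags], "sequence": [f.seq for f in frags],
         "score": [f.score for f in frags]}
    ).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> List[ScoredFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    return [
        ScoredFragment(str(r.id), str(r.sequence), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_centers_json(centers: TrainingCenters, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "c_pos": centers.c_pos.tolist(),
                "c_neg": centers.c_neg.tolist(),
                "n_pos": centers.n_pos,
                "n_neg": centers.n_neg,
            },
            fh,
            indent=2,
        )


def read_centers_json(path: str | Path) -> TrainingCenters:
    with open(path) as fh:
        d = json.load(fh)
    return TrainingCenters(
        c_pos=np.array(d["c_pos"]),
        c_neg=np.array(d["c_neg"]),
        n_pos=int(d["n_pos"]),
        n_neg=int(d["n_neg"]),
    )


def write_report_json(report: Dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
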