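"""Consecutive-runs detection of HRR and ROH segments.

The consecutive-runs method scans each chromosome left to right without a
sliding window.  A run extends over consecutive markers whose call matches
the target state (heterozygous for HRR; either homozygote for ROH),
tolerating up to ``max_missing`` missing calls and ``max_opposite``
opposite-state calls in its interior.  A run breaks when either tolerance
would be exceeded or when the gap to the next marker exceeds
``max_gap_bp``.  Candidate runs always start and end on a target call;
they are accepted when they contain at least ``min_snps`` target calls and
span at least ``min_length_bp``.  Accepted runs of one individual on one
chromosome never overlap: the scan is greedy left-to-right, resuming at
the first target call after the previous candidate.

Run length is ``end_bp - start_bp`` (positions of the first and last SNP
of the run), matching the coordinate arithmetic of the reported island
tables.  Two accepted runs separated by a single disallowed call remain
separate; no post-merging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hrrscan.genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypeDataset


@dataclass(frozen=True)
class RunParams:
    """Parameters of the consecutive-runs scan.

    The two standard HRR parameterizations use 5 SNPs minimum, zero
    opposite (homozygous) calls, a 1 Mb gap limit, and a minimum length of
    either 50 kb or 250 kb; ROH uses 10 SNPs minimum and 250 kb.
    """

    target_state: str  # "heterozygous" | "homozygous"
    min_snps: int
    min_length_bp: int
    max_opposite: int = 0
    max_missing: int = 1
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.target_state not in ("heterozygous", "homozygous"):
            raise ValueError(f"bad target_state {self.target_state!r}")
        if self.min_snps < 1 or self.min_length_bp <= 0:
            raise ValueError("min_snps >= 1 and min_length_bp > 0 required")
        if min(self.max_opposite, self.max_missing, self.max_gap_bp) < 0:
            raise ValueError("tolerances must be non-negative")

    @property
    def run_type(self) -> str:
        return "HRR" if self.target_state == "heterozygous" else "ROH"


HRR_50KB = RunParams("heterozygous", min_snps=5, min_length_bp=50_000)
HRR_250KB = RunParams("heterozygous", min_snps=5, min_length_bp=250_000)
ROH_250KB = RunParams("homozygous", min_snps=10, min_length_bp=250_000)


@dataclass(frozen=True)
class RunSegment:
    """One detected run in one individual (1-based inclusive SNP positions)."""

    individual_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    run_type: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _state_classes(calls: np.ndarray, target_state: str):
    """Boolean (target, opposite, missing) masks for a 1-D call vector."""
    missing = calls == MISSING
    if target_state == "heterozygous":
        target = calls == HET
    else:
        target = (calls == HOM_A) | (calls == HOM_B)
    opposite = ~target & ~missing
    return target, opposite, missing


def _candidate_runs(
    target: np.ndarray,
    opposite: np.ndarray,
    positions: np.ndarray,
    params: RunParams,
) -> list[tuple[int, int, int]]:
    """Greedy left-to-right candidates as (start_idx, end_idx, n_target)."""
    n = len(positions)
    out = []
    i = 0
    while i < n:
        if not target[i]:
            i += 1
            continue
        n_miss = n_opp = 0
        last_target = i
        n_target = 1
        k = i + 1
        while k < n:
            if positions[k] - positions[k - 1] > params.max_gap_bp:
                break
            if target[k]:
                last_target = k
                n_target += 1
            elif opposite[k]:
                n_opp += 1
                if n_opp > params.max_opposite:
                    break
            else:
                n_miss += 1
                if n_miss > params.max_missing:
                    break
            k += 1
        out.append((i, last_target, n_target))
        i = last_target + 1
    return out


def detect_runs(
    dataset: GenotypeDataset, individual_id: str, params: RunParams
) -> list[RunSegment]:
    """Detect accepted runs of one individual, chromosome by chromosome."""
    row = dataset.index_of_individual(individual_id)
    return _detect_runs_row(dataset, row, individual_id, params)


def _detect_runs_row(
    dataset: GenotypeDataset, row: int, individual_id: str, params: RunParams
) -> list[RunSegment]:
    segments: list[RunSegment] = []
    chroms = dataset.markers["chromosome"].to_numpy()
    all_pos = dataset.markers["position_bp"].to_numpy()
    calls = dataset.calls[row]
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        positions = all_pos[sel]
        if np.any(np.diff(positions) <= 0):
            raise ValueError(f"marker map unsorted on chromosome {chrom}")
        target, opposite, _ = _state_classes(calls[sel], params.target_state)
        for start, end, n_target in _candidate_runs(
            target, opposite, positions, params
        ):
            length = int(positions[end] - positions[start])
            if n_target >= params.min_snps and length >= params.min_length_bp:
                segments.append(
                    RunSegment(
                        individual_id=individual_id,
                        chromosome=int(chrom),
                        start_bp=int(positions[start]),
                        end_bp=int(positions[end]),
                        n_snps=n_target,
                        run_type=params.run_type,
                    )
                )
    return segments


def detect_all_runs(
    dataset: GenotypeDataset, params: RunParams
) -> list[RunSegment]:
    """Runs of every individual, ordered (individual, chromosome, start)."""
    out: list[RunSegment] = []
    for row, individual_id in enumerate(dataset.individuals["individual_id"]):
        out.extend(_detect_runs_row(dataset, row, individual_id, params))
    return out


def total_run_length(runs: Iterable[RunSegment], individual_id: str) -> int:
    """Sum of run lengths (bp) of one individual; 0 when it has none."""
    return sum(r.length_bp for r in runs if r.individual_id == individual_id)


def runs_to_frame(
    runs: Sequence[RunSegment], herd_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate runs (detectRUNS-compatible columns) for TSV export."""
    rows = [
        {
            "individual": r.individual_id,
            "herd": (herd_of or {}).get(r.individual_id, ""),
            "chrom": r.chromosome,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "n_snps": r.n_snps,
            "length_bp": r.length_bp,
            "type": r.run_type,
        }
        for r in runs
    ]
    return pd.DataFrame(
        rows,
        columns=["individual", "herd", "chrom", "start_bp", "end_bp",
                 "n_snps", "length_bp", "type"],
    )
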