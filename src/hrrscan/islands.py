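"""Per-SNP run incidence and island calling (HRRIs / ROH islands).

An island is a maximal stretch of consecutive markers whose run incidence
(fraction of a group's individuals covered by a run at the marker) stays at
or above a calling threshold.  Island boundaries are member-SNP positions,
and island support is the peak incidence inside the island.  A top-quantile
calling mode (threshold = a quantile of the incidence distribution, e.g.
0.999) is available as an alternative criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from hrrscan.genotype_io import GenotypeDataset
from hrrscan.runs import RunSegment


@dataclass
class IncidenceTrack:
    """Per-marker covered fraction for one group of individuals."""

    values: np.ndarray  # aligned to dataset.markers, each in [0, 1]
    chromosomes: np.ndarray
    positions: np.ndarray
    group_id: str
    run_type: str
    group_size: int


@dataclass(frozen=True)
class Island:
    """A chromosomal interval of elevated run incidence in one group."""

    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    support: float  # peak incidence inside the island
    group_id: str
    run_type: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def coverage_matrix(
    runs: Sequence[RunSegment], dataset: GenotypeDataset
) -> np.ndarray:
    """Boolean individuals x markers matrix: marker lies inside >= 1 run.

    Computed once from the run list; downstream group incidences are row
    means of this matrix, so permutation replicates never re-detect runs.
    """
    chroms = dataset.markers["chromosome"].to_numpy()
    pos = dataset.markers["position_bp"].to_numpy()
    # per-chromosome position arrays and global column offsets
    chrom_slices: dict[int, tuple[int, np.ndarray]] = {}
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        chrom_slices[int(chrom)] = (int(idx[0]), pos[idx])

    row_of = {iid: i for i, iid in
              enumerate(dataset.individuals["individual_id"])}
    cov = np.zeros((dataset.n_individuals, dataset.n_markers), dtype=bool)
    for r in runs:
        offset, cpos = chrom_slices[r.chromosome]
        lo = int(np.searchsorted(cpos, r.start_bp, side="left"))
        hi = int(np.searchsorted(cpos, r.end_bp, side="right"))
        cov[row_of[r.individual_id], offset + lo:offset + hi] = True
    return cov


def snp_incidence(
    runs: Sequence[RunSegment],
    dataset: GenotypeDataset,
    group: Sequence[str],
    group_id: str = "",
    run_type: str = "HRR",
) -> IncidenceTrack:
    """Fraction of group members whose runs cover each marker."""
    if len(group) == 0:
        raise ValueError("group of size 0")
    members = set(group)
    group_runs = [r for r in runs if r.individual_id in members]
    cov = coverage_matrix(group_runs, dataset)
    rows = [dataset.index_of_individual(i) for i in group]
    return IncidenceTrack(
        values=cov[rows].mean(axis=0),
        chromosomes=dataset.markers["chromosome"].to_numpy(),
        positions=dataset.markers["position_bp"].to_numpy(),
        group_id=group_id,
        run_type=run_type,
        group_size=len(group),
    )


def call_islands(track: IncidenceTrack, threshold: float) -> list[Island]:
    """Maximal supra-threshold stretches of consecutive markers.

    Islands never span a chromosome boundary and are separated by at least
    one sub-threshold marker.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return _call_islands_values(
        track.values, track.chromosomes, track.positions, threshold,
        track.group_id, track.run_type,
    )


def _call_islands_values(
    values: np.ndarray,
    chromosomes: np.ndarray,
    positions: np.ndarray,
    threshold: float,
    group_id: str,
    run_type: str,
) -> list[Island]:
    above = values >= threshold
    if not above.any():
        return []
    # stretch boundaries: state change or chromosome change
    change = np.empty(len(above), dtype=bool)
    change[0] = True
    change[1:] = (above[1:] != above[:-1]) | (chromosomes[1:] != chromosomes[:-1])
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], len(above))
    islands = []
    for s, e in zip(starts, ends):
        if not above[s]:
            continue
        islands.append(
            Island(
                chromosome=int(chromosomes[s]),
                start_bp=int(positions[s]),
                end_bp=int(positions[e - 1]),
                n_snps=int(e - s),
                support=float(values[s:e].max()),
                group_id=group_id,
                run_type=run_type,
            )
        )
    return islands


def quantile_threshold(track: IncidenceTrack, quantile: float = 0.999) -> float:
    """Top-quantile calling criterion: threshold from the incidence
    distribution itself (e.g. its 0.999 quantile)."""
    return float(np.quantile(track.values, quantile))


def island_length_kb(island: Island) -> float:
    """(end - start) / 1000, rounded half-up to one decimal (kb)."""
    kb = Decimal(island.end_bp - island.start_bp) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap of two 1-based inclusive intervals, in shared positions."""
    return min(a_end, b_end) - max(a_start, b_start) + 1


def match_islands(
    island: Island, candidates: Sequence[Island]
) -> Island | None:
    """The same-chromosome candidate with the largest (>= 1 bp) overlap."""
    best = None
    best_ov = 0
    for cand in candidates:
        if cand.chromosome != island.chromosome:
            continue
        ov = _overlap_bp(island.start_bp, island.end_bp,
                         cand.start_bp, cand.end_bp)
        if ov >= 1 and ov > best_ov:
            best, best_ov = cand, ov
    return best


def islands_to_frame(islands: Sequence[Island]) -> pd.DataFrame:
    """BED-like island table for TSV export."""
    return pd.DataFrame(
        [
            {
                "chrom": i.chromosome,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "n_snps": i.n_snps,
                "support": i.support,
                "group": i.group_id,
                "type": i.run_type,
            }
            for i in islands
        ],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "support",
                 "group", "type"],
    )
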