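"""Chromosome-level and herd-level summaries of detected runs.

Covers the length-class tabulations, the herd mean +/- SE aggregation
convention (arithmetic mean across herds, sample SD / sqrt(n_herds)), the
chromosome saturation rank, the coefficient of extended heterozygosity,
and rank/length correlation diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hrrscan.genotype_io import GenomeBuild
from hrrscan.runs import RunSegment, total_run_length


@dataclass(frozen=True)
class ClassEdges:
    """Half-open run length classes [lo, hi) in Mb; last class open-ended."""

    edges_mb: tuple[float, ...]

    def __post_init__(self) -> None:
        if list(self.edges_mb) != sorted(set(self.edges_mb)):
            raise ValueError("edges must be strictly increasing")

    def labels(self) -> list[str]:
        out = [
            f"{lo:g}-{hi:g}"
            for lo, hi in zip(self.edges_mb, self.edges_mb[1:])
        ]
        out.append(f">{self.edges_mb[-1]:g}")
        return out

    def assign(self, length_bp: int) -> int:
        length_mb = length_bp / 1e6
        if length_mb < self.edges_mb[0]:
            raise ValueError(
                f"run of {length_bp} bp shorter than the first class edge "
                f"({self.edges_mb[0]} Mb); violates the detection minimum"
            )
        return int(np.searchsorted(self.edges_mb, length_mb, side="right")) - 1


#: Length classes for the 50 kb and 250 kb minimum-length scans.
HRR_50KB_CLASSES = ClassEdges((0.05, 0.2, 0.4, 0.8, 1.6))
HRR_250KB_CLASSES = ClassEdges((0.25, 0.4, 0.8, 1.6))


def herd_mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and SE (sample SD / sqrt(n)) across herds.

    With a single value the SE is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def class_counts(
    runs: Iterable[RunSegment],
    edges: ClassEdges,
    herd_of: dict[str, str],
) -> pd.DataFrame:
    """Per-herd run counts per length class, with mean +/- SE columns.

    Rows are length classes, columns the herds (order of first appearance in
    ``herd_of``), plus ``mean``, ``se`` and ``proportion`` of the class means.
    """
    herds = list(dict.fromkeys(herd_of.values()))
    labels = edges.labels()
    counts = pd.DataFrame(0, index=labels, columns=herds, dtype=int)
    for r in runs:
        counts.loc[labels[edges.assign(r.length_bp)],
                   herd_of[r.individual_id]] += 1
    agg = counts.apply(lambda row: herd_mean_se(row.to_numpy()),
                       axis=1, result_type="expand")
    counts["mean"], counts["se"] = agg[0], agg[1]
    if counts["mean"].sum() > 0:
        counts["proportion"] = class_proportions(counts["mean"].to_numpy())
    else:
        counts["proportion"] = np.nan
    return counts


def class_proportions(class_means: Sequence[float]) -> np.ndarray:
    """Each class mean divided by the sum of class means."""
    v = np.asarray(class_means, dtype=float)
    if (v < 0).any():
        raise ValueError("negative class mean")
    total = v.sum()
    if total == 0:
        raise ValueError("all class means are zero")
    return v / total


@dataclass(frozen=True)
class ChromosomeRank:
    """Saturation rank: run share over length share (1 = proportional)."""

    chromosome: int
    n_runs: int
    rank: float
    outlier: bool  # |rank - mean rank| > 2 SD of the rank distribution


def chromosome_rank(
    runs: Iterable[RunSegment], build: GenomeBuild
) -> list[ChromosomeRank]:
    """One rank per autosome: (N_i / T) / (L_i / L_genome)."""
    counts: dict[int, int] = {c: 0 for c in build.lengths_bp}
    total = 0
    for r in runs:
        counts[r.chromosome] = counts.get(r.chromosome, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("zero total runs")
    ranks = {
        c: (counts.get(c, 0) / total) / build.length_share(c)
        for c in build.lengths_bp
    }
    values = np.array(list(ranks.values()))
    mean, sd = values.mean(), values.std(ddof=1)
    return [
        ChromosomeRank(
            chromosome=c,
            n_runs=counts.get(c, 0),
            rank=float(rank),
            outlier=bool(abs(rank - mean) > 2 * sd),
        )
        for c, rank in ranks.items()
    ]


def extended_het_coefficient(
    runs: Iterable[RunSegment], build: GenomeBuild, individual_id: str
) -> float:
    """Total HRR length of one individual over the SNP-covered autosome
    length (the heterozygous analogue of an ROH-based inbreeding
    coefficient)."""
    covered = build.total_covered_bp
    if covered <= 0:
        raise ValueError(
            "zero covered length; call GenomeBuild.with_coverage on the "
            "post-QC map first"
        )
    return total_run_length(runs, individual_id) / covered


def rank_correlations(
    per_chrom_run_share: Sequence[float],
    per_chrom_length_share: Sequence[float],
) -> tuple[float, float, float, float]:
    """Pearson and Spearman correlation (with p) of run share vs length
    share across chromosomes."""
    x = np.asarray(per_chrom_run_share, dtype=float)
    y = np.asarray(per_chrom_length_share, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return (
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue),
    )


def ranks_to_frame(ranks: Sequence[ChromosomeRank]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chromosome, "n_runs": r.n_runs,
             "rank": r.rank, "outlier": r.outlier}
            for r in sorted(ranks, key=lambda r: -r.rank)
        ]
    )
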