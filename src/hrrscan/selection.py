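"""Windowed Tajima's D scan and repeat-element coverage comparison.

Tajima's D contrasts mean pairwise diversity (pi) with the segregating-site
estimator of theta.  Genotypes of N diploid individuals are treated as
n = 2N sequences via per-site allele counts:

    pi      = sum over sites of 2 p (1 - p) * n / (n - 1)
    theta_W = S / a1
    D       = (pi - theta_W) / sqrt(e1 * S + e2 * S * (S - 1))

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2.  The genome is
scanned in non-overlapping 100 kb windows anchored at zero (half-open
[k*w, (k+1)*w)), and per chromosome, windows with D above 3 x SD of the
chromosome's D distribution are flagged as balancing-selection candidates.
No demographic correction is applied.

Repeat-element (LINE/SINE/simple-repeat/LTR) coverage of islands is the
merged element overlap divided by island length; island classes (HRR vs
ROH islands) are compared per element type with a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from hrrscan.genotype_io import HET, HOM_B, MISSING, GenotypeDataset
from hrrscan.islands import Island
from hrrscan.permutation import mwu_exact

ELEMENT_TYPES = ("LINE", "SINE", "simple_repeat", "LTR")


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Standard constants for n sequences (n = 2 x diploid individuals)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(
    window_genotypes: np.ndarray, constants: TajimaConstants
) -> float:
    """Tajima's D of one window of biallelic genotype calls.

    ``window_genotypes`` is individuals x sites in the package's call codes.
    Allele frequency per site is taken over non-missing calls; sites with
    every call missing are ignored.  Returns NaN when no site segregates.
    """
    g = np.atleast_2d(window_genotypes)
    n = constants.n
    present = g != MISSING
    n_alleles = 2 * present.sum(axis=0)
    # dosage of allele B = het count + 2 * hom_b count
    n_b = (np.where(present & (g == HET), 1, 0)
           + 2 * np.where(present & (g == HOM_B), 1, 0)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, n_b / np.maximum(n_alleles, 1), np.nan)
    seg = (p > 0) & (p < 1)
    s = int(np.count_nonzero(seg))
    if s == 0:
        return float("nan")
    pi = float((2.0 * p[seg] * (1.0 - p[seg]) * n / (n - 1)).sum())
    theta_w = s / constants.a1
    var = constants.e1 * s + constants.e2 * s * (s - 1)
    return (pi - theta_w) / np.sqrt(var)


@dataclass(frozen=True)
class TajimaScanConfig:
    window_bp: int = 100_000
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.sd_multiplier <= 0:
            raise ValueError("window_bp and sd_multiplier must be positive")


@dataclass(frozen=True)
class TajimaWindow:
    chromosome: int
    start_bp: int  # half-open [start_bp, start_bp + window_bp)
    end_bp: int
    n_sites: int
    s: int  # segregating sites
    pi: float
    d: float  # NaN when S = 0
    outlier: bool


def scan_tajima(
    dataset: GenotypeDataset,
    group: Sequence[str],
    config: TajimaScanConfig = TajimaScanConfig(),
    chromosomes: Sequence[int] | None = None,
) -> tuple[list[TajimaWindow], pd.DataFrame]:
    """Windowed D scan for a group, with a per-chromosome outlier report.

    Windows tile each chromosome from position zero; only windows holding
    at least one post-QC SNP are emitted.  Per chromosome the report gives
    the SD of the defined D values, the sd_multiplier x SD threshold, the
    number of windows exceeding it, and the maximum D.
    """
    if len(group) < 2:
        raise ValueError("group must have at least 2 individuals")
    rows = [dataset.index_of_individual(i) for i in group]
    consts = tajima_constants(2 * len(group))
    chroms_arr = dataset.markers["chromosome"].to_numpy()
    pos = dataset.markers["position_bp"].to_numpy()
    w = config.window_bp

    windows: list[TajimaWindow] = []
    report_rows = []
    scan_chroms = (
        [int(c) for c in pd.unique(chroms_arr)]
        if chromosomes is None else list(chromosomes)
    )
    for chrom in scan_chroms:
        sel = np.flatnonzero(chroms_arr == chrom)
        if sel.size == 0:
            report_rows.append(
                {"chrom": chrom, "n_windows": 0, "sd": np.nan,
                 "threshold": np.nan, "n_exceeding": 0, "max_d": np.nan}
            )
            continue
        bins = pos[sel] // w
        chrom_windows = []
        for b in np.unique(bins):
            cols = sel[bins == b]
            g = dataset.calls[np.ix_(rows, cols)]
            d = tajima_d(g, consts)
            present = g != MISSING
            n_alleles = 2 * present.sum(axis=0)
            n_b = (np.where(present & (g == HET), 1, 0)
                   + 2 * np.where(present & (g == HOM_B), 1, 0)).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n_alleles > 0, n_b / np.maximum(n_alleles, 1),
                             np.nan)
            seg = (p > 0) & (p < 1)
            s = int(np.count_nonzero(seg))
            n = consts.n
            pi = float((2 * p[seg] * (1 - p[seg]) * n / (n - 1)).sum())
            chrom_windows.append(
                dict(chromosome=chrom, start_bp=int(b * w),
                     end_bp=int((b + 1) * w), n_sites=len(cols), s=s,
                     pi=pi, d=float(d))
            )
        d_vals = np.array([cw["d"] for cw in chrom_windows])
        defined = d_vals[~np.isnan(d_vals)]
        if defined.size >= 2:
            sd = float(defined.std(ddof=1))
            threshold = config.sd_multiplier * sd
        else:
            sd = threshold = float("nan")
        n_exceed = 0
        for cw in chrom_windows:
            out = bool(
                not np.isnan(threshold)
                and not np.isnan(cw["d"])
                and cw["d"] > threshold
            )
            n_exceed += out
            windows.append(TajimaWindow(outlier=out, **cw))
        report_rows.append(
            {
                "chrom": chrom,
                "n_windows": len(chrom_windows),
                "sd": sd,
                "threshold": threshold,
                "n_exceeding": n_exceed,
                "max_d": float(np.nanmax(d_vals)) if defined.size else np.nan,
            }
        )
    return windows, pd.DataFrame(report_rows)


@dataclass(frozen=True)
class ElementCoverageRecord:
    """Merged element coverage of one island, as a fraction of its length."""

    island_id: str
    island_class: str  # "HRR" | "ROH"
    element_type: str
    fraction: float


def read_element_bed(path, element_type: str) -> list[tuple[int, int, int]]:
    """Read element intervals from BED (0-based half-open) as
    (chromosome, start_1based, end_exclusive) on the pipeline's axis."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track")):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0].removeprefix("chr")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: empty interval")
            out.append((int(chrom), start + 1, end + 1))
    return out


def element_fraction(
    island: Island,
    element_intervals: dict[str, Sequence[tuple[int, int, int]]],
    island_id: str | None = None,
) -> list[ElementCoverageRecord]:
    """Per element type: merged island-overlap bp over island length.

    Intervals of one type are merged before intersection, so the result is
    invariant to their order and fragmentation.  All intervals are handled
    half-open on the 1-based bp axis; the island occupies
    [start_bp, end_bp), consistent with length = end - start.
    """
    records = []
    island_iv = (island.start_bp, island.end_bp)
    length = island.end_bp - island.start_bp
    if length <= 0:
        raise ValueError("island of zero length")
    for etype, intervals in element_intervals.items():
        tree = IntervalTree()
        for item in intervals:
            chrom, start, end = item
            if chrom != island.chromosome:
                continue
            if end <= start:
                raise ValueError(f"malformed interval {item}")
            tree.addi(start, end)
        tree.merge_overlaps()
        overlap = 0
        for iv in tree.overlap(*island_iv):
            overlap += min(iv.end, island_iv[1]) - max(iv.begin, island_iv[0])
        records.append(
            ElementCoverageRecord(
                island_id=island_id
                or f"{island.chromosome}:{island.start_bp}-{island.end_bp}",
                island_class=island.run_type,
                element_type=etype,
                fraction=overlap / length,
            )
        )
    return records


def compare_enrichment(
    hrr_records: Sequence[ElementCoverageRecord],
    roh_records: Sequence[ElementCoverageRecord],
    element_type: str,
) -> float:
    """Two-sided Mann-Whitney U on per-island fractions between classes."""
    x = [r.fraction for r in hrr_records if r.element_type == element_type]
    y = [r.fraction for r in roh_records if r.element_type == element_type]
    if not x or not y:
        raise ValueError(f"no records for element type {element_type!r}")
    return mwu_exact(x, y, alternative="two-sided")


def windows_to_frame(windows: Sequence[TajimaWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": t.chromosome, "start_bp": t.start_bp,
             "end_bp": t.end_bp, "n_sites": t.n_sites, "S": t.s,
             "pi": t.pi, "D": t.d, "outlier": t.outlier}
            for t in windows
        ]
    )
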