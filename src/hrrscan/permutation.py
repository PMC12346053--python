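"""Permutation null for island significance.

Individuals are shuffled across herds, permuted groups are rebuilt, islands
are re-called per group from the (precomputed) run coverage, matched against
the observed islands by interval overlap, and the matched supports are
compared with the observed herd support.

Two p-values are reported per island.  ``p_empirical`` is the standard
permutation p, (1 + #{permuted support >= observed}) / (1 + #permuted),
over the pooled matched supports, and is the primary statistic.  ``p_mwu``
is an exact Mann-Whitney U of the observed herd support against the six
per-group mean permuted supports, mirroring how studies of this design
tabulate one permuted column per group; with one observed value against six
group means its two-sided floor is 2/7, so it is reported for comparability,
not as the primary inference.

Replicate randomness is counter-based: each replicate derives its stream
from (master seed, replicate index), so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from hrrscan.genotype_io import GenotypeDataset
from hrrscan.islands import Island, _call_islands_values, coverage_matrix
from hrrscan.runs import RunSegment
from hrrscan.summaries import herd_mean_se

_EXACT_MAX_N = 20


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation null.

    ``group_sizes=None`` uses the observed herd sizes so every individual is
    assigned each replicate; ``paper_mode`` groups of sixty leave the
    remainder idle.  Islands matched in fewer than ``min_matched_groups``
    permuted groups are flagged not evaluable.
    """

    n_permutations: int = 1000
    n_groups: int = 6
    group_sizes: tuple[int, ...] | None = None
    seed: int = 0
    min_matched_groups: int = 3

    def resolve_group_sizes(self, dataset: GenotypeDataset) -> tuple[int, ...]:
        if self.group_sizes is not None:
            sizes = tuple(self.group_sizes)
        else:
            sizes = tuple(dataset.herd_sizes().values())
        if len(sizes) != self.n_groups:
            raise ValueError(
                f"n_groups={self.n_groups} but {len(sizes)} group sizes"
            )
        if sum(sizes) > dataset.n_individuals:
            raise ValueError("group sizes exceed population")
        return sizes


def paper_mode_config(
    n_permutations: int = 10_000, seed: int = 0
) -> PermutationConfig:
    """Six permuted groups of sixty individuals each."""
    return PermutationConfig(
        n_permutations=n_permutations,
        n_groups=6,
        group_sizes=(60,) * 6,
        seed=seed,
    )


@dataclass
class IslandSignificance:
    """Observed vs permuted support of one island (one results-table row)."""

    island: Island
    observed_support: float
    group_mean_supports: dict[int, float]  # group index -> mean over matches
    n_matched: int  # pooled matched supports across replicates and groups
    perm_mean: float | None
    perm_se: float | None
    p_mwu: float | None
    p_empirical: float | None
    evaluable: bool


def shuffle_groups(
    n_individuals: int, config: PermutationConfig,
    replicate_index: int, group_sizes: Sequence[int],
) -> list[np.ndarray]:
    """Partition a uniformly random permutation of row indices into groups.

    Deterministic given (seed, replicate_index); indices beyond
    sum(group_sizes) are unassigned for the replicate.
    """
    if replicate_index < 0 or replicate_index >= config.n_permutations:
        raise ValueError("replicate_index out of range")
    if sum(group_sizes) > n_individuals:
        raise ValueError("group sizes exceed population")
    rng = np.random.default_rng([config.seed, replicate_index])
    perm = rng.permutation(n_individuals)
    groups, at = [], 0
    for size in group_sizes:
        groups.append(perm[at:at + size])
        at += size
    return groups


def build_null(
    dataset: GenotypeDataset,
    runs: Sequence[RunSegment],
    observed_islands: Sequence[Island],
    island_threshold: float,
    config: PermutationConfig,
) -> list[IslandSignificance]:
    """Assess each observed island against the permuted-group null.

    Runs are detected once per individual before entry: regrouping does not
    alter an individual's runs, only group incidence, so each replicate is
    a row-mean over a precomputed coverage matrix followed by island
    calling and overlap matching.
    """
    if not observed_islands:
        return []
    group_sizes = config.resolve_group_sizes(dataset)
    cov = coverage_matrix(runs, dataset)
    chroms = dataset.markers["chromosome"].to_numpy()
    positions = dataset.markers["position_bp"].to_numpy()
    run_type = observed_islands[0].run_type

    obs_chrom = np.array([i.chromosome for i in observed_islands])
    obs_start = np.array([i.start_bp for i in observed_islands])
    obs_end = np.array([i.end_bp for i in observed_islands])

    per_group: list[dict[int, list[float]]] = [
        {g: [] for g in range(config.n_groups)} for _ in observed_islands
    ]
    for rep in range(config.n_permutations):
        groups = shuffle_groups(
            dataset.n_individuals, config, rep, group_sizes
        )
        for g, rows in enumerate(groups):
            incidence = cov[rows].mean(axis=0)
            called = _call_islands_values(
                incidence, chroms, positions, island_threshold,
                group_id=f"perm{g}", run_type=run_type,
            )
            if not called:
                continue
            supports = _matched_supports(
                obs_chrom, obs_start, obs_end, called
            )
            for i, s in enumerate(supports):
                if not np.isnan(s):
                    per_group[i][g].append(float(s))

    results = []
    for obs, matches in zip(observed_islands, per_group):
        group_means = {
            g: float(np.mean(v)) for g, v in matches.items() if v
        }
        pooled = [s for v in matches.values() for s in v]
        evaluable = len(group_means) >= config.min_matched_groups
        perm_mean = perm_se = p_mwu = p_emp = None
        if evaluable:
            means = list(group_means.values())
            perm_mean, perm_se = herd_mean_se(means)
            p_mwu = mwu_exact([obs.support], means)
            n_ge = sum(s >= obs.support for s in pooled)
            p_emp = (1 + n_ge) / (1 + len(pooled))
        results.append(
            IslandSignificance(
                island=obs,
                observed_support=obs.support,
                group_mean_supports=group_means,
                n_matched=len(pooled),
                perm_mean=perm_mean,
                perm_se=perm_se,
                p_mwu=p_mwu,
                p_empirical=p_emp,
                evaluable=evaluable,
            )
        )
    return results


def _matched_supports(
    obs_chrom: np.ndarray,
    obs_start: np.ndarray,
    obs_end: np.ndarray,
    called: Sequence[Island],
) -> np.ndarray:
    """Support of the largest-overlap candidate per observed island.

    Vectorized equivalent of :func:`hrrscan.islands.match_islands` applied
    island by island; NaN where nothing overlaps.
    """
    c_chrom = np.array([c.chromosome for c in called])
    c_start = np.array([c.start_bp for c in called])
    c_end = np.array([c.end_bp for c in called])
    c_support = np.array([c.support for c in called])
    # overlap of 1-based inclusive intervals, obs x called
    ov = (
        np.minimum(obs_end[:, None], c_end[None, :])
        - np.maximum(obs_start[:, None], c_start[None, :])
        + 1
    )
    ov = np.where(obs_chrom[:, None] == c_chrom[None, :], ov, 0)
    best = ov.argmax(axis=1)
    out = c_support[best].astype(float)
    out[ov[np.arange(len(obs_chrom)), best] < 1] = np.nan
    return out


def mwu_exact(
    sample_x: Sequence[float],
    sample_y: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Mann-Whitney U p-value; exact by enumeration when n_x + n_y <= 20.

    The exact branch enumerates every assignment of the pooled values to
    the x-group, computing U from midranks, so ties are handled without
    approximation.  Larger samples fall back to the normal approximation
    with tie correction.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    n1, n2 = x.size, y.size
    if n1 + n2 > _EXACT_MAX_N:
        return float(
            stats.mannwhitneyu(x, y, alternative=alternative,
                               method="asymptotic").pvalue
        )

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    mu = n1 * n2 / 2
    total = comb(n1 + n2, n1)
    count = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if alternative == "two-sided":
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            hit = u >= u_obs - 1e-12
        else:
            hit = u <= u_obs + 1e-12
        count += hit
    return count / total


def significance_to_frame(results: Sequence[IslandSignificance], n_groups: int):
    """Results table mirroring the island-significance report columns."""
    import pandas as pd

    from hrrscan.islands import island_length_kb

    rows = []
    for r in results:
        row = {
            "chrom": r.island.chromosome,
            "region": f"{r.island.start_bp}-{r.island.end_bp}",
            "group": r.island.group_id,
            "n_snps": r.island.n_snps,
            "length_kb": island_length_kb(r.island),
            "observed_support": r.observed_support,
        }
        for g in range(n_groups):
            row[f"perm_group_{g + 1}"] = r.group_mean_supports.get(g)
        row.update(
            perm_mean=r.perm_mean,
            perm_se=r.perm_se,
            p_mwu=r.p_mwu,
            p_empirical=r.p_empirical,
            evaluable=r.evaluable,
        )
        rows.append(row)
    return pd.DataFrame(rows)
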