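"""Herd-structured SNP-array genotype simulator with planted features.

The simulator emulates the shape of a six-herd SNP50-array study: 366
individuals in herds of 57/85/73/44/58/54, 29 autosomes at ~50 kb mean
marker spacing, ~10% of markers near-monomorphic (MAF < 0.01), and modest
between-herd differentiation.  Herd allele frequencies follow the
Balding-Nichols model: for ancestral frequency p and differentiation F,
each herd's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected
Weir-Cockerham Fst across herds is approximately F.  Genotypes are
Hardy-Weinberg draws within herd; markers are independent (no LD model)
except inside planted features.

Planted heterozygote islands make carrier-herd individuals heterozygous
with probability h per marker; planted homozygous tracts give carriers a
single shared haplotype.  Missing calls are applied uniformly at random.
A truth table records every planted feature and the generating
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hrrscan.genotype_io import HET, MISSING, GenotypeDataset

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"),
                 ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class PlantedIsland:
    """Heterozygote-rich interval: carriers are het with probability h."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_herds: tuple[str, ...]
    het_prob: float

    def __post_init__(self) -> None:
        if not 0.0 < self.het_prob <= 1.0:
            raise ValueError("het_prob must be in (0, 1]")


@dataclass(frozen=True)
class PlantedTract:
    """Homozygous tract: carriers share one haplotype over the interval."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_herds: tuple[str, ...] = ()
    carrier_individuals: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults; override sizes downward for unit fixtures."""

    n_herds: int = 6
    herd_sizes: tuple[int, ...] = (57, 85, 73, 44, 58, 54)
    n_chromosomes: int = 29
    markers_per_chromosome: int = 1659
    mean_spacing_bp: int = 50_000
    rare_fraction: float = 0.10  # markers with ancestral MAF < 0.01
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    fst: float = 0.05
    missing_rate: float = 0.005
    planted_islands: tuple[PlantedIsland, ...] = ()
    planted_tracts: tuple[PlantedTract, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.herd_sizes) != self.n_herds:
            raise ValueError("herd_sizes length must equal n_herds")
        if any(s <= 0 for s in self.herd_sizes):
            raise ValueError("herd sizes must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")


@dataclass
class TruthTable:
    """Generating truth: planted features and allele frequencies."""

    seed: int
    planted_islands: list[dict]
    planted_tracts: list[dict]
    ancestral_freq: np.ndarray  # allele-B frequency per marker
    herd_freq: np.ndarray  # herds x markers

    def features_frame(self) -> pd.DataFrame:
        rows = []
        for feat in self.planted_islands:
            rows.append({"kind": "island", **{
                k: v for k, v in feat.items() if k != "carriers"
            }, "carriers": ",".join(feat["carriers"])})
        for feat in self.planted_tracts:
            rows.append({"kind": "tract", **{
                k: v for k, v in feat.items() if k != "carriers"
            }, "carriers": ",".join(feat["carriers"])})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.features_frame().to_csv(path, sep="\t", index=False)


def _herd_ids(config: SimConfig) -> list[str]:
    return [f"herd{i + 1}" for i in range(config.n_herds)]


def _pseudo_phenotype(k: int) -> str:
    # 1-based individual number; 2 and 9 collide with PLINK phenotype
    # codes, so those labels get a ".1" suffix (opaque-string contract).
    return f"{k}.1" if k in (2, 9) else str(k)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, TruthTable]:
    """Draw one dataset plus its truth table, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    n_markers = config.n_chromosomes * config.markers_per_chromosome
    mpc = config.markers_per_chromosome

    # marker map: gamma-distributed spacings around the target mean, so the
    # inter-marker gap rule is exercised by occasional long gaps
    spacings = rng.gamma(
        shape=4.0, scale=config.mean_spacing_bp / 4.0,
        size=(config.n_chromosomes, mpc),
    ).astype(np.int64)
    spacings = np.maximum(spacings, 1)
    positions = np.cumsum(spacings, axis=1).ravel()
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), mpc)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_markers)
    allele_a = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    allele_b = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    markers = pd.DataFrame(
        {
            "chromosome": chroms,
            "marker_id": [f"snp{c}_{p}" for c, p in zip(chroms, positions)],
            "position_bp": positions,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )

    # ancestral allele-B frequency: a rare_fraction of markers are
    # near-monomorphic (MAF < 0.01), the rest uniform up to 0.5
    rare = rng.random(n_markers) < config.rare_fraction
    lo, hi = config.common_maf_range
    p_anc = np.where(
        rare,
        rng.uniform(0.0, 0.01, size=n_markers),
        rng.uniform(lo, hi, size=n_markers),
    )

    # Balding-Nichols herd frequencies
    f = config.fst
    if f < 1e-12:
        herd_freq = np.tile(p_anc, (config.n_herds, 1))
    else:
        ratio = (1.0 - f) / f
        a = np.maximum(p_anc * ratio, 1e-12)
        b = np.maximum((1.0 - p_anc) * ratio, 1e-12)
        herd_freq = rng.beta(a, b, size=(config.n_herds, n_markers))
        herd_freq[:, p_anc <= 0.0] = 0.0

    herd_ids = _herd_ids(config)
    ind_rows = []
    k = 0
    for herd, size in zip(herd_ids, config.herd_sizes):
        for _ in range(size):
            k += 1
            ind_rows.append(
                {
                    "individual_id": f"{herd}_cow{k}",
                    "herd_id": herd,
                    "pseudo_phenotype": _pseudo_phenotype(k),
                }
            )
    individuals = pd.DataFrame(ind_rows)
    n_ind = len(individuals)

    # Hardy-Weinberg genotypes within herd: B-allele dosage == call code
    calls = np.empty((n_ind, n_markers), dtype=np.int8)
    at = 0
    for h, size in enumerate(config.herd_sizes):
        calls[at:at + size] = rng.binomial(
            2, herd_freq[h], size=(size, n_markers)
        ).astype(np.int8)
        at += size

    herd_rows = {
        h: np.flatnonzero(individuals["herd_id"].to_numpy() == h)
        for h in herd_ids
    }
    truth_islands, truth_tracts = [], []
    for isl in config.planted_islands:
        cols = np.flatnonzero(
            (chroms == isl.chromosome)
            & (positions >= isl.start_bp)
            & (positions <= isl.end_bp)
        )
        if cols.size == 0:
            raise ValueError(f"planted island outside the map: {isl}")
        carriers = []
        for herd in isl.carrier_herds:
            rows = herd_rows[herd]
            force = rng.random((rows.size, cols.size)) < isl.het_prob
            block = calls[np.ix_(rows, cols)]
            block[force] = HET
            calls[np.ix_(rows, cols)] = block
            carriers.extend(individuals["individual_id"].iloc[rows])
        truth_islands.append(
            {
                "chromosome": isl.chromosome,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "het_prob": isl.het_prob,
                "carriers": carriers,
            }
        )
    for tract in config.planted_tracts:
        cols = np.flatnonzero(
            (chroms == tract.chromosome)
            & (positions >= tract.start_bp)
            & (positions <= tract.end_bp)
        )
        if cols.size == 0:
            raise ValueError(f"planted tract outside the map: {tract}")
        rows = []
        for herd in tract.carrier_herds:
            rows.extend(herd_rows[herd])
        for iid in tract.carrier_individuals:
            rows.append(
                int(np.flatnonzero(
                    individuals["individual_id"].to_numpy() == iid
                )[0])
            )
        if not rows:
            raise ValueError(f"planted tract without carriers: {tract}")
        hap = (rng.random(cols.size) < p_anc[cols]).astype(np.int8) * 2
        calls[np.ix_(sorted(set(rows)), cols)] = hap
        truth_tracts.append(
            {
                "chromosome": tract.chromosome,
                "start_bp": tract.start_bp,
                "end_bp": tract.end_bp,
                "carriers": list(
                    individuals["individual_id"].iloc[sorted(set(rows))]
                ),
            }
        )

    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    dataset = GenotypeDataset(
        markers=markers, calls=calls, individuals=individuals
    )
    truth = TruthTable(
        seed=config.seed,
        planted_islands=truth_islands,
        planted_tracts=truth_tracts,
        ancestral_freq=p_anc,
        herd_freq=herd_freq,
    )
    return dataset, truth


# -- bundled deterministic fixtures -----------------------------------------

FIXTURES: dict[str, SimConfig] = {
    # 2 herds x 10 individuals x 200 markers, one strong planted island
    "mini-island": SimConfig(
        n_herds=2,
        herd_sizes=(10, 10),
        n_chromosomes=2,
        markers_per_chromosome=100,
        planted_islands=(
            PlantedIsland(
                chromosome=1, start_bp=2_000_000, end_bp=2_450_000,
                carrier_herds=("herd1",), het_prob=0.95,
            ),
        ),
        seed=101,
    ),
    # same shape, nothing planted
    "mini-null": SimConfig(
        n_herds=2,
        herd_sizes=(10, 10),
        n_chromosomes=2,
        markers_per_chromosome=100,
        seed=202,
    ),
    # one planted multi-Mb homozygous tract in herd 2
    "mini-roh": SimConfig(
        n_herds=2,
        herd_sizes=(10, 10),
        n_chromosomes=2,
        markers_per_chromosome=100,
        planted_tracts=(
            PlantedTract(
                chromosome=2, start_bp=1_000_000, end_bp=3_500_000,
                carrier_herds=("herd2",),
            ),
        ),
        seed=303,
    ),
}


def emit_fixture(name: str) -> tuple[GenotypeDataset, TruthTable]:
    """Deterministically regenerate a registered tiny fixture."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}"
        )
    return simulate_dataset(FIXTURES[name])
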