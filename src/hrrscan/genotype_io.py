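"""PLINK text PED/MAP input/output, QC filtering, and the genome build.

Genotype calls are held as an ``int8`` matrix (individuals x markers) with a
four-state alphabet: 0 = homozygous for allele A, 1 = heterozygous,
2 = homozygous for allele B, -1 = missing.  Allele A is the alphabetically
smaller of the two observed alleles, so a read/write cycle is a fixed point.

Coordinates are 1-based inclusive throughout (PLINK MAP convention).
The sixth PED column is an arbitrary per-individual pseudo-phenotype and is
preserved verbatim as a string, never parsed as a number: label permutation
of these strings is what permutes individuals among groups downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

VALID_ALLELES = frozenset("ACGT0")

#: Number of autosomes in the default (bovine) karyotype.
N_AUTOSOMES = 29


class PedParseError(ValueError):
    """Malformed PED/MAP content; the message names the offending line."""


class AlleleCodingError(ValueError):
    """Allele character outside {A, C, G, T, 0}."""


class EmptyDatasetError(ValueError):
    """QC removed every marker or every individual."""


# Marker table columns.  ``MarkerMap`` is a plain DataFrame with this schema;
# a thin alias keeps signatures readable.
MARKER_COLUMNS = ["chromosome", "marker_id", "position_bp", "allele_a", "allele_b"]
MarkerMap = pd.DataFrame


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds applied in fixed order.

    Markers failing ``max_snp_missing`` are removed first, then individuals
    failing ``max_ind_missing``, then (when ``min_maf`` is set) markers with
    MAF below ``min_maf``.  Non-autosomal markers are dropped up front when
    ``autosomes_only`` is set.
    """

    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.05
    min_maf: float | None = None
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("max_snp_missing", "max_ind_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_maf is not None and not 0.0 <= self.min_maf <= 1.0:
            raise ValueError(f"min_maf must be in [0, 1], got {self.min_maf}")


@dataclass
class GenotypeDataset:
    """Individuals x markers call matrix with herd labels and a marker map."""

    markers: pd.DataFrame
    calls: np.ndarray
    individuals: pd.DataFrame  # columns: individual_id, herd_id, pseudo_phenotype

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def herd_ids(self) -> list[str]:
        """Distinct herd labels in order of first appearance."""
        return list(dict.fromkeys(self.individuals["herd_id"]))

    def herd_sizes(self) -> dict[str, int]:
        return {h: int((self.individuals["herd_id"] == h).sum())
                for h in self.herd_ids()}

    def indices_of_herd(self, herd_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.individuals["herd_id"].to_numpy() == herd_id)
        if idx.size == 0:
            raise KeyError(f"unknown herd {herd_id!r}")
        return idx

    def index_of_individual(self, individual_id: str) -> int:
        pos = np.flatnonzero(
            self.individuals["individual_id"].to_numpy() == individual_id
        )
        if pos.size == 0:
            raise KeyError(f"unknown individual {individual_id!r}")
        return int(pos[0])

    def herd_of(self) -> dict[str, str]:
        """individual_id -> herd_id."""
        return dict(zip(self.individuals["individual_id"],
                        self.individuals["herd_id"]))

    def validate(self) -> None:
        if self.calls.shape != (self.n_individuals, self.n_markers):
            raise ValueError("calls shape does not match individuals x markers")
        per_chrom = self.markers.groupby("chromosome", sort=False)["position_bp"]
        if not per_chrom.apply(lambda s: bool((np.diff(s.to_numpy()) > 0).all())).all():
            raise ValueError("positions not strictly increasing within chromosome")


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray):
    order = np.lexsort((
        markers["marker_id"].to_numpy(),
        markers["position_bp"].to_numpy(),
        markers["chromosome"].to_numpy(),
    ))
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read a whitespace-separated PED/MAP pair into a GenotypeDataset.

    Markers are sorted by (chromosome, position); call columns follow.  The
    pseudo-phenotype (PED column 6) is kept verbatim as a string.
    """
    markers = _read_map(map_path)
    n_markers = len(markers)

    fids, iids, phenos = [], [], []
    geno_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise PedParseError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_markers} fields, got {len(fields)}"
                )
            fids.append(fields[0])
            iids.append(fields[1])
            phenos.append(fields[5])  # opaque string, never numeric
            geno_rows.append(fields[6:])
    if not geno_rows:
        raise PedParseError(f"{ped_path}: empty PED file, zero individuals")

    alleles = np.asarray(geno_rows, dtype="U1")
    bad = ~np.isin(alleles, list(VALID_ALLELES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AlleleCodingError(
            f"{ped_path}: line {i + 1}: allele {alleles[i, j]!r} "
            "not in {A,C,G,T,0}"
        )
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    if ((a1 == "0") != (a2 == "0")).any():
        raise PedParseError(
            f"{ped_path}: half-missing genotype (single '0' allele)"
        )

    calls = np.full((len(geno_rows), n_markers), MISSING, dtype=np.int8)
    allele_a = np.empty(n_markers, dtype="U1")
    allele_b = np.empty(n_markers, dtype="U1")
    for j in range(n_markers):
        c1, c2 = a1[:, j], a2[:, j]
        present = c1 != "0"
        observed = sorted(set(c1[present]) | set(c2[present]))
        if len(observed) > 2:
            raise AlleleCodingError(
                f"{ped_path}: marker {markers['marker_id'][j]!r} has "
                f"{len(observed)} alleles: {observed}"
            )
        aa = observed[0] if observed else "0"
        ab = observed[1] if len(observed) == 2 else "0"
        allele_a[j] = aa
        allele_b[j] = ab
        het = present & (c1 != c2)
        calls[het, j] = HET
        calls[present & ~het & (c1 == aa), j] = HOM_A
        if ab != "0":
            calls[present & ~het & (c1 == ab), j] = HOM_B
    markers = markers.assign(allele_a=allele_a, allele_b=allele_b)

    individuals = pd.DataFrame(
        {"individual_id": iids, "herd_id": fids, "pseudo_phenotype": phenos}
    )
    markers, calls = _sort_markers(markers, calls)
    ds = GenotypeDataset(markers=markers, calls=calls, individuals=individuals)
    ds.validate()
    return ds


def _read_map(map_path) -> pd.DataFrame:
    chroms, ids, positions = [], [], []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedParseError(
                    f"{map_path}: line {lineno}: expected 4 columns, "
                    f"got {len(fields)}"
                )
            chrom, marker_id, _cm, bp = fields
            if marker_id in seen:
                raise PedParseError(
                    f"{map_path}: line {lineno}: duplicate marker_id "
                    f"{marker_id!r}"
                )
            seen.add(marker_id)
            try:
                chrom_i = int(chrom)
            except ValueError:
                chrom_i = 0  # non-numeric chromosome: flagged non-autosomal
            chroms.append(chrom_i)
            ids.append(marker_id)
            try:
                positions.append(int(bp))
            except ValueError as exc:
                raise PedParseError(
                    f"{map_path}: line {lineno}: bad position {bp!r}"
                ) from exc
    return pd.DataFrame(
        {
            "chromosome": np.asarray(chroms, dtype=np.int64),
            "marker_id": ids,
            "position_bp": np.asarray(positions, dtype=np.int64),
            "allele_a": "0",
            "allele_b": "0",
        }
    )


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a PED/MAP pair that round-trips through :func:`read_ped_map`.

    Missing calls are encoded as ``0 0`` (PLINK convention); the genetic
    distance column of the MAP is written as 0.
    """
    m = dataset.markers
    with open(map_path, "w") as fh:
        for chrom, marker_id, pos in zip(
            m["chromosome"], m["marker_id"], m["position_bp"]
        ):
            fh.write(f"{chrom}\t{marker_id}\t0\t{pos}\n")

    aa = m["allele_a"].to_numpy(dtype="U1")
    ab = m["allele_b"].to_numpy(dtype="U1")
    lookup = np.stack([
        np.char.add(np.char.add(aa, " "), aa),   # HOM_A
        np.char.add(np.char.add(aa, " "), ab),   # HET
        np.char.add(np.char.add(ab, " "), ab),   # HOM_B
        np.full(len(m), "0 0", dtype="U3"),      # MISSING
    ])
    with open(ped_path, "w") as fh:
        for i in range(dataset.n_individuals):
            row = dataset.individuals.iloc[i]
            genos = lookup[dataset.calls[i], np.arange(len(m))]
            fh.write(
                f"{row['herd_id']} {row['individual_id']} 0 0 0 "
                f"{row['pseudo_phenotype']} " + " ".join(genos) + "\n"
            )


def compute_maf(dataset: GenotypeDataset, marker_id: str) -> float:
    """Minor-allele frequency of one marker over non-missing alleles."""
    j = np.flatnonzero(dataset.markers["marker_id"].to_numpy() == marker_id)
    if j.size == 0:
        raise KeyError(f"unknown marker {marker_id!r}")
    maf = _maf_vector(dataset.calls[:, j])
    if np.isnan(maf[0]):
        raise ValueError(f"marker {marker_id!r}: all calls missing")
    return float(maf[0])


def _maf_vector(calls: np.ndarray) -> np.ndarray:
    """MAF per column; NaN where every call is missing."""
    present = calls != MISSING
    n_alleles = 2 * present.sum(axis=0)
    n_b = np.where(present, calls, 0).sum(axis=0)  # B-allele dosage
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_alleles > 0, n_b / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(freq_b, 1.0 - freq_b)


@dataclass
class QCReport:
    n_markers_in: int = 0
    n_individuals_in: int = 0
    n_non_autosomal_removed: int = 0
    n_markers_missing_removed: int = 0
    n_individuals_missing_removed: int = 0
    n_markers_maf_removed: int = 0
    n_markers_out: int = 0
    n_individuals_out: int = 0

    def to_tsv(self, path) -> None:
        pd.DataFrame([vars(self)]).T.to_csv(path, sep="\t", header=False)


def apply_qc(
    dataset: GenotypeDataset, params: QCParams, n_autosomes: int = N_AUTOSOMES
) -> tuple[GenotypeDataset, QCReport]:
    """Apply QC in the fixed order: marker call rate, individual call rate,
    then optional MAF; non-autosomal markers dropped first."""
    if dataset.n_markers == 0 or dataset.n_individuals == 0:
        raise EmptyDatasetError("dataset is empty before QC")
    report = QCReport(
        n_markers_in=dataset.n_markers, n_individuals_in=dataset.n_individuals
    )
    markers, calls = dataset.markers, dataset.calls
    individuals = dataset.individuals

    if params.autosomes_only:
        keep = markers["chromosome"].between(1, n_autosomes).to_numpy()
        report.n_non_autosomal_removed = int((~keep).sum())
        markers, calls = markers[keep].reset_index(drop=True), calls[:, keep]

    if calls.shape[1]:
        miss_frac = (calls == MISSING).mean(axis=0)
        keep = miss_frac <= params.max_snp_missing
        report.n_markers_missing_removed = int((~keep).sum())
        markers, calls = markers[keep].reset_index(drop=True), calls[:, keep]

    if calls.shape[1]:
        ind_miss = (calls == MISSING).mean(axis=1)
        keep_ind = ind_miss <= params.max_ind_missing
        report.n_individuals_missing_removed = int((~keep_ind).sum())
        individuals = individuals[keep_ind].reset_index(drop=True)
        calls = calls[keep_ind]

    if params.min_maf is not None and calls.shape[1] and len(individuals):
        maf = _maf_vector(calls)
        keep = ~np.isnan(maf) & (maf >= params.min_maf)
        report.n_markers_maf_removed = int((~keep).sum())
        markers, calls = markers[keep].reset_index(drop=True), calls[:, keep]

    if not len(markers):
        raise EmptyDatasetError("empty after QC: all markers removed")
    if not len(individuals):
        raise EmptyDatasetError("empty after QC: all individuals removed")
    report.n_markers_out = len(markers)
    report.n_individuals_out = len(individuals)
    out = GenotypeDataset(markers=markers, calls=calls, individuals=individuals)
    return out, report


@dataclass
class GenomeBuild:
    """Per-chromosome lengths plus SNP-covered spans of the post-QC map."""

    lengths_bp: dict[int, int]
    covered_bp: dict[int, int] = field(default_factory=dict)

    @property
    def total_length_bp(self) -> int:
        return sum(self.lengths_bp.values())

    @property
    def total_covered_bp(self) -> int:
        return sum(self.covered_bp.values())

    def length_share(self, chromosome: int) -> float:
        return self.lengths_bp[chromosome] / self.total_length_bp

    def with_coverage(self, markers: pd.DataFrame) -> "GenomeBuild":
        """Covered length per chromosome = last SNP bp - first SNP bp."""
        covered = {}
        for chrom, grp in markers.groupby("chromosome"):
            pos = grp["position_bp"]
            span = int(pos.max() - pos.min())
            limit = self.lengths_bp.get(int(chrom))
            if limit is not None and span > limit:
                raise ValueError(
                    f"covered span {span} exceeds chromosome {chrom} "
                    f"length {limit}"
                )
            covered[int(chrom)] = span
        return GenomeBuild(lengths_bp=dict(self.lengths_bp), covered_bp=covered)

    @classmethod
    def from_tsv(cls, path) -> "GenomeBuild":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chromosome", "length_bp"], comment="#")
        return cls(lengths_bp=dict(
            zip(df["chromosome"].astype(int), df["length_bp"].astype(int))
        ))

    @classmethod
    def from_markers(cls, markers: pd.DataFrame) -> "GenomeBuild":
        """Build whose chromosome lengths are the last SNP position per
        chromosome (natural for simulated maps without a reference)."""
        lengths = {
            int(c): int(grp["position_bp"].max())
            for c, grp in markers.groupby("chromosome")
        }
        return cls(lengths_bp=lengths).with_coverage(markers)

    @classmethod
    def bovine_autosomes(cls) -> "GenomeBuild":
        """ARS-UCD bovine autosome lengths shipped with the package."""
        ref = importlib.resources.files("hrrscan.data") / "bovine_autosomes.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)
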