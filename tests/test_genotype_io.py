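import numpy as np
import pytest

from conftest import dataset_from_strings
from hrrscan.genotype_io import (
    AlleleCodingError,
    EmptyDatasetError,
    GenomeBuild,
    PedParseError,
    QCParams,
    apply_qc,
    compute_maf,
    read_ped_map,
    write_ped_map,
)


def _write(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text("".join(line + "\n" for line in ped_lines))
    mp.write_text("".join(line + "\n" for line in map_lines))
    return ped, mp


MAP3 = ["1 s1 0 1000", "1 s2 0 2000", "1 s3 0 3000"]


class TestReadPedMap:
    def test_pseudo_phenotype_kept_verbatim(self, tmp_path):
        # labels like "2.1" are opaque strings, never parsed numerically
        ped, mp = _write(
            tmp_path,
            ["f1 i1 0 0 0 2.1 A A A C C C",
             "f1 i2 0 0 0 -8 A A A A C C"],
            MAP3,
        )
        ds = read_ped_map(ped, mp)
        assert list(ds.individuals["pseudo_phenotype"]) == ["2.1", "-8"]

    def test_empty_ped_is_parse_error(self, tmp_path):
        ped, mp = _write(tmp_path, [], MAP3)
        with pytest.raises(PedParseError, match="empty"):
            read_ped_map(ped, mp)

    def test_wrong_field_count_names_line(self, tmp_path):
        ped, mp = _write(tmp_path, ["f1 i1 0 0 0 1 A A"], MAP3)
        with pytest.raises(PedParseError, match="line 1"):
            read_ped_map(ped, mp)

    def test_bad_allele_rejected(self, tmp_path):
        ped, mp = _write(
            tmp_path, ["f1 i1 0 0 0 1 A A N C C C"], MAP3
        )
        with pytest.raises(AlleleCodingError):
            read_ped_map(ped, mp)

    def test_duplicate_marker_rejected(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["f1 i1 0 0 0 1 A A A C C C"],
            ["1 s1 0 1000", "1 s1 0 2000", "1 s3 0 3000"],
        )
        with pytest.raises(PedParseError, match="duplicate"):
            read_ped_map(ped, mp)

    def test_markers_sorted_by_chrom_then_position(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["f1 i1 0 0 0 1 A A C C G G T T"],
            ["2 s1 0 500", "1 s2 0 9000", "1 s3 0 100", "2 s4 0 100"],
        )
        ds = read_ped_map(ped, mp)
        assert list(ds.markers["marker_id"]) == ["s3", "s2", "s4", "s1"]


class TestWritePedMap:
    def test_missing_encoded_as_zero_zero(self, tmp_path):
        ds = dataset_from_strings(["AH."])
        write_ped_map(ds, tmp_path / "o.ped", tmp_path / "o.map")
        assert (tmp_path / "o.ped").read_text().rstrip().endswith("0 0")

    def test_round_trip_is_identity(self, tmp_path, mini_island):
        ds, _ = mini_island
        write_ped_map(ds, tmp_path / "a.ped", tmp_path / "a.map")
        back = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
        assert np.array_equal(ds.calls, back.calls)
        assert list(ds.markers["marker_id"]) == list(back.markers["marker_id"])
        assert list(ds.markers["position_bp"]) == list(
            back.markers["position_bp"])
        assert list(ds.individuals["pseudo_phenotype"]) == list(
            back.individuals["pseudo_phenotype"])

    def test_read_write_read_fixed_point(self, tmp_path, mini_island):
        ds, _ = mini_island
        write_ped_map(ds, tmp_path / "a.ped", tmp_path / "a.map")
        once = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
        write_ped_map(once, tmp_path / "b.ped", tmp_path / "b.map")
        assert (tmp_path / "a.ped").read_bytes() == (
            tmp_path / "b.ped").read_bytes()
        assert (tmp_path / "a.map").read_bytes() == (
            tmp_path / "b.map").read_bytes()


class TestComputeMaf:
    @pytest.mark.parametrize(
        "column, expected",
        [
            (["A", "A", "A", "A"], 0.0),       # monomorphic
            (["A", "H", "B", "H"], 0.5),       # symmetric
            (["A", "A", "H", "."], 1.0 / 6),   # 5:1 over non-missing
        ],
    )
    def test_examples(self, column, expected):
        ds = dataset_from_strings([c for c in column])
        assert compute_maf(ds, "m0") == pytest.approx(expected)

    def test_all_missing_flagged(self):
        ds = dataset_from_strings([".", ".", "."])
        with pytest.raises(ValueError, match="missing"):
            compute_maf(ds, "m0")


class TestApplyQC:
    def test_marker_over_threshold_removed(self):
        # 1 of 16 calls missing per column -> 6.25% > 5% threshold
        genos = ["AH"] * 15 + [".H"]
        ds = dataset_from_strings(genos)
        out, report = apply_qc(ds, QCParams(max_ind_missing=1.0))
        assert list(out.markers["marker_id"]) == ["m1"]
        assert report.n_markers_missing_removed == 1

    def test_monomorphic_kept_without_maf_filter(self):
        ds = dataset_from_strings(["AH", "AH", "AH", "AH"])
        out_all, _ = apply_qc(ds, QCParams())
        assert out_all.n_markers == 2
        out_maf, _ = apply_qc(ds, QCParams(min_maf=0.01))
        assert list(out_maf.markers["marker_id"]) == ["m1"]

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(42)
        chars = np.array(list("AHB."))
        genos = ["".join(rng.choice(chars, p=[0.4, 0.3, 0.2, 0.1], size=10))
                 for _ in range(4)]
        ds = dataset_from_strings(genos)
        params = QCParams(max_snp_missing=0.25, max_ind_missing=0.2)
        out, _ = apply_qc(ds, params)

        # oracle: exhaustive per-column then per-row counting
        grid = np.array([list(g) for g in genos])
        keep_m = [j for j in range(10)
                  if (grid[:, j] == ".").mean() <= 0.25]
        keep_i = [i for i in range(4)
                  if (grid[i, keep_m] == ".").mean() <= 0.2]
        assert list(out.markers["marker_id"]) == [f"m{j}" for j in keep_m]
        assert list(out.individuals["individual_id"]) == [
            f"ind{i}" for i in keep_i]

    def test_idempotent(self, mini_island):
        ds, _ = mini_island
        params = QCParams(min_maf=0.01)
        once, _ = apply_qc(ds, params)
        twice, report = apply_qc(once, params)
        assert np.array_equal(once.calls, twice.calls)
        assert report.n_markers_missing_removed == 0
        assert report.n_markers_maf_removed == 0

    def test_maf_floor_after_filter(self, mini_island):
        ds, _ = mini_island
        out, _ = apply_qc(ds, QCParams(min_maf=0.01))
        for marker_id in out.markers["marker_id"][:25]:
            assert compute_maf(out, marker_id) >= 0.01

    def test_non_autosomes_dropped(self):
        ds = dataset_from_strings(["AHH"], chroms=[1, 30, 2])
        out, report = apply_qc(ds, QCParams())
        assert report.n_non_autosomal_removed == 1
        assert set(out.markers["chromosome"]) == {1, 2}

    def test_all_removed_is_explicit_error(self):
        ds = dataset_from_strings(["..", ".."])
        with pytest.raises(EmptyDatasetError, match="after QC"):
            apply_qc(ds, QCParams())


class TestGenomeBuild:
    def test_totals_and_coverage(self, mini_island):
        ds, _ = mini_island
        build = GenomeBuild(
            lengths_bp={1: 10_000_000, 2: 10_000_000}
        ).with_coverage(ds.markers)
        assert build.total_length_bp == 20_000_000
        for chrom, span in build.covered_bp.items():
            assert 0 < span <= build.lengths_bp[chrom]
        assert build.total_covered_bp == sum(build.covered_bp.values())

    def test_bundled_bovine_build(self):
        build = GenomeBuild.bovine_autosomes()
        assert len(build.lengths_bp) == 29
        assert build.lengths_bp[1] > build.lengths_bp[29]
        shares = [build.length_share(c) for c in build.lengths_bp]
        assert sum(shares) == pytest.approx(1.0)
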