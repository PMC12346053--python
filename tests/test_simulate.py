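import numpy as np
import pytest
from scipy import stats

from _oracles import weir_cockerham_fst
from hrrscan.genotype_io import HET, MISSING, write_ped_map
from hrrscan.islands import call_islands, snp_incidence
from hrrscan.runs import HRR_50KB, ROH_250KB, detect_all_runs
from hrrscan.simulate import (
    PlantedIsland,
    PlantedTract,
    SimConfig,
    emit_fixture,
    simulate_dataset,
)


def _herd_dosages(ds):
    out = []
    sizes = []
    for herd in ds.herd_ids():
        rows = ds.indices_of_herd(herd)
        out.append(ds.calls[rows])
        sizes.append(len(rows))
    return out, sizes


class TestFixtures:
    def test_reemission_is_byte_identical(self, tmp_path):
        for k, (ds, _) in enumerate(
            (emit_fixture("mini-island"), emit_fixture("mini-island"))
        ):
            write_ped_map(ds, tmp_path / f"{k}.ped", tmp_path / f"{k}.map")
        assert (tmp_path / "0.ped").read_bytes() == (
            tmp_path / "1.ped").read_bytes()
        assert (tmp_path / "0.map").read_bytes() == (
            tmp_path / "1.map").read_bytes()

    def test_null_fixture_has_no_islands(self, mini_null):
        ds, truth = mini_null
        assert truth.planted_islands == [] and truth.planted_tracts == []
        runs = detect_all_runs(ds, HRR_50KB)
        for herd in ds.herd_ids():
            members = list(ds.individuals.loc[
                ds.individuals["herd_id"] == herd, "individual_id"])
            track = snp_incidence(runs, ds, members, group_id=herd)
            assert call_islands(track, 0.4) == []

    def test_island_fixture_recovered_by_pipeline_stages(self, mini_island):
        ds, truth = mini_island
        planted = truth.planted_islands[0]
        runs = detect_all_runs(ds, HRR_50KB)
        members = planted["carriers"]
        track = snp_incidence(runs, ds, members, group_id="herd1")
        islands = call_islands(track, 0.4)
        assert any(
            i.chromosome == planted["chromosome"]
            and i.start_bp <= planted["end_bp"]
            and i.end_bp >= planted["start_bp"]
            for i in islands
        )

    def test_roh_fixture_gives_carriers_long_roh(self, mini_roh):
        ds, truth = mini_roh
        tract = truth.planted_tracts[0]
        runs = detect_all_runs(ds, ROH_250KB)
        for iid in tract["carriers"]:
            assert any(
                r.individual_id == iid and r.chromosome == tract["chromosome"]
                and r.length_bp >= 1_000_000
                for r in runs
            )

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            emit_fixture("nope")


class TestSimulateDataset:
    def test_shape_and_labels_follow_config(self):
        cfg = SimConfig(n_herds=3, herd_sizes=(4, 5, 6), n_chromosomes=2,
                        markers_per_chromosome=50, seed=1)
        ds, truth = simulate_dataset(cfg)
        assert ds.n_individuals == 15
        assert ds.n_markers == 100
        assert ds.herd_sizes() == {"herd1": 4, "herd2": 5, "herd3": 6}
        # labels 2 and 9 are avoided (PLINK phenotype collision)
        labels = list(ds.individuals["pseudo_phenotype"])
        assert "2" not in labels and "2.1" in labels
        ds.validate()

    def test_rare_fraction_emulated(self):
        cfg = SimConfig(n_herds=2, herd_sizes=(30, 30), n_chromosomes=4,
                        markers_per_chromosome=1000, fst=0.0, seed=3)
        _, truth = simulate_dataset(cfg)
        rare = (truth.ancestral_freq < 0.01).mean()
        assert 0.07 < rare < 0.13

    def test_hwe_within_herds_on_neutral_markers(self):
        cfg = SimConfig(n_herds=2, herd_sizes=(200, 200), n_chromosomes=2,
                        markers_per_chromosome=500, fst=0.02,
                        missing_rate=0.0, seed=8)
        ds, truth = simulate_dataset(cfg)
        reject = 0
        total = 0
        for h, herd in enumerate(ds.herd_ids()):
            rows = ds.indices_of_herd(herd)
            calls = ds.calls[rows]
            for j in range(0, ds.n_markers, 10):
                p = calls[:, j].mean() / 2
                if p < 0.05 or p > 0.95:
                    continue
                n = len(rows)
                expected = n * np.array(
                    [(1 - p) ** 2, 2 * p * (1 - p), p**2])
                observed = np.array([
                    (calls[:, j] == k).sum() for k in (0, 1, 2)])
                chi2 = ((observed - expected) ** 2 / expected).sum()
                reject += stats.chi2.sf(chi2, df=1) < 0.01
                total += 1
        assert total > 100
        assert reject / total <= 0.10

    def test_no_differentiation_limit(self):
        cfg = SimConfig(n_herds=6, herd_sizes=(60,) * 6, n_chromosomes=5,
                        markers_per_chromosome=1000, fst=0.0,
                        missing_rate=0.0, rare_fraction=0.0, seed=2)
        ds, _ = simulate_dataset(cfg)
        dosages, sizes = _herd_dosages(ds)
        assert abs(weir_cockerham_fst(dosages, sizes)) < 0.01

    def test_target_fst_realized(self):
        cfg = SimConfig(n_herds=6, herd_sizes=(60,) * 6, n_chromosomes=5,
                        markers_per_chromosome=1000, fst=0.05,
                        missing_rate=0.0, rare_fraction=0.0, seed=2)
        ds, _ = simulate_dataset(cfg)
        dosages, sizes = _herd_dosages(ds)
        assert 0.03 <= weir_cockerham_fst(dosages, sizes) <= 0.07

    def test_carrier_heterozygosity_at_least_h(self):
        h = 0.6
        cfg = SimConfig(n_herds=2, herd_sizes=(40, 40), n_chromosomes=1,
                        markers_per_chromosome=100, mean_spacing_bp=20_000,
                        missing_rate=0.0,
                        planted_islands=(
                            PlantedIsland(1, 500_000, 1_500_000,
                                          ("herd1",), h),
                        ),
                        seed=6)
        ds, truth = simulate_dataset(cfg)
        cols = np.flatnonzero(
            (ds.markers["position_bp"] >= 500_000)
            & (ds.markers["position_bp"] <= 1_500_000))
        rows = ds.indices_of_herd("herd1")
        het = (ds.calls[np.ix_(rows, cols)] == HET).mean()
        assert het >= h - 0.05

    def test_island_outside_map_rejected(self):
        cfg = SimConfig(n_herds=1, herd_sizes=(2,), n_chromosomes=1,
                        markers_per_chromosome=10,
                        planted_islands=(
                            PlantedIsland(1, 10**9, 2 * 10**9,
                                          ("herd1",), 0.5),),
                        seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_dataset(cfg)

    def test_tract_carriers_share_one_haplotype(self):
        cfg = SimConfig(n_herds=2, herd_sizes=(10, 10), n_chromosomes=1,
                        markers_per_chromosome=60, missing_rate=0.0,
                        planted_tracts=(
                            PlantedTract(1, 1, 10**9,
                                         carrier_herds=("herd2",)),),
                        seed=4)
        ds, truth = simulate_dataset(cfg)
        rows = ds.indices_of_herd("herd2")
        block = ds.calls[rows]
        assert (block == block[0]).all()
        assert np.isin(block, (0, 2)).all()


def test_missingness_rate_applied():
    cfg = SimConfig(n_herds=1, herd_sizes=(50,), n_chromosomes=2,
                    markers_per_chromosome=500, missing_rate=0.02, seed=9)
    ds, _ = simulate_dataset(cfg)
    rate = (ds.calls == MISSING).mean()
    assert 0.015 < rate < 0.025
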