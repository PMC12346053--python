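"""End-to-end orchestration: QC -> runs -> islands -> permutation null ->
summaries -> Tajima scan -> optional element enrichment.

Each stage writes its table under the output directory together with a run
log recording seeds, parameters and counts.  Outputs are deterministic for
a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hrrscan.genotype_io import GenomeBuild, QCParams, apply_qc, read_ped_map
from hrrscan.islands import call_islands, islands_to_frame, snp_incidence
from hrrscan.permutation import (
    PermutationConfig,
    build_null,
    significance_to_frame,
)
from hrrscan.runs import (
    HRR_50KB,
    HRR_250KB,
    ROH_250KB,
    RunParams,
    detect_all_runs,
    runs_to_frame,
)
from hrrscan.selection import (
    TajimaScanConfig,
    compare_enrichment,
    element_fraction,
    read_element_bed,
    scan_tajima,
    windows_to_frame,
)
from hrrscan.summaries import (
    HRR_50KB_CLASSES,
    HRR_250KB_CLASSES,
    class_counts,
    chromosome_rank,
    extended_het_coefficient,
    herd_mean_se,
    rank_correlations,
    ranks_to_frame,
)


@dataclass
class PipelineConfig:
    ped_path: str
    map_path: str
    out_dir: str
    build_path: str | None = None
    element_beds: dict[str, str] = field(default_factory=dict)
    maf_variant: str = "all"  # "all" | "maf01"
    scan: str = "50kb"  # "50kb" | "250kb"
    island_threshold: float = 0.4
    n_permutations: int = 200
    paper_mode: bool = False  # six permuted groups of sixty
    min_matched_groups: int = 3  # clamped to the number of groups
    significance_alpha: float = 0.05
    seed: int = 0
    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.05
    tajima_window_bp: int = 100_000
    tajima_sd_multiplier: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def qc_params(self) -> QCParams:
        return QCParams(
            max_snp_missing=self.max_snp_missing,
            max_ind_missing=self.max_ind_missing,
            min_maf=0.01 if self.maf_variant == "maf01" else None,
        )

    def hrr_params(self) -> RunParams:
        return HRR_50KB if self.scan == "50kb" else HRR_250KB

    def class_edges(self):
        return HRR_50KB_CLASSES if self.scan == "50kb" else HRR_250KB_CLASSES


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing TSVs plus a run log; returns the
    in-memory results keyed by stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    results: dict = {}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def finish() -> None:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    log(f"seed={config.seed}")
    log(f"maf_variant={config.maf_variant} scan={config.scan}")

    try:
        dataset = read_ped_map(config.ped_path, config.map_path)
        log(f"loaded {dataset.n_individuals} individuals x "
            f"{dataset.n_markers} markers")
    except Exception as exc:
        finish()
        raise StageError(f"load: {exc}") from exc

    try:
        dataset, qc_report = apply_qc(dataset, config.qc_params())
        qc_report.to_tsv(out / "qc_report.tsv")
        log(f"qc: {qc_report.n_markers_out} markers, "
            f"{qc_report.n_individuals_out} individuals retained")
        results["qc"] = qc_report
    except Exception as exc:
        finish()
        raise StageError(f"qc: {exc}") from exc

    build = (
        GenomeBuild.from_tsv(config.build_path)
        if config.build_path else GenomeBuild.bovine_autosomes()
    )
    build = GenomeBuild(
        lengths_bp={
            c: length for c, length in build.lengths_bp.items()
            if c in set(dataset.markers["chromosome"])
        }
    ).with_coverage(dataset.markers)
    results["build"] = build

    try:
        hrr_params = config.hrr_params()
        hrr_runs = detect_all_runs(dataset, hrr_params)
        roh_runs = detect_all_runs(dataset, ROH_250KB)
        herd_of = dataset.herd_of()
        runs_to_frame(hrr_runs, herd_of).to_csv(
            out / "runs_hrr.tsv", sep="\t", index=False)
        runs_to_frame(roh_runs, herd_of).to_csv(
            out / "runs_roh.tsv", sep="\t", index=False)
        log(f"runs: HRR params {dataclasses.asdict(hrr_params)}")
        log(f"runs: ROH params {dataclasses.asdict(ROH_250KB)}")
        log(f"runs: {len(hrr_runs)} HRR, {len(roh_runs)} ROH segments")
        results["hrr_runs"], results["roh_runs"] = hrr_runs, roh_runs
    except Exception as exc:
        finish()
        raise StageError(f"runs: {exc}") from exc

    try:
        observed_islands = []
        for herd in dataset.herd_ids():
            members = list(
                dataset.individuals.loc[
                    dataset.individuals["herd_id"] == herd, "individual_id"
                ]
            )
            track = snp_incidence(hrr_runs, dataset, members,
                                  group_id=herd, run_type="HRR")
            observed_islands.extend(
                call_islands(track, config.island_threshold))
        islands_to_frame(observed_islands).to_csv(
            out / "islands.tsv", sep="\t", index=False)
        log(f"islands: {len(observed_islands)} at threshold "
            f"{config.island_threshold}")
        results["islands"] = observed_islands
    except Exception as exc:
        finish()
        raise StageError(f"islands: {exc}") from exc

    significant = []
    try:
        if config.n_permutations > 0 and observed_islands:
            n_groups = len(dataset.herd_ids())
            perm_config = PermutationConfig(
                n_permutations=config.n_permutations,
                n_groups=6 if config.paper_mode else n_groups,
                group_sizes=(60,) * 6 if config.paper_mode else None,
                seed=config.seed,
                min_matched_groups=min(
                    config.min_matched_groups,
                    6 if config.paper_mode else n_groups,
                ),
            )
            sig = build_null(
                dataset, hrr_runs, observed_islands,
                config.island_threshold, perm_config,
            )
            frame = significance_to_frame(sig, perm_config.n_groups)
            frame.to_csv(out / "significance.tsv", sep="\t", index=False)
            significant = [
                r for r in sig
                if r.evaluable and r.p_empirical is not None
                and r.p_empirical < config.significance_alpha
            ]
            log(f"permtest: {config.n_permutations} permutations, "
                f"{sum(r.evaluable for r in sig)} evaluable, "
                f"{len(significant)} significant at "
                f"alpha={config.significance_alpha}")
            results["significance"] = sig
        else:
            islands_to_frame(observed_islands).assign(
                p_empirical="", evaluable=""
            ).to_csv(out / "significance.tsv", sep="\t", index=False)
            log("permtest: skipped (0 permutations)")
            results["significance"] = []
    except Exception as exc:
        finish()
        raise StageError(f"permtest: {exc}") from exc

    try:
        herd_of = dataset.herd_of()
        counts = class_counts(hrr_runs, config.class_edges(), herd_of)
        counts.to_csv(out / "class_counts.tsv", sep="\t")
        ranks = chromosome_rank(hrr_runs, build)
        ranks_to_frame(ranks).to_csv(
            out / "chromosome_ranks.tsv", sep="\t", index=False)
        ehc_rows = []
        for iid in dataset.individuals["individual_id"]:
            ehc_rows.append(
                {"individual": iid, "herd": herd_of[iid],
                 "coefficient": extended_het_coefficient(
                     hrr_runs, build, iid)}
            )
        ehc = pd.DataFrame(ehc_rows)
        ehc.to_csv(out / "extended_het.tsv", sep="\t", index=False)
        herd_means = ehc.groupby("herd", sort=False)["coefficient"].mean()
        mean, se = herd_mean_se(herd_means.to_numpy())
        log(f"summaries: extended het coefficient {mean:.4f} +/- {se:.4f}")
        run_share = np.array([r.n_runs for r in ranks], dtype=float)
        run_share /= run_share.sum()
        length_share = np.array(
            [build.length_share(r.chromosome) for r in ranks])
        if len(ranks) >= 3 and np.ptp(run_share) > 0:
            pr, pp, sr, sp = rank_correlations(run_share, length_share)
            pd.DataFrame(
                [{"pearson_r": pr, "pearson_p": pp,
                  "spearman_rho": sr, "spearman_p": sp}]
            ).to_csv(out / "correlations.tsv", sep="\t", index=False)
        results["class_counts"] = counts
        results["ranks"] = ranks
        results["extended_het"] = ehc
    except Exception as exc:
        finish()
        raise StageError(f"summarize: {exc}") from exc

    try:
        sig_chroms = sorted({r.island.chromosome for r in significant})
        tajima_windows, tajima_report = [], pd.DataFrame()
        if sig_chroms:
            sig_herds = {r.island.group_id for r in significant}
            all_windows, reports = [], []
            for herd in sorted(sig_herds):
                members = list(
                    dataset.individuals.loc[
                        dataset.individuals["herd_id"] == herd,
                        "individual_id",
                    ]
                )
                herd_chroms = sorted({
                    r.island.chromosome for r in significant
                    if r.island.group_id == herd
                })
                w, rep = scan_tajima(
                    dataset, members,
                    TajimaScanConfig(config.tajima_window_bp,
                                     config.tajima_sd_multiplier),
                    chromosomes=herd_chroms,
                )
                rep.insert(0, "herd", herd)
                all_windows.extend(w)
                reports.append(rep)
            tajima_windows = all_windows
            tajima_report = pd.concat(reports, ignore_index=True)
            windows_to_frame(tajima_windows).to_csv(
                out / "tajima_windows.tsv", sep="\t", index=False)
            tajima_report.to_csv(
                out / "tajima_report.tsv", sep="\t", index=False)
            log(f"tajima: scanned chromosomes {sig_chroms}")
        else:
            log("tajima: no significant islands, scan skipped")
        results["tajima_windows"] = tajima_windows
        results["tajima_report"] = tajima_report
    except Exception as exc:
        finish()
        raise StageError(f"tajima: {exc}") from exc

    try:
        if config.element_beds:
            elements = {
                etype: read_element_bed(path, etype)
                for etype, path in config.element_beds.items()
            }
            hrr_records, roh_records = [], []
            for isl in observed_islands:
                hrr_records.extend(element_fraction(isl, elements))
            roh_islands = []
            for herd in dataset.herd_ids():
                members = list(
                    dataset.individuals.loc[
                        dataset.individuals["herd_id"] == herd,
                        "individual_id",
                    ]
                )
                track = snp_incidence(roh_runs, dataset, members,
                                      group_id=herd, run_type="ROH")
                roh_islands.extend(
                    call_islands(track, config.island_threshold))
            for isl in roh_islands:
                roh_records.extend(element_fraction(isl, elements))
            rows = []
            for etype in elements:
                try:
                    p = compare_enrichment(hrr_records, roh_records, etype)
                except ValueError:
                    p = float("nan")
                rows.append({"element_type": etype, "p_mwu": p})
            pd.DataFrame(rows).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
            log(f"enrich: compared {len(elements)} element types")
            results["enrichment"] = rows
    except Exception as exc:
        finish()
        raise StageError(f"enrich: {exc}") from exc

    finish()
    return results
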