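# Methods

This note documents the statistical procedures implemented in `hrrscan`,
the conventions chosen where several readings were possible, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Genotype model and QC

Genotypes are biallelic SNP-array calls held as a 4-state matrix
(hom-A / het / hom-B / missing), with 1-based inclusive coordinates
(PLINK MAP convention) and allele A defined as the alphabetically smaller
observed allele so that a write/read cycle is a fixed point.  The sixth
PED column (pseudo-phenotype) is treated as an opaque string and never
parsed numerically: permuting these labels is how individuals are permuted
among groups, and labels such as `2.1` exist precisely to avoid collision
with reserved phenotype codes.

QC is order-dependent and applied in a fixed sequence: non-autosomal
markers are dropped, then markers with missingness > `geno` (default
0.05), then individuals with missingness > `mind` (default 0.05), then —
only in the "MAF-removed" variant — markers with MAF < 0.01.  MAF is
computed over non-missing alleles only (the convention of the standard
tooling).  Applying QC twice is a no-op.  Intensity-level call quality
(pre-PED filtering) is upstream of this package and out of scope.

## Consecutive-runs detection

A run is a maximal stretch of consecutive markers matching the target
state (heterozygous for HRR; either homozygote for ROH), scanned greedily
left to right within each chromosome.  Tolerances: up to `max_missing`
missing calls (default 1) and `max_opposite` opposite calls (default 0, as
both scans specify) in the run's interior; an inter-marker gap > 1 Mb
breaks the run.  Runs start and end on target calls; missing/opposite
calls never count toward the SNP minimum.  Candidates are accepted when
they hold ≥ `min_snps` target SNPs (HRR 5, ROH 10) **and** span
≥ `min_length_bp` (HRR 50 kb or 250 kb; ROH 250 kb).

Conventions worth noting:

* **Run length is `end − start`**, not `end − start + 1`: the published
  island tables reproduce their printed kb lengths under exactly this
  arithmetic (e.g. 66,630,647 − 66,483,743 = 146,904 → 146.9 kb).
* Two accepted runs separated by a single disallowed call stay separate;
  there is no post-merging.
* The scan is greedy-leftmost: a candidate is the longest extension of the
  first target call at or after the previous candidate's end, which
  guarantees non-overlapping runs per individual.  The test suite checks
  this against an exhaustive window-enumeration oracle on random inputs.

Removing near-monomorphic SNPs (which are overwhelmingly homozygous in
every individual) deletes interrupting opposite calls inside heterozygous
stretches; fragments merge into acceptable runs and the HRR count rises.
This qualitative effect is asserted on simulated fixtures.

## Islands and their permutation significance

Per-SNP incidence for a group is the fraction of members whose accepted
runs cover the SNP.  An island is a maximal stretch of consecutive SNPs
with incidence ≥ a threshold (default 0.4; a top-quantile mode, e.g. the
0.999 incidence quantile, is available since the literature uses both
styles of criterion).  Island support is the **peak** (not mean) incidence
inside the island — the published per-island proportions behave as maxima
— and island boundaries are member-SNP positions.

Significance follows a genotype-permutation design.  Individuals are
shuffled uniformly (counter-based RNG: each replicate derives its stream
from (seed, replicate), so any replicate is independently reproducible)
and split into groups; by default the groups are the observed herd sizes
so nobody idles, and a paper-mode uses six groups of sixty.  Within each
permuted group, incidence is a row-mean over a **precomputed** run-coverage
matrix — an individual's runs do not depend on its group, so runs are
detected exactly once — and islands are re-called and matched to each
observed island by largest interval overlap.

Two p-values are reported per island:

* `p_empirical = (1 + #{matched permuted support ≥ observed}) /
  (1 + #matched)` over all replicates and groups — the primary statistic.
* `p_mwu`: an exact Mann–Whitney U (full enumeration up to combined n = 20,
  midranks for ties; tie-corrected normal approximation beyond) of the
  observed support against the per-group mean matched supports, mirroring
  how such studies print one permuted column per group.  One observed value
  against six group means cannot fall below 2/7 two-sided, which is why the
  empirical p is primary.

Per-group aggregation (mean over the replicates in which that group index
matched) is a documented interpretation: thousands of permutations must
collapse to one printed value per group, and a per-group mean is the
reading consistent with a mean ± SE row over six columns.  Islands matched
in fewer than `min_matched_groups` (default 3, clamped to the number of
groups) permuted groups are *not evaluable* and carry no p-values — the
same phenomenon the study reports for islands absent from its permuted
sets.

Because matched supports live on a lattice (multiples of 1/group-size) the
empirical p is discretely conservative; the calibration test uses groups
of 200 so supports are nearly continuous, and verifies that under a fully
exchangeable simulation the fraction of islands with p < 0.05 stays near
the nominal rate.

## Herd aggregation, length classes, ranks

All "mean ± SE across herds" cells use the arithmetic mean of the six herd
values and sample SD (n − 1) / √6.  This convention reproduces the
published per-class count rows and per-island support rows to their
printed precision; the ± values of the two per-cow run-count tables do
**not** match it (nor SD, nor SE of per-cow values) and are left
undocumented rather than guessed at.

Run length classes are half-open in Mb — {0.05–0.2, 0.2–0.4, 0.4–0.8,
0.8–1.6, >1.6} for the 50 kb scan, {0.25–0.4, 0.4–0.8, 0.8–1.6, >1.6} for
the 250 kb scan — and class proportions are class means over their sum.

The chromosome rank is `(N_i/T) / (L_i/L_genome)` (share of runs over
share of genome length; 1 = proportional saturation), with chromosomes
deviating from the mean rank by more than 2 SD of the rank distribution
flagged.  The coefficient of extended heterozygosity is the individual's
total HRR length divided by the SNP-covered autosome length, where
"covered" is Σ per chromosome (last SNP − first SNP) on the post-QC map —
the only computable reading.  Bundled bovine autosome lengths (ARS-UCD)
serve as the default genome build; any 2-column TSV can be supplied, and
simulated maps derive a build from their own marker spans.

## Tajima's D scan

Genotypes of N diploids are treated as n = 2N sequences through per-site
allele frequencies: π = Σ 2p(1−p)·n/(n−1), θ_W = S/a₁, and
D = (π − θ_W)/√(e₁S + e₂S(S−1)) with the standard constants.  D is
undefined (NaN, never flagged) when S = 0.  Windows are 100 kb, anchored
at zero, half-open, non-overlapping; every post-QC SNP falls in exactly
one window.  Per chromosome the scan reports the SD of defined D values,
a threshold of 3·SD, the count of windows with **D > 3·SD** and the
maximum D.  The positive-tail reading (candidates for balancing
selection) is implemented; the source text's phrase "less than 3 SD" is
inconsistent with its own results table, whose "Number of Regions
Exceeding 3 SD" column matches 3 × SD of a near-zero-mean distribution.
The SD uses the n−1 denominator.  No demographic correction is applied.

## Element coverage

Repeat-element intervals arrive as BED (0-based half-open) and are
converted to the pipeline's 1-based axis.  Per element type, intervals are
merged before intersection (order- and fragmentation-invariant), and the
coverage fraction is merged-overlap bp / island length with the island
occupying [start, end) — consistent with length = end − start.  Island
classes are compared per element type with the same exact Mann–Whitney
used elsewhere.  The published per-island element fractions are not
available, so only the procedure — not the printed p-values — is
reproducible.

## Synthetic data

The generator emulates the shape of the study panel: six herds sized
57/85/73/44/58/54 (371 individuals as printed; the source text's "366
cows" disagrees with its own per-herd sizes), 29 autosomes, ~50 kb mean
marker spacing with gamma-distributed gaps (so the 1 Mb gap rule is
exercised), ~10% of markers with ancestral MAF < 0.01, genotyping
missingness 0.005, and Balding–Nichols herd frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at F = 0.05 by default (within the published
pairwise-Fst range 0.003–0.12; the realized Weir–Cockerham estimate is
checked against an independent oracle in tests).  Genotypes are
Hardy–Weinberg within herds.  Planted heterozygote islands set carriers
heterozygous with probability h per marker; planted homozygous tracts give
carriers one shared haplotype.  A truth table records every planted
feature.

What the generator does **not** emulate: linkage disequilibrium outside
planted features (markers are independent), realistic bovine recombination
or LD maps, pedigree structure, array intensity artifacts, and
chromosome-specific marker densities (all chromosomes share one span).
Passing tests therefore demonstrate correctness of the algorithms under a
clean generative model, not robustness to real-array LD structure.

## Problem sizes

The bundled fixtures are 2 herds × 10 individuals × 200 markers.  The
property suites use: 120 random 30-marker instances for the run-detection
oracle; 100 seeded replicates of a 6-herd × 400-marker panel for planted
island recovery (h = 0.6, threshold 0.4, ≥ 95% recovery); a 1200-
individual, 8000-marker exchangeable panel with 200 permutation replicates
for p calibration; and 50 random windows for the Tajima oracle (agreement
to 1e-9).  The acceptance script simulates the full 371 × ~48k panel with
300 permutation replicates.  These sizes keep the whole suite at about
15 s and the acceptance run under a minute on one CPU while leaving each
check statistically meaningful.

## Known limitations

* The exact construction behind the published per-island Mann–Whitney
  p-values (as small as 0.002 from six permuted values) cannot be
  reproduced; the empirical permutation p is reported as primary.
* The island-calling criterion of the source study is unstated; the fixed
  incidence threshold (0.4) is a documented choice, with the top-quantile
  alternative provided.
* Binary PLINK (BED/BIM/FAM), sex chromosomes, and gene annotation of
  islands are out of scope.
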