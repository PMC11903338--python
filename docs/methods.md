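# Methods

## Quantitative scaling model

The package treats a surface swab sample as a two-part measurement: a
relative composition (amplicon read proportions over ASVs) and an
independent total-abundance anchor (qPCR of total 16S rRNA gene copies).
The absolute abundance of taxon *a* in sample *s* is

    A(s, a) = reads(s, a) / Σ_a reads(s, ·) × N(s),

with N(s) the surface copy density

    N = n · C · V / (c · v · S).

Assumptions worth stating: swabbing recovers a constant fraction of the
standing community per cm²; DNA extraction and amplification do not
differ systematically between taxa (16S copy-number variation between
genomes is *not* corrected — abundances are gene copies, not cells,
unless divided by an operon count); and the qPCR and sequencing primer
pairs target the same underlying community. Extracts below the 0.5
ng·µL⁻¹ normalisation target are assumed to have entered the reaction
undiluted, so their effective input concentration is the extract
concentration itself (`c = C`, collapsing N to `n·V/(v·S)`).

Assay constants default to V = 50 µL, c = 0.5 ng·µL⁻¹, v = 1.5 µL,
S = 50 cm². Replicate qPCR wells are averaged on the copies scale, not
the Cq scale, because copies are the linear-scale quantity entering N. A
plausibility window of [10³, 10⁹] copies cm⁻² raises a flag but never
rejects: two orders of magnitude of legitimate variation are expected on
macroalgal surfaces (~10⁵–5·10⁷ copies cm⁻²).

## Filtering

Organellar removal is a pure column predicate: any lineage containing
Cyanobacteria, Chloroplast, Mitochondria or Eukaryota (case-insensitive,
any rank) is dropped. Contaminant identification follows the
negative-control prevalence rule; all three clauses must hold:

1. non-zero reads in at least one negative control;
2. frequency among real samples ≤ `max_freq` (default 11);
3. maximum per-sample relative abundance among real samples ≤ `max_relab`
   (default 1.5%).

The defaults are the observed maxima of a real application of this rule
and are deliberately configuration, not constants. Contaminant evidence
is evaluated on the post-organellar table, and on reads (not scaled
abundances), because negative controls have no qPCR anchor. Since both
filters drop columns only, their retained set is order-invariant whenever
decision margins are stable; the contaminant report header records the
order actually used.

Genus pooling sums ASV columns sharing a genus label; ASVs with an empty
label at the pooled rank are excluded from the pooled table and reported
separately, so mass is conserved up to the reported excluded part. This
mirrors the default behaviour of standard rank-agglomeration tools.

## Occupancy–redundancy core index

For one tissue, presence is `abundance ≥ detection_threshold` (default 1
read; configurable because absolute matrices are real-valued), organised
as taxon × month × replicate with missing design slots marked missing,
never absent. Monthly occupancy is the mean presence over *available*
replicates; redundancy is 1 iff the taxon is present in *all available*
replicates. The index is Σ_m (O_m + R_m) / (2·n_months).

Two deliberate choices:

* the scaling denominator is the theoretical maximum 2·n_months, not the
  observed maximum, so an always-present taxon scores exactly 1;
* months with a replicate deficit (two swabs instead of three) use all
  available replicates in both terms — a missing swab should not cap a
  taxon below 1.

Core classification requires index > threshold (strict; ties lose) on
every algal species, with the three *L. digitata* blade regions averaged
into one host column. The 0.65 default is an empirical cut on the index
distribution of the motivating dataset, not a derived constant; it is
exposed in configuration and in the CLI.

## Host-specificity sets

Set membership is detection (≥ 1 read) aggregated across all samples of a
host, with the three Ldig tissues collapsed to one host, giving exact
exclusive counts over the 2⁵−1 host subsets. Pair classes for the
shared-ASV analysis: intra-species (same brown algal species, including
pairs across Ldig blade regions), intra-phylum (different brown algae),
inter-phylum (brown vs. red/green). Pairs among the red and green algae
themselves fall outside this three-way scheme and are excluded from the
rank tests (they carry a null class in the pair table). All
same-level sample pairs enter the comparison; no per-month subsetting.

## Permutation statistics

PERMANOVA partitions squared Bray–Curtis dissimilarities:
SS_total = Σ_{i<j} d²_ij / N, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
pseudo-F = (SS_between/(k−1)) / (SS_within/(N−k)). The p-value permutes
whole sample labels with p = (1 + #{F_π ≥ F_obs}) / (1 + P), so p is
never 0 and is uniform on {1/(P+1), …, 1} under exchangeability (verified
by simulation: 1,000 null datasets × 99 permutations give a 4–5%
rejection rate at α = 0.05). All permutation procedures take an explicit
seed and are bit-reproducible; pairwise tests use seed + pair-index so a
two-group pairwise call reduces exactly to the omnibus test. Degenerate
inputs: SS_within = 0 yields an infinite F with a warning rather than an
error.

Dispersion embeds the distance matrix by principal coordinates; negative
eigenvalues (Bray–Curtis is generally non-Euclidean) are retained as
imaginary axes whose contribution is subtracted from squared distances to
group centroids, clipped at zero. The homogeneity test is an ANOVA-type F
over the distances with a label-permutation null. Centroids are means in
the embedding (not spatial medians).

Environmental pruning computes all pairwise Pearson correlations
(complete-case per pair), BH-adjusts the p-values, then removes variables
greedily — highest maximum |r| first, ties broken alphabetically — until
no retained pair has adjusted p < α (0.05) and |r| ≥ 0.8. The greedy rule
is a reproducible stand-in for what is usually a manual judgement; the
full correlation report is returned so the choice can be audited.
Constant variables have undefined correlations and are kept, flagged.

## Synthetic-data generator

The generator reproduces the structure the analyses assume, not real
sequence data. Defaults mirror the motivating study design: 7 tissues ×
10 months × 3 replicates with the two known 2-replicate deficits (208
samples) plus 2 negative controls; total loads log-normal around
10^6.85 ≈ 7·10⁶ copies cm⁻² (log₁₀ sd 0.4) clamped to [10⁵, 5·10⁷];
extract concentrations log-normal around ~7 ng·µL⁻¹ spanning
0.11–41.5 ng·µL⁻¹ so the undiluted qPCR path is exercised; sequencing
depth 20,000 reads; qPCR noise log-normal with log-sd 0.2.

Planted roles: 10 core genera (two ASVs each, so genus pooling is
exercised) present in every sample; 2 host-specific genera per host with
zero abundance off-host; 6 seasonal genera with an 8-fold abundance
multiplier in their season and only sporadic (35%) detection off-season —
year-round presence would make them indistinguishable from core taxa by
an occupancy criterion, which is exactly the boundary the recovery tests
probe; 120 sparse background genera (15% occurrence); 3 chloroplast-like
organellar ASVs; 10 contaminants planted in all controls and in 5 real
samples each at ~0.5% relative abundance, inside the filter's default
bounds. A separate constructed fixture holds one taxon at constant
absolute abundance while total load rises 5× into summer, operationalising
the compositional artifact: the quantitative fold-change estimate stays
near 1 while the relative-only estimate collapses to ~1/5.

What the generator does **not** emulate: sequence-level error, chimeras,
PCR bias, taxon-specific extraction efficiency, spatial autocorrelation
between replicates, and realistic rank-abundance tails. Passing recovery
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to those real-data pathologies.

## Problem sizes and numerics

The test suite runs the full 208-sample design for recovery checks and
smaller designs (2–3 tissues, 4 months) for orchestration tests;
permutation calibration uses 1,000 simulated 24-sample datasets with 99
permutations each, and exhaustive enumeration on 6 samples cross-checks
the sampler. Tolerances: absolute-abundance row sums match loads to 1e-6
relative; standard-curve round-trips to 1e-9 relative; dispersion against
the planar closed form to 1e-8 absolute. TSV floats are written with 12
significant digits, which round-trips IEEE doubles for these magnitudes.

## Known limitations

* Single-factor PERMANOVA only; no nested/two-way designs or residual
  permutation schemes.
* No ordination (NMDS/dbRDA) — distance matrices are exported for
  external tools; no differential-abundance model.
* The contaminant rule is the prevalence heuristic, not a mixture model.
* Copies-to-cells conversion assumes one global operon count; real
  communities mix genomes with 1–15 operons.
* The sparse "BIOM-style" input dialect is a plain TSV triplet format,
  not the binary BIOM container.
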