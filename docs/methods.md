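# Methods

This note documents the statistical models implemented in `durumwp`, the
choices made where the methodology was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Phenotype processing

**Yield components.** Grains per m² is derived as
`Gr.m⁻² = harvested_weight / (plot_area × TKW/1000)` with weight in grams,
area in m² and TKW (1000-kernel weight) in grams; grains per spike is
`GpS = Gr.m⁻² / Spk.m⁻²`. Missing inputs leave the component absent for that
plot (logged), never an error, and a measured GpS is never overwritten.
Missing plot observations are dropped listwise per trait; no imputation.

**BLUEs.** Genotype means are adjusted per environment by ordinary least
squares with genotype fixed. For the augmented design, block effects are
identified by the replicated checks (sum-to-zero block coding; the OLS
solution coincides with the classic check-based additive adjustment when
test entries are unreplicated), and every block must contain a check — a
block without one is a design error, reported by name. For the
alpha-lattice, replicate and incomplete-block effects enter the same way.
Standard errors come from the OLS covariance with σ² estimated from the
residual mean square; with zero residual degrees of freedom the SE is 0.

**Variance partition.** G, E, G×E and residual sums of squares are computed
from cell means and counts (exact for balanced data, sequential for mildly
unbalanced layouts); shares are SS over total SS. Note that with
unreplicated test entries (augmented design) the plot residual is
inseparable from G×E and is absorbed there — the replicated alpha-lattice
separates all four components. Broad-sense heritability per environment is
the replicate-based formula H² = σ²g/(σ²g + σ²e/r) with components from the
one-way genotype ANOVA; REML variance components are deliberately out of
scope (the closed form is deterministic and testable).

**Scaling and correlations.** Yield potential across environments of very
different productivity is compared as the ratio to the top entry per
environment, averaged over environments. Trait–yield correlations are
Pearson r with two-sided t tests on n−2 df, starred at P < 0.001; absent or
constant traits print "-".

## Climate matrix and mega-environments

The climate table carries five growth-stage windows (pre-sowing,
vegetative, flowering, grain-fill, maturity) per variable. Environment-mean
yield is regressed on each (stage, variable) factor by simple OLS; factors
with P < 0.05 are retained, standardized, projected on principal components
keeping ≥ 80% of the variance (configurable), and environments are
clustered by Ward linkage cut at k = 2. Ward on PC scores is the
conventional default of the factor-analysis tooling family this follows.
The cluster with lower mean total moisture is labelled *moisture-stressed*
— a deterministic labelling rule replacing manual annotation, so the
stressed-group mean is lower by construction. With k = 1 the single group
is labelled against a 400 mm pivot.

## AMMI and the wide-adaptation index

The two-way genotype × environment table (missing cells filled by
row+column expectation iterated to 1e-6) is fitted additively; the SVD of
the doubly-centred residual gives interaction principal components, with
genotype and environment scores each scaled by √λ so their products
reconstruct the interaction exactly (checked to 1e-8). sᵢ = λᵢ²/Σλ² is the
share of G×E variance on axis i. Axis significance uses an F test with
Gollob degrees of freedom dfₖ = (g−1)+(e−1)−(2k−1), against the pooled
plot-level error when available and otherwise against the pooled trailing
axes; a non-trivial axis with an exactly rank-deficient tail counts as
significant. Significant axes are the leading run that passes at α = 0.05
(configurable).

AWAI_g = Σ sᵢ·|PCᵢ,g| over the significant axes; 0 marks the most widely
adapted genotype. Because the index is also conventionally reported on a
0–1 scale with 1 best, the ratio-to-min form min(AWAI₊)/AWAI (clipped to
[0,1], zero-AWAI genotypes mapped to 1) is emitted alongside the raw value;
the raw value is primary. The selection surface flags genotypes strictly
above the mean ratio-to-max yield and strictly below the mean AWAI.

## Water productivity classes

WP = GY / total moisture (kg ha⁻¹ per mm). Group slopes are the OLS slope
of environment-mean yield on moisture within each mega-environment
(≥ 3 environments required); the defaults 5.08 (stressed) and 4.85
(non-stressed) are available as frozen replication values, with
recomputation from data the default. Each genotype's per-environment BLUEs
are regressed on moisture within each group, giving b_i, r² and p per
group. Classification:

| class | name | stressed | non-stressed |
|---|---|---|---|
| 1 | Stable water response | b_i ≤ b_group | b_i ≤ b_group |
| 2 | Responsive to low moisture | b_i > b_group | b_i ≤ b_group |
| 3 | Responsive to high moisture | b_i ≤ b_group | b_i > b_group |
| 4 | Highly water responsive | b_i > b_group | b_i > b_group |
| 5 | No water response | overall regression P ≥ α (default 0.01) | |

Exact ties sit on the "≤" side (deterministic tie-break). The
unresponsiveness gate is the genotype's *single* regression of yield on
moisture over all environments: requiring both within-group regressions to
clear P < 0.01 instead proves far too conservative at realistic network
sizes — with seven wetter environments a df = 5 regression needs r² ≈ 0.77,
and most genuinely responsive genotypes would land in class 5. Slopes are
tested against zero, not against the group trend. Genotypes seen in fewer
than three environments in a group are reported unclassifiable with a
reason, never silently dropped.

## Association mapping

**Curation.** Markers with missing rate ≥ 1%, MAF < 5% or heterozygosity
> 5% are removed, with per-filter counts reported.

**Structure and kinship.** Q covariates are leading principal components of
the centred dosage matrix (count chosen at the explained-variance elbow by
default, capped at 10); K is the VanRaden genomic relationship matrix
M M′ / 2Σp(1−p), symmetric PSD.

**LD decay.** Within-chromosome pairwise allelic r², binned by physical
distance; an exponential a·e^(−d/τ) + c is fitted to the binned means and
the LD distance is where the fitted curve crosses the critical r²
(fallback: first binned crossing). The QTL merge distance defaults to twice
this estimate; the 102.6 Mbp default of the reference network is available as frozen
configuration.

**Models.** GLM_Q regresses the phenotype on each marker with intercept, Q
and covariates (days to heading by default, to avoid rediscovering
phenology loci); the scan is vectorised by projecting covariates out of
phenotype and dosages once. MLM_QK adds one random polygenic term with
covariance K; the variance ratio is profiled once on the null model via the
eigendecomposition of K and reused for every marker (the
population-parameters-previously-determined approximation — exact
per-marker REML is out of scope for speed), after which each marker is a
weighted regression in the rotated basis. With K = I the MLM reproduces the
GLM exactly. `auto` runs both and keeps the model whose genomic inflation
factor λ (median χ² ratio) is nearer 1 — an operationalisation of visual
Q–Q plot comparison. Marker r² is the incremental r² after covariates;
missing dosages are mean-imputed for association only, never for curation
statistics. An MTA must clear both the LOD and the r² gate.

**QTL.** Same-chromosome MTAs closer than the merge distance are chained by
single linkage into one locus (so a chain 10–100–190 Mbp under a 102.6 Mbp
rule is one QTL spanning 180 Mbp — a documented consequence of
transitivity). A QTL is *consistent* when its members include a
combined-context association and more than one individual environment, and
a *true positive* when an independent panel's QTL overlaps its span
(closed, 1-based bp intervals). The representative marker has the highest
LOD, ties broken by higher r² then lower position.

## Haplotypes and marker validation

Genotypes are partitioned by their +/− pattern at the representative
markers ("+" = homozygous favorable, with the favorable allele inherited
from the discovery-panel effect sign and never re-estimated in validation
panels); heterozygous or missing calls exclude a genotype, logged.
Haplotypes are numbered by descending favorable-allele count then
lexicographic pattern. Group effects use a one-way fixed-effects fit with
pairwise LSD = t(1−α/2, df) · √(MSE(1/nₐ+1/n_b)) (unequal-n form) and an
insert-and-absorb compact letter display.

Validation over phenotypic extremes: genotypes ranked by yield (ties broken
by id, deterministically), top n = positives, bottom n = negatives (n = 20
by default); carrying the favorable allele predicts positive. Standard
confusion-matrix definitions are used — accuracy (TP+TN)/2n, sensitivity
TP/n, specificity TN/n — because the alternative reading with denominator
2n (available behind `pooled_denominator`) makes the three metrics
non-comparable. On balanced extremes accuracy = (sensitivity+specificity)/2
identically. The AND-rule over a marker set can only lower sensitivity and
raise specificity relative to its members.

## Synthetic data

`simdata` generates inbred-line genomes and trial networks with the target
statistical structure:

- **Genomes**: per-marker ancestral frequencies drifted between
  subpopulations (Balding–Nichols, Fst-like `subpop_drift` = 0.15); founder
  haplotypes are Markov chains along each chromosome (allele persistence
  e^(−d/L)) and each line is a founder mosaic, inducing LD on the scale of
  `ld_block_length` (30 Mbp default; the measured decay distance recovers
  it within a factor of ~1.5). Haplotypes are doubled (inbreds), ~2% of
  calls made heterozygous, and a built-in curation pass enforces the
  MAF/het/missing rules; deliberately violating markers can be appended to
  exercise downstream curation.
- **Trials**: plot yield = grand mean (3500 kg/ha) + genotype effect +
  environment effect affine in moisture with a distinct slope per moisture
  group (5.08/4.85 defaults, continuous at the 400 mm pivot) +
  genotype-specific slope deviation × centred moisture + unstructured G×E
  noise + QTL main and QTL×moisture effects + block effect + residual.
  Variance components default to shares (E, G, G×E, resid) =
  (0.73, 0.10, 0.12, 0.05) — the E-dominant structure of Mediterranean
  networks — and the non-E components are rescaled against the realized
  moisture-driven E variance so the *shares* hold regardless of the
  moisture spread. QTL variance counts against the G and G×E budgets.
  `gxe_slope_share` = 0.15 of G×E goes to systematic slope deviations
  (sd ≈ 1.5 kg/ha/mm, the scale at which responsiveness classes separate);
  the rest is iid. The moisture layout is quantile-matched to a real
  18-environment Mediterranean network (11 environments below 400 mm,
  7 above). Secondary traits (TKW, SPK, DTH) share a configurable genetic
  correlation (0.5) with yield.
- **`simulate_wp_panel`** plants genotypes in each responsiveness class at
  ±1.5 kg/ha/mm around the group slopes plus flat (class-5) genotypes, with
  Gaussian noise of 100 kg/ha on per-environment genotype means — the
  precision (~3% CV) of a replicated-trial BLUE. Classification recovery is
  sensitive to this noise: at ~5% CV the significance gate begins rejecting
  genuinely responsive low-slope genotypes.

All draws come from one explicitly threaded `numpy.random.Generator`; a
fixed seed gives byte-identical output. Not emulated: meiosis/pedigree
structure, spatial field trends, weather generation, and any correlation
between climate variables beyond their common dependence on total moisture
— so passing tests demonstrate the statistical machinery, not robustness to
spatial artefacts or real weather covariance.

## Problem sizes and numerics

The test suite and the acceptance script run synthetic networks of up to
200 genotypes × 18 environments with 500–1200 markers, and calibration
studies of 20 seeds × (200 × 500) null scans — sizes at which every
quantity of interest (variance shares, slopes, class recovery, type-I
error, power, LD scale) is stable to well within the asserted tolerances.
Two-way imputation converges at 1e-6; SVD reconstruction is asserted at
1e-8; eigenvalues of K are clipped at −1e-8 for PSD checks; the MLM
variance ratio is profiled on log δ ∈ [−10, 10]. Ties are always broken
deterministically (documented per operation).
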