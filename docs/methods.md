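# Methods

This note documents the statistical models implemented in `poolgwas`, the
synthetic-data generator used to exercise them, the numerical choices,
and the limits of what the tests demonstrate.

## Phenology

Daily thermal time is `max(0, T̄ − T_base)` with `T_base = 1 °C` and `T̄`
the daily mean air temperature. Intervals are half-open in days,
`[from, to)`: the start day contributes, the event day does not. This
convention makes thermal time exactly additive over adjacent intervals
and is asserted by a property test; field protocols are usually silent on
the boundary day, so the choice is documented rather than inferred.
Degree-day models sometimes use a min/max or optimum/ceiling formulation
(hemp growth has an optimum near 29 °C and a ceiling near 41 °C); here
the daily mean with a base-temperature clamp is used, and an optional
ceiling cap is available but off by default, since the trait definitions
reference only the base temperature.

Plots whose plants never flowered keep missing flowering traits; they are
never imputed with season-end values, because that would fabricate
censored observations. Accession × location values are arithmetic means
over plots with data. The sex score is the plot mean of {1, 2, 3} and is
treated downstream as a continuous response in the same mixed model; the
bounded, ordinal nature of the scale is a known approximation.

## Genotypes and QC

A pool-seq genotype is the proportion of the panel-major allele in a DNA
pool of `pool_size` plants (default 8, i.e. 16 haplotypes), a continuous
dosage in [0, 1]. The panel-major allele is the allele with the largest
mean frequency over accessions, ties broken by the fixed order
A < C < G < T and logged.

SNP selection applies four rules in a fixed order (call rate 1.0;
top-two-allele frequency sum ≥ 0.95; minor allele frequency ≥ 0.02;
standard deviation of the major-allele proportion ≥ 0.1). The order only
affects the per-rule removal counts in the report; the surviving set is
order-free, which the tests assert implicitly via a brute-force predicate
oracle. The biallelic rule needs the top-two allele frequency sum, which
a matrix of major-allele proportions alone cannot supply; it is carried
as optional marker metadata (`top2_sum`) by the four-allele scoring step,
and passes trivially for inputs that arrive already scored.

Kinship is the VanRaden genomic relationship matrix on the 0–2 dosage
scale (dosage = 2 × proportion), `K = ZZ′ / (2 Σ p_j(1−p_j))`, with
fixed markers excluded. On individual-like genotypes the mean diagonal is
≈ 1; pooled frequencies compress within-accession variance, so the
absolute scale of K is smaller — harmless for the mixed model, which
estimates a free variance multiplier.

The effective number of independent tests M_eff uses the Li–Ji
eigenvalue formula, Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)], applied per
scaffold in windows of at most 200 markers and summed. Eigenvalues are
rounded to 8 decimals before flooring because the formula is
discontinuous at integers and duplicate-marker blocks land exactly
there. The windowed sum is not identical to Li–Ji on the full matrix
when sampling noise moves an eigenvalue across an integer (an intrinsic
property of the formula, demonstrated in the tests); within one scaffold
and window it is exactly the full-matrix value.

## Mixed-model scan

REML for `y = μ1 + u + e`, `u ~ N(0, σ_g²K)`: eigendecompose K once,
rotate, and profile the criterion over log₁₀ δ (δ = σ_e²/σ_g²) on a grid
from −5 to 5 at 0.1 spacing, then refine with bounded Brent to
|Δlog₁₀ δ| < 1e−6; the refined optimum is never allowed to fall below
the grid's best point. The log-likelihood includes the −log|X′X| REML
constant so it matches textbook dense evaluations exactly; the test
suite checks agreement with a dense, no-eigen-shortcut implementation to
1e−6.

Markers are tested by GLS in the rotated space at the null-model δ (the
standard "population parameters previously determined" shortcut); a flag
re-estimates δ per marker, verified against a dense per-marker REML
oracle. The Wald statistic uses the residual-rescaled GLS standard
error with χ²(1) reference; the reference distribution is a modelling
choice, as is 1 df for the single marker effect. Markers collinear with
the intercept after rotation (relative determinant below 1e−10) are
flagged unusable and never significant. p-values below the smallest
positive double are reported at that representable limit. Missing
phenotypes are dropped case-wise per trait × location, and each
trait × location is analysed independently; G×E is handled downstream by
cross-location consolidation, not by interaction terms.

Calibration diagnostics: a seeded sample of 3,000 records is compared to
uniform order statistics, with the genomic inflation factor
λ_GC = median(Wald)/0.4549 and a Kolmogorov–Smirnov statistic as
summaries. On a structured null panel the kinship-corrected scan is
calibrated (empirical type-I ≈ 0.05) while the uncorrected scan is
grossly anticonservative — the package's equivalent of the classic
corrected-versus-naive cumulative p-value contrast.

## MultiQTL modelling

"Explains the largest phenotypic variance" is read as incremental
(conditional) r² during forward selection, which at the first step
equals the largest marginal r²; ties break by larger Wald, then
lexicographic marker id. Collinearity uses Pearson |r| on the
major-allele-proportion vectors; the absolute value is used because the
sign carries no meaning for unphased frequency data. Membership follows
a first-assignment rule (a marker collinear with two representatives
joins the earlier QTL), making the output a deterministic partition.
Selection stops only when candidates are exhausted — no significance
stop is applied, since every candidate already passed the genome-wide
threshold. Explained variance of a model is the squared correlation of
fitted versus observed values from a joint regression on the
representatives.

The marker-profile PCA treats markers as observations and accessions as
variables (column-centred, SVD), pairing each significant marker's PC1
and PC2 with its −log₁₀ p — the coordinates of the 3-D cluster plots
that stand in for Manhattan plots on map-less assemblies. Signs are
fixed by making each component's largest-magnitude loading positive.

Cross-location consolidation correlates representative genotype vectors
between models of different locations, links pairs at |r| ≥ 0.3, and
reports connected components spanning ≥ 2 locations, numbered in the
order of their lexicographically smallest member so that the output does
not depend on model input order. Components confined to one location are
dropped. Whether the original analysis correlated genotype profiles or
some other marker attribute is not documented; genotype profiles are the
natural choice for frequency data and are used here.

## Synthetic panels

The generator emulates a pooled-DNA accession panel at desk scale:

- **Structure.** Markers live on `n_scaffolds` short scaffolds, grouped
  into LD blocks of `ld_block_length` bp. Block base frequencies are
  drawn per subpopulation by the Balding–Nichols construction at the
  configured between-subpopulation F_ST (default 0.15, 3
  subpopulations); each accession then receives its own block frequency
  by a second Balding–Nichols step at `accession_fst` (default 0.2),
  because an accession is itself a differentiated population (a cultivar
  or landrace), not a random draw of plants from its subpopulation —
  without this level, accessions within a subpopulation would be
  statistically exchangeable and between-accession heritability of 0.9
  would be incoherent. Markers within a block share a per-haplotype
  latent uniform (comonotone coupling) plus a per-marker mutation
  probability (default 0.05), giving strong within-block and near-zero
  cross-block correlation; a per-marker jitter (SD 0.05) keeps block
  members from being exact copies.
- **Pools and reads.** Each accession pools 8 diploid plants; observed
  frequencies add binomial read noise at Poisson-distributed depth
  (default mean 30×; the depth is a free choice, as the source protocol
  reports only total data volume). `read_depth: null` disables read
  noise, leaving frequencies on the k/16 grid.
- **Phenotypes.** Per trait and location, the genetic value is the sum
  of planted-QTL effects on the true dosage (each scaled to contribute
  exactly its variance fraction) and a polygenic term with covariance
  proportional to the true-frequency kinship, sized to
  h² − Σ variance fractions. Polygenic values are correlated across
  locations at `env_genetic_correlation` (default 0.8, shared +
  location-specific decomposition); shared QTLs act identically in all
  locations, so total genetic correlation slightly exceeds the polygenic
  one. Non-shared QTLs are assigned to locations round-robin. Plot noise
  is sized so accession × location means hit the target narrow-sense
  heritability (default 0.93, matching the high broad-sense estimates
  reported for such panels). Trait scales are configurable
  (mean, SD) pairs — begin flowering 650 ± 130 °Cd, a full-flowering gap
  of 160 ± 45 °Cd above it (floored at 10 °Cd so FL_Full ≥ FL_Begin
  always holds), and a unit sex liability cut at ±1 SD into plot scores
  {1, 2, 3}. Setting an SD to 0 produces the degenerate all-identical
  panel used in tests. VEG is not simulated separately: it is the
  calendar-day image of the begin-flowering degree-day value, as in the
  field protocol, and planted "VEG" QTLs act on FL_Begin.
- **Planting policy.** Auto-placed QTLs go on polymorphic markers
  (true-frequency SD ≥ 0.12) whose variance is mostly within-structure
  (between-subpopulation share ≤ 0.25), at most one per scaffold.
  Structure-aligned causal variation is removed by the kinship
  correction by design, so planting there would create QTLs that no
  structure-corrected method could recover.
- **Temperatures.** Daily means are a seasonal cosine (peak at day-of-
  year 200) plus Gaussian noise; the three default locations differ in
  mean temperature (18 / 16 / 14.5 °C over a 185-day season), mimicking
  a warm-south-to-cool-north trial gradient. Flowering degree-day values
  are inverted through each location's accumulation curve into calendar
  dates, so recovered traits carry realistic one-day quantisation.
- **Randomness.** One child RNG stream per purpose (genotypes,
  temperatures, phenotypes) is spawned from the seed, so adding markers
  does not perturb phenotypes; temperature streams are additionally
  keyed by a CRC of the location id. The same seed reproduces byte-
  identical outputs, asserted end to end through the CLI.

What the generator does **not** emulate: coalescent-accurate LD decay,
sequencing reads (FASTQ), linked selection, selfing or crossing
structure, physical sex chromosomes, photoperiod-dependent flowering, or
heterogeneous per-plot emergence. Passing tests therefore demonstrate the
statistical machinery on panels with block LD and hierarchical drift,
not performance on any particular real dataset.

## Power at desk scale — a deliberate red flag

With heritability 0.9 and four planted QTLs of 8 % variance each, the
construction mandates a polygenic background of 0.58. For a single-
marker test, polygenic variance that the kinship cannot concentrate into
low-dimensional structure is irreducible noise — and in a self-
consistent simulation the correction removes signal and background
symmetrically at every structure level. The per-marker Wald statistic is
therefore capped near n·vf / (1 − vf) ≈ 10–12 at n = 123, while the
Bonferroni threshold on M_eff ≈ 215 demands ≈ 13.6. Empirically ~17 % of
causal marker tests reach genome-wide significance under these
conditions, and about 1 of 4 planted QTLs ends up in a cross-location
QTL per run. The corresponding end-to-end recovery test asserts the
stated ≥ 3-of-4 bar and fails; it is kept failing deliberately, as the
honest statement of a detection limit rather than a defect: the analysis
design only detects QTLs of roughly ≥ 20 % explained variance at this
panel size, which is exactly the effect-size range of the QTLs such
studies report (see the worked example in the README, where 20–25 %
QTLs are recovered cleanly in all locations).

## Motif search and annotation

Motif (miRNA) location uses exact or Hamming-distance matching on both
strands, with 1-based inclusive coordinates on the forward strand and
'N' never matching; gapped alignment (BLAST-style) is intentionally out
of scope for ~20-nt probes. Published miRNA coordinate tables sometimes
use an end-exclusive convention (end − start = length); a
`--table1-style` flag reproduces that convention for comparability,
default off. Candidate-gene assignment is a plain inner join of QTL
scaffolds against a user-supplied annotation table (TSV, GFF3 or BED);
the gene-ontology-based selection of candidate transcripts is an
upstream curation step represented by the table's `tags` column, not
recomputed.

## Problem sizes used in checks

The packaged checks run at: 25 accessions for dense-oracle equivalence;
120 accessions × ~2,000 filtered markers × 5 phenotype replicates
(~10,000 tests) for type-I calibration; 123 accessions × ~650 markers ×
3 locations × 5 seeds for end-to-end recovery. These sizes were chosen
as the smallest at which the respective statistical statements are
stable.
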