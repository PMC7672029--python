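# poolgwas

QTL mapping for pooled-DNA accession panels on fragmented genome
assemblies, built around the analysis design used for flowering time and
sex determination in hemp (*Cannabis sativa* L.): thermal-time phenotypes,
allele-frequency ("pool-seq") genotypes, a kinship-corrected mixed-model
association scan, forward-selection MultiQTL models with collinearity
clustering, and consolidation of QTLs across field locations. A
synthetic-panel generator with planted truth makes every step testable
end to end.

It is aimed at plant quantitative geneticists working with panels where
each "genotype" is a DNA pool of several plants per accession (so marker
dosages are continuous allele frequencies in [0, 1], not 0/1/2 calls) and
where the reference assembly is thousands of short scaffolds without a
physical map.

## The model

Phenotypes: flowering is recorded in accumulated thermal time above a
base temperature of 1 °C. For a plot with emergence day *e* and an event
day *d* (begin or full flowering),

    FL = Σ_{t ∈ [e, d)} max(0, T̄(t) − 1 °C)   [°Cd]

VEG is the vegetative period in calendar days (emergence to begin of
flowering), and sex determination is a plot score (1 = dioecious,
2 = mixed, 3 = monoecious) averaged over plots.

Association: for each marker, the linear mixed model

    y = Xα + Kβ + e,   u = Kβ ~ N(0, σ_g² K),   e ~ N(0, σ_e² I)

with y the accession × location trait means, X the marker dosage
(2 × major-allele proportion), and K the VanRaden genomic relationship
matrix K = ZZ′ / (2 Σ_j p_j(1−p_j)). Variance components come from REML
via a single eigendecomposition of K (profiled over δ = σ_e²/σ_g²); each
marker is then tested by generalised least squares at the null-model δ,
with the Wald statistic (α̂/SE)² referred to χ²(1). Family-wise
significance uses a Bonferroni correction on the effective number of
independent markers (Li–Ji eigenvalue method per scaffold window):
−log₁₀(p) ≥ −log₁₀(α / M_eff). With M_eff = 557 and α = 0.05 this
reproduces a genome-wide cut-off of 4.047.

MultiQTL: significant markers are collapsed by forward selection — the
marker with the largest (incremental) explained variance becomes a QTL
representative, every remaining candidate correlated with it at
|r| ≥ 0.3 (r² ≥ 0.1) joins that QTL as a collinear member, and selection
continues on the rest. The model's explained variance is the squared
correlation between fitted and observed trait values. Representatives
from different locations correlated at |r| ≥ 0.3 are merged into
cross-location QTLs.

## Worked example

Simulate a 123-accession, three-location panel with two planted QTLs of
paper-typical size (20 % of variance on begin flowering, 25 % on sex
determination) and run the whole pipeline:

```yaml
# config.yaml
simulation:
  n_accessions: 123
  n_scaffolds: 100
  planted_qtls:
    - {trait: FL_Begin, variance_fraction: 0.2}
    - {trait: Sex_det, variance_fraction: 0.25}
  heritability: 0.93
  seed: 11
```

```bash
poolgwas all --config config.yaml --out-dir out/
# pipeline complete (M_eff=214.0) -> out
```

`out/multiqtl_summary_FL_Begin.tsv` then reads

```
trait     location_id  n_qtls  explained_variance  representative_markers
FL_Begin  CRA          1       26.64               scaffold77_2176
FL_Begin  FNPC         1       26.96               scaffold77_3721
FL_Begin  VDS          1       21.11               scaffold77_2176
```

i.e. each per-location model found one QTL explaining 21–27 % of the
trait variance, represented by markers on scaffold77 — the scaffold
carrying the planted FL_Begin QTL (`out/truth.yaml` records it as
scaffold77_3871; the representatives are collinear block-mates of the
causal marker). Consolidation (`out/crossloc_FL_Begin.tsv`) links the
three representatives into a single QTL spanning all locations:

```
qtl             trait     CRA              FNPC             VDS
QTL_FL_Begin_1  FL_Begin  scaffold77_2176  scaffold77_3721  scaffold77_2176
```

and the sex-determination QTL is likewise recovered on its causal
scaffold in all three locations. Scaffolds of cross-location QTLs can
then be joined to a candidate-gene table with `poolgwas annotate`, and
short regulatory sequences (e.g. mature miRNAs) located in scaffold
FASTA with `poolgwas motif`.

Every step is also available as a standalone subcommand
(`simulate`, `phenotype`, `qc`, `kinship`, `gwas`, `multiqtl`,
`crossloc`, `annotate`, `motif`) reading and writing plain TSV/CSV, and
as library functions (`poolgwas.association_scan`,
`poolgwas.forward_select`, ...).

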