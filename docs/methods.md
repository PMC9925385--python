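# Methods

This note documents the statistical model, the numerical choices, and the
simulator that backs the test bench, in enough detail to reproduce or audit
any number the package computes.

## Data model and conventions

Per-cohort GWAS summary statistics carry, for variant *j* in cohort *k*, an
effect estimate b<sub>jk</sub> on the standardized-genotype scale (genotypes
normalized to mean 0, variance 1), a standard error s<sub>jk</sub> > 0, a
sample size n<sub>jk</sub>, and the effect-allele frequency. On this scale
z<sub>jk</sub> = b<sub>jk</sub>/s<sub>jk</sub> ≈ √n<sub>jk</sub>·b<sub>jk</sub>;
score-based studies that report only (z, n) are converted via b = z/√n,
s = 1/√n. Variant identity is (chrom, pos, ref, alt); rsIDs are treated as
opaque labels. All effects are harmonized to the weight table's effect-allele
orientation before analysis: swapped alleles flip the sign of b and replace f
by 1 − f; strand-ambiguous A/T and C/G variants are dropped by default (a
flag keeps them when |f − 0.5| > 0.08 makes frequency-based orientation
defensible). Gene-model variants missing from a cohort are excluded from that
variant's fit — never zero-imputed, which would bias the regression toward
the null.

## Ancestry coordinates

The cohort-by-variant frequency matrix F (variants shared by all cohorts) is
column-centered by default and decomposed by SVD; cohort scores are
X = F<sub>c</sub>E<sub>F</sub> and the eQTL panel's frequency vector is
mapped through the same centering and loadings. Centering is a deliberate
choice: the uncentered leading component is dominated by mean allele
frequency rather than ancestry, while the centered PC1 separates the most
diverged ancestry groups; the raw uncentered decomposition is available via
`center=False`. Component signs are fixed by making the largest-magnitude
loading positive, so runs are bit-reproducible. Three PCs are retained by
default (model orders L = 0…3); the number of retained components must be
smaller than the number of cohorts. The panel may lack up to 5% of the PC
variants; missing entries are simply excluded from the projection inner
products (a small-bias convenience preferable to failing a run).

## Per-variant meta-regression

For each variant, cohort effects are modeled as
b<sub>jk</sub> = Σ<sub>l=0..L</sub> X<sub>kl</sub>γ<sub>lj</sub> + ε<sub>jk</sub>
with b<sub>jk</sub> ~ N(·, s²<sub>jk</sub>), X<sub>k0</sub> ≡ 1, and fitted
by weighted least squares with inverse-variance weights W = diag(s⁻²). (Some
presentations print the weight matrix as diag(s); with the stated sampling
distribution the inverse-variance form is the one consistent with weighted
least squares, and it is what this package uses.) The projected effect at the
panel coordinates is the linear form

  b̂<sub>j</sub><sup>[L]</sup> = X̃<sup>[L]</sup>(X′WX)⁻¹X′W b<sub>j·</sub> = h<sub>j</sub><sup>[L]</sup>·b<sub>j·</sub>,

and the "hat" rows h are retained. Because b̂ is linear in the cohort
effects, its covariance across variants and across model orders follows from
the within-cohort sampling covariance
Cov(b<sub>j₁k</sub>, b<sub>j₂k</sub>) = r<sup>(k)</sup><sub>j₁j₂</sub>s<sub>j₁k</sub>s<sub>j₂k</sub>,
with r from the LD panel assigned to cohort k's ancestry and independence
across cohorts. Cross-model blocks Cov(b̂<sup>[L]</sup>, b̂<sup>[L′]</sup>)
use the two hat maps in the same sum; this linear-map derivation is the
normative definition used throughout.

Degenerate designs are handled per variant: the order is reduced until at
least L + 2 cohorts carry the variant and the weighted design has full column
rank (relative SVD tolerance 1e−8); downgrades are recorded in the output.
At L = 0 the hat row is the vector of normalized inverse-variance weights —
nonnegative, summing to one — so the 0-PC model is exactly fixed-effects
meta-analysis.

## Gene-level statistics

With eQTL weights w, projected effects b̂, standard deviations ŝ (square
roots of diag Σ<sub>b</sub>) and D = diag(ŝ):

  U<sup>[L]</sup> = Σ<sub>j</sub> w<sub>j</sub>b̂<sub>j</sub>/ŝ<sub>j</sub>,
  V<sup>[L]</sup> = w′D⁻¹Σ<sub>b</sub><sup>[L]</sup>D⁻¹w,
  T<sup>[L]</sup> = U/√V,  p<sup>[L]</sup> = 2Φ(−|T|).

All tests are two-sided. Variants without a finite projected effect drop out
(zero effective weight); a gene whose variance degenerates (all effective
weights zero, or exact cancellation under perfect LD) is flagged untestable
and emitted with p = NA rather than silently dropped.

**Minimal-P combination.** P\* = min<sub>L</sub> p<sup>[L]</sup> is
calibrated as Pr(min p ≤ p<sub>min</sub>) = 1 − Pr(|T<sup>[L]</sup>| < t ∀L)
under the zero-mean multivariate normal with the cross-model correlation
matrix, t = Φ⁻¹(1 − p<sub>min</sub>/2) (a common threshold across margins).
The rectangle probability is computed with Genz's separation-of-variables
transform over a scrambled Sobol grid (8,192 points, fixed seed), which is
deterministic and typically accurate to well below 1e−5 in these dimensions;
the estimate is clamped to its analytic bounds [p<sub>min</sub>,
m·p<sub>min</sub>] (perfect dependence / Bonferroni). Below
p<sub>min</sub> = 1e−15 the rectangle integral is numerically uninformative
and the Bonferroni bound is returned. The correlation matrix is repaired
before integration by eigenvalue clipping at 1e−10 and diagonal
renormalization, since finite-sample covariance assembly can produce tiny
negative eigenvalues.

**Cauchy combination.** Tissue p-values are combined as
S = Σ w<sub>i</sub>tan((0.5 − p<sub>i</sub>)π), p = 0.5 − arctan(S)/π, with
equal tissue weights by default, the 1/(pπ) substitution below p = 1e−15 and
the matching 1/(Sπ) back-transform for huge S. The combination is valid under
arbitrary dependence between tissues.

**Comparators.** FE-TWAS is coded directly from the inverse-variance formulas
(independently of the meta-regression path, so the exact L = 0 equivalence is
a genuine cross-check, verified to 12 significant digits in the tests).
RE-TWAS uses DerSimonian–Laird per variant; the between-study variance τ²
enters only the diagonal of the effect covariance (random effects of
different variants treated as independent), and the DL combination weights
are treated as fixed for covariance assembly — standard practice, and a
comparator-fidelity caveat rather than a component of the main method.
Subset-TWAS is FE restricted to cohorts whose ancestry label matches the eQTL
panel. Genomic-control λ (median χ² over its null median) is logged per
tissue as a diagnostic, not a correction.

## Simulator

The simulator emulates the structure the method consumes, directly at the
summary level (the method never touches genotypes, so nothing is lost and
replication is fast):

* **Frequencies.** Per-variant base frequencies ~ U(0.1, 0.9); ancestries sit
  on a shared one-dimensional cline (per-variant N(0,1) direction scaled by
  `freq_offset` = 0.15 and the ancestry's position), cohorts add N(0, 0.01²)
  within-ancestry noise, everything clipped to (0.01, 0.99). The eQTL panel
  tracks the target ancestry's base frequencies. With these defaults the
  centered PC1 cleanly orders the ancestries.
* **LD.** First-order autoregressive correlation r = ρ^|j₁−j₂| per ancestry,
  ρ = (0.8, 0.6, 0.4) by default — stronger LD in the panel-matched ancestry,
  controllable cross-ancestry differences.
* **Summary statistics.** Within cohort k,
  b<sub>·k</sub> ~ MVN(β<sub>·k</sub>, R<sub>ancestry(k)</sub>/n<sub>k</sub>),
  s<sub>jk</sub> = 1/√n<sub>k</sub> exactly.
* **Architectures.** All mediated through weights w (drawn N(0,1) per gene)
  and a gene-to-trait effect c: `homogeneous` (β = w·c everywhere);
  `pc_heterogeneous` (β<sub>jk</sub> = w<sub>j</sub>(c − slope·d<sub>k</sub>),
  d = displacement from the panel along the standardized PC1, oriented so the
  cohort mass lies at positive d — anchoring at the panel removes the
  arbitrary PC sign, and the trend stays linear in PC1 so the one-PC model is
  correctly specified); `single_ancestry` (β = w·c only in the target
  ancestry).

Default scale: 3 ancestries × 4 cohorts of 10,000 samples, 10 variants per
gene. What the simulator does **not** emulate: genotype-level sampling,
binary-trait liability scales, realistic MAF–LD coupling, imputation error,
cross-cohort sample overlap, and weight-training noise (weights are taken as
given, as in the method itself). Passing tests therefore demonstrate
correctness of the statistics under the stated sampling model, not robustness
to those real-data artifacts.

## Study conditions used by the test bench

* Null calibration: 10,000 simulated null genes on the default design;
  expected size 0.05 ± 3√(0.05·0.95/10⁴) and genomic-control λ in (0.9, 1.1).
* Power grids: mediation effect c ∈ {0.001, 0.002, 0.003} per standardized
  genotype (spanning FE power ≈ 0.1–0.85 at n = 10,000/cohort), 2,000
  replicates per cell. Heterogeneous cells use slope = c/1.22 per
  standardized-PC1 unit: effect c in the panel-matched ancestry, ~0 at the
  middle ancestry, −c at the far one. TESLA is required to beat FE by more
  than 3 Monte-Carlo se at every heterogeneous point.
* Homogeneous near-parity: the minimal-P combination across four model
  orders buys adaptivity at a small price — with this 12-cohort, 3-cluster
  design the cross-model correlation Corr(T⁰, T¹) ≈ 0.6 and the measured
  power deficit versus FE is ≈ 0.03–0.05 absolute at mid powers. The
  near-parity requirement is therefore the multiplicative band
  power<sub>TESLA</sub> ≥ 0.9·power<sub>FE</sub> (with Monte-Carlo
  allowance); designs whose cohorts concentrate near the panel ancestry, or
  with more cohorts, push the correlation up and the deficit toward zero.

## Numerical choices, edge cases, limitations

* Pseudo-inverse tolerance 1e−8 for rank decisions; LD shrinkage toward the
  identity (default λ = 0.1) when estimating LD from genotype panels, which
  guarantees positive definiteness on small panels.
* Determinism: fixed inputs give bit-identical outputs (SVD sign convention,
  fixed Sobol seed, seeded generators); the pipeline records package version,
  seed and a config hash in every results file.
* Multi-allelic sites are treated as distinct (chrom, pos, ref, alt) records.
  No liftover, no INDEL normalization beyond exact allele matching, no
  genotype-level association, no fine-mapping, no enrichment analyses.
* The minimal-P calibration assumes the T statistics are jointly normal with
  the assembled correlation; with very few cohorts and heavy missingness the
  per-variant downgrades make this an approximation.
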