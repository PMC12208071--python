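# Methods

This note documents the models implemented in `hapmosaic`, the choices made
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## Source panels

The resampling source is a panel of phased biallelic SNP haplotypes
(alleles coded 0 = reference, 1 = alternative) with a population label per
sample. Panels are read from phased VCF; multiallelic records, non-SNPs,
records with missing genotypes, and records with unphased *heterozygous*
genotypes are dropped with logged counts. Unphased homozygotes are
accepted: their phase is unambiguous, and rejecting them would discard
usable data for no information gain. Internally coordinates are 0-based
half-open; VCF emission converts back to 1-based.

Optional locus filtering composes in a fixed order: pooled folded
minor-allele frequency threshold, then every-nth retention (stride anchored
at ordinal 0), then a union with explicitly named rsids. The MAF filter
pools all populations and folds to the minor allele; rsid-only calls select
exactly the named loci.

## Genetic maps and crossovers

Maps are 3-column text (position, rate in cM/Mb, cumulative cM). Loci
inside the map range get centimorgan positions by linear interpolation;
loci outside get the chromosome's least-squares line fitted to all map
points, clamped to the nearest map endpoint so the assignment stays
non-decreasing. Centimorgan distances between consecutive retained loci
convert to per-interval crossover probabilities at 1 cM = 0.01 expected
crossovers, giving θ\_l and the chromosome parameter λ = Σ θ\_l.

Crossover counts use a floor-adjusted Poisson model: r = 1 + r\*, with
r\* ~ Poisson(λ\*). Requiring the mean to be preserved, E[r] = 1 + E[r\*],
forces λ\* = λ − 1; we clamp at zero, so E[r] = max(λ, 1). For whole human
chromosomes λ is comfortably above 1 and the clamp is inert; for short
regional panels (λ < 1) the floor dominates, the chromosome is logged, and
the realized mean is 1 rather than λ. This is the only reading we found
consistent with both the mean-preservation equation and a hard floor of one
crossover per chromosome.

Crossover *positions* are not specified by the count model. We place the r
crossovers in r distinct intervals sampled without replacement with
probability proportional to θ, which concentrates breakpoints in map
hotspots and gives each interval the correct expected crossover intensity.
No interference model beyond the without-replacement constraint is applied.
If a draw exceeds the number of positive-θ intervals it is redrawn (up to
50 times) and finally clamped with a warning — only reachable on degenerate
maps.

## Mosaic construction and admixture

Each individual carries an admixture row a\_i (fixed vector, per-individual
matrix, or Dirichlet-sampled). Segment source populations are i.i.d.
Categorical(a\_i), independently for the two haplotypes, so realized
ancestry varies around the target rather than matching it exactly — the
realized-vs-target scatter is itself a property under test. Source
haplotypes are drawn uniformly within the segment's population, with
replacement across segments and individuals (resampling, not permutation),
and independently for an individual's two haplotypes.

Realized ancestry fractions weight each inter-locus interval by θ and
attribute it to the segment of its left locus; with a genome of zero map
length, intervals are weighted equally.

Forced genotypes (used by the case/control common design) are split into
per-haplotype alleles — g = 1 phases 50/50 — and the segment containing a
forced locus restricts its source pool to haplotypes carrying the required
allele. If the drawn population's pool has no such haplotype, the segment's
population is redrawn from a\_i restricted to feasible populations
(renormalized; uniform if a\_i puts no mass there), and only if no
population carries the allele does the build fail.

## Phenotype designs

**Case/control, common variants.** One intercept per population per causal
SNP is solved from p\_k = Σ\_g P\_k(g) · logistic(α + gβ) with P\_k(g) the
Hardy–Weinberg triple at the population's panel allele frequency. We use
the HWE-expected form rather than an empirical average over the N\_k source
individuals: the two coincide as N\_k grows and the expected form is
deterministic; the empirical form is retained
(`solve_alpha_cc_empirical`) for strict fidelity. The solver is bracketed
root finding on a strictly monotone function (plug-back residual < 1e-10;
uniqueness by monotonicity). At most one causal SNP per chromosome is
allowed in this design.

Cohorts with exact case/control counts are produced by direct conditional
sampling rather than rejection: for each individual with assigned status D,
the causal genotype is drawn from the posterior ∝ P(D | g, a\_i) · P(g |
a\_i), where the prior is the HWE triple at the ancestry-mixed frequency
f\_i = a\_iᵀ f\_{·s} (equivalent to drawing each haplotype's allele from
the a\_i-mixture of population frequencies). Multiple causal SNPs (on
different chromosomes) are drawn independently from their per-SNP
posteriors.

**Quantitative trait, common variants.** z\_i = a\_iᵀα + g\_iᵀβ + ε\_i,
ε\_i ~ N(0, σ²), genotypes never conditioned on the phenotype. The
calibration equation over all 3^S causal-genotype combinations with
independent HWE locus probabilities is linear in α\_k and collapses, by
linearity of expectation, to α\_k = μ\_k − Σ\_s 2 f\_ks β\_s. The closed
form is primary; the explicit enumeration is kept as an independent oracle
and the two are required to agree to 1e-10. The product-form calibration
assumes linkage equilibrium between causal SNPs at the calibration step,
even though simulated genotypes can carry mosaic-induced LD — a fidelity
caveat, not an implementation choice. σ = 0 is permitted and yields a
deterministic trait.

**Rare-variant burden designs.** Per-population alternative-allele
frequencies are folded to the minor allele and averaged with equal
population weights; loci with averaged MAF strictly below the threshold
(and above zero — monomorphic loci carry no signal) form the rare set.
Fixed weights are 1; Madsen–Browning weights are [f(1−f)]^(−1/2).
Adjusted effect sizes β\_s = β\* S w\_s / Σw make the mean adjusted weight
exactly β\*. Burden genotypes count minor alleles: at the few loci where
the alternative allele is the major one, the reference allele is counted,
so the burden accumulates rare alleles.

Haplotypes are always built without phenotype conditioning. For the
case/control design the per-population intercepts are solved on the
*realized* cohort's burden scores (empirical mean-probability equation) and
status assigned as D\_i ~ Bernoulli(logistic(a\_iᵀα + c\_i)); for the
quantitative design α\_k = μ\_k − mean(c over population k) and
z\_i = a\_iᵀα + c\_i + ε\_i. Admixed individuals are assigned to a
calibration population by dominant ancestry (argmax of a\_i; ties go to the
first population); a population with no assigned individuals is calibrated
against the whole cohort with a logged warning. Calibration tests use
pure-population cohorts to avoid this ambiguity.

The bundled burden test uses the *raw* weights w as the analysis score —
as an analyst without knowledge of the generating β\* would — so the test
is defined for cohorts generated under β\* = 0. Case/control cohorts get a
1-df logistic score test (U²/V with V = p̄(1−p̄) Σ(c−c̄)²); quantitative
cohorts a linear-regression slope test.

## Synthetic fixtures

The generator emulates a real phased reference panel: K populations whose
per-locus frequencies are Balding–Nichols perturbations of a shared
ancestral frequency (divergence d gives Var(f\_k) = d·p(1−p); d ≈ 0.1 is
comparable to continental-scale F\_ST), with an optional fraction of loci
forced rare (per-population folded frequencies below 0.01). Haplotype
alleles are drawn independently per locus — the source panel is in linkage
equilibrium by construction, so any LD observed in simulated cohorts is
attributable purely to the mosaic resampling machinery. That is what the
tests need to isolate, but it is also the generator's main departure from
real data: it reproduces neither real haplotype-block LD structure nor a
realistic site-frequency spectrum, so passing calibration tests demonstrates
the correctness of the simulator's mechanics, not realism of any particular
panel. Synthetic maps distribute a specified total centimorgan length over
intervals, optionally concentrating it in hotspot intervals (default 30×
background intensity).

## Numerical and reproducibility choices

- Intercept solves: `scipy.optimize.brentq` on [−745, 745] (logistic
  saturation guarantees a bracket), xtol 1e-14, plug-back residual
  tolerance 1e-12 at solve time; invariants assert 1e-8 or better.
- θ is not capped above; a warning is emitted if any θ > 0.5 (only
  plausible with extremely sparse loci relative to the map).
- One `numpy.random.Generator` drives a whole run. Draw order per
  individual and chromosome is fixed (forced-heterozygote phase splits,
  then per haplotype: crossover count, breakpoint placement, segment
  ancestries, segment sources; phenotype noise after genotypes), making
  runs with identical config and seed byte-identical.
- Duplicate map positions collapse to the first occurrence; duplicate VCF
  positions after the first are dropped with a count.

## Problem sizes in the test suite

The calibration suite runs at desk scale, chosen to make each statistical
check well-powered while keeping the default run fast: panels of 100–200
diploid samples per population and 40–600 loci, cohorts of 20–8,000
individuals, 10⁵ draws for crossover-count checks, ≥ 500 null loci for the
association-scan type-I check, and 400 replicate cohorts for the burden
null. Tolerance conventions: deterministic identities at 1e-8–1e-12;
Monte-Carlo quantities within 3 standard errors (occasionally 3.5 where a
fixture is reused and an unlucky seed would otherwise couple tests).

## Known limitations

- No crossover interference model; placement is proportional-to-θ without
  replacement only.
- X chromosome and sex-specific maps are out of scope; autosomes only.
- Phenotype models include no covariates beyond ancestry, no dominance or
  epistasis, and the rare designs assume unidirectional effects.
- Admixture is single-generation in spirit: segment ancestries are i.i.d.
  across segments, with no model of admixture-LD decay over generations.
- The case/control common design allows one causal SNP per chromosome (its
  conditional-genotype construction is per-SNP marginal); use the
  quantitative design for dense multi-SNP architectures.
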