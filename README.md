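# hapmosaic

A resampling simulator of genotype–phenotype cohorts with population
admixture, for designing and benchmarking genetic association studies.

Simulation studies for GWAS methods need genotypes that look like real
data — realistic allele frequencies, population structure, and linkage
disequilibrium — together with phenotypes generated under a *known* model,
so that power and type-I error can be measured against the truth.
`hapmosaic` builds simulated individuals as **mosaics of real (or
synthetic) phased haplotypes**: each simulated chromosome copy is stitched
together from segments of source haplotypes, with crossover locations
driven by a genetic map and each segment's source population drawn from the
individual's admixture proportions. Phenotypes are then attached under one
of four designs — {case/control, quantitative trait} × {common causal SNPs,
rare-variant burden}.

## The model

**Mosaic haplotypes.** For a chromosome with per-interval crossover
probabilities θ\_l (0.01 × the centimorgan distance between consecutive
retained loci), the expected crossover count is λ = Σ θ\_l. Counts are
drawn from a floor-adjusted Poisson model, r = 1 + Poisson(λ\*) with
λ\* = max(λ − 1, 0), so every chromosome recombines at least once while
E[r] = max(λ, 1). Crossovers are placed in intervals with probability
proportional to θ (hotspots attract breakpoints); each of the r + 1
segments gets a source population k ~ Categorical(a\_i) from the
individual's admixture vector a\_i, and alleles are copied from a source
haplotype drawn uniformly from that population's pool.

**Case/control, common variants.** Disease follows a logistic liability
model, ln(π\_i / (1 − π\_i)) = a\_iᵀα\_s + g\_is β\_s, with one intercept
per source population per causal SNP. The α\_ks are solved numerically so
that the Hardy–Weinberg–expected prevalence in each pure population equals
the user's target p\_k. Causal genotypes are drawn *conditional on the
assigned status* by Bayes' rule, so exact case/control counts come for free.

**Quantitative trait, common variants.** z\_i ~ N(a\_iᵀα + g\_iᵀβ, σ²),
with one intercept per population calibrated to the target population means
μ\_k (closed form α\_k = μ\_k − Σ\_s 2 f\_ks β\_s; an explicit 3^S
enumeration is kept as an independent cross-check). Genotypes are never
conditioned on the phenotype.

**Rare-variant burden designs.** Rare loci are selected by averaged
minor-allele frequency below a threshold and weighted either uniformly
(Fixed) or by w\_s = [f\_s(1 − f\_s)]^(−1/2) (Madsen–Browning); weights are
rescaled so their mean equals the user's mean effect β\*. The burden score
c\_i = g\_iᵀβ enters a logistic model (case/control; intercepts solved on
the realized cohort) or a normal trait model. A burden test (logistic score
test / linear slope test) is included as the evaluation harness for power
and type-I-error studies.

## Worked example

```python
import numpy as np
import hapmosaic as hm

# a synthetic two-population source panel (200 SNPs, 100 samples/pop)
spec = hm.SyntheticPanelSpec(K=2, n_per_pop=100, L=200, divergence=0.1, seed=7)
panel, _ = hm.generate_synthetic_panel(spec)
gmap = hm.generate_synthetic_map(200, chrom_length_cm=150.0, seed=8,
                                 positions=panel.positions("1"))
profiles = hm.recombination_profiles(gmap, panel)
print(profiles["1"].lam, profiles["1"].lam_star)   # 1.5 0.5

cfg = hm.CommonCCConfig(
    causal=[hm.CausalVariant("1", 0, 0.5)],          # rs1_00000, beta = 0.5
    prevalence={"pop1": 0.1, "pop2": 0.2},
    n_cases=500, n_controls=500,
    admixture=hm.AdmixtureSpec(dirichlet=np.array([3.0, 2.0])))
cohort = hm.simulate_cc_common(panel, profiles, cfg, np.random.default_rng(42))

print(np.round(cohort.metadata["alpha"].alpha, 4))
# [[-2.5671]
#  [-1.621 ]]
g, D = cohort.genotype_matrix("1")[:, 0], cohort.phenotypes
print(g[D == 1].mean() / 2, g[D == 0].mean() / 2)   # 0.362 0.249
```

The 150 cM map gives λ = 1.5 expected crossovers (λ\* = 0.5 after the
floor adjustment). The solved intercepts are the log-odds of disease for a
non-carrier-leaning genotype mix in each population: pop1 (causal allele
frequency 0.325, prevalence 0.10) needs a lower baseline (−2.567) than pop2
(frequency 0.210, prevalence 0.20; −1.621). With β = 0.5 the causal allele
is enriched in cases (36.2% vs 24.9% in controls), while the mean realized
pop1 ancestry fraction (0.599) tracks the mean Dirichlet target (0.602).

The same workflow is available from the shell:

```bash
hapmosaic make-fixtures --out fixtures/ --seed 3
hapmosaic simulate --config config.yaml --seed 42 --out run1
```

which writes a phased VCF of the simulated cohort, a phenotype table with
admixture proportions, a local-ancestry BED track per haplotype, and a
provenance sidecar. Identical config + seed reproduces outputs
byte-for-byte.

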