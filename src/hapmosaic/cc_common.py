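"""Case/control design for common variants.

Disease follows a logistic liability model: for individual i with admixture
proportions a_i and genotype g_is at causal SNP s,

    ln(pi_i / (1 - pi_i)) = a_i^T alpha_s + g_is * beta_s,

where alpha_s holds one intercept per source population, solved so that the
model reproduces the user-specified disease prevalence p_k in each pure
population.  Causal genotypes are then drawn conditional on the assigned
case/control status by Bayes' rule against a Hardy-Weinberg prior at the
ancestry-mixed allele frequency, which makes fixed case/control counts
exact without rejection sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import SimulatedCohort
from .mosaic import AdmixtureSpec, build_individual
from .panel_io import (HaplotypePanel, PopulationFrequencies,
                       hwe_genotype_freqs, population_allele_frequencies)

logger = logging.getLogger(__name__)

__all__ = [
    "CausalVariant",
    "CommonCCConfig",
    "AncestryCoefficientsCC",
    "solve_logistic_intercept",
    "solve_alpha_cc",
    "solve_alpha_cc_empirical",
    "ancestry_coefficients_cc",
    "disease_probability",
    "causal_genotype_given_status",
    "simulate_cc_common",
]


@dataclass(frozen=True)
class CausalVariant:
    """A causal locus with its per-allele log-odds (or trait) effect size."""

    chrom: str
    index: int  # 0-based ordinal on the chromosome's retained loci
    beta: float


@dataclass
class CommonCCConfig:
    causal: list[CausalVariant]
    prevalence: dict[str, float]  # population -> p_k
    n_cases: int
    n_controls: int
    admixture: AdmixtureSpec

    def validate(self, panel: HaplotypePanel) -> None:
        chroms_seen = set()
        for cv in self.causal:
            if cv.chrom in chroms_seen:
                raise ValueError(
                    "case/control common design allows at most one causal locus "
                    f"per chromosome (duplicate on {cv.chrom})"
                )
            chroms_seen.add(cv.chrom)
            if cv.chrom not in panel.loci or not 0 <= cv.index < len(panel.loci[cv.chrom]):
                raise ValueError(f"causal locus {cv} not present in panel")
            if not np.isfinite(cv.beta):
                raise ValueError(f"effect size must be finite: {cv}")
        for pop in panel.pops:
            p = self.prevalence.get(pop)
            if p is None:
                raise ValueError(f"no prevalence given for population {pop!r}")
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {pop!r} must be in (0, 1), got {p}")
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValueError("need a positive number of cases + controls")


@dataclass
class AncestryCoefficientsCC:
    """Solved intercepts alpha_ks, one per population per causal SNP."""

    pops: list[str]
    causal: list[CausalVariant]
    alpha: np.ndarray  # (K, S_causal)

    def per_snp(self, s: int) -> np.ndarray:
        return self.alpha[:, s]


def solve_logistic_intercept(offsets, weights, p: float, tol: float = 1e-12) -> float:
    """Solve p = sum_j w_j * expit(alpha + offset_j) for alpha.

    The left side is strictly increasing in alpha, so the root is unique;
    it is found by bracketed root finding with plug-back residual below
    ``tol`` (the logistic saturates, so [-745, 745] always brackets).
    """
    offsets = np.asarray(offsets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not 0 < p < 1:
        raise ValueError(f"target probability must be in (0, 1), got {p}")

    def h(alpha: float) -> float:
        return float(np.dot(weights, expit(alpha + offsets))) - p

    lo, hi = -745.0, 745.0
    alpha = brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    resid = abs(h(alpha))
    if resid > tol:
        raise RuntimeError(
            f"intercept solve did not converge: residual {resid:.3e} at alpha={alpha}"
        )
    return float(alpha)


def solve_alpha_cc(f: float, beta: float, p: float) -> float:
    """Intercept alpha_ks from the HWE-expected prevalence equation.

    Solves p = sum_g P(g) expit(alpha + g beta) with P(g) the Hardy-Weinberg
    genotype probabilities at allele frequency f.
    """
    p0, p1, p2 = hwe_genotype_freqs(f)
    return solve_logistic_intercept(np.array([0.0, beta, 2 * beta]),
                                    np.array([p0, p1, p2]), p)


def solve_alpha_cc_empirical(genotypes, beta: float, p: float) -> float:
    """Intercept from the empirical average over observed source genotypes.

    Strict-fidelity variant of :func:`solve_alpha_cc`: the prevalence
    equation averages over the N_k source individuals' genotypes instead of
    the HWE-expected distribution; the two coincide as N_k grows.
    """
    g = np.asarray(genotypes, dtype=float)
    return solve_logistic_intercept(g * beta, np.full(g.size, 1.0 / g.size), p)


def ancestry_coefficients_cc(freqs: PopulationFrequencies,
                             causal: list[CausalVariant],
                             prevalence: dict[str, float]) -> AncestryCoefficientsCC:
    """Solve alpha_ks for every population x causal SNP."""
    K, S = len(freqs.pops), len(causal)
    alpha = np.empty((K, S))
    for s, cv in enumerate(causal):
        f_ks = freqs.at(cv.chrom, cv.index)
        for k, pop in enumerate(freqs.pops):
            alpha[k, s] = solve_alpha_cc(float(f_ks[k]), cv.beta, prevalence[pop])
    return AncestryCoefficientsCC(pops=list(freqs.pops), causal=list(causal), alpha=alpha)


def disease_probability(a_i, g_is: int, alpha_s, beta: float) -> float:
    """Case probability pi_i = expit(a_i^T alpha_s + g_is * beta)."""
    return float(expit(np.dot(a_i, alpha_s) + g_is * beta))


def causal_genotype_given_status(a_i, alpha_s, beta: float, D: int, f_ks) -> np.ndarray:
    """Posterior P(g | D, a_i) over g in {0, 1, 2} at one causal SNP.

    The prior is the HWE triple at the ancestry-mixed allele frequency
    f_i = a_i^T f_ks; the likelihood is the logistic case probability (or
    its complement for controls); the posterior is their normalized product.
    """
    a_i = np.asarray(a_i, dtype=float)
    f_mix = float(np.dot(a_i, np.asarray(f_ks, dtype=float)))
    prior = np.asarray(hwe_genotype_freqs(f_mix))
    pi = expit(np.dot(a_i, alpha_s) + np.arange(3) * beta)
    lik = pi if D == 1 else 1.0 - pi
    post = prior * lik
    total = post.sum()
    if total <= 0:
        raise RuntimeError("degenerate genotype posterior (all mass zero)")
    return post / total


def simulate_cc_common(panel: HaplotypePanel, profiles, config: CommonCCConfig,
                       rng: np.random.Generator,
                       freqs: PopulationFrequencies | None = None) -> SimulatedCohort:
    """Simulate a case/control cohort with exact case and control counts.

    For each individual the causal genotypes are drawn from their posterior
    given the assigned status, then the mosaic haplotypes are built with
    those genotypes forced.
    """
    config.validate(panel)
    if freqs is None:
        freqs = population_allele_frequencies(panel)
    coeffs = ancestry_coefficients_cc(freqs, config.causal, config.prevalence)
    n = config.n_cases + config.n_controls
    statuses = np.concatenate([np.ones(config.n_cases, dtype=int),
                               np.zeros(config.n_controls, dtype=int)])
    A = config.admixture.rows(n, rng)
    if A.shape[1] != len(panel.pops):
        raise ValueError(f"admixture has {A.shape[1]} populations, panel has "
                         f"{len(panel.pops)}")
    pops = panel.pops
    pop_rows = {k: panel.pop_rows(p) for k, p in enumerate(pops)}
    individuals = []
    for i in range(n):
        D = int(statuses[i])
        forced: dict[tuple[str, int], int] = {}
        for s, cv in enumerate(config.causal):
            post = causal_genotype_given_status(
                A[i], coeffs.per_snp(s), cv.beta, D, freqs.at(cv.chrom, cv.index)
            )
            forced[(cv.chrom, cv.index)] = int(rng.choice(3, p=post))
        ind = build_individual(panel, profiles, A[i], rng,
                               forced_genotypes=forced, pops=pops, pop_rows=pop_rows)
        ind.phenotype = D
        individuals.append(ind)
    return SimulatedCohort(
        design="cc-common",
        sample_ids=[f"sim{i:06d}" for i in range(n)],
        loci={c: panel.loci[c].copy() for c in panel.chroms},
        pops=pops,
        individuals=individuals,
        phenotype_name="status",
        metadata={"alpha": coeffs, "config": config},
    )
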