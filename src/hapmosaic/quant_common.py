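"""Quantitative-trait design for common variants.

The trait is normal given genotype and ancestry:

    z_i ~ Normal(a_i^T alpha + g_i^T beta, sigma^2),

with a single intercept alpha_k per source population solved so the
expected trait value in a pure population k equals the user-specified mean
mu_k.  Unlike the case/control design, genotypes are never conditioned on
the phenotype (mosaics are built first, traits drawn afterwards) and
multiple causal SNPs per chromosome are allowed.

Writing the calibration equation over all M = 3^S causal-genotype
combinations with independent HWE locus probabilities,

    mu_k = sum_m (alpha_k + g_m . beta) * prod_s P_k(g_ms),

is linear in alpha_k, and by linearity of expectation (E[g_s] = 2 f_ks)
collapses to the closed form alpha_k = mu_k - sum_s 2 f_ks beta_s.  The
closed form is primary; the explicit 3^S enumeration is retained as an
independent fidelity oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .cohort import SimulatedCohort
from .mosaic import AdmixtureSpec, build_individual
from .panel_io import (HaplotypePanel, PopulationFrequencies,
                       hwe_genotype_freqs, population_allele_frequencies)
from .cc_common import CausalVariant

logger = logging.getLogger(__name__)

__all__ = [
    "QuantCommonConfig",
    "QuantIntercepts",
    "solve_alpha_quant",
    "enumerate_alpha_oracle",
    "quant_intercepts",
    "simulate_quant_common",
]


@dataclass
class QuantCommonConfig:
    causal: list[CausalVariant]  # multiple per chromosome allowed
    means: dict[str, float]  # population -> mu_k
    sigma: float  # residual standard deviation
    n_individuals: int
    admixture: AdmixtureSpec

    def validate(self, panel: HaplotypePanel) -> None:
        for cv in self.causal:
            if cv.chrom not in panel.loci or not 0 <= cv.index < len(panel.loci[cv.chrom]):
                raise ValueError(f"causal locus {cv} not present in panel")
        for pop in panel.pops:
            if pop not in self.means:
                raise ValueError(f"no trait mean given for population {pop!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")


@dataclass
class QuantIntercepts:
    """One solved trait intercept per source population."""

    pops: list[str]
    alpha: np.ndarray  # K-vector


def solve_alpha_quant(f_ks, beta, mu_k: float) -> float:
    """Closed-form intercept: alpha_k = mu_k - sum_s 2 f_ks beta_s."""
    f_ks = np.atleast_1d(np.asarray(f_ks, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return float(mu_k - np.dot(2.0 * f_ks, beta))


def enumerate_alpha_oracle(f_ks, beta, mu_k: float, max_s: int = 12) -> float:
    """Solve the 3^S-combination calibration equation by direct enumeration.

    Evaluates mu_k = sum_m (alpha + g_m . beta) prod_s P_k(g_ms) over every
    genotype combination g_m, which is linear in alpha.  Guarded against
    exponential blowup; use :func:`solve_alpha_quant` for large S.
    """
    f_ks = np.atleast_1d(np.asarray(f_ks, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    S = beta.size
    if S > max_s:
        raise ValueError(f"S={S} too large for enumeration; use solve_alpha_quant")
    if S == 0:
        return float(mu_k)
    triples = [hwe_genotype_freqs(f) for f in f_ks]
    total_p = 0.0
    e_gb = 0.0
    for combo in itertools.product((0, 1, 2), repeat=S):
        p = 1.0
        for s, g in enumerate(combo):
            p *= triples[s][g]
        total_p += p
        e_gb += p * float(np.dot(combo, beta))
    if abs(total_p - 1.0) > 1e-9:
        raise RuntimeError(f"enumeration probabilities sum to {total_p}, not 1")
    return float(mu_k - e_gb)


def quant_intercepts(freqs: PopulationFrequencies, causal: list[CausalVariant],
                     means: dict[str, float]) -> QuantIntercepts:
    beta = np.asarray([cv.beta for cv in causal], dtype=float)
    alpha = np.empty(len(freqs.pops))
    for k, pop in enumerate(freqs.pops):
        f_k = np.asarray([freqs.at(cv.chrom, cv.index)[k] for cv in causal])
        alpha[k] = solve_alpha_quant(f_k, beta, means[pop])
    return QuantIntercepts(pops=list(freqs.pops), alpha=alpha)


def simulate_quant_common(panel: HaplotypePanel, profiles,
                          config: QuantCommonConfig, rng: np.random.Generator,
                          freqs: PopulationFrequencies | None = None
                          ) -> SimulatedCohort:
    """Simulate a quantitative-trait cohort (mosaics first, traits after)."""
    config.validate(panel)
    if freqs is None:
        freqs = population_allele_frequencies(panel)
    intercepts = quant_intercepts(freqs, config.causal, config.means)
    n = config.n_individuals
    A = config.admixture.rows(n, rng)
    if A.shape[1] != len(panel.pops):
        raise ValueError(f"admixture has {A.shape[1]} populations, panel has "
                         f"{len(panel.pops)}")
    pops = panel.pops
    pop_rows = {k: panel.pop_rows(p) for k, p in enumerate(pops)}
    individuals = [
        build_individual(panel, profiles, A[i], rng, pops=pops, pop_rows=pop_rows)
        for i in range(n)
    ]
    beta = np.asarray([cv.beta for cv in config.causal], dtype=float)
    G = np.column_stack(
        [[ind.genotypes[cv.chrom][cv.index] for ind in individuals]
         for cv in config.causal]
    ).astype(float) if config.causal else np.zeros((n, 0))
    z = A @ intercepts.alpha + G @ beta + rng.normal(0.0, config.sigma, size=n)
    for ind, zi in zip(individuals, z):
        ind.phenotype = float(zi)
    return SimulatedCohort(
        design="quant-common",
        sample_ids=[f"sim{i:06d}" for i in range(n)],
        loci={c: panel.loci[c].copy() for c in panel.chroms},
        pops=pops,
        individuals=individuals,
        phenotype_name="trait",
        metadata={"alpha": intercepts, "config": config},
    )
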