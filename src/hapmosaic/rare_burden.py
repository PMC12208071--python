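"""Rare-variant burden designs: weights, burden scores, and phenotypes.

Rare loci are selected by an averaged minor-allele frequency threshold
(per-population alternative-allele frequencies folded to the minor allele,
then averaged with equal population weights).  Two weighting schemes are
supported:

* Fixed: w_s = 1 for every rare locus;
* Madsen-Browning: w_s = [f_s (1 - f_s)]^(-1/2), up-weighting the rarest.

Raw weights are rescaled to adjusted effect sizes beta_s = beta* S w_s /
sum(w), so the mean adjusted weight equals the user-specified mean effect
beta* exactly.  The burden score is c_i = g_i^T beta over minor-allele
counts.  Haplotypes are always built without phenotype conditioning; the
phenotype is attached afterwards: case/control status via a logistic model
with per-population intercepts solved on the realized cohort's burden
scores, or a quantitative trait z_i = a_i^T alpha + c_i + eps_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import SimulatedCohort
from .mosaic import AdmixtureSpec, build_individual
from .panel_io import (HaplotypePanel, PopulationFrequencies,
                       population_allele_frequencies)
from .cc_common import solve_logistic_intercept

logger = logging.getLogger(__name__)

__all__ = [
    "RareConfig",
    "BurdenWeights",
    "BurdenTestResult",
    "averaged_maf",
    "select_rare_loci",
    "madsen_browning_weights",
    "scale_weights",
    "compute_burden_weights",
    "burden_genotypes",
    "burden_scores",
    "solve_alpha_rare_cc",
    "solve_alpha_rare_quant",
    "simulate_cc_rare",
    "simulate_quant_rare",
    "burden_test",
]


@dataclass
class RareConfig:
    chroms: list[str]
    f_thresh: float  # minor-allele frequency threshold (strict <)
    scheme: Literal["fixed", "madsen_browning"]
    beta_star: float  # target mean adjusted weight
    n_individuals: int
    admixture: AdmixtureSpec
    prevalence: dict[str, float] | None = None  # case/control design
    means: dict[str, float] | None = None  # quantitative design
    sigma: float | None = None

    def validate(self, panel: HaplotypePanel, design: str) -> None:
        if not 0 < self.f_thresh <= 0.5:
            raise ValueError(f"f_thresh must be in (0, 0.5], got {self.f_thresh}")
        if self.scheme not in ("fixed", "madsen_browning"):
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if not np.isfinite(self.beta_star):
            raise ValueError("beta_star must be finite")
        for chrom in self.chroms:
            if chrom not in panel.loci:
                raise ValueError(f"chromosome {chrom!r} not in panel")
        if design == "cc-rare":
            if self.prevalence is None:
                raise ValueError("cc-rare design needs prevalences")
            for pop in panel.pops:
                p = self.prevalence.get(pop)
                if p is None or not 0 < p < 1:
                    raise ValueError(f"prevalence for {pop!r} must be in (0, 1)")
        else:
            if self.means is None or self.sigma is None:
                raise ValueError("quant-rare design needs means and sigma")
            if self.sigma < 0:
                raise ValueError("sigma must be non-negative")
            for pop in panel.pops:
                if pop not in self.means:
                    raise ValueError(f"no trait mean for population {pop!r}")


@dataclass
class BurdenWeights:
    """Rare-locus set with raw and adjusted (effect-size) weights."""

    loci: list[tuple[str, int]]  # (chrom, locus index) per rare locus
    f_bar: np.ndarray  # averaged minor-allele frequency on the rare set
    w: np.ndarray  # raw weights
    beta: np.ndarray  # adjusted weights, mean(beta) == beta_star
    alt_is_minor: np.ndarray  # bool per rare locus: count alt (True) or ref alleles
    scheme: str
    beta_star: float


@dataclass
class BurdenTestResult:
    statistic: float
    pvalue: float
    kind: str  # "logistic-score" or "linear"


def averaged_maf(freqs: PopulationFrequencies, chrom: str) -> np.ndarray:
    """Minor-allele frequency per locus, averaged over populations.

    Per-population alternative-allele frequencies are folded to the minor
    allele (min(f, 1-f)) before the unweighted average across populations.
    """
    f = freqs.f[chrom]
    return np.minimum(f, 1.0 - f).mean(axis=0)


def select_rare_loci(f_bar, f_thresh: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices with 0 < f_bar < f_thresh and their Fixed-scheme weights (1)."""
    f_bar = np.asarray(f_bar, dtype=float)
    idx = np.flatnonzero((f_bar > 0) & (f_bar < f_thresh))
    if idx.size == 0:
        raise ValueError(
            f"no polymorphic loci with averaged MAF below {f_thresh}; "
            "use a larger region or a higher threshold"
        )
    return idx, np.ones(idx.size)


def madsen_browning_weights(f_bar) -> np.ndarray:
    """w_s = 1 / sqrt(f_s (1 - f_s)); strictly decreasing in f on (0, 0.5]."""
    f_bar = np.asarray(f_bar, dtype=float)
    if np.any(f_bar <= 0) or np.any(f_bar >= 1):
        raise ValueError("Madsen-Browning weights need frequencies in (0, 1)")
    return 1.0 / np.sqrt(f_bar * (1.0 - f_bar))


def scale_weights(w, beta_star: float) -> np.ndarray:
    """Adjusted weights beta_s = beta* S w_s / sum(w); mean(beta) == beta*."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return beta_star * w.size * w / total


def compute_burden_weights(freqs: PopulationFrequencies, chroms: list[str],
                           f_thresh: float, scheme: str,
                           beta_star: float) -> BurdenWeights:
    """Select the rare set over the requested chromosomes and weight it."""
    loci: list[tuple[str, int]] = []
    fbars: list[np.ndarray] = []
    alt_minor: list[np.ndarray] = []
    for chrom in chroms:
        fb = averaged_maf(freqs, chrom)
        idx, _ = select_rare_loci(fb, f_thresh)
        loci.extend((chrom, int(i)) for i in idx)
        fbars.append(fb[idx])
        # the counted (minor) allele is alt unless alt is the major allele
        alt_minor.append(freqs.f[chrom][:, idx].mean(axis=0) <= 0.5)
    f_bar = np.concatenate(fbars)
    alt_is_minor = np.concatenate(alt_minor)
    if scheme == "madsen_browning":
        w = madsen_browning_weights(f_bar)
    else:
        w = np.ones(f_bar.size)
    return BurdenWeights(loci=loci, f_bar=f_bar, w=w,
                         beta=scale_weights(w, beta_star),
                         alt_is_minor=alt_is_minor, scheme=scheme,
                         beta_star=beta_star)


def burden_genotypes(cohort_or_individuals, weights: BurdenWeights) -> np.ndarray:
    """(n, S) minor-allele counts on the rare set."""
    individuals = getattr(cohort_or_individuals, "individuals", cohort_or_individuals)
    n = len(individuals)
    G = np.empty((n, len(weights.loci)), dtype=np.int64)
    for s, (chrom, idx) in enumerate(weights.loci):
        g = np.asarray([ind.genotypes[chrom][idx] for ind in individuals],
                       dtype=np.int64)
        G[:, s] = g if weights.alt_is_minor[s] else 2 - g
    return G


def burden_scores(G, beta) -> np.ndarray:
    """Per-individual burden c_i = g_i^T beta."""
    return np.asarray(G, dtype=float) @ np.asarray(beta, dtype=float)


def dominant_ancestry(A: np.ndarray) -> np.ndarray:
    """Calibration population per individual: argmax of the ancestry row."""
    return np.argmax(A, axis=1)


def solve_alpha_rare_cc(c, pop_idx, prevalence: dict[str, float],
                        pops: list[str]) -> np.ndarray:
    """Solve p_k = mean_i expit(alpha_k + c_i) over population k's individuals.

    Populations with no assigned individuals fall back to calibrating
    against the whole cohort's burden scores.
    """
    c = np.asarray(c, dtype=float)
    pop_idx = np.asarray(pop_idx)
    alpha = np.empty(len(pops))
    for k, pop in enumerate(pops):
        ck = c[pop_idx == k]
        if ck.size == 0:
            logger.warning("no individuals with dominant ancestry %r; "
                           "calibrating its intercept on the whole cohort", pop)
            ck = c
        alpha[k] = solve_logistic_intercept(ck, np.full(ck.size, 1.0 / ck.size),
                                            prevalence[pop])
    return alpha


def solve_alpha_rare_quant(c, pop_idx, means: dict[str, float],
                           pops: list[str]) -> np.ndarray:
    """Closed form alpha_k = mu_k - mean(c_i over population k)."""
    c = np.asarray(c, dtype=float)
    pop_idx = np.asarray(pop_idx)
    alpha = np.empty(len(pops))
    for k, pop in enumerate(pops):
        ck = c[pop_idx == k]
        if ck.size == 0:
            logger.warning("no individuals with dominant ancestry %r; "
                           "calibrating its intercept on the whole cohort", pop)
            ck = c
        alpha[k] = means[pop] - ck.mean()
    return alpha


def _build_unconditioned(panel, profiles, config, rng):
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
    return individuals, A


def simulate_cc_rare(panel: HaplotypePanel, profiles, config: RareConfig,
                     rng: np.random.Generator,
                     freqs: PopulationFrequencies | None = None) -> SimulatedCohort:
    """Rare-variant case/control cohort: genotypes first, status after.

    Haplotypes are generated independently of disease status; per-population
    intercepts are then solved on the realized burden scores and status
    assigned as D_i ~ Bernoulli(expit(a_i^T alpha + c_i)).
    """
    config.validate(panel, "cc-rare")
    if freqs is None:
        freqs = population_allele_frequencies(panel)
    weights = compute_burden_weights(freqs, config.chroms, config.f_thresh,
                                     config.scheme, config.beta_star)
    individuals, A = _build_unconditioned(panel, profiles, config, rng)
    c = burden_scores(burden_genotypes(individuals, weights), weights.beta)
    pops = panel.pops
    alpha = solve_alpha_rare_cc(c, dominant_ancestry(A), config.prevalence, pops)
    pi = expit(A @ alpha + c)
    D = rng.binomial(1, pi)
    for ind, d in zip(individuals, D):
        ind.phenotype = int(d)
    return SimulatedCohort(
        design="cc-rare",
        sample_ids=[f"sim{i:06d}" for i in range(len(individuals))],
        pops=pops,
        loci={ch: panel.loci[ch].copy() for ch in panel.chroms},
        individuals=individuals,
        phenotype_name="status",
        metadata={"weights": weights, "burden": c, "alpha": alpha,
                  "config": config},
    )


def simulate_quant_rare(panel: HaplotypePanel, profiles, config: RareConfig,
                        rng: np.random.Generator,
                        freqs: PopulationFrequencies | None = None
                        ) -> SimulatedCohort:
    """Rare-variant quantitative cohort: z_i = a_i^T alpha + c_i + eps_i."""
    config.validate(panel, "quant-rare")
    if freqs is None:
        freqs = population_allele_frequencies(panel)
    weights = compute_burden_weights(freqs, config.chroms, config.f_thresh,
                                     config.scheme, config.beta_star)
    individuals, A = _build_unconditioned(panel, profiles, config, rng)
    c = burden_scores(burden_genotypes(individuals, weights), weights.beta)
    pops = panel.pops
    alpha = solve_alpha_rare_quant(c, dominant_ancestry(A), config.means, pops)
    z = A @ alpha + c + rng.normal(0.0, config.sigma, size=len(individuals))
    for ind, zi in zip(individuals, z):
        ind.phenotype = float(zi)
    return SimulatedCohort(
        design="quant-rare",
        sample_ids=[f"sim{i:06d}" for i in range(len(individuals))],
        pops=pops,
        loci={ch: panel.loci[ch].copy() for ch in panel.chroms},
        individuals=individuals,
        phenotype_name="trait",
        metadata={"weights": weights, "burden": c, "alpha": alpha,
                  "config": config},
    )


def _logistic_score_test(c: np.ndarray, D: np.ndarray) -> BurdenTestResult:
    p_bar = D.mean()
    if not 0 < p_bar < 1:
        raise ValueError("all-case or all-control cohort: test undefined")
    cc = c - c.mean()
    U = float(np.dot(D - p_bar, cc))
    V = float(p_bar * (1 - p_bar) * np.dot(cc, cc))
    stat = U * U / V
    return BurdenTestResult(statistic=stat,
                            pvalue=float(stats.chi2.sf(stat, df=1)),
                            kind="logistic-score")


def burden_test(cohort: SimulatedCohort, weights: BurdenWeights) -> BurdenTestResult:
    """Test the burden score against the cohort phenotype.

    The score is computed from the raw (unscaled) weights, as an analyst
    would, so the test is defined even for cohorts generated under
    beta* = 0.  Case/control cohorts get a 1-df logistic score test;
    quantitative cohorts a linear-regression slope test.
    """
    c = burden_scores(burden_genotypes(cohort, weights), weights.w)
    if np.ptp(c) == 0:
        raise ValueError("burden score is constant; test statistic undefined")
    phen = cohort.phenotypes.astype(float)
    if cohort.phenotype_name == "status":
        return _logistic_score_test(c, phen)
    res = stats.linregress(c, phen)
    return BurdenTestResult(statistic=float(res.slope / res.stderr),
                            pvalue=float(res.pvalue), kind="linear")
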