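"""Admixed mosaic haplotype construction by resampling a source panel.

Each simulated haplotype of a chromosome is a mosaic: a crossover count is
drawn from the floor-adjusted Poisson model, crossovers are placed between
loci with probability proportional to the interval crossover probabilities
(so hotspots attract breakpoints), each resulting segment is assigned a
source population from the individual's admixture proportions, and alleles
are copied from a source haplotype drawn uniformly from that population's
pool.  Source haplotypes are resampled with replacement across segments and
individuals.

Random draws per individual follow a fixed order — for each chromosome:
phase splits for forced heterozygous genotypes, then per haplotype the
crossover count, the breakpoint placements, the segment ancestries, and the
segment source haplotypes — so a seeded generator reproduces cohorts
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .genetic_map import RecombinationProfile, draw_crossover_count

if TYPE_CHECKING:  # pragma: no cover
    from .panel_io import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "MosaicError",
    "AdmixtureSpec",
    "CrossoverPlan",
    "SimulatedIndividual",
    "place_crossovers",
    "assign_segment_populations",
    "build_haplotype",
    "build_individual",
    "realized_ancestry_fractions",
]


class MosaicError(RuntimeError):
    """Raised when a mosaic cannot be built from the source panel."""


@dataclass
class AdmixtureSpec:
    """Per-individual ancestry proportions over K source populations.

    Either fixed ``proportions`` (a K-vector applied to everyone, or an
    (n, K) matrix) or a Dirichlet concentration vector from which
    per-individual proportions are drawn.
    """

    proportions: np.ndarray | None = None
    dirichlet: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.proportions is None) == (self.dirichlet is None):
            raise ValueError("specify exactly one of proportions or dirichlet")
        if self.proportions is not None:
            self.proportions = np.atleast_1d(np.asarray(self.proportions, dtype=float))
            a = np.atleast_2d(self.proportions)
            if np.any(a < 0) or np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("admixture rows must be non-negative and sum to 1")
        else:
            self.dirichlet = np.asarray(self.dirichlet, dtype=float)
            if np.any(self.dirichlet <= 0):
                raise ValueError("Dirichlet concentrations must be positive")

    @property
    def n_pops(self) -> int:
        if self.proportions is not None:
            return np.atleast_2d(self.proportions).shape[1]
        return self.dirichlet.size

    def rows(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestry proportion matrix (n, K) for a cohort of n individuals."""
        if self.dirichlet is not None:
            return rng.dirichlet(self.dirichlet, size=n)
        a = self.proportions
        if a.ndim == 1:
            return np.tile(a, (n, 1))
        if a.shape[0] != n:
            raise ValueError(f"admixture matrix has {a.shape[0]} rows, cohort needs {n}")
        return a.copy()


@dataclass
class CrossoverPlan:
    """Breakpoints and per-segment population/source choices for one haplotype.

    A breakpoint at interval index l places the segment boundary between
    loci l and l+1; r breakpoints give r+1 segments.
    """

    r: int
    breakpoints: np.ndarray  # sorted interval indices, length r
    segment_pops: np.ndarray  # population indices, length r+1
    segment_sources: np.ndarray  # source haplotype row indices, length r+1

    def validate(self) -> None:
        if len(self.breakpoints) != self.r:
            raise ValueError("breakpoint count != r")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segment_pops) != self.r + 1 or len(self.segment_sources) != self.r + 1:
            raise ValueError("need r+1 segment populations and sources")

    def bounds(self, n_loci: int) -> np.ndarray:
        """Segment boundaries as locus indices: [0, b0+1, ..., n_loci]."""
        return np.concatenate(([0], np.asarray(self.breakpoints) + 1, [n_loci]))

    def segments(self, n_loci: int):
        """Yield (start_locus, end_locus_exclusive, pop_index) per segment."""
        b = self.bounds(n_loci)
        for j in range(len(self.segment_pops)):
            yield int(b[j]), int(b[j + 1]), int(self.segment_pops[j])


@dataclass
class SimulatedIndividual:
    """One simulated individual: two mosaic haplotypes per chromosome."""

    haplotypes: dict[str, np.ndarray]  # chrom -> (2, L) uint8
    genotypes: dict[str, np.ndarray]  # chrom -> (L,) uint8
    plans: dict[str, tuple[CrossoverPlan, CrossoverPlan]]
    a: np.ndarray  # ancestry proportions, K-vector
    phenotype: float | None = None


def place_crossovers(theta: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Sample r distinct intervals with probability proportional to theta."""
    theta = np.asarray(theta, dtype=float)
    if r == 0:
        return np.zeros(0, dtype=np.int64)
    n_pos = int(np.count_nonzero(theta))
    if r > n_pos:
        raise MosaicError(f"cannot place {r} crossovers in {n_pos} positive intervals")
    p = theta / theta.sum()
    idx = rng.choice(theta.size, size=r, replace=False, p=p)
    return np.sort(idx).astype(np.int64)


def assign_segment_populations(a_i: np.ndarray, n_segments: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw each segment's source population i.i.d. from categorical(a_i)."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    a_i = np.asarray(a_i, dtype=float)
    return rng.choice(a_i.size, size=n_segments, p=a_i).astype(np.int64)


def _feasible_rows(haps: np.ndarray, rows: np.ndarray, constraints) -> np.ndarray:
    """Source rows among ``rows`` carrying every (locus, allele) constraint."""
    mask = np.ones(rows.size, dtype=bool)
    for locus, allele in constraints:
        mask &= haps[rows, locus] == allele
    return rows[mask]


def build_haplotype(panel: "HaplotypePanel", chrom: str, plan: CrossoverPlan,
                    rng: np.random.Generator,
                    forced_alleles: dict[int, int] | None = None,
                    pops: list[str] | None = None,
                    pop_rows: dict[int, np.ndarray] | None = None) -> np.ndarray:
    """Copy allele stretches from source haplotypes according to a plan.

    When a segment contains forced loci, the source pool is restricted to
    haplotypes carrying the forced alleles; an empty pool raises
    MosaicError (build_individual falls back by redrawing the segment
    population).  ``plan.segment_sources`` is filled in place.
    """
    pops = pops if pops is not None else panel.pops
    if pop_rows is None:
        pop_rows = {k: panel.pop_rows(p) for k, p in enumerate(pops)}
    haps = panel.haps[chrom]
    L = haps.shape[1]
    out = np.empty(L, dtype=np.uint8)
    forced_alleles = forced_alleles or {}
    bounds = plan.bounds(L)
    sources = np.empty(plan.r + 1, dtype=np.int64)
    for j in range(plan.r + 1):
        start, end = int(bounds[j]), int(bounds[j + 1])
        constraints = [(l, al) for l, al in forced_alleles.items() if start <= l < end]
        rows = pop_rows[int(plan.segment_pops[j])]
        if constraints:
            rows = _feasible_rows(haps, rows, constraints)
            if rows.size == 0:
                raise MosaicError(
                    f"no source haplotype in population "
                    f"{pops[int(plan.segment_pops[j])]!r} carries the forced "
                    f"allele(s) {constraints} on {chrom}"
                )
        src = int(rows[rng.integers(rows.size)])
        sources[j] = src
        out[start:end] = haps[src, start:end]
    plan.segment_sources = sources
    return out


def _draw_count(profile: RecombinationProfile, rng: np.random.Generator) -> int:
    """Crossover count clamped to the number of positive-theta intervals."""
    n_pos = int(np.count_nonzero(profile.theta))
    if n_pos == 0:
        return 0
    r = draw_crossover_count(profile.lam_star, rng)
    tries = 0
    while r > n_pos and tries < 50:
        r = draw_crossover_count(profile.lam_star, rng)
        tries += 1
    if r > n_pos:
        logger.warning("clamping crossover count %d to %d positive intervals", r, n_pos)
        r = n_pos
    return r


def _build_one_haplotype(panel, chrom, profile, a_i, rng, forced, pops, pop_rows):
    r = _draw_count(profile, rng)
    breakpoints = place_crossovers(profile.theta, r, rng) if r else np.zeros(0, np.int64)
    seg_pops = assign_segment_populations(a_i, r + 1, rng)
    plan = CrossoverPlan(r=r, breakpoints=breakpoints, segment_pops=seg_pops,
                         segment_sources=np.zeros(r + 1, dtype=np.int64))
    haps = panel.haps[chrom]
    L = haps.shape[1]
    bounds = plan.bounds(L)
    # resolve forced-allele conflicts segment by segment before copying
    for j in range(r + 1):
        start, end = int(bounds[j]), int(bounds[j + 1])
        constraints = [(l, al) for l, al in (forced or {}).items() if start <= l < end]
        if not constraints:
            continue
        if _feasible_rows(haps, pop_rows[int(seg_pops[j])], constraints).size:
            continue
        feasible = [k for k in range(len(pops))
                    if _feasible_rows(haps, pop_rows[k], constraints).size]
        if not feasible:
            raise MosaicError(
                f"no population carries forced allele(s) {constraints} on {chrom}"
            )
        w = np.asarray([a_i[k] for k in feasible], dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(feasible), 1.0 / len(feasible))
        seg_pops[j] = feasible[int(rng.choice(len(feasible), p=w))]
        logger.debug("redrew segment population for forced allele(s) %s", constraints)
    alleles = build_haplotype(panel, chrom, plan, rng, forced_alleles=forced,
                              pops=pops, pop_rows=pop_rows)
    return alleles, plan


def build_individual(panel: "HaplotypePanel",
                     profiles: dict[str, RecombinationProfile],
                     a_i: np.ndarray, rng: np.random.Generator,
                     forced_genotypes: dict[tuple[str, int], int] | None = None,
                     pops: list[str] | None = None,
                     pop_rows: dict[int, np.ndarray] | None = None
                     ) -> SimulatedIndividual:
    """Build one admixed individual (two mosaic haplotypes per chromosome).

    ``forced_genotypes`` maps (chrom, locus_index) -> g in {0, 1, 2}; a
    forced genotype is split into per-haplotype alleles (g=1 phases 50/50)
    and the mosaic is constrained to carry them.
    """
    pops = pops if pops is not None else panel.pops
    if pop_rows is None:
        pop_rows = {k: panel.pop_rows(p) for k, p in enumerate(pops)}
    forced_genotypes = forced_genotypes or {}
    haplotypes, genotypes, plans = {}, {}, {}
    for chrom in panel.chroms:
        forced_chrom = {l: g for (c, l), g in forced_genotypes.items() if c == chrom}
        per_hap: tuple[dict, dict] = ({}, {})
        for l, g in forced_chrom.items():
            if g not in (0, 1, 2):
                raise ValueError(f"forced genotype must be 0/1/2, got {g}")
            if g == 1:
                first = int(rng.integers(2))
                per_hap[first][l] = 1
                per_hap[1 - first][l] = 0
            else:
                per_hap[0][l] = g // 2
                per_hap[1][l] = g // 2
        hap_vecs, hap_plans = [], []
        for h in (0, 1):
            alleles, plan = _build_one_haplotype(
                panel, chrom, profiles[chrom], a_i, rng, per_hap[h], pops, pop_rows
            )
            hap_vecs.append(alleles)
            hap_plans.append(plan)
        haplotypes[chrom] = np.vstack(hap_vecs)
        genotypes[chrom] = (hap_vecs[0].astype(np.uint8) + hap_vecs[1]).astype(np.uint8)
        plans[chrom] = (hap_plans[0], hap_plans[1])
    return SimulatedIndividual(haplotypes=haplotypes, genotypes=genotypes,
                               plans=plans, a=np.asarray(a_i, dtype=float))


def realized_ancestry_fractions(ind: SimulatedIndividual,
                                profiles: dict[str, RecombinationProfile],
                                n_pops: int) -> np.ndarray:
    """Fraction of total genetic length (cM) assigned to each population.

    Each inter-locus interval carries weight theta and is attributed to the
    segment of its left locus; fractions are tallied over both haplotypes of
    every chromosome and sum to 1.  If the whole genome has zero map length,
    intervals are weighted equally.
    """
    weight = np.zeros(n_pops)
    total_theta = sum(float(profiles[c].theta.sum()) for c in ind.plans)
    for chrom, (p0, p1) in ind.plans.items():
        theta = profiles[chrom].theta
        if theta.size == 0:
            continue
        w = theta if total_theta > 0 else np.ones_like(theta)
        intervals = np.arange(theta.size)
        for plan in (p0, p1):
            seg_of_interval = np.searchsorted(plan.breakpoints, intervals, side="left")
            pops_of_interval = plan.segment_pops[seg_of_interval]
            np.add.at(weight, pops_of_interval, w)
    if weight.sum() == 0:
        raise MosaicError("individual has no intervals to tally ancestry over")
    return weight / weight.sum()
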