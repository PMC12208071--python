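"""Genetic maps, centimorgan interpolation, and the crossover-count model.

A genetic map assigns each physical position a cumulative genetic distance in
centimorgans (cM).  Distances between consecutive retained loci convert to
per-interval crossover probabilities at 1 cM = 0.01 expected crossovers, so
the expected crossover count on a chromosome is ``lam = sum(theta)``.

Crossover counts per simulated chromosome haplotype follow a floor-adjusted
Poisson model: counts are drawn as ``r = 1 + Poisson(lam_star)`` with
``lam_star = max(lam - 1, 0)``, so every simulated chromosome experiences at
least one crossover while the mean count is ``max(lam, 1)`` — unchanged from
the plain Poisson model whenever ``lam >= 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "RecombinationProfile",
    "load_genetic_map",
    "write_genetic_map",
    "cm_at_positions",
    "interval_probs",
    "adjusted_lambda",
    "draw_crossover_count",
    "recombination_profiles",
]


@dataclass
class ChromosomeMap:
    """Map points for one chromosome plus its extrapolation line."""

    pos: np.ndarray  # physical positions, bp, strictly increasing
    cm: np.ndarray  # cumulative genetic position, cM, non-decreasing
    slope: float = field(init=False)  # cM per bp, least-squares over all points
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.pos.size < 2:
            raise ValueError("a chromosome map needs at least 2 points")
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing in position")
        self.slope, self.intercept = np.polyfit(self.pos.astype(float), self.cm, 1)


@dataclass
class GeneticMap:
    """Genetic maps keyed by chromosome label."""

    chroms: dict[str, ChromosomeMap] = field(default_factory=dict)

    def add(self, chrom: str, pos, cm) -> None:
        self.chroms[chrom] = ChromosomeMap(np.asarray(pos), np.asarray(cm))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms


def load_genetic_map(path, chrom: str = "1") -> GeneticMap:
    """Parse a 3-column map file (position, rate cM/Mb, cumulative cM).

    A non-numeric header line is tolerated.  Rows are sorted by position and
    duplicate positions collapsed keeping the first occurrence.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                p, _rate, cm = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                continue  # header
            rows.append((p, cm))
    if len(rows) < 2:
        raise ValueError(f"genetic map {path!s} has fewer than 2 usable rows")
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    _, first = np.unique(arr[:, 0], return_index=True)
    arr = arr[np.sort(first)]
    if arr.shape[0] < 2:
        raise ValueError(f"genetic map {path!s} has fewer than 2 distinct positions")
    if np.any(np.diff(arr[:, 1]) < 0):
        raise ValueError(f"genetic map {path!s}: cumulative cM decreases with position")
    gmap = GeneticMap()
    gmap.add(chrom, arr[:, 0].astype(np.int64), arr[:, 1])
    return gmap


def write_genetic_map(gmap: GeneticMap, chrom: str, path) -> None:
    """Write one chromosome in the 3-column text format (with header)."""
    cmap = gmap.chroms[chrom]
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        dpos = np.diff(cmap.pos).astype(float)
        dcm = np.diff(cmap.cm)
        rate = np.append(dcm / dpos * 1e6, 0.0)
        for p, r, c in zip(cmap.pos, rate, cmap.cm):
            fh.write(f"{int(p)} {r:.8f} {c:.10f}\n")


def cm_at_positions(gmap: GeneticMap, chrom: str, positions) -> np.ndarray:
    """Cumulative cM at physical positions (sorted ascending).

    Positions inside the map range are linearly interpolated between map
    points; positions outside are evaluated on the chromosome's least-squares
    line fitted to all map points, clamped so the result never dips below the
    nearest map endpoint, and the output is made non-decreasing overall.
    """
    cmap = gmap.chroms[chrom]
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1:
        raise ValueError("positions must be 1-D")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    out = np.interp(positions, cmap.pos.astype(float), cmap.cm)
    line = cmap.slope * positions + cmap.intercept
    below = positions < cmap.pos[0]
    above = positions > cmap.pos[-1]
    out[below] = np.minimum(line[below], cmap.cm[0])
    out[above] = np.maximum(line[above], cmap.cm[-1])
    return np.maximum.accumulate(out)


def interval_probs(cm) -> np.ndarray:
    """Per-interval crossover probabilities: theta_l = 0.01 * (cm[l+1] - cm[l])."""
    cm = np.asarray(cm, dtype=float)
    if cm.size < 2:
        raise ValueError("need at least 2 cM values")
    d = np.diff(cm)
    if np.any(d < -1e-12):
        raise ValueError("cM values must be non-decreasing")
    theta = 0.01 * np.clip(d, 0.0, None)
    if np.any(theta > 0.5):
        logger.warning(
            "%d interval crossover probabilities exceed 0.5; loci are very sparse "
            "relative to the map",
            int(np.sum(theta > 0.5)),
        )
    return theta


def adjusted_lambda(lam: float) -> float:
    """Adjusted Poisson parameter preserving the mean under the floor of 1.

    With r = 1 + r*, r* ~ Poisson(lam_star), the condition E[r] = 1 + E[r*]
    = lam gives lam_star = lam - 1, clamped at 0 so short chromosomes get
    exactly one crossover in the mean (E[r] = max(lam, 1)).
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if lam < 1:
        logger.info("chromosome lambda=%.4f < 1: crossover floor dominates (mean=1)", lam)
    return max(lam - 1.0, 0.0)


def draw_crossover_count(lam_star: float, rng: np.random.Generator, size=None):
    """Draw r = 1 + Poisson(lam_star); every chromosome gets >= 1 crossover."""
    if lam_star < 0:
        raise ValueError("lam_star must be non-negative")
    draw = rng.poisson(lam_star, size=size)
    if size is None:
        return int(1 + draw)
    return 1 + draw


@dataclass
class RecombinationProfile:
    """Crossover model for one chromosome's retained loci."""

    theta: np.ndarray  # per-interval crossover probabilities, length L-1
    lam: float  # sum(theta)
    lam_star: float  # adjusted Poisson parameter
    cm: np.ndarray | None = None  # cumulative cM at the retained loci

    @classmethod
    def from_cm(cls, cm) -> "RecombinationProfile":
        cm = np.asarray(cm, dtype=float)
        theta = interval_probs(cm)
        lam = float(theta.sum())
        return cls(theta=theta, lam=lam, lam_star=adjusted_lambda(lam), cm=cm)


def recombination_profiles(gmap: GeneticMap, panel) -> dict[str, RecombinationProfile]:
    """Build a RecombinationProfile per panel chromosome from a genetic map."""
    profiles: dict[str, RecombinationProfile] = {}
    for chrom in panel.chroms:
        if chrom not in gmap.chroms:
            raise KeyError(f"no genetic map for chromosome {chrom!r}")
        cm = cm_at_positions(gmap, chrom, panel.positions(chrom))
        if cm.size < 2:
            # single-locus chromosome: no intervals, no crossovers possible
            profiles[chrom] = RecombinationProfile(
                theta=np.zeros(0), lam=0.0, lam_star=0.0, cm=cm
            )
        else:
            profiles[chrom] = RecombinationProfile.from_cm(cm)
    return profiles
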