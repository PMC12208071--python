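"""Synthetic haplotype panels and genetic maps for self-contained runs.

The generator emulates the structure of a real phased reference panel —
several source populations with controllable allele-frequency
differentiation — without any download.  Per-population frequencies follow
a Balding-Nichols perturbation of a shared ancestral frequency: with
divergence parameter d, f_k ~ Beta(p(1-d)/d, (1-p)(1-d)/d), whose variance
around p is d*p*(1-p) (d = 0 means identical generating frequencies).
Haplotype alleles are drawn independently per locus (linkage equilibrium in
the source), so linkage disequilibrium in simulated cohorts is attributable
purely to the mosaic resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap, write_genetic_map
from .panel_io import (HaplotypePanel, PopulationFrequencies, write_panel_vcf,
                       write_population_table)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticPanelSpec", "generate_synthetic_panel",
           "generate_synthetic_map", "write_fixture_files"]


@dataclass
class SyntheticPanelSpec:
    """Parameters of a synthetic source panel.

    Defaults give a modest two-population regional panel: 100 diploid
    samples per population, 200 loci on one chromosome, divergence 0.1
    (comparable to continental-scale F_ST), common-variant ancestral
    frequencies uniform on [0.05, 0.5].
    """

    K: int = 2
    n_per_pop: int = 100
    L: int = 200
    n_chrom: int = 1
    divergence: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    rare_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.K, self.n_per_pop, self.L, self.n_chrom) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if not 0 <= self.rare_fraction <= 1:
            raise ValueError("rare_fraction must be in [0, 1]")


def generate_synthetic_panel(spec: SyntheticPanelSpec
                             ) -> tuple[HaplotypePanel, PopulationFrequencies]:
    """Generate a panel plus the generating per-population frequencies.

    A ``rare_fraction`` of loci is forced rare: their per-population folded
    frequencies are drawn below 0.01, bypassing the divergence model.
    """
    rng = np.random.default_rng(spec.seed)
    pops = [f"pop{k + 1}" for k in range(spec.K)]
    sample_ids = [f"{pop}_{j:04d}" for pop in pops for j in range(spec.n_per_pop)]
    pop_of_sample = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    pop_of_hap = np.repeat(np.arange(spec.K), 2 * spec.n_per_pop)

    loci, haps, fdict = {}, {}, {}
    bases = np.array(list("ACGT"))
    for c in range(spec.n_chrom):
        chrom = str(c + 1)
        lo, hi = spec.maf_range
        p_anc = rng.uniform(lo, hi, size=spec.L)
        n_rare = int(round(spec.rare_fraction * spec.L))
        rare_idx = rng.choice(spec.L, size=n_rare, replace=False) if n_rare else []
        if spec.divergence > 0:
            d = spec.divergence
            f = rng.beta(p_anc * (1 - d) / d, (1 - p_anc) * (1 - d) / d,
                         size=(spec.K, spec.L))
            f = np.clip(f, 1e-4, 1 - 1e-4)
        else:
            f = np.tile(p_anc, (spec.K, 1))
        if n_rare:
            f[:, rare_idx] = rng.uniform(5e-4, 9e-3, size=(spec.K, n_rare))
        u = rng.random((2 * spec.K * spec.n_per_pop, spec.L))
        haps[chrom] = (u < f[pop_of_hap]).astype(np.uint8)
        pos = 1000 + np.cumsum(rng.integers(500, 1500, size=spec.L))
        ref_idx = rng.integers(0, 4, size=spec.L)
        ref = bases[ref_idx]
        alt = bases[(ref_idx + rng.integers(1, 4, size=spec.L)) % 4]
        loci[chrom] = pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "rsid": [f"rs{chrom}_{i:05d}" for i in range(spec.L)],
            "ref": ref,
            "alt": alt,
        })
        fdict[chrom] = f
    panel = HaplotypePanel(loci=loci, haps=haps, sample_ids=sample_ids,
                           pop_of_sample=pop_of_sample)
    panel.validate()
    freqs = PopulationFrequencies(pops=pops, f=fdict,
                                  n_hap_per_pop={p: 2 * spec.n_per_pop for p in pops})
    return panel, freqs


def generate_synthetic_map(L: int, chrom_length_cm: float = 100.0,
                           hotspot_fraction: float = 0.2, seed: int = 0,
                           positions=None, chrom: str = "1",
                           hotspot_intensity: float = 30.0) -> GeneticMap:
    """Generate a map whose total length is exactly ``chrom_length_cm``.

    With hotspot_fraction = 0 every interval carries equal map length; a
    positive fraction concentrates most of the length in randomly chosen
    hotspot intervals (each ``hotspot_intensity`` times the background).
    """
    if L < 2:
        raise ValueError("need at least 2 loci for a map")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = 1 + 1000 * np.arange(L, dtype=np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size != L:
            raise ValueError("positions length must equal L")
    w = np.ones(L - 1)
    n_hot = int(round(hotspot_fraction * (L - 1)))
    if n_hot:
        w[rng.choice(L - 1, size=n_hot, replace=False)] = hotspot_intensity
    cm = np.concatenate(([0.0], np.cumsum(w)))
    cm *= chrom_length_cm / cm[-1]
    gmap = GeneticMap()
    gmap.add(chrom, positions, cm)
    return gmap


def write_fixture_files(panel: HaplotypePanel, gmap: GeneticMap, outdir) -> dict:
    """Persist a fixture panel as VCF + population TSV + per-chromosome maps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / "panel.vcf", "pops": outdir / "panel.pops.tsv"}
    write_panel_vcf(panel, paths["vcf"])
    write_population_table(panel, paths["pops"])
    paths["maps"] = {}
    for chrom in panel.chroms:
        mp = outdir / f"map_chr{chrom}.txt"
        write_genetic_map(gmap, chrom, mp)
        paths["maps"][chrom] = mp
    return paths
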