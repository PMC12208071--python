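import numpy as np
import pytest

from hapmosaic import (
    GeneticMap,
    SyntheticPanelSpec,
    generate_synthetic_map,
    generate_synthetic_panel,
    recombination_profiles,
)


def make_panel_with_map(spec: SyntheticPanelSpec, chrom_length_cm=150.0,
                        map_seed=1000, hotspot_fraction=0.2):
    """Synthetic panel + matching per-chromosome genetic map + profiles."""
    panel, gen_freqs = generate_synthetic_panel(spec)
    gmap = GeneticMap()
    for i, chrom in enumerate(panel.chroms):
        sub = generate_synthetic_map(
            spec.L, chrom_length_cm=chrom_length_cm, seed=map_seed + i,
            chrom=chrom, positions=panel.positions(chrom),
            hotspot_fraction=hotspot_fraction,
        )
        gmap.chroms.update(sub.chroms)
    profiles = recombination_profiles(gmap, panel)
    return panel, gen_freqs, gmap, profiles


@pytest.fixture(scope="session")
def two_pop():
    """Two-population common-variant panel used across module tests."""
    spec = SyntheticPanelSpec(K=2, n_per_pop=100, L=120, n_chrom=1,
                              divergence=0.1, maf_range=(0.05, 0.5), seed=11)
    return make_panel_with_map(spec)


@pytest.fixture(scope="session")
def rare_panel():
    """Panel where most loci are rare (averaged MAF < 0.01)."""
    spec = SyntheticPanelSpec(K=2, n_per_pop=150, L=80, n_chrom=1,
                              divergence=0.05, rare_fraction=0.7, seed=21)
    return make_panel_with_map(spec, chrom_length_cm=80.0, map_seed=2000)


def polymorphic_locus(panel, chrom="1", min_maf=0.15, skip=0):
    """Deterministic causal-locus pick: ordinal of a well-polymorphic SNP."""
    from hapmosaic.panel_io import pooled_maf

    idx = np.flatnonzero(pooled_maf(panel, chrom) >= min_maf)
    return int(idx[skip])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
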