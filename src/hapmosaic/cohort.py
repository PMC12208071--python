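"""Container for simulated cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mosaic import SimulatedIndividual

__all__ = ["SimulatedCohort"]


@dataclass
class SimulatedCohort:
    """Simulated individuals with phenotypes and local-ancestry tracks.

    ``phenotype_name`` is "status" (0/1 case-control) or "trait"
    (quantitative).  ``metadata`` carries design-specific artifacts such as
    solved ancestry intercepts and burden weights.
    """

    design: str
    sample_ids: list[str]
    loci: dict[str, pd.DataFrame]
    pops: list[str]
    individuals: list[SimulatedIndividual]
    phenotype_name: str
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def chroms(self) -> list[str]:
        return list(self.loci.keys())

    @property
    def phenotypes(self) -> np.ndarray:
        return np.asarray([ind.phenotype for ind in self.individuals])

    @property
    def admixture(self) -> np.ndarray:
        return np.vstack([ind.a for ind in self.individuals])

    def genotype_matrix(self, chrom: str) -> np.ndarray:
        """(n, L) matrix of genotypes 0/1/2 on one chromosome."""
        return np.vstack([ind.genotypes[chrom] for ind in self.individuals])

    def haplotype_matrix(self, chrom: str) -> np.ndarray:
        """(2n, L) matrix of phased alleles; individual i owns rows 2i, 2i+1."""
        return np.vstack([ind.haplotypes[chrom] for ind in self.individuals])
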