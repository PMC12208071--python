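"""Phased haplotype panels: reading, filtering, frequencies, and cohort output.

The resampling source is a panel of phased biallelic SNP haplotypes with a
population label per sample.  Alleles are coded 0 (reference) / 1
(alternative); each sample contributes two haplotype rows.  Genotype
frequencies follow Hardy-Weinberg equilibrium: P(g=0) = (1-f)^2,
P(g=2) = f^2, P(g=1) = 1 - P(g=0) - P(g=2) for alternative-allele
frequency f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "HaplotypePanel",
    "PopulationFrequencies",
    "read_population_table",
    "read_phased_vcf",
    "filter_loci",
    "population_allele_frequencies",
    "hwe_genotype_freqs",
    "write_panel_vcf",
    "write_population_table",
    "write_cohort",
]

LOCUS_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt"]


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP."""

    chrom: str
    pos: int  # 1-based physical coordinate
    rsid: str  # "." when absent
    ref_allele: str
    alt_allele: str
    index_on_chrom: int  # 0-based ordinal among retained loci


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes over ordered biallelic loci, with population labels.

    ``haps[chrom]`` is a uint8 matrix of shape (2 * n_samples, L); sample j
    owns rows 2j and 2j+1.  ``loci[chrom]`` is a DataFrame with columns
    chrom, pos, rsid, ref, alt, ordered by strictly increasing position.
    """

    loci: dict[str, pd.DataFrame]
    haps: dict[str, np.ndarray]
    sample_ids: list[str]
    pop_of_sample: dict[str, str]
    drop_counts: dict[str, int] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.loci.keys())

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def pops(self) -> list[str]:
        return sorted(set(self.pop_of_sample[s] for s in self.sample_ids))

    def positions(self, chrom: str) -> np.ndarray:
        return self.loci[chrom]["pos"].to_numpy()

    def locus(self, chrom: str, index: int) -> Locus:
        row = self.loci[chrom].iloc[index]
        return Locus(
            chrom=chrom,
            pos=int(row["pos"]),
            rsid=str(row["rsid"]),
            ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]),
            index_on_chrom=int(index),
        )

    def pop_rows(self, pop: str) -> np.ndarray:
        """Haplotype row indices belonging to population ``pop``."""
        rows = [
            r
            for j, s in enumerate(self.sample_ids)
            if self.pop_of_sample[s] == pop
            for r in (2 * j, 2 * j + 1)
        ]
        return np.asarray(rows, dtype=np.int64)

    def find_locus(self, chrom: str, rsid: str | None = None, pos: int | None = None) -> int:
        """Resolve a locus to its 0-based ordinal by rsid or position."""
        df = self.loci[chrom]
        if rsid is not None:
            hits = np.flatnonzero(df["rsid"].to_numpy() == rsid)
            if hits.size == 0:
                raise KeyError(f"rsid {rsid!r} not found on chromosome {chrom}")
            return int(hits[0])
        if pos is not None:
            hits = np.flatnonzero(df["pos"].to_numpy() == pos)
            if hits.size == 0:
                raise KeyError(f"position {pos} not found on chromosome {chrom}")
            return int(hits[0])
        raise ValueError("provide rsid or pos")

    def validate(self) -> None:
        for chrom, df in self.loci.items():
            pos = df["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if np.any(df["ref"].to_numpy() == df["alt"].to_numpy()):
                raise ValueError(f"{chrom}: ref == alt at some locus")
            h = self.haps[chrom]
            if h.shape != (2 * self.n_samples, len(df)):
                raise ValueError(f"{chrom}: haplotype matrix shape mismatch")
            if not np.isin(h, (0, 1)).all():
                raise ValueError(f"{chrom}: haplotype entries must be 0/1")
        for pop in self.pops:
            if self.pop_rows(pop).size == 0:
                raise ValueError(f"population {pop!r} has no samples")


@dataclass
class PopulationFrequencies:
    """Per-population alternative-allele frequencies on the source panel."""

    pops: list[str]
    f: dict[str, np.ndarray]  # chrom -> (K, L) matrix
    n_hap_per_pop: dict[str, int]

    def at(self, chrom: str, index: int) -> np.ndarray:
        """K-vector of alternative-allele frequencies at one locus."""
        return self.f[chrom][:, index]


def read_population_table(path) -> dict[str, str]:
    """Read a 2-column TSV mapping sample_id -> population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     comment="#", dtype=str)
    if len(df) and df.iloc[0, 0] in ("sample", "sample_id"):
        df = df.iloc[1:]
    return dict(zip(df["sample"], df["pop"]))


def _parse_region(region):
    if region is None:
        return None
    if isinstance(region, (tuple, list)):
        chrom, start, end = (list(region) + [None, None])[:3]
        return str(chrom), start, end
    s = str(region)
    if ":" in s:
        chrom, rng = s.split(":", 1)
        start, end = rng.replace(",", "").split("-")
        return chrom, int(start), int(end)
    return s, None, None


def read_phased_vcf(path, pop_table, region=None) -> HaplotypePanel:
    """Read a phased VCF into a HaplotypePanel.

    Only biallelic SNP records with complete, phased genotypes for the
    retained samples are kept; everything else is dropped with a logged
    count (homozygous genotypes are accepted regardless of phase separator,
    their phase being unambiguous).  Samples absent from ``pop_table`` are
    dropped.
    """
    from cyvcf2 import VCF

    if isinstance(pop_table, (str, Path)):
        pop_table = read_population_table(pop_table)
    probe = VCF(str(path))
    keep = [s for s in probe.samples if s in pop_table]
    probe.close()
    if not keep:
        raise ValueError(f"no samples in {path!s} have a population assignment")
    vcf = VCF(str(path), samples=keep)
    samples = list(vcf.samples)  # order as retained by the reader

    reg = _parse_region(region)
    drop = {"multiallelic_or_non_snp": 0, "unphased": 0, "missing_gt": 0,
            "duplicate_position": 0}
    per_chrom: dict[str, dict] = {}
    for v in vcf:
        chrom = v.CHROM
        if reg is not None:
            rchrom, rstart, rend = reg
            if chrom != rchrom:
                continue
            if rstart is not None and (v.POS < rstart or v.POS > rend):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            drop["multiallelic_or_non_snp"] += 1
            continue
        gts = v.genotypes
        alleles = np.empty(2 * len(samples), dtype=np.uint8)
        bad = None
        for j, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                bad = "missing_gt"
                break
            if not phased and a0 != a1:
                bad = "unphased"
                break
            alleles[2 * j] = a0
            alleles[2 * j + 1] = a1
        if bad:
            drop[bad] += 1
            continue
        store = per_chrom.setdefault(chrom, {"pos": [], "rsid": [], "ref": [],
                                             "alt": [], "rows": []})
        if store["pos"] and v.POS <= store["pos"][-1]:
            drop["duplicate_position"] += 1
            continue
        store["pos"].append(v.POS)
        store["rsid"].append(v.ID if v.ID else ".")
        store["ref"].append(v.REF)
        store["alt"].append(v.ALT[0])
        store["rows"].append(alleles)
    vcf.close()

    if not per_chrom:
        if region is not None:
            raise ValueError(f"region {region!r} contains no usable records")
        raise ValueError(f"no phased biallelic SNP records in {path!s}")
    dropped = {k: n for k, n in drop.items() if n}
    if dropped:
        logger.warning("dropped records while reading %s: %s", path, dropped)

    loci, haps = {}, {}
    for chrom, store in per_chrom.items():
        loci[chrom] = pd.DataFrame(
            {"chrom": chrom, "pos": np.asarray(store["pos"], dtype=np.int64),
             "rsid": store["rsid"], "ref": store["ref"], "alt": store["alt"]}
        )
        haps[chrom] = np.column_stack(store["rows"]).astype(np.uint8)
    panel = HaplotypePanel(loci=loci, haps=haps, sample_ids=samples,
                           pop_of_sample={s: pop_table[s] for s in samples},
                           drop_counts=drop)
    panel.validate()
    return panel


def pooled_maf(panel: HaplotypePanel, chrom: str) -> np.ndarray:
    """Folded minor-allele frequency on the pooled panel (all populations)."""
    f = panel.haps[chrom].mean(axis=0)
    return np.minimum(f, 1.0 - f)


def filter_loci(panel: HaplotypePanel, maf_min: float | None = None,
                every_nth: int | None = None,
                rsid_keep: list[str] | None = None) -> HaplotypePanel:
    """Filter panel loci; criteria compose as MAF, then stride, then rsid union.

    ``maf_min`` drops loci whose pooled folded MAF is below the threshold;
    ``every_nth`` keeps ordinals 0, n, 2n, ... of the loci surviving the MAF
    step; loci named in ``rsid_keep`` are retained regardless.  Locus order
    is preserved.
    """
    if every_nth is not None and every_nth < 1:
        raise ValueError("every_nth must be a positive integer")
    keep_set = set(rsid_keep or [])
    found = set()
    new_loci, new_haps = {}, {}
    rsid_only = maf_min is None and every_nth is None and bool(keep_set)
    for chrom in panel.chroms:
        df = panel.loci[chrom]
        # rsid_keep alone selects exactly the named loci; combined with other
        # criteria it unions them back in after those filters
        mask = np.zeros(len(df), dtype=bool) if rsid_only \
            else np.ones(len(df), dtype=bool)
        if maf_min is not None:
            mask &= pooled_maf(panel, chrom) >= maf_min
        if every_nth is not None:
            surv = np.flatnonzero(mask)
            mask = np.zeros(len(df), dtype=bool)
            mask[surv[::every_nth]] = True
        if keep_set:
            rs_mask = df["rsid"].isin(keep_set).to_numpy()
            found.update(df["rsid"][rs_mask])
            mask |= rs_mask
        if mask.any():
            new_loci[chrom] = df[mask].reset_index(drop=True)
            new_haps[chrom] = panel.haps[chrom][:, mask]
    missing = keep_set - found
    if missing:
        logger.warning("rsid_keep entries not present in panel: %s", sorted(missing))
    return HaplotypePanel(loci=new_loci, haps=new_haps,
                          sample_ids=list(panel.sample_ids),
                          pop_of_sample=dict(panel.pop_of_sample),
                          drop_counts=dict(panel.drop_counts))


def population_allele_frequencies(panel: HaplotypePanel) -> PopulationFrequencies:
    """Alternative-allele frequency per population per locus (haplotype mean)."""
    pops = panel.pops
    rows = {pop: panel.pop_rows(pop) for pop in pops}
    f = {
        chrom: np.vstack([panel.haps[chrom][rows[pop]].mean(axis=0) for pop in pops])
        for chrom in panel.chroms
    }
    return PopulationFrequencies(
        pops=pops, f=f, n_hap_per_pop={pop: int(rows[pop].size) for pop in pops}
    )


def hwe_genotype_freqs(f):
    """Hardy-Weinberg genotype probabilities (P0, P1, P2) at allele frequency f."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"allele frequency outside [0, 1]: {f}")
    p0 = (1.0 - arr) ** 2
    p2 = arr**2
    p1 = 1.0 - p0 - p2
    if arr.ndim == 0:
        return float(p0), float(p1), float(p2)
    return p0, p1, p2


# ---------------------------------------------------------------------------
# output


def _write_vcf(loci: dict[str, pd.DataFrame], haps: dict[str, np.ndarray],
               sample_ids: list[str], path) -> None:
    import pysam

    header = pysam.VariantHeader()
    for chrom, df in loci.items():
        header.contigs.add(chrom, length=int(df["pos"].max()) + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, df in loci.items():
            h = haps[chrom]
            for i, row in enumerate(df.itertuples(index=False)):
                rec = out.new_record(
                    contig=chrom, start=int(row.pos) - 1, stop=int(row.pos),
                    alleles=(row.ref, row.alt),
                    id=None if row.rsid == "." else row.rsid,
                )
                for j, s in enumerate(sample_ids):
                    rec.samples[s]["GT"] = (int(h[2 * j, i]), int(h[2 * j + 1, i]))
                    rec.samples[s].phased = True
                out.write(rec)


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel's phased haplotypes as an uncompressed VCF."""
    _write_vcf(panel.loci, panel.haps, panel.sample_ids, path)


def write_population_table(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.pop_of_sample[s]}\n")


def write_cohort(cohort, out_prefix) -> dict[str, Path]:
    """Write a simulated cohort: phased VCF, phenotype TSV, local-ancestry BED.

    The BED uses 0-based half-open intervals with columns chrom, start, end,
    name (sampleID_hapIndex), score (0), strand (.), and the source
    population label in column 7 (custom dialect).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "phenotypes": Path(str(prefix) + ".phenotypes.tsv"),
        "ancestry": Path(str(prefix) + ".ancestry.bed"),
    }

    hap_mats = {c: cohort.haplotype_matrix(c) for c in cohort.chroms}
    _write_vcf(cohort.loci, hap_mats, cohort.sample_ids, paths["vcf"])

    pheno = pd.DataFrame({"sample_id": cohort.sample_ids,
                          cohort.phenotype_name: cohort.phenotypes})
    admix = cohort.admixture
    for k, pop in enumerate(cohort.pops):
        pheno[f"admix_{pop}"] = admix[:, k]
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False,
                 float_format="%.10g")

    with open(paths["ancestry"], "w") as fh:
        for i, ind in enumerate(cohort.individuals):
            sid = cohort.sample_ids[i]
            for chrom in cohort.chroms:
                pos = cohort.loci[chrom]["pos"].to_numpy()
                for h, plan in enumerate(ind.plans[chrom]):
                    for start_l, end_l, pop_idx in plan.segments(pos.size):
                        start = int(pos[start_l]) - 1  # 0-based half-open
                        end = int(pos[end_l - 1])
                        fh.write(f"{chrom}\t{start}\t{end}\t{sid}_{h}\t0\t.\t"
                                 f"{cohort.pops[pop_idx]}\n")
    return paths
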