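"""Variant filtering and per-sample heterozygosity accounting.

The in-memory substrate is :class:`VariantTable`: one row per biallelic
SNV with a per-sample genotype code (0 hom-ref, 1 het, 2 hom-alt,
-1 missing) and per-sample read depth.  Filters reproduce a
VCFtools-style post-calling pipeline: per-genotype depth masking,
site-level quality, missingness and minor-allele-frequency cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rohscan.io import CallabilityMask, GenomeIndex
from rohscan import intervals as iv

__all__ = [
    "VariantTable",
    "FilterParams",
    "FilterStats",
    "read_vcf",
    "filter_variants",
    "select_scaffolds",
    "exclude_coverage_outliers",
    "genome_wide_heterozygosity",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantTable:
    """Biallelic SNV records with per-sample genotypes and depths.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, column order of the genotype matrix.
    scaffold : (n_sites,) array of str
    position : (n_sites,) int array, 1-based
    qual : (n_sites,) float array, phred-scaled site quality
    genotypes : (n_sites, n_samples) int8 array
        0 hom-ref, 1 het, 2 hom-alt, -1 missing.  A genotype with any
        missing allele counts as missing; phasing is ignored.
    depth : (n_sites, n_samples) int32 array of per-genotype read depth
    """

    samples: list[str]
    scaffold: np.ndarray
    position: np.ndarray
    qual: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.position)
        if not (len(self.scaffold) == len(self.qual) == n
                and self.genotypes.shape == (n, len(self.samples))
                and self.depth.shape == (n, len(self.samples))):
            raise ValueError("inconsistent VariantTable dimensions")
        if n and np.any(self.position < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        if n and np.any(self.depth < 0):
            raise ValueError("negative depth")

    @property
    def n_sites(self) -> int:
        return len(self.position)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def het_positions(self, sample: str) -> dict[str, np.ndarray]:
        """Sorted heterozygous-site positions per scaffold for one sample."""
        j = self.sample_index(sample)
        het = self.genotypes[:, j] == HET
        out: dict[str, np.ndarray] = {}
        for scaf in pd.unique(self.scaffold):
            m = het & (self.scaffold == scaf)
            out[str(scaf)] = np.sort(self.position[m])
        return out

    def subset_sites(self, keep: np.ndarray) -> "VariantTable":
        return VariantTable(self.samples, self.scaffold[keep], self.position[keep],
                            self.qual[keep], self.genotypes[keep], self.depth[keep])


@dataclass
class FilterParams:
    """Site/genotype filter thresholds (defaults follow a 3-30x, Q30 design)."""

    depth_min: int = 3
    depth_max: int = 30
    qual_min: float = 30.0
    max_missing_frac: float = 0.20
    maf_min: float = 0.02


@dataclass
class FilterStats:
    n_input: int = 0
    n_multiallelic_rejected: int = 0
    n_genotypes_depth_masked: int = 0
    n_dropped_qual: int = 0
    n_dropped_missing: int = 0
    n_dropped_maf: int = 0
    n_dropped_all_missing: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_vcf(path: str | Path, stats: FilterStats | None = None) -> VariantTable:
    """Load biallelic SNVs from a VCF (plain or bgzipped) via cyvcf2.

    Records with more than one ALT allele, or with non-SNV alleles, are
    rejected and counted; they are never decomposed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    scafs, poss, quals, gts, dps = [], [], [], [], []
    n_rejected = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_rejected += 1
            continue
        scafs.append(v.CHROM)
        poss.append(v.POS)
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        gt = np.asarray(v.gt_types, dtype=np.int8)  # gts012: 0,1,2; 3=missing
        gt[gt == 3] = MISSING
        gts.append(gt)
        dp = v.format("DP")
        if dp is None:
            dps.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dp = dp.astype(np.int32).reshape(-1)
            dp[dp < 0] = 0
            dps.append(dp)
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} multi-allelic or non-SNV records")
        if stats is not None:
            stats.n_multiallelic_rejected = n_rejected
    if not poss:
        empty = np.empty((0, len(samples)), dtype=np.int8)
        return VariantTable(samples, np.empty(0, dtype=object), np.empty(0, dtype=np.int64),
                            np.empty(0), empty, empty.astype(np.int32))
    return VariantTable(
        samples,
        np.array(scafs, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(quals, dtype=float),
        np.stack(gts),
        np.stack(dps),
    )


def filter_variants(table: VariantTable, params: FilterParams | None = None,
                    stats: FilterStats | None = None) -> VariantTable:
    """Apply depth masking and site-level quality/missingness/MAF filters.

    A genotype whose depth falls outside ``[depth_min, depth_max]`` is set
    to missing at that sample only.  A site failing the quality cut, the
    missingness cut (computed on the depth-masked genotypes) or the MAF
    cut (allele frequency from the same masked genotypes) is dropped
    entirely.  Input order is preserved; the operation is idempotent.
    """
    params = params or FilterParams()
    stats = stats if stats is not None else FilterStats()
    stats.n_input = table.n_sites
    if table.n_sites == 0:
        stats.n_output = 0
        return table

    gt = table.genotypes.copy()
    bad_depth = ((table.depth < params.depth_min) | (table.depth > params.depth_max)) & (gt != MISSING)
    stats.n_genotypes_depth_masked = int(bad_depth.sum())
    gt[bad_depth] = MISSING

    n_samples = len(table.samples)
    missing = gt == MISSING
    n_missing = missing.sum(axis=1)
    n_called = n_samples - n_missing

    pass_qual = np.nan_to_num(table.qual, nan=-np.inf) >= params.qual_min
    any_called = n_called > 0
    pass_missing = n_missing <= params.max_missing_frac * n_samples

    alt_alleles = np.where(gt == HET, 1, 0).sum(axis=1) + 2 * np.where(gt == HOM_ALT, 1, 0).sum(axis=1)
    n_alleles = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_alleles > 0, alt_alleles / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    pass_maf = maf >= params.maf_min

    stats.n_dropped_qual = int((~pass_qual).sum())
    stats.n_dropped_all_missing = int((pass_qual & ~any_called).sum())
    stats.n_dropped_missing = int((pass_qual & any_called & ~pass_missing).sum())
    stats.n_dropped_maf = int((pass_qual & any_called & pass_missing & ~pass_maf).sum())

    keep = pass_qual & any_called & pass_missing & pass_maf
    stats.n_output = int(keep.sum())
    out = VariantTable(table.samples, table.scaffold[keep], table.position[keep],
                       table.qual[keep], gt[keep], table.depth[keep])
    return out


def select_scaffolds(index: GenomeIndex, min_len: int = 45_000_000) -> list[str]:
    """Scaffolds strictly longer than ``min_len`` bp, in index order."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    kept = [s for s, ln in index.lengths.items() if ln > min_len]
    if not kept:
        raise ValueError(f"no scaffold longer than {min_len} bp; pipeline cannot proceed")
    return kept


def exclude_coverage_outliers(coverage_windows: pd.DataFrame, index: GenomeIndex,
                              sd_x: float = 1.0, sd_auto: float = 2.0) -> CallabilityMask:
    """Windows whose mean depth deviates from the genome-wide mean.

    The deviation threshold is ``sd_x`` standard deviations on the
    X-aligned scaffold and ``sd_auto`` elsewhere — the asymmetry targets
    hemizygous (half-coverage) sex-linked sequence in males while leaving
    ordinary autosomal coverage noise alone.

    Parameters
    ----------
    coverage_windows : DataFrame with columns scaffold, start, end, depth
        1-based inclusive window coordinates and mean depth per window.

    Returns
    -------
    CallabilityMask of *excluded* intervals, to be subtracted from the
    callability mask.
    """
    required = {"scaffold", "start", "end", "depth"}
    if not required.issubset(coverage_windows.columns):
        raise ValueError(f"coverage_windows needs columns {sorted(required)}")
    depth = coverage_windows["depth"].to_numpy(dtype=float)
    mean, sd = float(np.mean(depth)), float(np.std(depth))
    if sd == 0.0:
        warnings.warn("coverage is constant (SD = 0); no coverage exclusions applied")
        return CallabilityMask({})
    is_x = coverage_windows["scaffold"].to_numpy() == index.x_scaffold
    thresh = np.where(is_x, sd_x, sd_auto) * sd
    out = np.abs(depth - mean) > thresh
    regions: dict[str, np.ndarray] = {}
    for scaf, sub in coverage_windows.loc[out].groupby("scaffold", sort=False):
        regions[str(scaf)] = iv.merge(sub[["start", "end"]].to_numpy(dtype=np.int64))
    return CallabilityMask(regions)


def genome_wide_heterozygosity(table: VariantTable, mask: CallabilityMask,
                               sample: str) -> tuple[float, pd.DataFrame]:
    """Heterozygous positions per callable bp, overall and per scaffold.

    Only het sites lying inside the callability mask are counted; the
    denominator is the mask's callable bp on its scaffolds.
    """
    total_callable = mask.total_bp
    if total_callable == 0:
        raise ValueError("callability mask is empty; heterozygosity undefined")
    j = table.sample_index(sample)
    het = table.genotypes[:, j] == HET
    rows = []
    total_het = 0
    for scaf, regions in mask.regions.items():
        m = het & (table.scaffold == scaf)
        pos = table.position[m]
        inside = int(mask.contains(scaf, pos).sum())
        callable_bp = iv.total_bp(regions)
        rows.append({"scaffold": scaf, "het_sites": inside, "callable_bp": callable_bp,
                     "heterozygosity": inside / callable_bp if callable_bp else np.nan})
        total_het += inside
    return total_het / total_callable, pd.DataFrame(rows)
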