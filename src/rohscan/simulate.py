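"""Synthetic diploid genomes with known autozygosity.

The analysis pipeline consumes only per-site het/hom status, depth and
quality, so the generator emulates exactly that: a marked Poisson
process of heterozygous sites at a background rate outside autozygous
tracts and a much lower rate inside them, on a multi-scaffold genome
with callability gaps, sequenced at low coverage (Poisson depth around
7x).  No coalescent genealogy is simulated — the marked-process model
is the minimal sufficient emulation for windowed-heterozygosity RoH
detection, and every emitted dataset ships its ground truth.

Two modes:

* ``planted`` — autozygous tracts drawn directly from a length
  distribution until a target genome fraction is reached, independently
  per sample.
* ``gene_drop`` — founder haplotypes dropped through a pedigree with
  Poisson crossovers; an interval is autozygous when both inherited
  haplotype labels coincide, so realized IBD varies around F_PED
  through Mendelian sampling and linkage.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rohscan import intervals as iv
from rohscan.io import CallabilityMask, GenomeIndex, write_bed
from rohscan.pedigree import Pedigree
from rohscan.variants import VariantTable

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "plant_tracts",
    "gene_drop",
    "realized_ibd_replicates",
    "simulate_het_positions",
    "build_mask",
    "make_variant_table",
    "emit_dataset",
    "write_vcf",
    "cohort_pedigree",
]


def _default_lengths() -> dict[str, int]:
    return {f"scaffold_{i}": 15_000_000 for i in range(1, 5)}


def _default_groups() -> dict[str, int]:
    # captive-breeding cohort design: founders, two captive-born
    # generations, and an unmanaged wild reference group
    return {"Founder": 13, "F1": 8, "F2": 4, "Moroccan": 5}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the study system at reduced genome size.

    Rates are per bp: background heterozygosity 2.4e-4 (the observed
    cohort medians are 2.1-2.66e-4) and 1e-5 inside autozygous tracts.
    Depth is Poisson with mean 7 so the 3-30x depth filter is
    meaningfully exercised.  ``recombination_rate`` is crossovers per
    Mb per meiosis (0.01 = 1 cM/Mb).
    """

    scaffold_lengths: dict[str, int] = field(default_factory=_default_lengths)
    x_scaffold: str | None = None
    background_het_rate: float = 2.4e-4
    roh_het_rate: float = 1e-5
    mask_gap_fraction: float = 0.05
    mask_gap_mean_len: int = 10_000
    groups: dict[str, int] = field(default_factory=_default_groups)
    mode: str = "planted"  # or "gene_drop"
    roh_fraction: float = 0.25
    tract_min_len: int = 500_000
    tract_mean_len: int = 2_000_000
    recombination_rate: float = 0.01
    depth_mean: float = 7.0
    spiked_fail_fraction: float = 0.0
    pedigree: Pedigree | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.roh_fraction <= 1:
            raise ValueError("roh_fraction must lie in [0, 1]")
        if self.roh_het_rate >= self.background_het_rate:
            raise ValueError("roh_het_rate must be below background_het_rate")
        if min(self.background_het_rate, self.roh_het_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.mode not in ("planted", "gene_drop"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tract_min_len > self.tract_mean_len:
            raise ValueError("tract_min_len must not exceed tract_mean_len")

    @property
    def index(self) -> GenomeIndex:
        return GenomeIndex(dict(self.scaffold_lengths), self.x_scaffold)

    @property
    def genome_bp(self) -> int:
        return sum(self.scaffold_lengths.values())

    def sample_names(self) -> list[str]:
        if self.mode == "gene_drop":
            if self.pedigree is None:
                raise ValueError("gene_drop mode requires a pedigree")
            return self.pedigree.individuals
        n = sum(self.groups.values())
        return [f"S{i:02d}" for i in range(1, n + 1)]

    def sample_groups(self) -> dict[str, str]:
        names = self.sample_names()
        if self.mode == "gene_drop" and "cohort" in self.pedigree.table.columns:
            return dict(zip(self.pedigree.table["id"], self.pedigree.table["cohort"]))
        labels = [g for g, k in self.groups.items() for _ in range(k)]
        if len(labels) < len(names):
            labels += [labels[-1] if labels else "all"] * (len(names) - len(labels))
        return dict(zip(names, labels))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class TruthSet:
    """Ground-truth autozygosity: per-sample tracts and genome fractions."""

    tracts: dict[str, dict[str, np.ndarray]]
    fractions: dict[str, float]
    realized_ibd: dict[str, float] | None = None

    def write_bed(self, path: str | Path, sample: str, header: str | None = None) -> None:
        write_bed(path, self.tracts[sample], header=header)


# ---------------------------------------------------------------------------
# planted mode

def _place_tracts(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Non-overlapping tracts until the target fraction is within half a mean length."""
    target = config.roh_fraction * config.genome_bp
    if config.roh_fraction > 0.95:
        raise ValueError("target autozygous fraction > 0.95 is infeasible "
                         "for non-overlapping placement")
    scafs = list(config.scaffold_lengths)
    lens = np.array([config.scaffold_lengths[s] for s in scafs], dtype=float)
    probs = lens / lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in scafs}
    total = 0.0
    half_mean = 0.5 * config.tract_mean_len
    max_tries = 10_000
    while total < target - half_mean:
        length = config.tract_min_len + int(rng.exponential(
            config.tract_mean_len - config.tract_min_len)) if config.tract_mean_len > config.tract_min_len \
            else config.tract_min_len
        # cap the closing tract so the total never overshoots by more than half a mean
        length = min(length, int(target + half_mean - total))
        if length < 1:
            break
        for _ in range(max_tries):
            scaf = scafs[rng.choice(len(scafs), p=probs)]
            L = config.scaffold_lengths[scaf]
            if length > L:
                continue
            start = int(rng.integers(1, L - length + 2))
            end = start + length - 1
            if all(end < s0 - 1 or start > e0 + 1 for s0, e0 in placed[scaf]):
                placed[scaf].append((start, end))
                total += length
                break
        else:
            raise RuntimeError("could not place tract without overlap; "
                               "target fraction too high for tract length distribution")
    return {s: iv.merge(np.array(v, dtype=np.int64)) for s, v in placed.items() if v}


def plant_tracts(config: SimulationConfig) -> TruthSet:
    """Independent per-sample autozygous tracts at the configured genome fraction."""
    rng = config._rng(1)
    tracts: dict[str, dict[str, np.ndarray]] = {}
    fractions: dict[str, float] = {}
    for sample in config.sample_names():
        if config.roh_fraction == 0:
            tracts[sample] = {}
            fractions[sample] = 0.0
            continue
        t = _place_tracts(config, rng)
        tracts[sample] = t
        fractions[sample] = sum(iv.total_bp(r) for r in t.values()) / config.genome_bp
    return TruthSet(tracts=tracts, fractions=fractions)


# ---------------------------------------------------------------------------
# gene-drop mode

class _Mosaic:
    """Haplotype as founder-label segments: ends (cumulative, 1-based) + labels."""

    __slots__ = ("ends", "labels")

    def __init__(self, ends: np.ndarray, labels: np.ndarray):
        self.ends = ends
        self.labels = labels

    @classmethod
    def founder(cls, length: int, label: int) -> "_Mosaic":
        return cls(np.array([length], dtype=np.int64), np.array([label], dtype=np.int64))

    def slice_labels(self, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """Segment ends and labels covering [a, b]."""
        i0 = int(np.searchsorted(self.ends, a))
        i1 = int(np.searchsorted(self.ends, b))
        ends = self.ends[i0:i1 + 1].copy()
        ends[-1] = b
        return ends, self.labels[i0:i1 + 1].copy()


def _gamete(h1: _Mosaic, h2: _Mosaic, length: int, rate_per_bp: float,
            rng: np.random.Generator) -> _Mosaic:
    n_x = rng.poisson(rate_per_bp * length)
    if n_x:
        cuts = np.unique(rng.integers(1, length, size=n_x))
    else:
        cuts = np.empty(0, dtype=np.int64)
    bounds = np.concatenate([[0], cuts, [length]]).astype(np.int64)
    which = int(rng.integers(2))
    ends_parts, label_parts = [], []
    for k in range(len(bounds) - 1):
        a, b = int(bounds[k]) + 1, int(bounds[k + 1])
        src = (h1, h2)[(which + k) % 2]
        e, l = src.slice_labels(a, b)
        ends_parts.append(e)
        label_parts.append(l)
    ends = np.concatenate(ends_parts)
    labels = np.concatenate(label_parts)
    # merge equal-label neighbours
    keep = np.ones(len(ends), dtype=bool)
    keep[:-1] = labels[:-1] != labels[1:]
    return _Mosaic(ends[keep], labels[keep])


def _autozygous_intervals(h1: _Mosaic, h2: _Mosaic) -> np.ndarray:
    """Intervals where the two haplotype mosaics carry the same founder label."""
    bounds = np.unique(np.concatenate([h1.ends, h2.ends]))
    starts = np.concatenate([[1], bounds[:-1] + 1])
    l1 = h1.labels[np.searchsorted(h1.ends, starts)]
    l2 = h2.labels[np.searchsorted(h2.ends, starts)]
    same = l1 == l2
    if not same.any():
        return np.empty((0, 2), dtype=np.int64)
    return iv.merge(np.column_stack([starts[same], bounds[same]]))


def gene_drop(ped: Pedigree, config: SimulationConfig,
              rng: np.random.Generator | None = None) -> TruthSet:
    """One Monte-Carlo transmission of founder haplotypes through the pedigree.

    Each founder carries two globally unique haplotype labels.  Every
    meiosis draws Poisson crossovers with uniform positions; an interval
    is autozygous when both inherited labels are identical.
    """
    if rng is None:
        rng = config._rng(2)
    rate_per_bp = config.recombination_rate / 1e6
    scafs = list(config.scaffold_lengths)
    genomes: dict[str, dict[str, tuple[_Mosaic, _Mosaic]]] = {}
    next_label = 0
    for ind in ped.topological_order:
        sire, dam = ped.parents(ind)
        genomes[ind] = {}
        for scaf in scafs:
            L = config.scaffold_lengths[scaf]
            haps = []
            for parent in (sire, dam):
                if parent is None:
                    haps.append(_Mosaic.founder(L, next_label))
                    next_label += 1
                else:
                    p1, p2 = genomes[parent][scaf]
                    haps.append(_gamete(p1, p2, L, rate_per_bp, rng))
            genomes[ind][scaf] = (haps[0], haps[1])

    tracts: dict[str, dict[str, np.ndarray]] = {}
    fractions: dict[str, float] = {}
    genome_bp = config.genome_bp
    for ind in ped.individuals:
        t = {}
        for scaf in scafs:
            auto = _autozygous_intervals(*genomes[ind][scaf])
            if len(auto):
                t[scaf] = auto
        tracts[ind] = t
        fractions[ind] = sum(iv.total_bp(r) for r in t.values()) / genome_bp
    return TruthSet(tracts=tracts, fractions=fractions, realized_ibd=dict(fractions))


def realized_ibd_replicates(ped: Pedigree, config: SimulationConfig,
                            n_replicates: int, seed: int | None = None) -> dict[str, np.ndarray]:
    """Realized autozygous fractions over repeated gene drops, per individual."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = config.seed if seed is None else seed
    out = {ind: np.empty(n_replicates) for ind in ped.individuals}
    for r in range(n_replicates):
        truth = gene_drop(ped, config, rng=np.random.default_rng([int(base), 2, r]))
        for ind, f in truth.fractions.items():
            out[ind][r] = f
    return out


def cohort_pedigree(n_founders: int = 13, n_f1: int = 8, n_f2: int = 4,
                    seed: int = 0) -> Pedigree:
    """Random three-cohort pedigree: founders -> F1 -> F2 matings.

    Founder sexes alternate; each F1 individual draws a founder sire and
    dam, each F2 individual draws parents among founder males and F1
    females, so later cohorts can be inbred.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for i in range(1, n_founders + 1):
        name = f"G{i:02d}"
        sex = "M" if i % 2 else "F"
        (males if sex == "M" else females).append(name)
        rows.append({"id": name, "sire": "0", "dam": "0", "sex": sex, "cohort": "Founder"})
    f1_females = []
    for i in range(1, n_f1 + 1):
        name = f"F1_{i:02d}"
        sex = "M" if i % 2 else "F"
        rows.append({"id": name, "sire": males[rng.integers(len(males))],
                     "dam": females[rng.integers(len(females))], "sex": sex, "cohort": "F1"})
        if sex == "F":
            f1_females.append(name)
    for i in range(1, n_f2 + 1):
        name = f"F2_{i:02d}"
        dam_pool = f1_females or females
        rows.append({"id": name, "sire": males[rng.integers(len(males))],
                     "dam": dam_pool[rng.integers(len(dam_pool))],
                     "sex": "M" if i % 2 else "F", "cohort": "F2"})
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# emission

def build_mask(config: SimulationConfig) -> CallabilityMask:
    """Callability mask with random uncallable gaps carved per scaffold."""
    rng = config._rng(3)
    regions = {}
    for scaf, L in config.scaffold_lengths.items():
        gaps = []
        n_gaps = rng.poisson(config.mask_gap_fraction * L / max(config.mask_gap_mean_len, 1))
        for _ in range(n_gaps):
            length = max(1, int(rng.exponential(config.mask_gap_mean_len)))
            start = int(rng.integers(1, max(L - length, 1) + 1))
            gaps.append((start, min(start + length - 1, L)))
        full = np.array([[1, L]], dtype=np.int64)
        if gaps:
            regions[scaf] = iv.subtract(full, np.array(gaps, dtype=np.int64))
        else:
            regions[scaf] = full
    return CallabilityMask(regions)


def _positions_in(regions: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-process positions on the bp covered by merged intervals."""
    n_bp = iv.total_bp(regions)
    if n_bp == 0 or rate <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * n_bp)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.sort(rng.integers(0, n_bp, size=n))
    lens = regions[:, 1] - regions[:, 0] + 1
    cum = np.concatenate([[0], np.cumsum(lens)])
    k = np.searchsorted(cum, offsets, side="right") - 1
    pos = regions[k, 0] + (offsets - cum[k])
    return np.unique(pos)


def simulate_het_positions(truth: TruthSet, config: SimulationConfig,
                           mask: CallabilityMask | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample het-site positions: background rate outside tracts, low rate inside."""
    if mask is None:
        mask = build_mask(config)
    rng = config._rng(4)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample in truth.tracts:
        per_scaf: dict[str, np.ndarray] = {}
        for scaf in config.scaffold_lengths:
            callable_ = mask.for_scaffold(scaf)
            t = truth.tracts[sample].get(scaf, np.empty((0, 2), dtype=np.int64))
            inside = iv.intersect(callable_, t)
            outside = iv.subtract(callable_, t)
            pos = np.concatenate([
                _positions_in(outside, config.background_het_rate, rng),
                _positions_in(inside, config.roh_het_rate, rng),
            ])
            per_scaf[scaf] = np.sort(pos)
        out[sample] = per_scaf
    return out


def make_variant_table(truth: TruthSet, config: SimulationConfig,
                       mask: CallabilityMask | None = None,
                       het_positions: dict[str, dict[str, np.ndarray]] | None = None,
                       ) -> tuple[VariantTable, CallabilityMask, dict[str, dict[str, np.ndarray]]]:
    """Multi-sample genotype table consistent with each sample's het/hom truth.

    Het-site positions are unioned across samples.  At each site the alt
    allele frequency is drawn from Beta(0.5, 0.5); a sample that is not
    heterozygous there is homozygous alt with that probability and
    homozygous ref otherwise, so no extra heterozygosity is introduced.
    Depth is Poisson(depth_mean) per genotype and quality passes the Q30
    filter, except for spiked filter-failing sites (see
    ``spiked_fail_fraction``), whose positions are returned for truth
    bookkeeping.

    Returns (table, mask, spiked) where ``spiked`` maps filter class ->
    scaffold -> positions of sites constructed to fail that class.
    """
    if mask is None:
        mask = build_mask(config)
    if het_positions is None:
        het_positions = simulate_het_positions(truth, config, mask)
    rng = config._rng(5)
    samples = list(truth.tracts)
    n_samples = len(samples)

    scafs_arr, pos_arr, qual_arr, gt_rows, dp_rows = [], [], [], [], []
    spiked: dict[str, dict[str, list[int]]] = {c: {} for c in ("qual", "depth", "missing", "maf")}
    for scaf in config.scaffold_lengths:
        union = np.unique(np.concatenate(
            [het_positions[s].get(scaf, np.empty(0, dtype=np.int64)) for s in samples]
            or [np.empty(0, dtype=np.int64)]))
        if len(union) == 0:
            continue
        het_mask = np.zeros((len(union), n_samples), dtype=bool)
        for j, s in enumerate(samples):
            p = het_positions[s].get(scaf, np.empty(0, dtype=np.int64))
            het_mask[np.searchsorted(union, p), j] = True
        p_alt = rng.beta(0.5, 0.5, size=len(union))
        hom_alt = rng.random((len(union), n_samples)) < p_alt[:, None]
        gt = np.where(het_mask, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
        dp = rng.poisson(config.depth_mean, size=gt.shape).astype(np.int32)
        qual = rng.uniform(40.0, 90.0, size=len(union))

        if config.spiked_fail_fraction > 0:
            n_spike = int(round(config.spiked_fail_fraction * len(union)))
            free = iv.subtract(mask.for_scaffold(scaf),
                               np.column_stack([union, union]))
            for cls in spiked:
                extra = _positions_in_exact(free, n_spike, rng)
                extra = np.setdiff1d(extra, union)
                if len(extra) == 0:
                    continue
                spiked[cls].setdefault(scaf, []).extend(extra.tolist())
                e_gt = np.zeros((len(extra), n_samples), dtype=np.int8)
                e_dp = rng.poisson(config.depth_mean, size=e_gt.shape).astype(np.int32)
                e_qual = rng.uniform(40.0, 90.0, size=len(extra))
                # every spiked class stays variable (one het carrier) so only
                # the targeted filter can be the reason it is removed
                e_gt[:, 0] = 1
                if cls == "qual":
                    e_qual[:] = 10.0
                elif cls == "depth":
                    e_dp[:] = 1  # below depth_min everywhere -> all genotypes masked
                elif cls == "missing":
                    k = max(1, int(np.ceil(0.25 * n_samples)) + 1)
                    e_gt[:, -k:] = -1
                elif cls == "maf":
                    e_gt[:, 1:] = 0  # single het carrier: MAF = 1/(2n) < 0.02 for n >= 26
                    e_dp[:] = 7  # keep every genotype callable so n stays >= 26
                union = np.concatenate([union, extra])
                gt = np.vstack([gt, e_gt])
                dp = np.vstack([dp, e_dp])
                qual = np.concatenate([qual, e_qual])
            order = np.argsort(union, kind="stable")
            union, gt, dp, qual = union[order], gt[order], dp[order], qual[order]

        scafs_arr.append(np.full(len(union), scaf, dtype=object))
        pos_arr.append(union)
        qual_arr.append(qual)
        gt_rows.append(gt)
        dp_rows.append(dp)

    if not pos_arr:
        empty = np.empty((0, n_samples), dtype=np.int8)
        table = VariantTable(samples, np.empty(0, dtype=object), np.empty(0, dtype=np.int64),
                             np.empty(0), empty, empty.astype(np.int32))
    else:
        table = VariantTable(samples, np.concatenate(scafs_arr), np.concatenate(pos_arr),
                             np.concatenate(qual_arr), np.vstack(gt_rows), np.vstack(dp_rows))
    spiked_arr = {c: {s: np.array(sorted(v), dtype=np.int64) for s, v in d.items()}
                  for c, d in spiked.items()}
    return table, mask, spiked_arr


def _positions_in_exact(regions: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    n_bp = iv.total_bp(regions)
    if n_bp == 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.sort(rng.choice(n_bp, size=min(n, n_bp), replace=False))
    lens = regions[:, 1] - regions[:, 0] + 1
    cum = np.concatenate([[0], np.cumsum(lens)])
    k = np.searchsorted(cum, offsets, side="right") - 1
    return regions[k, 0] + (offsets - cum[k])


_BASES = np.array(list("ACGT"))


def write_vcf(table: VariantTable, path: str | Path, index: GenomeIndex,
              seed: int | None = None) -> None:
    """Write a plain-text VCF v4.2 with GT:DP genotype fields."""
    rng = np.random.default_rng(0 if seed is None else seed)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##rohscan_seed={seed}\n")
        for scaf, ln in index.lengths.items():
            fh.write(f"##contig=<ID={scaf},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        refs = _BASES[rng.integers(0, 4, size=table.n_sites)]
        alt_off = rng.integers(1, 4, size=table.n_sites)
        for i in range(table.n_sites):
            ref = refs[i]
            alt = _BASES[(np.where(_BASES == ref)[0][0] + alt_off[i]) % 4]
            fields = [f"{gt_str[int(g)]}:{int(d)}"
                      for g, d in zip(table.genotypes[i], table.depth[i])]
            fh.write(f"{table.scaffold[i]}\t{table.position[i]}\t.\t{ref}\t{alt}\t"
                     f"{table.qual[i]:.1f}\tPASS\t.\tGT:DP\t" + "\t".join(fields) + "\n")


def emit_dataset(truth: TruthSet, config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset: VCF, mask BED, genome index,
    sample sheet, pedigree TSV (gene_drop mode) and per-sample truth BEDs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, mask, spiked = make_variant_table(truth, config)
    index = config.index
    paths: dict[str, Path] = {}

    paths["vcf"] = outdir / "variants.vcf"
    write_vcf(table, paths["vcf"], index, seed=config.seed)
    paths["mask"] = outdir / "callable.bed"
    mask.write_bed(paths["mask"], header=f"rohscan_seed={config.seed}")
    paths["index"] = outdir / "genome.tsv"
    index.write_tsv(paths["index"])

    groups = config.sample_groups()
    sheet = pd.DataFrame({
        "sample": list(truth.tracts),
        "group": [groups.get(s, "all") for s in truth.tracts],
        "studbook_id": [s if config.mode == "gene_drop" else "" for s in truth.tracts],
    })
    paths["sample_sheet"] = outdir / "samples.tsv"
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    if config.mode == "gene_drop" and config.pedigree is not None:
        paths["pedigree"] = outdir / "pedigree.tsv"
        config.pedigree.write_tsv(paths["pedigree"])

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for sample in truth.tracts:
        p = truth_dir / f"{sample}.roh_truth.bed"
        truth.write_bed(p, sample, header=f"rohscan_seed={config.seed}")
        paths[f"truth:{sample}"] = p
    if any(d for d in spiked.values()):
        rows = [(cls, scaf, int(p)) for cls, d in spiked.items()
                for scaf, arr in d.items() for p in arr]
        paths["spiked"] = outdir / "spiked_sites.tsv"
        pd.DataFrame(rows, columns=["filter_class", "scaffold", "position"]).to_csv(
            paths["spiked"], sep="\t", index=False)
    return paths
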