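"""End-to-end orchestration: filter -> windows -> HMM -> RoH -> inbreeding -> sharing.

`run_pipeline` ties the stages together on files (VCF + mask + index +
sample sheet [+ pedigree]) and writes every declared output as TSV/BED
with a provenance header (tool version, config hash, seed).  All stages
are deterministic functions of (inputs, config, seed): re-running with
the same inputs gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rohscan import intervals as iv
from rohscan.io import CallabilityMask, GenomeIndex, write_bed, write_header
from rohscan.variants import (FilterParams, FilterStats, filter_variants,
                              genome_wide_heterozygosity, read_vcf, select_scaffolds)
from rohscan.windows import build_window_track
from rohscan.hmm import (WindowHMM, baseline_threshold_caller, roh_to_regions)
from rohscan.inbreeding import compare_groups, correlation_matrix, f_hom_all, f_roh
from rohscan.sharing import jaccard_matrix, sharing_spectrum
from rohscan.pedigree import Pedigree, f_ped, kinship_matrix

log = logging.getLogger("rohscan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; defaults are the published design."""

    vcf: str = ""
    mask: str = ""
    genome_index: str = ""
    sample_sheet: str = ""
    pedigree: str = ""
    outdir: str = "rohscan_out"
    x_scaffold: str | None = None
    min_scaffold_len: int = 45_000_000
    window_width: int = 150_000
    window_overlap: int = 100_000
    max_noncallable: int = 60_000
    min_roh_windows: int = 3
    baseline_cutoff: float = 1e-4
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 1000
    var_floor: float = 1e-12
    decode_method: str = "viterbi"
    seed: int = 0
    filters: FilterParams = field(default_factory=FilterParams)

    def validate(self) -> None:
        if self.window_width <= 0 or not 0 <= self.window_overlap < self.window_width:
            raise ValueError("window geometry invalid: need 0 <= overlap < width")
        if self.min_roh_windows < 1:
            raise ValueError("min_roh_windows must be >= 1")
        if self.hmm_tol <= 0 or self.hmm_max_iter < 1 or self.var_floor <= 0:
            raise ValueError("invalid HMM settings")
        if self.decode_method not in ("viterbi", "posterior"):
            raise ValueError("decode_method must be 'viterbi' or 'posterior'")
        for name in ("vcf", "mask", "genome_index"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        filt = raw.pop("filters", None)
        cfg = cls(**raw)
        if filt:
            cfg.filters = FilterParams(**filt)
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # results are a function of inputs, not destination
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results keyed by stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    results: dict[str, object] = {"config": config}

    index = GenomeIndex.read_tsv(config.genome_index, x_scaffold=config.x_scaffold)
    try:
        scaffolds = select_scaffolds(index, config.min_scaffold_len)
    except ValueError:
        # desk-scale inputs: fall back to all scaffolds rather than abort
        log.warning("no scaffold exceeds %d bp; retaining all scaffolds",
                    config.min_scaffold_len)
        scaffolds = index.scaffolds
    autosomes = [s for s in scaffolds if s != index.x_scaffold]
    mask = CallabilityMask.read_bed(config.mask).restrict(autosomes)

    stats = FilterStats()
    table = _stage("filter")(lambda: filter_variants(read_vcf(config.vcf, stats),
                                                     config.filters, stats))()
    keep = np.isin(table.scaffold, autosomes)
    table = table.subset_sites(keep)
    log.info("filter accounting: %s", stats.as_dict())
    results["filter_stats"] = stats

    sheet = (pd.read_csv(config.sample_sheet, sep="\t", dtype=str)
             if config.sample_sheet else
             pd.DataFrame({"sample": table.samples, "group": "all", "studbook_id": ""}))
    groups = dict(zip(sheet["sample"], sheet.get("group", "all")))

    het_rates = {}
    roh_hmm: dict[str, pd.DataFrame] = {}
    roh_base: dict[str, pd.DataFrame] = {}
    models = {}
    for i, sample in enumerate(table.samples):
        het_pos = {s: p[mask.contains(s, p)] for s, p in table.het_positions(sample).items()
                   if s in autosomes}
        track = build_window_track(het_pos, mask, index, sample=sample,
                                   width=config.window_width, overlap=config.window_overlap,
                                   scaffolds=autosomes)
        het_rates[sample], _ = genome_wide_heterozygosity(table, mask, sample)
        model = WindowHMM(track, var_floor=config.var_floor,
                          max_noncallable=config.max_noncallable)
        res = model.fit(seed=config.seed + i, tol=config.hmm_tol,
                        max_iter=config.hmm_max_iter)
        models[sample] = res
        roh_hmm[sample] = res.call_roh(min_windows=config.min_roh_windows,
                                       method=config.decode_method)
        roh_base[sample] = baseline_threshold_caller(track, config.baseline_cutoff,
                                                     config.min_roh_windows)
        log.info("sample %s: het=%.3e, RoH(HMM)=%d, RoH(baseline)=%d",
                 sample, het_rates[sample], len(roh_hmm[sample]), len(roh_base[sample]))
    results["models"] = models
    results["roh_hmm"] = roh_hmm
    results["roh_baseline"] = roh_base
    results["heterozygosity"] = het_rates

    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    all_segments = []
    for sample, segs in roh_hmm.items():
        models[sample].to_yaml(models_dir / f"{sample}.yaml")
        out = segs.copy()
        out.insert(0, "sample", sample)
        all_segments.append(out)
        write_bed(outdir / f"{sample}.roh.bed", roh_to_regions(segs),
                  header=f"sample={sample} seed={meta['seed']} config={meta['config_hash']}")
    seg_table = (pd.concat(all_segments, ignore_index=True) if all_segments
                 else pd.DataFrame(columns=["sample", "scaffold", "start", "end",
                                            "length", "n_windows", "mean_ratio"]))
    _write_tsv(outdir / "roh_segments.tsv", seg_table, meta)

    autosome_len = sum(index.lengths[s] for s in autosomes)
    inb = pd.DataFrame({
        "sample": list(table.samples),
        "group": [groups.get(s, "all") for s in table.samples],
        "heterozygosity": [het_rates[s] for s in table.samples],
        "F_ROH1": [f_roh(roh_hmm[s], autosome_len) for s in table.samples],
        "F_ROH2": [f_roh(roh_base[s], autosome_len) for s in table.samples],
    })
    inb = inb.merge(f_hom_all(table)["F_HOM"], left_on="sample", right_index=True)

    if config.pedigree:
        ped = Pedigree.read_tsv(config.pedigree)
        kin = kinship_matrix(ped)
        _write_tsv(outdir / "kinship.tsv", kin.reset_index(names="id"), meta)
        sb = dict(zip(sheet["sample"], sheet.get("studbook_id", "")))
        inb["F_PED"] = [
            f_ped(ped, sb[s], kin=kin) if sb.get(s) and str(sb[s]) in ped.individuals else np.nan
            for s in inb["sample"]]
        results["pedigree"] = ped
    _write_tsv(outdir / "inbreeding.tsv", inb, meta)
    results["inbreeding"] = inb

    metric_cols = [c for c in ("F_PED", "F_HOM", "F_ROH1", "F_ROH2") if c in inb.columns]
    rho, pval = correlation_matrix(inb.set_index("sample")[metric_cols])
    _write_tsv(outdir / "inbreeding_correlation.tsv", rho.reset_index(names="metric"), meta)
    results["correlation"] = (rho, pval)

    if inb["group"].nunique() >= 2 and inb.groupby("group").size().ge(2).sum() >= 2:
        comps = []
        for metric, test in [("heterozygosity", "anova_tukey"), ("F_ROH1", "wilcoxon_bh"),
                             ("F_ROH2", "wilcoxon_bh"), ("F_HOM", "wilcoxon_bh")]:
            c = compare_groups(inb[metric], inb["group"], test=test)
            c.insert(0, "metric", metric)
            c.insert(1, "test", test)
            comps.append(c)
        comp_table = pd.concat(comps, ignore_index=True)
        _write_tsv(outdir / "group_comparisons.tsv", comp_table, meta)
        results["group_comparisons"] = comp_table

    roh_sets = {s: roh_to_regions(df) for s, df in roh_hmm.items()}
    jac = jaccard_matrix(roh_sets)
    _write_tsv(outdir / "jaccard.tsv", jac.reset_index(names="sample"), meta)
    results["jaccard"] = jac
    if len(roh_sets) >= 2:
        spectrum, private = sharing_spectrum(roh_sets)
        _write_tsv(outdir / "sharing_spectrum.tsv", spectrum, meta)
        _write_tsv(outdir / "private_roh.tsv",
                   private.rename_axis("sample").reset_index(), meta)
        results["sharing"] = (spectrum, private)
    return results


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        write_header(fh, **meta)
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
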