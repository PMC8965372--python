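"""Genomic inbreeding coefficients and their comparison across estimators.

Three estimators on the same samples:

* ``F_ROH`` — fraction of the autosomal genome inside runs of
  homozygosity (from either the HMM caller, F_ROH1, or the threshold
  baseline, F_ROH2).
* ``F_HOM`` — method-of-moments coefficient from observed vs expected
  homozygous genotype counts, ``(O - E) / (N - E)``, with the
  finite-sample correction ``E_i = 1 - 2 p_i (1 - p_i) n_i / (n_i - 1)``
  per site.  Can be negative when a sample is more heterozygous than the
  panel's Hardy-Weinberg expectation.
* ``F_PED`` — pedigree expectation (see :mod:`rohscan.pedigree`),
  available only for samples with studbook records.

Cross-estimator agreement is summarized with pairwise-complete Spearman
correlations, and group contrasts with either pairwise rank-sum tests
under Benjamini-Hochberg control or one-way ANOVA followed by Tukey HSD.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rohscan.variants import VariantTable, HET, MISSING
from rohscan import intervals as iv

__all__ = ["f_roh", "f_hom", "f_hom_all", "correlation_matrix", "compare_groups"]


def f_roh(segments, autosome_len: int) -> float:
    """Fraction of the autosomes inside RoH.

    Parameters
    ----------
    segments : DataFrame with scaffold/start/end columns, or a mapping
        scaffold -> interval array.  Overlapping segments are merged
        before summing.
    autosome_len : total bp of the retained autosomal scaffolds.
    """
    if autosome_len <= 0:
        raise ValueError("autosome_len must be positive")
    if isinstance(segments, pd.DataFrame):
        from rohscan.hmm import roh_to_regions
        regions = roh_to_regions(segments)
    else:
        regions = segments
    total = sum(iv.total_bp(iv.merge(r)) for r in regions.values())
    return total / autosome_len


def _expected_hom_per_site(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site expected homozygosity and a usable-site flag.

    Allele frequencies come from all non-missing genotypes at the site;
    sites with fewer than 2 non-missing alleles (n_i - 1 = 0) are unusable.
    """
    called = gt != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(gt == HET, 1, 0).sum(axis=1) + 2 * np.where(gt == 2, 1, 0).sum(axis=1)
    usable = n_alleles >= 2
    p = np.zeros(len(gt), dtype=float)
    p[usable] = alt[usable] / n_alleles[usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(n_alleles > 1, n_alleles / np.maximum(n_alleles - 1, 1), 0.0)
    e_hom = 1.0 - 2.0 * p * (1.0 - p) * corr
    return e_hom, usable


def f_hom(table: VariantTable, sample: str) -> float:
    """Method-of-moments inbreeding coefficient for one sample."""
    return float(f_hom_all(table).loc[sample, "F_HOM"])


def f_hom_all(table: VariantTable) -> pd.DataFrame:
    """F_HOM for every sample: columns O_hom, E_hom, N_sites, F_HOM."""
    gt = table.genotypes
    e_hom, usable = _expected_hom_per_site(gt)
    rows = []
    for j, sample in enumerate(table.samples):
        called = (gt[:, j] != MISSING) & usable
        n = int(called.sum())
        obs = int(((gt[:, j] != HET) & called).sum())
        exp = float(e_hom[called].sum())
        denom = n - exp
        f = (obs - exp) / denom if denom != 0 else np.nan
        if denom == 0:
            warnings.warn(f"F_HOM undefined for {sample!r} (N - E = 0)")
        rows.append({"sample": sample, "O_hom": obs, "E_hom": exp, "N_sites": n, "F_HOM": f})
    return pd.DataFrame(rows).set_index("sample")


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       min_pairs: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete rank correlations between inbreeding estimators.

    Columns of ``table`` are estimators (e.g. F_PED, F_HOM, F_ROH1,
    F_ROH2), rows are samples; missing entries (samples without pedigree
    data) restrict that pair to its complete cases.

    Returns (rho, p) DataFrames; entries with fewer than ``min_pairs``
    complete cases are NaN, the diagonal is 1.
    """
    if method != "spearman":
        raise ValueError("only Spearman rank correlation is supported")
    cols = list(table.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        pair = table[[a, b]].dropna()
        if len(pair) < min_pairs:
            r = p = np.nan
        else:
            r, p = stats.spearmanr(pair[a], pair[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def compare_groups(values: pd.Series, groups: pd.Series,
                   test: str = "wilcoxon_bh") -> pd.DataFrame:
    """All pairwise group contrasts of a per-sample metric.

    ``wilcoxon_bh``: two-sided rank-sum (Mann-Whitney) tests for every
    group pair, Benjamini-Hochberg adjusted.  ``anova_tukey``: one-way
    ANOVA then Tukey HSD.  Groups with fewer than 2 members are excluded
    with a warning.

    Returns a DataFrame with group_a, group_b, statistic, p_raw, p_adj.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 members: {small}")
        df = df[~df["group"].isin(small)]
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    by = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in names}

    if test == "wilcoxon_bh":
        rows = []
        for a, b in combinations(names, 2):
            res = stats.mannwhitneyu(by[a], by[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
        out = pd.DataFrame(rows)
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        return out
    if test == "anova_tukey":
        anova = stats.f_oneway(*[by[g] for g in names])
        tukey = stats.tukey_hsd(*[by[g] for g in names])
        rows = []
        for i, a in enumerate(names):
            for k in range(i + 1, len(names)):
                b = names[k]
                rows.append({"group_a": a, "group_b": b,
                             "statistic": float(tukey.statistic[i, k]),
                             "p_raw": float(anova.pvalue),
                             "p_adj": float(tukey.pvalue[i, k])})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown test {test!r}")
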