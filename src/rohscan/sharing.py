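"""RoH colocalization among samples.

Two summaries of where RoH fall in the genome relative to each other:
pairwise Jaccard coefficients (shared RoH bp over union RoH bp) and the
sharing spectrum (how many bp of RoH are carried by exactly k samples).
Both run on merged 1-based inclusive interval sets via interval sweeps,
never per-bp loops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rohscan import intervals as iv

__all__ = ["jaccard", "jaccard_matrix", "sharing_spectrum"]

RegionMap = dict[str, np.ndarray]


def _merged(a: RegionMap) -> RegionMap:
    return {s: iv.merge(r) for s, r in a.items() if len(r)}


def jaccard(a: RegionMap, b: RegionMap) -> float:
    """Intersection-over-union in bp of two samples' RoH sets.

    When both sets are empty the coefficient is undefined in the pure
    formula; we return 0 by convention.
    """
    a, b = _merged(a), _merged(b)
    inter = sum(iv.total_bp(iv.intersect(a[s], b[s])) for s in a.keys() & b.keys())
    size_a = sum(iv.total_bp(r) for r in a.values())
    size_b = sum(iv.total_bp(r) for r in b.values())
    union = size_a + size_b - inter
    if union == 0:
        return 0.0
    return inter / union


def jaccard_matrix(roh_sets: dict[str, RegionMap]) -> pd.DataFrame:
    """Symmetric sample x sample Jaccard matrix.

    The diagonal is 1 for samples with any RoH and 0 (the empty-set
    convention) for samples with none.
    """
    samples = list(roh_sets)
    mat = pd.DataFrame(np.zeros((len(samples), len(samples))),
                       index=samples, columns=samples)
    for i, a in enumerate(samples):
        mat.loc[a, a] = jaccard(roh_sets[a], roh_sets[a])
        for b in samples[i + 1:]:
            j = jaccard(roh_sets[a], roh_sets[b])
            mat.loc[a, b] = mat.loc[b, a] = j
    return mat


def sharing_spectrum(roh_sets: dict[str, RegionMap]) -> tuple[pd.DataFrame, pd.Series]:
    """RoH bp by carrier count, plus per-sample private-RoH bp.

    Returns
    -------
    spectrum : DataFrame with columns n_carriers (1..n_samples) and bp.
    private_bp : Series, per sample, of RoH bp carried by that sample alone.
    """
    if len(roh_sets) < 2:
        raise ValueError("sharing spectrum needs at least 2 samples")
    samples = list(roh_sets)
    merged = {s: _merged(roh_sets[s]) for s in samples}
    scaffolds = sorted({sc for m in merged.values() for sc in m})

    counts: dict[int, int] = {}
    for sc in scaffolds:
        sets = [m.get(sc, np.empty((0, 2), dtype=np.int64)) for m in merged.values()]
        hist = iv.coverage_histogram(sets)
        for k, bp in hist.items():
            counts[k] = counts.get(k, 0) + bp
    spectrum = pd.DataFrame({
        "n_carriers": np.arange(1, len(samples) + 1),
        "bp": [counts.get(k, 0) for k in range(1, len(samples) + 1)],
    })

    private = {}
    for s in samples:
        own = merged[s]
        others: RegionMap = {}
        for t in samples:
            if t == s:
                continue
            for sc, r in merged[t].items():
                others[sc] = iv.merge(np.vstack([others.get(sc, np.empty((0, 2), dtype=np.int64)), r]))
        private[s] = sum(
            iv.total_bp(iv.subtract(r, others.get(sc, np.empty((0, 2), dtype=np.int64))))
            for sc, r in own.items())
    return spectrum, pd.Series(private, name="private_bp")
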