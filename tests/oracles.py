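"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — per-bp loops, exhaustive
enumeration — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_viterbi(log_obs: np.ndarray, log_start: np.ndarray,
                        log_trans: np.ndarray) -> tuple[np.ndarray, float]:
    """Best state path by scoring all K^T sequences (vectorized enumeration)."""
    T, K = log_obs.shape
    paths = np.stack(np.unravel_index(np.arange(K ** T), (K,) * T), axis=1)
    score = log_start[paths[:, 0]] + log_obs[0, paths[:, 0]]
    for t in range(1, T):
        score = score + log_trans[paths[:, t - 1], paths[:, t]] + log_obs[t, paths[:, t]]
    best = int(np.argmax(score))
    return paths[best].astype(np.int8), float(score[best])


def kinship_by_enumeration(parents: dict[str, tuple[str | None, str | None]],
                           order: list[str]) -> dict[tuple[str, str], float]:
    """Exact kinship by enumerating every equally likely inheritance vector.

    Each non-founder allele independently copies one of the two parental
    alleles; enumerating all 4^(n_nonfounders) segregation outcomes and
    averaging the probability that random alleles drawn from x and y
    share a founder-allele label gives Θ(x, y) exactly.
    """
    nonfounders = [i for i in order if parents[i] != (None, None)]
    founders = [i for i in order if parents[i] == (None, None)]
    n = len(nonfounders)
    theta: dict[tuple[str, str], float] = {}
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i:]]
    acc = {p: 0.0 for p in pairs}
    n_vectors = 4 ** n
    for vec in itertools.product(range(4), repeat=n):
        labels: dict[str, tuple] = {}
        for f in founders:
            labels[f] = ((f, 0), (f, 1))
        for ind, choice in zip(nonfounders, vec):
            sire, dam = parents[ind]
            pat = labels[sire][choice & 1] if sire is not None else (ind, "pat")
            mat = labels[dam][(choice >> 1) & 1] if dam is not None else (ind, "mat")
            labels[ind] = (pat, mat)
        for a, b in pairs:
            la, lb = labels[a], labels[b]
            acc[(a, b)] += sum(la[i] == lb[j] for i in range(2) for j in range(2)) / 4.0
    for p, v in acc.items():
        theta[p] = theta[p[::-1]] = v / n_vectors
    return theta


def per_bp_coverage(interval_sets: list[np.ndarray], genome_len: int) -> dict[int, int]:
    """Carrier-count histogram by literally counting every base pair."""
    depth = np.zeros(genome_len + 1, dtype=int)
    for ivs in interval_sets:
        covered = np.zeros(genome_len + 1, dtype=bool)
        for s, e in np.asarray(ivs, dtype=int).reshape(-1, 2):
            covered[s:e + 1] = True
        depth += covered
    hist: dict[int, int] = {}
    for d in depth[1:]:
        if d > 0:
            hist[int(d)] = hist.get(int(d), 0) + 1
    return hist


def per_bp_jaccard(a: list[tuple[int, int]], b: list[tuple[int, int]],
                   genome_len: int) -> float:
    cov_a = np.zeros(genome_len + 1, dtype=bool)
    cov_b = np.zeros(genome_len + 1, dtype=bool)
    for s, e in a:
        cov_a[s:e + 1] = True
    for s, e in b:
        cov_b[s:e + 1] = True
    union = int(np.sum(cov_a | cov_b))
    if union == 0:
        return 0.0
    return int(np.sum(cov_a & cov_b)) / union


def f1_bp(called: dict[str, np.ndarray], truth: dict[str, np.ndarray]) -> float:
    """Base-pair-level F1 of called vs true intervals (set arithmetic)."""
    from rohscan import intervals as iv

    inter = sum(iv.total_bp(iv.intersect(called.get(s, np.empty((0, 2), dtype=np.int64)),
                                         truth[s]))
                for s in truth)
    n_called = sum(iv.total_bp(iv.merge(r)) for r in called.values())
    n_true = sum(iv.total_bp(iv.merge(r)) for r in truth.values())
    if n_called == 0 or n_true == 0:
        return 0.0
    precision = inter / n_called
    recall = inter / n_true
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
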