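"""3-state Gaussian-emission HMM segmentation of window heterozygosity.

The model treats the per-window heterozygosity ratio of one sample as
emissions of a hidden 3-state chain: the state with the lowest emission
mean captures runs of homozygosity (RoH) and the other two absorb the
remaining heterozygosity fluctuations.  Emission priors come from 1-D
k-means on well-covered windows; transition rows are initialized at
random (Dirichlet(1,1,1) under the caller's seed); both are then
optimized by Baum-Welch (EM on the forward-backward statistics, in log
space).  Decoding is Viterbi by default, and a maximal run of at least
``min_windows`` consecutive RoH-state windows becomes one segment.

Segment coordinates follow the convention that a run of *n* windows at
step *s* spans ``start`` to ``start + n*s`` inclusive, so with the
default geometry (150 kb windows every 50 kb) the shortest callable
segment is exactly 150,001 bp.

Usage::

    model = WindowHMM(track)
    res = model.fit(seed=7)
    segments = res.call_roh()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from rohscan.windows import WindowTrack, filter_windows_for_init
from rohscan import intervals as iv

__all__ = [
    "WindowHMM",
    "WindowHMMResults",
    "kmeans3_init",
    "fit_baum_welch",
    "decode_states",
    "call_roh",
    "baseline_threshold_caller",
    "roh_to_regions",
]

VAR_FLOOR = 1e-12  # ratio^2 units; guards against collapse on constant stretches


def kmeans3_init(ratios: np.ndarray, seed: int, n_states: int = 3,
                 var_floor: float = VAR_FLOOR) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emission priors from 1-D k-means: (means, variances, weights), ascending mean.

    Clusters with fewer than 2 members get the floor variance with a
    warning; all-identical input is degenerate and raises.
    """
    x = np.asarray(ratios, dtype=float).reshape(-1, 1)
    if len(x) < n_states:
        raise ValueError(f"need at least {n_states} points for k-means, got {len(x)}")
    if np.unique(x).size < n_states:
        raise ValueError("fewer distinct het-ratio values than clusters; "
                         "degenerate input for k-means initialization")
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed).fit(x)
    labels = km.labels_
    means = np.empty(n_states)
    variances = np.empty(n_states)
    weights = np.empty(n_states)
    for k in range(n_states):
        members = x[labels == k, 0]
        means[k] = members.mean()
        if len(members) < 2:
            warnings.warn(f"k-means cluster {k} has {len(members)} member(s); "
                          "variance set to floor")
            variances[k] = var_floor
        else:
            variances[k] = max(members.var(), var_floor)
        weights[k] = len(members) / len(x)
    order = np.argsort(means)
    return means[order], variances[order], weights[order]


# ---------------------------------------------------------------------------
# log-space forward/backward primitives

def _log_gaussian(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, K) log N(x | mean_k, var_k)."""
    x = x[:, None]
    return -0.5 * (np.log(2 * np.pi * variances)[None, :] + (x - means[None, :]) ** 2 / variances[None, :])


def _forward(log_obs: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    T, K = log_obs.shape
    alpha = np.empty((T, K))
    alpha[0] = log_start + log_obs[0]
    for t in range(1, T):
        alpha[t] = log_obs[t] + logsumexp(alpha[t - 1][:, None] + log_trans, axis=0)
    return alpha


def _backward(log_obs: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    T, K = log_obs.shape
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_trans + (log_obs[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def _e_step(obs: np.ndarray, means: np.ndarray, variances: np.ndarray,
            start_probs: np.ndarray, transition: np.ndarray,
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward pass: (log-likelihood, gamma, summed xi).

    Linear-space recursions with per-step normalization c_t and a
    per-frame log-max shift of the emission densities, so tiny Gaussian
    densities in het-ratio units neither underflow nor overflow.
    Per-frame shifts cancel in the posteriors and are added back to the
    log-likelihood.
    """
    T = len(obs)
    K = len(means)
    log_obs = _log_gaussian(obs, means, variances)
    m = log_obs.max(axis=1)
    e = np.exp(log_obs - m[:, None])  # row maxima are exactly 1

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = start_probs * e[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * e[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    ll = float(np.sum(np.log(c)) + np.sum(m))

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (e[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    if T > 1:
        # xi_t(i,j) = alpha_t(i) A_ij e_{t+1}(j) beta_{t+1}(j) / c_{t+1}
        xi_sum = transition * np.einsum(
            "ti,tj->ij", alpha[:-1], e[1:] * beta[1:] / c[1:, None])
    else:
        xi_sum = np.zeros((K, K))
    return ll, gamma, xi_sum


def _viterbi(log_obs: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Most probable state path; ties resolve toward the lower state index."""
    T, K = log_obs.shape
    delta = log_start + log_obs[0]
    back = np.zeros((T, K), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)  # argmax takes the first (lowest) index on ties
        delta = cand[back[t], np.arange(K)] + log_obs[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# model / results

@dataclass
class WindowHMMResults:
    """Fitted HMM parameters and segmentation methods for one sample.

    States are not re-ordered during EM; ``roh_state`` is always re-derived
    as the argmin of the emission means, so the RoH calls are invariant to
    any permutation of state labels in the initialization.
    """

    model: "WindowHMM"
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    transition: np.ndarray
    start_probs: np.ndarray
    log_likelihood: float
    n_iterations: int
    seed: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def n_states(self) -> int:
        return len(self.means)

    @property
    def roh_state(self) -> int:
        return int(np.argmin(self.means))

    def decode(self, track: WindowTrack | None = None, method: str = "viterbi") -> np.ndarray:
        return decode_states(track if track is not None else self.model.track, self, method=method)

    def call_roh(self, track: WindowTrack | None = None, min_windows: int = 3,
                 method: str = "viterbi") -> pd.DataFrame:
        track = track if track is not None else self.model.track
        return call_roh(self.decode(track, method=method), track, min_windows=min_windows,
                        roh_state=self.roh_state)

    def summary(self) -> str:
        lines = [
            "Window-heterozygosity HMM (3-state Gaussian emissions)",
            f"  sample:          {self.model.track.sample or '<unnamed>'}",
            f"  windows (decodable): {int(self.model.track.decodable.sum())}",
            f"  log-likelihood:  {self.log_likelihood:.4f}",
            f"  EM iterations:   {self.n_iterations} (converged: {self.converged})",
            f"  RoH state:       {self.roh_state}",
            "",
            f"  {'state':>5} {'mean':>12} {'std':>12} {'weight':>8}",
        ]
        for k in range(self.n_states):
            tag = " <- RoH" if k == self.roh_state else ""
            lines.append(f"  {k:>5} {self.means[k]:>12.4e} {np.sqrt(self.variances[k]):>12.4e} "
                         f"{self.weights[k]:>8.3f}{tag}")
        lines.append("")
        lines.append("  transition matrix:")
        for k in range(self.n_states):
            lines.append("    " + "  ".join(f"{p:.4f}" for p in self.transition[k]))
        return "\n".join(lines)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "sample": self.model.track.sample,
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "weights": self.weights.tolist(),
            "transition": self.transition.tolist(),
            "start_probs": self.start_probs.tolist(),
            "roh_state": self.roh_state,
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": int(self.n_iterations),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


class WindowHMM:
    """HMM over one sample's window-heterozygosity track.

    Parameters
    ----------
    track : WindowTrack
        Observation sequence; runs of decodable windows per scaffold are
        treated as independent sequences.
    n_states : int
        Number of hidden states (3: RoH, mid, high heterozygosity).
    var_floor : float
        Lower bound on emission variances, in ratio^2 units.
    max_noncallable : int
        Windows with at least this much noncallable bp (against the
        nominal width) are excluded from the k-means initialization.
    """

    def __init__(self, track: WindowTrack, n_states: int = 3,
                 var_floor: float = VAR_FLOOR, max_noncallable: int = 60_000):
        self.track = track
        self.n_states = n_states
        self.var_floor = var_floor
        self.max_noncallable = max_noncallable

    def sequences(self) -> list[np.ndarray]:
        """Observation sequences: runs of decodable windows per scaffold."""
        return _decodable_sequences(self.track)[1]

    def fit(self, seed: int, tol: float = 1e-6, max_iter: int = 1000,
            init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None) -> WindowHMMResults:
        """Baum-Welch fit; ``init`` overrides the k-means emission priors."""
        seqs = self.sequences()
        n_obs = sum(len(s) for s in seqs)
        if n_obs < 10:
            raise ValueError(f"only {n_obs} decodable windows; need at least 10 to fit")
        if init is None:
            ratios = filter_windows_for_init(self.track, self.max_noncallable)
            init = kmeans3_init(ratios, seed=seed, n_states=self.n_states,
                                var_floor=self.var_floor)
        means, variances, weights = (np.array(a, dtype=float) for a in init)
        rng = np.random.default_rng(seed)
        transition = rng.dirichlet(np.ones(self.n_states), size=self.n_states)
        start_probs = weights / weights.sum()
        return fit_baum_welch(self.track, (means, variances, weights),
                              seed=seed, tol=tol, max_iter=max_iter,
                              transition=transition, start_probs=start_probs,
                              var_floor=self.var_floor, model=self)


def _decodable_sequences(track: WindowTrack) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """(index arrays into track.windows, het-ratio arrays) per unbroken run."""
    df = track.windows
    dec = track.decodable
    idx_runs: list[np.ndarray] = []
    obs_runs: list[np.ndarray] = []
    positions = np.arange(len(df))
    for scaf in track.scaffold_order():
        on = (df["scaffold"] == scaf).to_numpy()
        pos = positions[on]
        ok = dec[on]
        # split at non-decodable windows
        run: list[int] = []
        for p, good in zip(pos, ok):
            if good:
                run.append(p)
            elif run:
                idx_runs.append(np.array(run))
                run = []
        if run:
            idx_runs.append(np.array(run))
    ratios = df["het_ratio"].to_numpy(dtype=float)
    for r in idx_runs:
        obs_runs.append(ratios[r])
    return idx_runs, obs_runs


def fit_baum_welch(track: WindowTrack, init: tuple[np.ndarray, np.ndarray, np.ndarray],
                   seed: int, tol: float = 1e-6, max_iter: int = 1000,
                   transition: np.ndarray | None = None,
                   start_probs: np.ndarray | None = None,
                   var_floor: float = VAR_FLOOR,
                   model: WindowHMM | None = None) -> WindowHMMResults:
    """EM on forward-backward statistics; log-likelihood must not decrease.

    Scaffold runs are independent observation sequences sharing one
    parameter set.  Stops when the total log-likelihood improves by less
    than ``tol`` or after ``max_iter`` iterations.
    """
    means, variances, weights = (np.array(a, dtype=float) for a in init)
    K = len(means)
    rng = np.random.default_rng(seed)
    if transition is None:
        transition = rng.dirichlet(np.ones(K), size=K)
    else:
        transition = np.array(transition, dtype=float)
    if start_probs is None:
        start_probs = weights / weights.sum()
    else:
        start_probs = np.array(start_probs, dtype=float)
    variances = np.maximum(variances, var_floor)

    if model is None:
        model = WindowHMM(track, n_states=K, var_floor=var_floor)
    _, seqs = _decodable_sequences(track)
    seqs = [s for s in seqs if len(s)]
    if not seqs:
        raise ValueError("no decodable observation sequences")

    history = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        total_ll = 0.0
        start_acc = np.zeros(K)
        trans_acc = np.zeros((K, K))
        w_acc = np.zeros(K)
        x_acc = np.zeros(K)
        x2_acc = np.zeros(K)
        for obs in seqs:
            ll, gamma, xi_sum = _e_step(obs, means, variances, start_probs, transition)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite likelihood at iteration {n_iter}; "
                    f"means={means}, variances={variances}")
            total_ll += ll
            start_acc += gamma[0]
            trans_acc += xi_sum
            w_acc += gamma.sum(axis=0)
            x_acc += gamma.T @ obs
            x2_acc += gamma.T @ obs ** 2

        if history and total_ll < history[-1] - 1e-8 * (1.0 + abs(history[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: "
                f"{history[-1]:.10g} -> {total_ll:.10g}")
        history.append(total_ll)
        if len(history) >= 2 and history[-1] - history[-2] < tol:
            converged = True
            break

        # M-step
        start_probs = start_acc / start_acc.sum()
        row = trans_acc.sum(axis=1, keepdims=True)
        ok_rows = row[:, 0] > 0
        transition = transition.copy()
        transition[ok_rows] = trans_acc[ok_rows] / row[ok_rows]
        occupied = w_acc > 1e-300
        new_means = means.copy()
        new_vars = variances.copy()
        new_means[occupied] = x_acc[occupied] / w_acc[occupied]
        new_vars[occupied] = np.maximum(
            x2_acc[occupied] / w_acc[occupied] - new_means[occupied] ** 2, var_floor)
        means, variances = new_means, new_vars
        weights = w_acc / w_acc.sum()

    return WindowHMMResults(
        model=model, means=means, variances=variances, weights=weights,
        transition=transition, start_probs=start_probs,
        log_likelihood=float(history[-1]), n_iterations=n_iter, seed=seed,
        loglik_history=np.array(history), converged=converged)


def decode_states(track: WindowTrack, results: WindowHMMResults,
                  method: str = "viterbi") -> np.ndarray:
    """Per-window state path aligned to the track; -1 marks undecodable windows.

    ``method`` is ``"viterbi"`` (joint MAP path) or ``"posterior"``
    (per-window argmax of the forward-backward posterior).
    """
    path = np.full(len(track.windows), -1, dtype=np.int8)
    idx_runs, obs_runs = _decodable_sequences(track)
    tiny = 1e-300
    log_trans = np.log(np.maximum(results.transition, tiny))
    log_start = np.log(np.maximum(results.start_probs, tiny))
    for idx, obs in zip(idx_runs, obs_runs):
        if len(obs) == 0:
            continue
        log_obs = _log_gaussian(obs, results.means, results.variances)
        if method == "viterbi":
            path[idx] = _viterbi(log_obs, log_start, log_trans)
        elif method == "posterior":
            alpha = _forward(log_obs, log_start, log_trans)
            beta = _backward(log_obs, log_trans)
            path[idx] = np.argmax(alpha + beta, axis=1).astype(np.int8)
        else:
            raise ValueError(f"unknown decode method {method!r}")
    return path


def _segments_from_state(is_roh: np.ndarray, track: WindowTrack,
                         min_windows: int) -> pd.DataFrame:
    """Turn a boolean per-window flag into RoH segments (runs >= min_windows).

    Runs never span scaffold boundaries or undecodable windows (the flag
    must already be False there).  A run of n windows spans start of the
    first window to start + n*step (inclusive), truncated at the scaffold
    end.
    """
    df = track.windows
    step = track.step
    scaffold = df["scaffold"].to_numpy()
    starts = df["start"].to_numpy()
    ratios = df["het_ratio"].to_numpy(dtype=float)
    scaffold_end = {s: int(df.loc[df["scaffold"] == s, "end"].max())
                    for s in track.scaffold_order()}
    rows = []
    i, n = 0, len(df)
    while i < n:
        if not is_roh[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_roh[j + 1] and scaffold[j + 1] == scaffold[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_windows:
            scaf = scaffold[i]
            seg_start = int(starts[i])
            seg_end = min(seg_start + run_len * step, scaffold_end[str(scaf)])
            rows.append({
                "scaffold": scaf, "start": seg_start, "end": seg_end,
                "length": seg_end - seg_start + 1, "n_windows": run_len,
                "mean_ratio": float(np.nanmean(ratios[i:j + 1])),
            })
        i = j + 1
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "length",
                                       "n_windows", "mean_ratio"])


def call_roh(path: np.ndarray, track: WindowTrack, min_windows: int = 3,
             roh_state: int | None = None) -> pd.DataFrame:
    """RoH segments from a decoded state path.

    ``roh_state`` defaults to 0 (paths from :func:`decode_states` put -1
    at undecodable windows, which always break runs).
    """
    if roh_state is None:
        roh_state = 0
    is_roh = np.asarray(path) == roh_state
    return _segments_from_state(is_roh, track, min_windows)


def baseline_threshold_caller(track: WindowTrack, ratio_cutoff: float = 1e-4,
                              min_windows: int = 3) -> pd.DataFrame:
    """Model-free comparator: windows below a fixed het-ratio cutoff.

    Uses the same run and coordinate conventions as the HMM caller, so
    per-sample RoH fractions from the two callers are directly comparable.
    """
    if ratio_cutoff <= 0:
        raise ValueError("ratio_cutoff must be positive")
    ratios = track.windows["het_ratio"].to_numpy(dtype=float)
    is_roh = track.decodable & (np.nan_to_num(ratios, nan=np.inf) < ratio_cutoff)
    return _segments_from_state(is_roh, track, min_windows)


def roh_to_regions(segments: pd.DataFrame) -> dict[str, np.ndarray]:
    """Segment table -> merged per-scaffold interval arrays."""
    out: dict[str, np.ndarray] = {}
    if len(segments) == 0:
        return out
    for scaf, sub in segments.groupby("scaffold", sort=False):
        out[str(scaf)] = iv.merge(sub[["start", "end"]].to_numpy(dtype=np.int64))
    return out
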