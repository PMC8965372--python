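"""Studbook pedigrees, tabular kinship, and pedigree inbreeding.

The kinship coefficient Θ(x, y) is the probability that one allele drawn
at random from x and one from y are identical by descent.  The tabular
(recursive) method computes it for every pair in one topological pass:

    Θ(x, y) = ½ [Θ(sire_x, y) + Θ(dam_x, y)]   for x later than y,
    Θ(x, x) = ½ [1 + Θ(sire_x, dam_x)],

with an unknown parent contributing 0.  Founders are assumed unrelated
and noninbred unless founder kinship is supplied explicitly.  The
pedigree inbreeding coefficient is F_PED(x) = Θ(sire_x, dam_x), and
self-kinship satisfies Θ(x, x) = ½ (1 + F_x) — 0.5 for a noninbred
individual (or, equivalently, for a pair of monozygotic twins).

F_PED is an expectation; the realized autozygous fraction varies around
it through Mendelian sampling and linkage, which
:func:`expected_vs_realized` quantifies against gene-drop simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "kinship_matrix", "f_ped", "expected_vs_realized"]

UNKNOWN = "0"  # studbook convention for an unrecorded parent


@dataclass
class Pedigree:
    """Individuals with sire/dam links; unknown parents encoded as "0".

    ``table`` columns: id, sire, dam, and optionally sex and cohort.
    Validation rejects cycles (an individual among its own ancestors),
    self-parentage, and individuals used both as sire and dam.
    """

    table: pd.DataFrame
    _topo: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("id", "sire", "dam"):
            if col not in t.columns:
                raise ValueError(f"pedigree table missing column {col!r}")
            t[col] = t[col].astype(str)
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate individuals: {dup}")
        if (t["id"] == UNKNOWN).any():
            raise ValueError('"0" is reserved for unknown parents')
        known = set(t["id"])
        for col in ("sire", "dam"):
            bad = set(t[col]) - known - {UNKNOWN}
            if bad:
                raise ValueError(f"{col} identifiers not in pedigree: {sorted(bad)}")
        if ((t["sire"] == t["id"]) | (t["dam"] == t["id"])).any():
            raise ValueError("individual recorded as its own parent")
        sires = set(t["sire"]) - {UNKNOWN}
        dams = set(t["dam"]) - {UNKNOWN}
        both = sires & dams
        if both:
            raise ValueError(f"individuals used as both sire and dam: {sorted(both)}")
        self.table = t
        self._topo = self._toposort()

    def _toposort(self) -> list[str]:
        parents = {r.id: [p for p in (r.sire, r.dam) if p != UNKNOWN]
                   for r in self.table.itertuples()}
        order: list[str] = []
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        for root in parents:
            if state.get(root):
                continue
            stack = [(root, iter(parents[root]))]
            state[root] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 1:
                        raise ValueError(f"pedigree cycle involving {p!r}")
                    if not state.get(p):
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return order

    @property
    def individuals(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def topological_order(self) -> list[str]:
        return list(self._topo)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["id"] == individual]
        if row.empty:
            raise KeyError(f"unknown individual {individual!r}")
        sire, dam = row["sire"].iloc[0], row["dam"].iloc[0]
        return (None if sire == UNKNOWN else sire, None if dam == UNKNOWN else dam)

    def founders(self) -> list[str]:
        t = self.table
        return t.loc[(t["sire"] == UNKNOWN) & (t["dam"] == UNKNOWN), "id"].tolist()

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def kinship_matrix(ped: Pedigree,
                   founder_kinship: dict[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """All-pairs kinship by the tabular method.

    ``founder_kinship`` optionally relaxes the unrelated-founders
    assumption: entries ``(a, b) -> Θ`` (including ``(a, a)`` to make a
    founder inbred) seed the corresponding cells before the recursion.
    """
    order = ped.topological_order
    pos = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    theta = np.zeros((n, n))
    par = {ind: ped.parents(ind) for ind in order}
    fk = {}
    if founder_kinship:
        founders = set(ped.founders())
        for (a, b), v in founder_kinship.items():
            if a not in founders or b not in founders:
                raise ValueError(f"founder_kinship entry ({a!r}, {b!r}) names a non-founder")
            fk[(a, b)] = fk[(b, a)] = float(v)

    def parent_theta(x: str, y: str) -> float:
        s, d = par[x]
        ts = theta[pos[s], pos[y]] if s else 0.0
        td = theta[pos[d], pos[y]] if d else 0.0
        return 0.5 * (ts + td)

    for i, x in enumerate(order):
        s, d = par[x]
        if s is None and d is None:
            theta[i, i] = fk.get((x, x), 0.5)
        else:
            tsd = 0.0
            if s and d:
                tsd = theta[pos[s], pos[d]]
            theta[i, i] = 0.5 * (1.0 + tsd)
        for j in range(i):
            y = order[j]
            if s is None and d is None:
                v = fk.get((x, y), 0.0)
            else:
                v = parent_theta(x, y)
            theta[i, j] = theta[j, i] = v

    ids = ped.individuals
    out = pd.DataFrame(theta, index=order, columns=order)
    return out.loc[ids, ids]


def f_ped(ped: Pedigree, individual: str,
          kin: pd.DataFrame | None = None) -> float:
    """Pedigree inbreeding coefficient: the kinship of the parents.

    0 for founders and for individuals with an unknown parent (the
    Malécot convention: an unrecorded parent is treated as an unrelated
    founder).
    """
    sire, dam = ped.parents(individual)
    if sire is None or dam is None:
        return 0.0
    if kin is None:
        kin = kinship_matrix(ped)
    return float(kin.loc[sire, dam])


def expected_vs_realized(ped: Pedigree,
                         realized: dict[str, np.ndarray]) -> pd.DataFrame:
    """Compare F_PED with realized IBD fractions from gene-drop replicates.

    Parameters
    ----------
    realized : mapping individual -> array of realized autozygous
        fractions, one per gene-drop replicate on the same pedigree.

    Returns a per-individual table with F_PED, the mean and variance of
    the realized fraction, the bias (mean - F_PED), and the replicate
    count.  Variance is NaN with fewer than 2 replicates.
    """
    kin = kinship_matrix(ped)
    rows = []
    for ind in ped.individuals:
        reps = np.asarray(realized.get(ind, ()), dtype=float)
        mean = float(reps.mean()) if len(reps) else np.nan
        var = float(reps.var(ddof=1)) if len(reps) >= 2 else np.nan
        fp = f_ped(ped, ind, kin=kin)
        rows.append({"id": ind, "F_PED": fp, "mean_realized": mean,
                     "var_realized": var, "bias": mean - fp, "n_replicates": len(reps)})
    return pd.DataFrame(rows).set_index("id")
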