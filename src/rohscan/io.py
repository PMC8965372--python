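"""Genome index, callability mask, and on-disk formats.

Coordinates are 1-based inclusive in memory; BED files are written and
read as 0-based half-open intervals, so a BED line ``chr 0 100`` becomes
the interval ``[1, 100]``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rohscan import intervals as iv

__all__ = ["GenomeIndex", "CallabilityMask", "read_bed", "write_bed", "write_header"]


@dataclass
class GenomeIndex:
    """Scaffold lengths plus the scaffold flagged as X-chromosome-aligned."""

    lengths: dict[str, int]
    x_scaffold: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate scaffold identifiers")
        for name, ln in self.lengths.items():
            if ln <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length {ln}")
        if self.x_scaffold is not None and self.x_scaffold not in self.lengths:
            raise ValueError(f"x_scaffold {self.x_scaffold!r} not in index")

    @property
    def scaffolds(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def autosomes(self) -> list[str]:
        return [s for s in self.lengths if s != self.x_scaffold]

    def autosome_bp(self) -> int:
        return sum(self.lengths[s] for s in self.autosomes())

    @classmethod
    def read_tsv(cls, path: str | Path, x_scaffold: str | None = None) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["scaffold", "length"], dtype={"scaffold": str})
        return cls(dict(zip(df["scaffold"], df["length"].astype(int))), x_scaffold)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, ln in self.lengths.items():
                fh.write(f"{name}\t{ln}\n")


@dataclass
class CallabilityMask:
    """Per-scaffold sorted, non-overlapping callable intervals (1-based inclusive)."""

    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = {s: iv.merge(r) for s, r in self.regions.items()}

    @classmethod
    def full(cls, index: GenomeIndex, scaffolds: list[str] | None = None) -> "CallabilityMask":
        names = scaffolds if scaffolds is not None else index.scaffolds
        return cls({s: np.array([[1, index.lengths[s]]], dtype=np.int64) for s in names})

    def for_scaffold(self, scaffold: str) -> np.ndarray:
        return self.regions.get(scaffold, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bp(self) -> int:
        return sum(iv.total_bp(r) for r in self.regions.values())

    def restrict(self, scaffolds) -> "CallabilityMask":
        keep = set(scaffolds)
        return CallabilityMask({s: r for s, r in self.regions.items() if s in keep})

    def subtract(self, other: "CallabilityMask") -> "CallabilityMask":
        out = {}
        for s, r in self.regions.items():
            res = iv.subtract(r, other.for_scaffold(s))
            if len(res):
                out[s] = res
        return CallabilityMask(out)

    def contains(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of 1-based positions in the callable set."""
        r = self.for_scaffold(scaffold)
        positions = np.asarray(positions, dtype=np.int64)
        if len(r) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(r[:, 0], positions, side="right")
        inside = idx > 0
        inside[inside] &= positions[inside] <= r[idx[inside] - 1, 1]
        return inside

    def callable_in(self, scaffold: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Callable bp inside each [start, end] window (vectorized prefix sums)."""
        r = self.for_scaffold(scaffold)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if len(r) == 0:
            return np.zeros(len(starts), dtype=np.int64)
        lens = r[:, 1] - r[:, 0] + 1
        cum = np.concatenate([[0], np.cumsum(lens)])

        def cum_at(p: np.ndarray) -> np.ndarray:
            # callable bp in [1, p]
            k = np.searchsorted(r[:, 0], p, side="right")
            c = cum[k].copy()
            has = k > 0
            over = np.zeros_like(c)
            over[has] = np.maximum(0, r[k[has] - 1, 1] - p[has])
            return c - over

        return cum_at(ends) - cum_at(starts - 1)

    @classmethod
    def read_bed(cls, path: str | Path) -> "CallabilityMask":
        return cls(read_bed(path))

    def write_bed(self, path: str | Path, header: str | None = None) -> None:
        write_bed(path, self.regions, header=header)


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED3 into per-scaffold 1-based inclusive interval arrays."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.setdefault(chrom, []).append((int(start) + 1, int(end)))
    return {s: iv.merge(np.array(v, dtype=np.int64)) for s, v in out.items()}


def write_bed(path: str | Path, regions: dict[str, np.ndarray], header: str | None = None) -> None:
    """Write per-scaffold 1-based inclusive intervals as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for scaffold, arr in regions.items():
            for s, e in np.asarray(arr, dtype=np.int64):
                fh.write(f"{scaffold}\t{s - 1}\t{e}\n")


def write_header(fh: _io.TextIOBase, **meta) -> None:
    """Write ``#key=value`` provenance lines (tool version, seed, config hash)."""
    from rohscan import __version__

    fh.write(f"#rohscan={__version__}\n")
    for k, v in meta.items():
        fh.write(f"#{k}={v}\n")
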