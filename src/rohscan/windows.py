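"""Overlapping-window heterozygosity tracks.

Each retained scaffold is tiled with windows of ``width`` bp (default
150 kb) every ``step = width - overlap`` bp (default 50 kb), anchored at
position 1.  Tiling stops at the first window that reaches the scaffold
end; that trailing window is truncated to the scaffold end, so each
scaffold is covered exactly once with at most one partial window.

The per-window heterozygosity ratio — het sites / callable bp — is the
observation fed to the segmentation HMM.  Windows with zero callable bp
have an undefined ratio; they stay in the track but are excluded from
fitting and decoding and break state runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rohscan.io import CallabilityMask, GenomeIndex, write_header

__all__ = ["WindowTrack", "build_window_track", "filter_windows_for_init"]

TRACK_COLUMNS = ["scaffold", "start", "end", "callable_bp", "het_count", "het_ratio"]


@dataclass
class WindowTrack:
    """Ordered per-scaffold heterozygosity windows for one sample.

    ``windows`` has columns scaffold, start, end (1-based inclusive),
    callable_bp, het_count, het_ratio (NaN where callable_bp = 0),
    sorted by (scaffold appearance order, start).
    """

    sample: str
    windows: pd.DataFrame
    width: int = 150_000
    step: int = 50_000

    @property
    def noncallable_bp(self) -> np.ndarray:
        """Noncallable bp against the nominal width (truncated windows score high)."""
        return self.width - self.windows["callable_bp"].to_numpy()

    @property
    def decodable(self) -> np.ndarray:
        return self.windows["callable_bp"].to_numpy() > 0

    def scaffold_order(self) -> list[str]:
        return list(pd.unique(self.windows["scaffold"]))

    def write_tsv(self, path: str | Path, **meta) -> None:
        with open(path, "w") as fh:
            write_header(fh, sample=self.sample, width=self.width, step=self.step, **meta)
            out = self.windows.copy()
            out.insert(0, "sample", self.sample)
            out.to_csv(fh, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "WindowTrack":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "=" in line:
                    k, v = line[1:].rstrip("\n").split("=", 1)
                    meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(sample=meta.get("sample", str(df["sample"].iloc[0])),
                   windows=df[TRACK_COLUMNS].copy(),
                   width=int(meta.get("width", 150_000)),
                   step=int(meta.get("step", 50_000)))


def window_starts(scaffold_len: int, width: int, step: int) -> np.ndarray:
    """Grid starts 1, 1+step, ... up to the first window reaching the scaffold end."""
    if scaffold_len < 1:
        raise ValueError("scaffold length must be positive")
    # smallest k with 1 + k*step + width - 1 >= scaffold_len
    k_last = max(0, -(-(scaffold_len - width) // step))
    return 1 + step * np.arange(k_last + 1, dtype=np.int64)


def build_window_track(het_sites: dict[str, np.ndarray], mask: CallabilityMask,
                       index: GenomeIndex, sample: str = "",
                       width: int = 150_000, overlap: int = 100_000,
                       scaffolds: list[str] | None = None) -> WindowTrack:
    """Tile scaffolds and count het sites and callable bp per window.

    Parameters
    ----------
    het_sites : mapping scaffold -> sorted 1-based het positions
        Heterozygous site positions for the sample, already restricted to
        the callability mask.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not 0 <= overlap < width:
        raise ValueError("overlap must satisfy 0 <= overlap < width")
    step = width - overlap
    names = scaffolds if scaffolds is not None else index.scaffolds
    frames = []
    for scaf in names:
        length = index.lengths[scaf]
        starts = window_starts(length, width, step)
        ends = np.minimum(starts + width - 1, length)
        callable_bp = mask.callable_in(scaf, starts, ends)
        pos = np.asarray(het_sites.get(scaf, ()), dtype=np.int64)
        het = np.searchsorted(pos, ends, side="right") - np.searchsorted(pos, starts, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(callable_bp > 0, het / np.maximum(callable_bp, 1), np.nan)
        frames.append(pd.DataFrame({
            "scaffold": scaf, "start": starts, "end": ends,
            "callable_bp": callable_bp, "het_count": het, "het_ratio": ratio,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    return WindowTrack(sample=sample, windows=df, width=width, step=step)


def synthetic_track(ratios, width: int = 150_000, step: int = 50_000,
                    sample: str = "synthetic", scaffold: str = "scaffold_1") -> WindowTrack:
    """Fully callable single-scaffold track with prescribed het ratios.

    Testing/demonstration utility: het counts are the ratios times the
    window width rounded to integers (ratios are re-derived from the
    counts, so they are quantized to multiples of 1/width).  NaN entries
    become zero-callable (undecodable) windows.
    """
    ratios = np.asarray(ratios, dtype=float)
    starts = 1 + step * np.arange(len(ratios), dtype=np.int64)
    ends = starts + width - 1
    callable_bp = np.where(np.isnan(ratios), 0, width).astype(np.int64)
    het = np.where(np.isnan(ratios), 0, np.rint(np.nan_to_num(ratios) * width)).astype(np.int64)
    with np.errstate(invalid="ignore"):
        ratio = np.where(callable_bp > 0, het / np.maximum(callable_bp, 1), np.nan)
    df = pd.DataFrame({"scaffold": scaffold, "start": starts, "end": ends,
                       "callable_bp": callable_bp, "het_count": het, "het_ratio": ratio})
    return WindowTrack(sample=sample, windows=df, width=width, step=step)


def filter_windows_for_init(track: WindowTrack, max_noncallable: int = 60_000) -> np.ndarray:
    """Het ratios of windows with noncallable bp strictly below the cutoff.

    These well-covered windows seed the k-means emission priors; gappy
    and truncated windows are left out so mask artefacts do not distort
    the initial clusters.  Order is preserved.
    """
    keep = (track.noncallable_bp < max_noncallable) & track.decodable
    ratios = track.windows.loc[keep, "het_ratio"].to_numpy(dtype=float)
    if len(ratios) < 3:
        raise ValueError(
            f"only {len(ratios)} windows with < {max_noncallable} noncallable bp; "
            "k-means initialization needs at least 3")
    return ratios
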