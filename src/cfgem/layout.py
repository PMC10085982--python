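"""Genome window grids.

Both arms of the pipeline tile the genome into fixed-width,
non-overlapping windows: 1-Mb windows for mutation/variant density and
5-Mb windows for the coverage baselines.  :class:`GenomeLayout` holds
one such tiling and provides vectorized position-to-window lookup.

A trailing remnant shorter than half the window width is dropped
(density estimates in very short windows are unstable); a remnant of at
least half the width is kept as a final, shorter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from cfgem.errors import InvalidInputError


@dataclass(frozen=True)
class GenomeLayout:
    """Non-overlapping window tiling of a genome (0-based, half-open)."""

    chrom_lengths: dict[str, int]
    window_size: int
    windows: pd.DataFrame = field(repr=False)  # columns: chrom, start, end; index = window id

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def window_of(self, chrom: np.ndarray | pd.Series, pos: np.ndarray | pd.Series) -> np.ndarray:
        """Map 0-based positions to window ids; -1 for positions in no window.

        Unknown chromosomes raise :class:`InvalidInputError`.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        known = set(self.chrom_lengths)
        bad = {c for c in np.unique(chrom) if c not in known}
        if bad:
            raise InvalidInputError(f"unknown chromosome(s): {sorted(bad)}")
        out = np.full(len(pos), -1, dtype=np.int64)
        for c, (first_id, n_win) in self._chrom_offsets().items():
            m = chrom == c
            if not m.any():
                continue
            p = pos[m]
            idx = p // self.window_size
            # a kept remnant window is always shorter than window_size, so
            # floor division lands in it directly; dropped remnants give
            # idx >= n_win and map to -1
            ok = (p >= 0) & (p < self.chrom_lengths[c]) & (idx < n_win)
            out[m] = np.where(ok, first_id + idx, -1)
        return out

    def _chrom_offsets(self) -> dict[str, tuple[int, int]]:
        offsets: dict[str, tuple[int, int]] = {}
        for c in self.chrom_lengths:
            sub = self.windows.index[self.windows["chrom"] == c]
            offsets[c] = (int(sub[0]) if len(sub) else 0, len(sub))
        return offsets


def make_layout(chrom_lengths: Mapping[str, int], window_size: int) -> GenomeLayout:
    """Tile each chromosome into ``window_size`` windows.

    Windows are 0-based half-open, sorted by (chrom insertion order,
    start).  The final remnant is kept only when its length is at least
    half the window size.
    """
    if window_size <= 0:
        raise InvalidInputError("window_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length <= 0:
            raise InvalidInputError(f"chromosome {chrom!r} has non-positive length {length}")
        n_full, rem = divmod(length, window_size)
        for i in range(n_full):
            rows.append((chrom, i * window_size, (i + 1) * window_size))
        if rem >= window_size / 2:
            rows.append((chrom, n_full * window_size, length))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    windows.index.name = "window_id"
    return GenomeLayout(chrom_lengths=dict(chrom_lengths), window_size=int(window_size), windows=windows)
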