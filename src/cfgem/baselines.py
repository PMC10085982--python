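"""Comparison feature sets: cnv, fragpattern, fragsize.

* ``cnv``: fragment coverage in non-overlapping 5-Mb windows, z-scored
  within sample — a copy-number surrogate.
* ``fragpattern``: per-5-Mb-window short (100-150 bp) and long
  (151-220 bp) fragment counts, GC-corrected by LOWESS (span 0.75;
  residual plus genome-wide median of the fitted values added back),
  then the corrected total and short blocks z-scored per sample.
* ``fragsize``: 125 counts in 2-bp length bins [0,2) ... [248,250),
  z-scored per sample.

z-scores use the population (n) denominator throughout.  Window masks
(N-content / low-GC exclusion) are caller-supplied inputs, all-pass in
synthetic mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from cfgem.errors import InvalidInputError
from cfgem.layout import GenomeLayout

FRAGSIZE_BINS = 125


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population denominator
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _window_counts(fragments: pd.DataFrame, layout: GenomeLayout, mask=None) -> np.ndarray:
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    center = (start + end) // 2
    wid = layout.window_of(fragments["chrom"].to_numpy(object), center)
    counts = np.bincount(wid[wid >= 0], minlength=layout.n_windows).astype(float)
    if mask is not None:
        counts = counts[np.asarray(mask, dtype=bool)]
    return counts


def cnv_features(fragments: pd.DataFrame, layout: GenomeLayout, window_mask=None) -> np.ndarray:
    """z-scored per-window coverage (fragment centers per 5-Mb window)."""
    if len(fragments) == 0:
        raise InvalidInputError("empty sample")
    counts = _window_counts(fragments, layout, window_mask)
    if counts.size < 2:
        raise InvalidInputError("need >= 2 windows for z-scoring")
    return _zscore(counts)


def _gc_correct(counts: np.ndarray, gc: np.ndarray, span: float = 0.75) -> np.ndarray:
    """LOWESS(count ~ GC) residual + genome-wide median of the fit."""
    if np.ptp(gc) < 1e-12:
        warnings.warn("constant GC: LOWESS degenerates to the mean")
        fit = np.full_like(counts, counts.mean())
    else:
        fit = lowess(counts, gc, frac=span, return_sorted=False)
    return counts - fit + np.median(fit)


def fragpattern_features(
    fragments: pd.DataFrame,
    layout: GenomeLayout,
    gc_fractions: np.ndarray,
    window_mask=None,
    span: float = 0.75,
    blocks: tuple[str, ...] = ("total", "short"),
) -> np.ndarray:
    """GC-corrected fragmentation-pattern features.

    Short = lengths 100-150 bp inclusive, long = 151-220 bp inclusive;
    both corrected against per-window GC by LOWESS; the emitted feature
    vector concatenates the z-scored corrected blocks named in
    ``blocks`` (default: corrected total then corrected short).
    """
    if len(fragments) == 0:
        raise InvalidInputError("empty sample")
    ln = fragments["end"] - fragments["start"]
    short = _window_counts(fragments[(ln >= 100) & (ln <= 150)], layout, window_mask)
    long_ = _window_counts(fragments[(ln >= 151) & (ln <= 220)], layout, window_mask)
    gc = np.asarray(gc_fractions, dtype=float)
    if window_mask is not None:
        gc = gc[np.asarray(window_mask, dtype=bool)]
    if gc.shape != short.shape:
        raise InvalidInputError("gc_fractions length must match (masked) window count")
    short_c = _gc_correct(short, gc, span)
    long_c = _gc_correct(long_, gc, span)
    corrected = {"short": short_c, "long": long_c, "total": short_c + long_c}
    return np.concatenate([_zscore(corrected[b]) for b in blocks])


def fragsize_features(fragments: pd.DataFrame) -> np.ndarray:
    """125-bin 2-bp fragment-length histogram, z-scored within sample.

    Lengths >= 250 bp fall outside the histogram (half-open top bin).
    """
    if len(fragments) == 0:
        raise InvalidInputError("empty sample")
    ln = (fragments["end"] - fragments["start"]).to_numpy()
    ln = ln[(ln >= 0) & (ln < 250)]
    counts = np.bincount(ln // 2, minlength=FRAGSIZE_BINS).astype(float)
    assert counts.size == FRAGSIZE_BINS
    return _zscore(counts)
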