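"""Tissue-specific nucleosome-depleted-region (NDR) reference.

ATAC-seq peak sets from many tissue samples are merged into a
non-overlapping meta-peak catalog (keeping the strongest peak within
any group of overlapping peaks), short fragments (< 150 bp) covering
each meta-peak midpoint are counted per sample, counts are
TMM-normalized, and for each tissue the ``selection_size`` meta-peaks
with the smallest one-vs-rest moderated-t p-value on log2-CPM are
selected as that tissue's NDR list.

The moderated test is a from-scratch log-CPM t-test with
empirical-Bayes variance shrinkage toward a pooled scaled-inverse-chi2
prior (precision weights omitted) — a documented approximation to the
voom/limma route; acceptance rests on planted-truth recovery.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from cfgem.errors import InvalidInputError
from cfgem.lmd import tmm_factors


@dataclass
class NDRReference:
    """Meta-peaks, count matrix, and per-tissue selections."""

    meta_peaks: pd.DataFrame                  # chrom, start, end, score, midpoint
    counts: pd.DataFrame | None = None        # meta-peaks x samples
    tissue_lists: dict[str, pd.DataFrame] = field(default_factory=dict)
    norm_factors: np.ndarray | None = None


def filter_peak_samples(peak_sets: list[pd.DataFrame], min_peaks: int = 30_000) -> list[pd.DataFrame]:
    """Drop samples with fewer than ``min_peaks`` called peaks (strict)."""
    kept = [p for p in peak_sets if len(p) >= min_peaks]
    if not kept:
        warnings.warn("all peak samples excluded by the min-peak filter")
    return kept


def merge_meta_peaks(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample peaks into a non-overlapping meta-peak catalog.

    Iterative strongest-first resolution: the highest-score peak is
    kept, every peak overlapping it is discarded, and the rule recurses
    on the remainder — so two peaks that only overlapped a discarded
    middle peak are both kept.  Score ties keep the leftmost (smaller
    start).  Output is sorted by (chrom, start) with midpoints attached.
    """
    if not peak_sets:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "midpoint"])
    allp = pd.concat([p[["chrom", "start", "end", "score"]] for p in peak_sets], ignore_index=True)
    allp = allp.sort_values(["score", "start"], ascending=[False, True], kind="mergesort")
    kept_rows = []
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in allp.itertuples(index=False):
        intervals = kept_by_chrom.setdefault(row.chrom, [])
        i = bisect_left(intervals, (row.start, row.end))
        overlaps = False
        if i < len(intervals) and intervals[i][0] < row.end:
            overlaps = True
        if i > 0 and intervals[i - 1][1] > row.start:
            overlaps = True
        if not overlaps:
            insort(intervals, (int(row.start), int(row.end)))
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows, columns=["chrom", "start", "end", "score"])
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    out["midpoint"] = (out["start"] + out["end"]) // 2
    out.index.name = "peak_id"
    return out


def count_ndr_fragments(
    fragment_tables: dict[str, pd.DataFrame],
    meta_peaks: pd.DataFrame,
    max_fragment_len: int = 150,
) -> pd.DataFrame:
    """Meta-peak x sample matrix of short fragments covering midpoints.

    A fragment counts toward peak p when its length is strictly less
    than ``max_fragment_len`` and its [start, end) interval contains the
    peak midpoint.
    """
    counts = pd.DataFrame(0, index=meta_peaks.index, columns=list(fragment_tables), dtype=np.int64)
    for s, frags in fragment_tables.items():
        ln = frags["end"] - frags["start"]
        short = frags[ln < max_fragment_len]
        for chrom, grp in short.groupby("chrom"):
            peaks = meta_peaks[meta_peaks["chrom"] == chrom]
            if len(peaks) == 0:
                continue
            starts = np.sort(grp["start"].to_numpy())
            ends = np.sort(grp["end"].to_numpy())
            mids = peaks["midpoint"].to_numpy()
            # coverage(m) = #(start <= m) - #(end <= m)
            cov = np.searchsorted(starts, mids, side="right") - np.searchsorted(ends, mids, side="right")
            counts.loc[peaks.index, s] = cov
    return counts


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-peak variances toward a fitted scaled-inv-chi2 prior.

    Moment fit on z = log(s2): E z = log(s0^2) + digamma(df/2) -
    log(df/2) + (digamma(d0/2) - log(d0/2) with opposite sign for the
    prior); var z = trigamma(df/2) + trigamma(d0/2).  Returns
    (posterior variances, prior df d0).
    """
    pos = s2 > 0
    z = np.log(s2[pos]) if pos.any() else np.array([0.0])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    ev = max(np.var(z, ddof=1) - special.polygamma(1, df / 2), 1e-9) if z.size > 1 else 1e-9

    def gap(d0):
        return special.polygamma(1, d0 / 2) - ev

    if gap(1e6) > 0:  # residual variation below chi2 noise: infinite prior df
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
    else:
        d0 = float(optimize.brentq(gap, 1e-3, 1e6))
        s0 = float(np.exp(np.mean(e) - special.digamma(d0 / 2) + np.log(d0 / 2)))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


def moderated_ttest(logcpm: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Vectorized two-group moderated t-test per row.

    Returns columns (delta, t, p, df_total); ``delta`` is mean(in) -
    mean(out) of log2-CPM.
    """
    g = group.astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n0 < 2:
        raise InvalidInputError("need >= 2 samples in each group")
    m1 = logcpm[:, g].mean(axis=1)
    m0 = logcpm[:, ~g].mean(axis=1)
    ss = logcpm[:, g].var(axis=1, ddof=1) * (n1 - 1) + logcpm[:, ~g].var(axis=1, ddof=1) * (n0 - 1)
    df = n1 + n0 - 2
    s2 = ss / df
    post, d0 = _squeeze_var(s2, df)
    c = 1.0 / n1 + 1.0 / n0
    t = (m1 - m0) / np.sqrt(np.maximum(post * c, 1e-300))
    df_total = df + (0 if np.isinf(d0) else d0)
    dist_df = 1e6 if np.isinf(df_total) else df_total
    p = 2.0 * stats.t.sf(np.abs(t), dist_df)
    return pd.DataFrame({"delta": m1 - m0, "t": t, "p": p, "df_total": df_total})


def select_tissue_ndrs(
    counts: pd.DataFrame,
    tissue_labels: pd.Series,
    selection_size: int = 10_000,
) -> tuple[dict[str, pd.DataFrame], np.ndarray]:
    """Per-tissue one-vs-rest selection of the most specific NDRs.

    TMM-normalize, form log2-CPM with a 0.5 pseudo-count, run the
    moderated t per tissue, and keep the ``selection_size`` peaks with
    the smallest p (ties: smaller p, then peak id).  Tissues with a
    single sample are excluded with a warning.  Returns
    ``(tissue_lists, norm_factors)``.
    """
    labels = tissue_labels.reindex(counts.columns)
    sizes = labels.value_counts()
    usable = [t for t in sizes.index if sizes[t] >= 2]
    dropped = [t for t in sizes.index if sizes[t] < 2]
    if dropped:
        warnings.warn(f"tissues with a single sample excluded: {dropped}")
    if len(usable) < 2:
        raise InvalidInputError("need >= 2 tissues with >= 2 samples each")
    factors = tmm_factors(counts)
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    eff = libsize * factors
    cpm = (counts.to_numpy(dtype=float) + 0.5) / eff[None, :] * 1e6
    logcpm = np.log2(cpm)
    out: dict[str, pd.DataFrame] = {}
    for t in sorted(usable):
        res = moderated_ttest(logcpm, (labels == t).to_numpy())
        res.index = counts.index
        res = res.sort_values(["p"], kind="mergesort")  # stable: index order breaks ties
        top = res.head(selection_size).copy()
        top.index.name = "peak_id"
        out[t] = top.reset_index()
    return out, factors
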