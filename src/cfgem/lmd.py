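"""Cancer-type-specific local-mutation-density (LMD) reference.

Passenger mutation burden is shaped by replication timing and
chromatin, giving each cancer type a characteristic regional mutation
density landscape.  From a tumor mutation table this module counts
mutations in 1-Mb windows per sample, normalizes libraries with TMM
(trimmed mean of M-values), tests each window for one-vs-rest
enrichment per cancer type with a negative-binomial GLM, and keeps the
top 25 enriched (high-LMD) and top 25 depleted (low-LMD) windows per
type at FDR 0.05.

The differential test is a likelihood-ratio test on a
negative-binomial regression with a method-of-moments common
dispersion and offset ``log(library size x TMM factor)`` — a
deliberate, documented approximation to a quasi-likelihood F-test;
correctness here is judged by planted-truth recovery, not by
coefficient parity with any particular count-model package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from cfgem.errors import InvalidInputError
from cfgem.layout import GenomeLayout


@dataclass
class LMDMatrix:
    """Per-(sample, window) mutation counts with type labels."""

    counts: pd.DataFrame          # windows x samples, integer counts
    sample_types: pd.Series       # sample -> cancer type

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class LMDReference:
    """Selected high/low LMD windows per cancer type.

    ``high``/``low`` map cancer type to a DataFrame with columns
    (window_id, log2fc, fdr), sorted by |log2fc| descending (ties broken
    by smaller FDR, then window id).
    """

    high: dict[str, pd.DataFrame] = field(default_factory=dict)
    low: dict[str, pd.DataFrame] = field(default_factory=dict)
    tested: pd.DataFrame | None = None  # full per-(type, window) table
    excluded_windows: list[int] = field(default_factory=list)


def compute_lmd_matrix(maf: pd.DataFrame, layout: GenomeLayout) -> LMDMatrix:
    """Count mutations per (sample, window) from a MAF-like table.

    ``maf`` columns: sample, cancer_type, chrom, pos (1-based), ref, alt.
    Mutations falling into dropped remnant windows are not counted.
    """
    samples = maf[["sample", "cancer_type"]].drop_duplicates()
    if samples["sample"].duplicated().any():
        raise InvalidInputError("a sample appears under two cancer types")
    counts = pd.DataFrame(0, index=np.arange(layout.n_windows), columns=samples["sample"].tolist(), dtype=np.int64)
    if len(maf):
        wid = layout.window_of(maf["chrom"].to_numpy(object), maf["pos"].to_numpy() - 1)
        hit = wid >= 0
        tab = pd.crosstab(wid[hit], maf["sample"].to_numpy(object)[hit])
        counts.loc[tab.index, tab.columns] += tab.to_numpy()
    counts.index.name = "window_id"
    stypes = samples.set_index("sample")["cancer_type"]
    return LMDMatrix(counts=counts, sample_types=stypes)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _quantile_factor(counts: np.ndarray, libsize: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(counts[:, j], p) / libsize[j] for j in range(counts.shape[1])])


def tmm_factors(counts: pd.DataFrame | np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Per-sample TMM normalization factors.

    The reference sample is the column whose upper-quartile (of counts
    over library size) is closest to the mean upper-quartile.  For each
    sample the factor is ``2**f`` where ``f`` is the mean of the
    M-values (log2 ratios vs the reference after library-size division)
    over windows surviving a two-sided trim of ``trim_m`` on M and
    ``trim_a`` on A (average log intensity), weighted by inverse
    asymptotic binomial variance.  Windows with a zero count in either
    sample of a pair are excluded pairwise.  Factors are rescaled to a
    geometric mean of 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InvalidInputError("need a windows x samples matrix with >= 2 samples")
    libsize = x.sum(axis=0)
    if (libsize == 0).any():
        raise InvalidInputError("sample with zero library size")
    f75 = _quantile_factor(x, libsize)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        factors[j] = _pairwise_tmm(x[:, j], x[:, ref], libsize[j], libsize[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _pairwise_tmm(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# differential selection
# ---------------------------------------------------------------------------

def _common_dispersion(counts: np.ndarray, offsets: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over windows.

    Counts are scaled to a common effective library; per window,
    ``alpha = (s^2 - mu) / mu^2`` on the scaled counts, floored at 0 and
    pooled by the median over informative windows.
    """
    scale = np.exp(offsets - offsets.mean())
    y = counts / scale  # windows x samples on a common scale
    mu = y.mean(axis=1)
    s2 = y.var(axis=1, ddof=1)
    ok = mu > 0
    if not ok.any():
        return 0.0
    alpha = (s2[ok] - mu[ok]) / mu[ok] ** 2
    alpha = alpha[np.isfinite(alpha)]
    return float(max(0.0, np.median(alpha))) if alpha.size else 0.0


def _nb_lrt(y: np.ndarray, group: np.ndarray, offset: np.ndarray, alpha: float) -> tuple[float, float]:
    """One-window LRT of group effect; returns (log2fc, p)."""
    fam = sm.families.NegativeBinomial(alpha=alpha) if alpha > 1e-8 else sm.families.Poisson()
    x1 = np.column_stack([np.ones_like(offset), group.astype(float)])
    x0 = x1[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit1 = sm.GLM(y, x1, family=fam, offset=offset).fit()
            fit0 = sm.GLM(y, x0, family=fam, offset=offset).fit()
        except Exception:
            return 0.0, 1.0
    from scipy.stats import chi2
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    p = float(chi2.sf(stat, df=1))
    log2fc = float(fit1.params[1] / np.log(2.0))
    return log2fc, p


def select_lmd_regions(
    matrix: LMDMatrix,
    fdr: float = 0.05,
    top_k: int = 25,
) -> LMDReference:
    """Select high/low LMD windows per cancer type.

    Per type, a one-vs-rest negative-binomial LRT per window (offset =
    log(library size x TMM factor)); BH adjustment across windows within
    the type; significant windows split by fold-change sign; the
    ``top_k`` per direction by |log2 fold change| kept (ties: smaller
    FDR, then window id).  Windows with all-zero counts are excluded
    from testing and reported.
    """
    counts = matrix.counts.to_numpy(dtype=np.int64)
    types = matrix.sample_types.reindex(matrix.counts.columns)
    if types.nunique() < 2:
        raise InvalidInputError("need >= 2 cancer types")
    if (types.value_counts() < 2).any():
        raise InvalidInputError("need >= 2 samples per type")
    libsize = counts.sum(axis=0).astype(float)
    factors = tmm_factors(matrix.counts)
    offset = np.log(libsize * factors)
    nonzero = counts.sum(axis=1) > 0
    excluded = list(np.flatnonzero(~nonzero))
    alpha = _common_dispersion(counts[nonzero], offset)

    ref = LMDReference(excluded_windows=[int(w) for w in excluded])
    all_rows = []
    for ctype in sorted(types.unique()):
        group = (types == ctype).to_numpy()
        rows = []
        for w in np.flatnonzero(nonzero):
            log2fc, p = _nb_lrt(counts[w], group, offset, alpha)
            rows.append((ctype, int(w), log2fc, p))
        tab = pd.DataFrame(rows, columns=["cancer_type", "window_id", "log2fc", "p"])
        tab["fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
        all_rows.append(tab)
        sig = tab[tab["fdr"] <= fdr]
        for name, sub in (("high", sig[sig["log2fc"] > 0]), ("low", sig[sig["log2fc"] < 0])):
            sub = sub.assign(abs_fc=sub["log2fc"].abs())
            sub = sub.sort_values(["abs_fc", "fdr", "window_id"], ascending=[False, True, True])
            top = sub.head(top_k)[["window_id", "log2fc", "fdr"]].reset_index(drop=True)
            getattr(ref, name)[ctype] = top
    ref.tested = pd.concat(all_rows, ignore_index=True)
    return ref
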