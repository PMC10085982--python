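"""Seeded synthetic cfDNA cohorts.

The simulator plants, with known truth, the statistical structure the
two detection models assume:

* tumor mutations concentrated in cancer-type-specific high-LMD windows
  (and suppressed in low-LMD windows) in tumor-tissue MAF tables;
* plasma samples whose fragments are a tumor-fraction mixture of a
  normal (~166 bp) and a shorter tumor (~145 bp) length distribution,
  with coverage at the label-matched tissue's NDRs multiplicatively
  depleted;
* somatic-like variants in the label's high-LMD windows with VAF
  proportional to tumor fraction, plus contaminant variants (germline,
  VAF=1 artifacts, single-strand support, adjacent MNVs, read-end
  artifacts) each carrying exactly the evidence signature its filter
  rule targets.

Every draw flows from one top-level seed through named substreams
(:func:`cfgem.rng.substream`), so cohorts are bit-identical under a
fixed seed and per-sample output does not depend on cohort composition.

Base-level sequencing-error simulation and real genome sequence content
are out of scope: positions are coordinates on an abstract assembly and
flanking bases are drawn, not read from a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cfgem.errors import InvalidInputError
from cfgem.layout import GenomeLayout, make_layout
from cfgem.rng import substream

BASES = np.array(["A", "C", "G", "T"])

#: canonical substitution classes, pyrimidine-reference convention
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "alt_depth", "alt_fwd", "alt_rev",
    "offsets", "flank5", "flank3", "truth_class",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``high_windows`` / ``low_windows`` map each cancer type to the
    window ids (of the accompanying layout) planted with elevated or
    suppressed mutation rates.  ``ndr_depletion`` is the depth of
    nucleosome-depleted-region coverage loss attributable to pure tumor
    cfDNA: a sample with tumor fraction ``tf`` keeps fragments covering
    a matched-tissue NDR midpoint with probability ``1 - tf *
    ndr_depletion``.
    """

    seed: int = 0
    cancer_types: tuple[str, ...] = ("breast", "liver", "lung")
    high_windows: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    low_windows: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    # tumor fraction range for cancer samples (uniform draw)
    tumor_fraction_range: tuple[float, float] = (0.05, 0.35)
    # fragments
    fragments_per_sample: int = 30_000
    normal_frag_mean: float = 166.0
    normal_frag_sd: float = 10.0
    tumor_frag_mean: float = 145.0
    tumor_frag_sd: float = 10.0
    frag_len_bounds: tuple[int, int] = (60, 400)
    ndr_depletion: float = 0.5
    ndr_center_fraction: float = 0.30  # share of fragments centered near some NDR
    ndr_center_halfspan: int = 500
    # tumor-tissue MAF simulation
    maf_background_rate: float = 2.0  # mutations per window per sample
    maf_fold: float = 8.0
    # cfDNA variants
    background_variants_mean: float = 120.0  # filter-passing passengers, any sample
    tumor_variants_per_unit_tf: float = 1200.0
    high_window_share: float = 0.8
    read_length: int = 100
    read_end_bp: int = 10
    # contaminants per sample
    n_germline_sites: int = 60
    n_vaf1_artifacts: int = 8
    n_single_strand: int = 8
    n_mnv_pairs: int = 4
    n_read_end: int = 8
    #: per-type substitution spectra (rows sum to 1, order = SUBSTITUTIONS)
    type_signatures: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndr_depletion <= 1.0:
            raise InvalidInputError("ndr_depletion must lie in [0, 1]")
        lo, hi = self.tumor_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidInputError("tumor_fraction_range must lie in [0, 1]")

    def signature(self, cancer_type: str) -> np.ndarray:
        sig = self.type_signatures.get(cancer_type)
        if sig is None:
            return np.full(6, 1 / 6)
        sig = np.asarray(sig, dtype=float)
        return sig / sig.sum()


def default_signatures(cancer_types: Sequence[str]) -> dict[str, tuple[float, ...]]:
    """Distinct, mildly skewed substitution spectra, one per cancer type.

    Real tumor types differ in mutational signature composition; a
    different dominant substitution per type gives the 150
    variant-context features genuine localization signal.
    """
    out = {}
    for i, t in enumerate(cancer_types):
        w = np.full(6, 1.0)
        w[i % 6] = 4.0
        out[t] = tuple(w / w.sum())
    return out


def demo_layout(n_windows: int = 40, window_size: int = 1_000_000, n_chroms: int = 4) -> GenomeLayout:
    """Small multi-chromosome layout used across examples and tests."""
    per = n_windows // n_chroms
    lengths = {f"chr{i + 1}": per * window_size for i in range(n_chroms)}
    extra = n_windows - per * n_chroms
    if extra:
        lengths[f"chr{n_chroms}"] += extra * window_size
    return make_layout(lengths, window_size)


def default_config(layout: GenomeLayout, seed: int = 0, **overrides) -> SimulationConfig:
    """Config with planted windows laid out disjointly across types.

    Each cancer type receives 3 high-LMD and 3 low-LMD windows, all
    disjoint, assigned deterministically from the layout.
    """
    types = overrides.pop("cancer_types", ("breast", "liver", "lung"))
    n_each = 3
    need = 2 * n_each * len(types)
    if layout.n_windows < need:
        raise InvalidInputError(f"layout has {layout.n_windows} windows; need >= {need}")
    ids = np.linspace(0, layout.n_windows - 1, need).astype(int)
    ids = np.unique(ids)
    if len(ids) < need:  # tiny layouts: fall back to first windows
        ids = np.arange(need)
    high = {t: tuple(int(w) for w in ids[i * n_each:(i + 1) * n_each]) for i, t in enumerate(types)}
    off = n_each * len(types)
    low = {t: tuple(int(w) for w in ids[off + i * n_each: off + (i + 1) * n_each]) for i, t in enumerate(types)}
    cfg = SimulationConfig(
        seed=seed, cancer_types=tuple(types), high_windows=high, low_windows=low,
        type_signatures=default_signatures(types), **overrides,
    )
    _check_windows(cfg, layout)
    return cfg


def _check_windows(config: SimulationConfig, layout: GenomeLayout) -> None:
    for mapping in (config.high_windows, config.low_windows):
        for t, wins in mapping.items():
            for w in wins:
                if not 0 <= int(w) < layout.n_windows:
                    raise InvalidInputError(f"planted window {w} for type {t!r} outside layout")


# ---------------------------------------------------------------------------
# NDR catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NDRCatalog:
    """Planted tissue-specific nucleosome-depleted regions.

    ``table`` columns: chrom, start, end, tissue (0-based half-open,
    non-overlapping, sorted).  Midpoint = floor((start+end)/2).
    """

    table: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def midpoints(self, tissue: str | None = None) -> pd.DataFrame:
        t = self.table if tissue is None else self.table[self.table["tissue"] == tissue]
        out = t.copy()
        out["midpoint"] = (out["start"] + out["end"]) // 2
        return out.reset_index(drop=True)

    def tissue_lists(self) -> dict[str, pd.DataFrame]:
        return {t: self.midpoints(t) for t in self.tissues}


def plant_ndr_catalog(
    layout: GenomeLayout,
    tissues: Sequence[str],
    per_tissue: int = 80,
    width: int = 1000,
    spacing: int = 20_000,
) -> NDRCatalog:
    """Place ``per_tissue`` NDRs per tissue on a deterministic grid.

    Sites are spaced ``spacing`` bp apart (far beyond any fragment
    length, so a fragment can cover at most one NDR midpoint) and
    assigned to tissues round-robin.
    """
    n_needed = per_tissue * len(tissues)
    slots = []
    for chrom, length in layout.chrom_lengths.items():
        for s in range(spacing // 2, length - width, spacing):
            slots.append((chrom, s))
    if len(slots) < n_needed:
        raise InvalidInputError(f"layout too small for {n_needed} NDRs at spacing {spacing}")
    step = len(slots) / n_needed
    picks = [slots[int(i * step)] for i in range(n_needed)]
    rows = [
        (chrom, start, start + width, tissues[i % len(tissues)])
        for i, (chrom, start) in enumerate(picks)
    ]
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "tissue"])
    table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    return NDRCatalog(table=table)


# ---------------------------------------------------------------------------
# tumor-tissue MAF
# ---------------------------------------------------------------------------

def simulate_tumor_maf(
    layout: GenomeLayout,
    config: SimulationConfig,
    n_samples_per_type: int,
) -> pd.DataFrame:
    """Simulate a tumor-tissue mutation table (MAF-like).

    Per sample, per window, mutation counts are Poisson with rate
    ``maf_background_rate``, multiplied by ``maf_fold`` in the sample
    type's planted high windows and divided by it in the planted low
    windows.  Returns columns (sample, cancer_type, chrom, pos, ref, alt);
    ``pos`` is 1-based as in MAF exports.
    """
    if config.maf_fold <= 0:
        raise InvalidInputError("maf_fold must be positive")
    _check_windows(config, layout)
    for t in config.cancer_types:
        if set(config.high_windows.get(t, ())) & set(config.low_windows.get(t, ())):
            raise InvalidInputError(f"high/low planted windows overlap for type {t!r}")
    win = layout.windows
    starts = win["start"].to_numpy()
    widths = (win["end"] - win["start"]).to_numpy()
    chroms = win["chrom"].to_numpy()
    frames = []
    for ctype in config.cancer_types:
        rate = np.full(layout.n_windows, config.maf_background_rate, dtype=float)
        rate[list(config.high_windows.get(ctype, ()))] *= config.maf_fold
        rate[list(config.low_windows.get(ctype, ()))] /= config.maf_fold
        sig = config.signature(ctype)
        for i in range(n_samples_per_type):
            sample = f"{ctype}_tumor_{i:03d}"
            rng = substream(config.seed, "maf", sample)
            counts = rng.poisson(rate)
            wid = np.repeat(np.arange(layout.n_windows), counts)
            if len(wid) == 0:
                continue
            pos0 = starts[wid] + (rng.random(len(wid)) * widths[wid]).astype(np.int64)
            ref, alt, *_ = _draw_substitutions(rng, len(wid), sig)
            frames.append(pd.DataFrame({
                "sample": sample, "cancer_type": ctype, "chrom": chroms[wid],
                "pos": pos0 + 1, "ref": ref, "alt": alt,
            }))
    if not frames:
        return pd.DataFrame(columns=["sample", "cancer_type", "chrom", "pos", "ref", "alt"])
    return pd.concat(frames, ignore_index=True)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_substitutions(rng: np.random.Generator, n: int, sig: np.ndarray):
    """Draw n substitutions from a pyrimidine-reference spectrum.

    Half are emitted on the purine strand (ref A/G) so that the
    reverse-complement collapse in the featurizer is exercised; flanking
    bases are uniform.  Returns (ref, alt, flank5, flank3) arrays.
    """
    sub_idx = rng.choice(6, size=n, p=sig)
    ref = np.where(sub_idx < 3, "C", "T").astype(object)
    alts_by_sub = np.array(["A", "G", "T", "A", "C", "G"])
    alt = alts_by_sub[sub_idx].astype(object)
    flank5 = rng.choice(BASES, size=n).astype(object)
    flank3 = rng.choice(BASES, size=n).astype(object)
    flip = rng.random(n) < 0.5
    for i in np.flatnonzero(flip):
        ref[i], alt[i] = _COMP[ref[i]], _COMP[alt[i]]
        flank5[i], flank3[i] = _COMP[flank3[i]], _COMP[flank5[i]]
    return ref, alt, flank5, flank3


# ---------------------------------------------------------------------------
# cfDNA sample: fragments + raw annotated variants
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _uniform_positions(rng: np.random.Generator, layout: GenomeLayout, n: int):
    chroms = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[ci]).astype(np.int64)
    return np.array(chroms, dtype=object)[ci], pos


def simulate_cfdna_sample(
    layout: GenomeLayout,
    ndr_catalog: NDRCatalog,
    config: SimulationConfig,
    label: str,
    sample_id: str | None = None,
    tumor_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one plasma sample.

    ``label`` is ``"normal"`` or one of ``config.cancer_types``.
    Returns ``(fragments, variants)``:

    * ``fragments``: columns (chrom, start, end), 0-based half-open;
    * ``variants``: raw annotated SNV records (:data:`VARIANT_COLUMNS`)
      including the planted contaminant classes, with a ``truth_class``
      column that downstream filters must never read.

    Cancer samples draw a tumor-fraction share of fragments from the
    shorter length distribution, and fragments covering a matched-tissue
    NDR midpoint are kept with probability ``1 - tf * ndr_depletion``.
    """
    if label != "normal" and label not in config.cancer_types:
        raise InvalidInputError(f"unknown label {label!r}")
    bad = ndr_catalog.table.merge(
        pd.DataFrame({"chrom": list(layout.chrom_lengths), "clen": list(layout.chrom_lengths.values())}),
        on="chrom", how="left")
    if bad["clen"].isna().any() or (bad["end"] > bad["clen"]).any():
        raise InvalidInputError("ndr_catalog coordinates outside layout")
    sample_id = sample_id or f"{label}_000"
    rng = substream(config.seed, "sample", sample_id)
    if tumor_fraction is None:
        tf = 0.0 if label == "normal" else float(rng.uniform(*config.tumor_fraction_range))
    else:
        tf = float(tumor_fraction)
    if not 0.0 <= tf <= 1.0:
        raise InvalidInputError("tumor fraction must lie in [0, 1]")

    fragments = _simulate_fragments(rng, layout, ndr_catalog, config, label, tf)
    variants = _simulate_variants(rng, layout, config, label, tf)
    fragments.attrs.update({"sample": sample_id, "label": label, "tumor_fraction": tf})
    variants.attrs.update({"sample": sample_id, "label": label, "tumor_fraction": tf})
    return fragments, variants


def _simulate_fragments(rng, layout, ndr_catalog, config, label, tf) -> pd.DataFrame:
    n = config.fragments_per_sample
    lo, hi = config.frag_len_bounds
    is_tumor = rng.random(n) < tf
    lengths = np.empty(n)
    n_t = int(is_tumor.sum())
    lengths[~is_tumor] = _truncnorm(rng, config.normal_frag_mean, config.normal_frag_sd, lo, hi, n - n_t)
    if n_t:
        lengths[is_tumor] = _truncnorm(rng, config.tumor_frag_mean, config.tumor_frag_sd, lo, hi, n_t)
    lengths = np.round(lengths).astype(np.int64)

    near = rng.random(n) < (config.ndr_center_fraction if len(ndr_catalog.table) else 0.0)
    chrom = np.empty(n, dtype=object)
    center = np.empty(n, dtype=np.int64)
    n_near = int(near.sum())
    if n_near:
        mids = ndr_catalog.midpoints()
        pick = rng.integers(0, len(mids), size=n_near)
        chrom[near] = mids["chrom"].to_numpy(dtype=object)[pick]
        center[near] = mids["midpoint"].to_numpy()[pick] + rng.integers(
            -config.ndr_center_halfspan, config.ndr_center_halfspan, size=n_near)
    chrom[~near], center[~near] = _uniform_positions(rng, layout, n - n_near)

    start = center - lengths // 2
    end = start + lengths
    clens = np.array([layout.chrom_lengths[c] for c in chrom])
    shift = np.maximum(0, -start) - np.maximum(0, end - clens)
    start, end = start + shift, end + shift

    keep = np.ones(n, dtype=bool)
    if label != "normal" and tf > 0 and config.ndr_depletion > 0:
        matched = ndr_catalog.midpoints(label)
        if len(matched):
            covered = np.zeros(n, dtype=bool)
            for c, grp in matched.groupby("chrom"):
                mids = np.sort(grp["midpoint"].to_numpy())
                m = chrom == c
                # NDR spacing exceeds fragment length: at most one candidate midpoint
                idx = np.searchsorted(mids, start[m], side="left")
                idx = np.clip(idx, 0, len(mids) - 1)
                covered[m] = (mids[idx] >= start[m]) & (mids[idx] < end[m])
            keep[covered] = rng.random(int(covered.sum())) >= tf * config.ndr_depletion
    df = pd.DataFrame({"chrom": chrom[keep], "start": start[keep], "end": end[keep]})
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _interior_offsets(rng, n_reads: int, read_len: int, end_bp: int) -> list[tuple[int, int]]:
    o5 = rng.integers(end_bp, read_len - end_bp, size=n_reads)
    return [(int(o), int(read_len - 1 - o)) for o in o5]


def _end_offsets(rng, n_reads: int, read_len: int, end_bp: int) -> list[tuple[int, int]]:
    o5 = rng.integers(0, end_bp, size=n_reads)
    o5 = np.where(rng.random(n_reads) < 0.5, o5, read_len - 1 - o5)
    return [(int(o), int(read_len - 1 - o)) for o in o5]


def germline_catalog(layout: GenomeLayout, config: SimulationConfig) -> pd.DataFrame:
    """Cohort-shared germline sites (same in every sample under one seed)."""
    rng = substream(config.seed, "germline-catalog")
    chrom, pos0 = _uniform_positions(rng, layout, config.n_germline_sites)
    ref, alt, f5, f3 = _draw_substitutions(rng, config.n_germline_sites, np.full(6, 1 / 6))
    hom = rng.random(config.n_germline_sites) < 0.3
    return pd.DataFrame({"chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                         "flank5": f5, "flank3": f3, "hom": hom})


def _variant_rows(rng, config, chrom, pos, ref, alt, f5, f3, truth, *, vaf=None,
                  alt_depth=None, strand_mode="both", offsets_mode="interior"):
    n = len(pos)
    if alt_depth is None:
        alt_depth = 4 + rng.poisson(4.0, size=n)
    alt_depth = np.maximum(np.asarray(alt_depth), 1)
    if vaf is None:
        vaf = np.clip(rng.normal(0.05, 0.02, size=n), 0.01, 0.5)
    vaf = np.asarray(vaf, dtype=float)
    depth = np.maximum(alt_depth, np.round(alt_depth / np.maximum(vaf, 1e-9)).astype(np.int64))
    if strand_mode == "both":
        fwd = rng.binomial(alt_depth, 0.5)
    elif strand_mode == "balanced":
        # guaranteed >= 1 read per strand (needs alt_depth >= 2)
        fwd = np.maximum(1, alt_depth // 2)
    elif strand_mode == "fwd":
        fwd = alt_depth.copy()
    else:
        fwd = np.zeros(n, dtype=np.int64)
    rev = alt_depth - fwd
    make_off = _interior_offsets if offsets_mode == "interior" else _end_offsets
    offsets = [make_off(rng, int(a), config.read_length, config.read_end_bp) for a in alt_depth]
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "depth": depth, "alt_depth": alt_depth, "alt_fwd": fwd, "alt_rev": rev,
        "offsets": offsets, "flank5": f5, "flank3": f3, "truth_class": truth,
    })


def _simulate_variants(rng, layout, config, label, tf) -> pd.DataFrame:
    parts: list[pd.DataFrame] = []
    # germline sites: present in every sample; het VAF ~ 0.5, hom VAF = 1.0
    g = germline_catalog(layout, config)
    alt_depth = 10 + rng.poisson(10.0, size=len(g))
    vaf = np.where(g["hom"].to_numpy(), 1.0, np.clip(rng.normal(0.5, 0.05, size=len(g)), 0.3, 0.7))
    parts.append(_variant_rows(rng, config, g["chrom"].to_numpy(object), g["pos"].to_numpy(),
                               g["ref"].to_numpy(object), g["alt"].to_numpy(object),
                               g["flank5"].to_numpy(object), g["flank3"].to_numpy(object),
                               "germline", vaf=vaf, alt_depth=alt_depth))

    def random_snvs(k, truth, sig=None, **kw):
        if k <= 0:
            return None
        chrom, pos0 = _uniform_positions(rng, layout, k)
        ref, alt, f5, f3 = _draw_substitutions(rng, k, np.full(6, 1 / 6) if sig is None else sig)
        return _variant_rows(rng, config, chrom, pos0 + 1, ref, alt, f5, f3, truth, **kw)

    # filter-passing background passengers (all samples, incl. normals)
    n_bg = rng.poisson(config.background_variants_mean)
    parts.append(random_snvs(int(n_bg), "background"))
    # contaminant classes with the evidence signature each rule targets
    nv = rng.poisson(config.n_vaf1_artifacts)
    p = random_snvs(int(nv), "vaf1")
    if p is not None:
        p["depth"] = p["alt_depth"]
        parts.append(p)
    ns = rng.poisson(config.n_single_strand)
    half = int(ns) // 2
    parts.append(random_snvs(half, "single_strand", strand_mode="fwd"))
    parts.append(random_snvs(int(ns) - half, "single_strand", strand_mode="rev"))
    nm = rng.poisson(config.n_mnv_pairs)
    if nm > 0:
        chrom, pos0 = _uniform_positions(rng, layout, int(nm))
        for shiftpos in (0, 1):
            ref, alt, f5, f3 = _draw_substitutions(rng, int(nm), np.full(6, 1 / 6))
            # both-strand support guaranteed so adjacency is the only
            # signature the pair carries into the cascade
            parts.append(_variant_rows(rng, config, chrom, pos0 + 1 + shiftpos, ref, alt,
                                       f5, f3, "mnv", strand_mode="balanced"))
    ne = rng.poisson(config.n_read_end)
    parts.append(random_snvs(int(ne), "read_end", offsets_mode="ends"))

    # tumor variants, concentrated in the label's planted high-LMD windows
    if label != "normal" and tf > 0:
        k = int(rng.poisson(tf * config.tumor_variants_per_unit_tf))
        if k:
            high = list(config.high_windows.get(label, ()))
            in_high = rng.random(k) < (config.high_window_share if high else 0.0)
            chrom = np.empty(k, dtype=object)
            pos0 = np.empty(k, dtype=np.int64)
            n_h = int(in_high.sum())
            if n_h:
                win = layout.windows
                wid = np.array(high)[rng.integers(0, len(high), size=n_h)]
                w_start = win["start"].to_numpy()[wid]
                w_len = (win["end"] - win["start"]).to_numpy()[wid]
                chrom[in_high] = win["chrom"].to_numpy(object)[wid]
                pos0[in_high] = w_start + (rng.random(n_h) * w_len).astype(np.int64)
            chrom[~in_high], pos0[~in_high] = _uniform_positions(rng, layout, k - n_h)
            ref, alt, f5, f3 = _draw_substitutions(rng, k, config.signature(label))
            vaf = np.clip(rng.normal(tf / 2, tf / 8 + 0.005, size=k), 0.02, 0.6)
            alt_depth = 4 + rng.poisson(4.0 + 30.0 * tf, size=k)
            parts.append(_variant_rows(rng, config, chrom, pos0 + 1, ref, alt, f5, f3,
                                       "tumor", vaf=vaf, alt_depth=alt_depth))

    parts = [p for p in parts if p is not None and len(p)]
    if not parts:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)[VARIANT_COLUMNS]


# ---------------------------------------------------------------------------
# panel of normals
# ---------------------------------------------------------------------------

def simulate_panel(normal_variant_tables: Iterable[pd.DataFrame], recurrence_threshold: int = 2) -> pd.DataFrame:
    """Build a panel of normals: sites seen in >= threshold normal samples.

    Mirrors how recurrent variant calls from healthy cfDNA are pooled
    into a reference panel.  Returns unique (chrom, pos, ref, alt) rows.
    """
    if recurrence_threshold < 1:
        raise InvalidInputError("recurrence_threshold must be >= 1")
    tables = list(normal_variant_tables)
    if not tables:
        raise InvalidInputError("need at least one normal sample")
    per_sample = [t[["chrom", "pos", "ref", "alt"]].drop_duplicates() for t in tables]
    allv = pd.concat(per_sample, ignore_index=True)
    counts = allv.groupby(["chrom", "pos", "ref", "alt"], sort=True).size()
    panel = counts[counts >= recurrence_threshold].reset_index()[["chrom", "pos", "ref", "alt"]]
    return panel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# whole cohorts & ATAC-style inputs
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """One simulated plasma cohort: sample sheet plus per-sample tables."""

    samples: pd.DataFrame  # columns: sample, label, tumor_fraction
    fragments: dict[str, pd.DataFrame]
    variants: dict[str, pd.DataFrame]
    layout: GenomeLayout
    ndr_catalog: NDRCatalog
    config: SimulationConfig


def simulate_cohort(
    layout: GenomeLayout,
    ndr_catalog: NDRCatalog,
    config: SimulationConfig,
    n_cancer_per_type: int,
    n_normal: int,
) -> Cohort:
    """Simulate a labeled cohort of cancer and normal plasma samples."""
    rows = []
    fragments: dict[str, pd.DataFrame] = {}
    variants: dict[str, pd.DataFrame] = {}
    for label in list(config.cancer_types) + ["normal"]:
        n = n_normal if label == "normal" else n_cancer_per_type
        for i in range(n):
            sid = f"{label}_{i:03d}"
            fr, va = simulate_cfdna_sample(layout, ndr_catalog, config, label, sample_id=sid)
            fragments[sid], variants[sid] = fr, va
            rows.append((sid, label, fr.attrs["tumor_fraction"]))
    samples = pd.DataFrame(rows, columns=["sample", "label", "tumor_fraction"])
    return Cohort(samples=samples, fragments=fragments, variants=variants,
                  layout=layout, ndr_catalog=ndr_catalog, config=config)


def simulate_ndr_count_matrix(
    n_peaks: int,
    tissues: Sequence[str],
    samples_per_tissue: int,
    seed: int = 0,
    specific_per_tissue: int = 2000,
    fold: float = 6.0,
    base_mean: float = 50.0,
    dispersion: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series, dict[str, np.ndarray]]:
    """Simulate a meta-peak x sample short-fragment count matrix.

    Each tissue owns ``specific_per_tissue`` planted peaks whose
    accessibility (hence count mean) is ``fold`` times higher in that
    tissue's samples — the tissue-specific openness that the reference
    builder is meant to recover.  Counts are negative binomial.

    Returns ``(counts, tissue_labels, truth)`` where ``truth`` maps each
    tissue to its planted peak row indices.
    """
    if specific_per_tissue * len(tissues) > n_peaks:
        raise InvalidInputError("planted peaks exceed n_peaks")
    rng = substream(seed, "ndr-counts")
    base = base_mean * rng.lognormal(0.0, 0.5, size=n_peaks)
    truth = {}
    next_id = 0
    for t in tissues:
        truth[t] = np.arange(next_id, next_id + specific_per_tissue)
        next_id += specific_per_tissue
    cols, labels = [], []
    for t in tissues:
        for i in range(samples_per_tissue):
            mu = base.copy()
            mu[truth[t]] *= fold
            r = 1.0 / dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            cols.append(counts)
            labels.append(t)
    counts = pd.DataFrame(np.column_stack(cols),
                          columns=[f"{t}_{i}" for t in tissues for i in range(samples_per_tissue)])
    counts.index.name = "peak_id"
    return counts, pd.Series(labels, index=counts.columns, name="tissue"), truth


def simulate_peak_sets(
    layout: GenomeLayout,
    tissues: Sequence[str],
    samples_per_tissue: int,
    peaks_per_sample: int = 200,
    width: int = 800,
    jitter: int = 150,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Simulate per-sample ATAC peak sets around a shared site grid.

    Every sample calls peaks at a common grid of candidate sites (with
    positional jitter and random signal scores); used to exercise
    meta-peak merging and the peak-count sample filter.
    """
    rng = substream(seed, "peak-sets")
    grid_chrom, grid_pos = _uniform_positions(rng, layout, peaks_per_sample * 2)
    order = np.lexsort((grid_pos, grid_chrom.astype(str)))
    grid_chrom, grid_pos = grid_chrom[order], grid_pos[order]
    out = []
    for t in tissues:
        for i in range(samples_per_tissue):
            srng = substream(seed, "peak-sets", t, i)
            pick = np.sort(srng.choice(len(grid_pos), size=peaks_per_sample, replace=False))
            start = grid_pos[pick] + srng.integers(-jitter, jitter + 1, size=peaks_per_sample)
            start = np.maximum(start, 0)
            df = pd.DataFrame({
                "chrom": grid_chrom[pick], "start": start, "end": start + width,
                "score": srng.gamma(4.0, 5.0, size=peaks_per_sample),
            })
            df.attrs.update({"sample": f"{t}_atac_{i}", "tissue": t})
            out.append(df)
    return out
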