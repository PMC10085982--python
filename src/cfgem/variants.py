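"""Somatic variant filtering for plasma cfDNA.

Tumor-derived variants are a needle in a haystack of germline calls,
clonal-hematopoiesis variants and sequencing artifacts.  The cascade
removes, in a fixed order:

1. non-SNV records (SNV extraction),
2. variants inside blacklisted intervals,
3. variants at panel-of-normals sites,
4. variants at known germline sites,
5. VAF = 100% variants (homozygous germline leftovers),
6. strand-discordant variants (alt allele seen on only one strand),
7. multi-nucleotide variants (same-sample calls at adjacent positions),
8. variants whose every supporting read places the alt allele within
   ``read_end_bp`` of a read end.

Each stage's removals are accounted for in a :class:`FilterReport`.

Conventions: a variant is "strand discordant" when ``min(alt_fwd,
alt_rev) == 0`` with positive alt depth; an MNV is a pair of
same-sample variants at distance exactly 1 bp on one chromosome (both
members removed); the read-end rule spares a variant as soon as one
supporting read is interior (a single well-placed read argues against a
position-specific error); VAF is compared with 1.0 after rounding to 6
decimals to avoid float jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cfgem.errors import InvalidInputError
from cfgem.simulate import VARIANT_COLUMNS

STAGES = ["snv", "blacklist", "panel", "germline", "vaf", "strand", "mnv", "read_end"]

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class FilterReport:
    """Per-stage accounting of the filter cascade."""

    stages: list[str]
    input_count: int
    surviving: dict[str, int] = field(default_factory=dict)
    removed_sites: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows, prev = [], self.input_count
        for s in self.stages:
            surv = self.surviving[s]
            rows.append((s, prev, surv, prev - surv))
            prev = surv
        return pd.DataFrame(rows, columns=["stage", "input", "surviving", "removed"])

    def check(self) -> None:
        prev = self.input_count
        for s in self.stages:
            if self.surviving[s] > prev:
                raise AssertionError(f"stage {s}: counts not monotone")
            prev = self.surviving[s]


def _round_vaf(df: pd.DataFrame) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = df["alt_depth"].to_numpy(float) / np.maximum(df["depth"].to_numpy(float), 1e-12)
    return np.round(vaf, 6)


def annotate_variants(records: pd.DataFrame, reads: pd.DataFrame, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Annotate raw VCF-style records with read-level evidence.

    ``records`` needs (chrom, pos, ref, alt) with 1-based positions and
    may carry flank5/flank3; ``reads`` is an aligned-read table with
    columns (chrom, start, end, strand, alt_pos, alt_base) where
    ``alt_pos`` is the 1-based position of a non-reference base carried
    by the read (NaN for reference-matching reads).

    Every output record carries the full evidence schema; records with
    no supporting reads get an empty offset list and zero alt depth.
    """
    if chrom_lengths is not None:
        bad = records[~records["chrom"].isin(chrom_lengths)]
        if len(bad) == 0:
            over = records.merge(
                pd.DataFrame({"chrom": list(chrom_lengths), "clen": list(chrom_lengths.values())}),
                on="chrom")
            bad = over[over["pos"] > over["clen"]]
        if len(bad):
            raise InvalidInputError("record position outside any chromosome")
    out_rows = []
    for _, r in records.iterrows():
        pos0 = int(r["pos"]) - 1
        over = reads[(reads["chrom"] == r["chrom"]) & (reads["start"] <= pos0) & (reads["end"] > pos0)]
        sup = over[(over["alt_pos"] == r["pos"]) & (over["alt_base"] == r["alt"])]
        offsets = []
        fwd = rev = 0
        for _, rd in sup.iterrows():
            readlen = int(rd["end"] - rd["start"])
            if rd["strand"] == "+":
                o5 = pos0 - int(rd["start"])
                fwd += 1
            else:
                o5 = int(rd["end"]) - 1 - pos0
                rev += 1
            offsets.append((o5, readlen - 1 - o5))
        out_rows.append({
            "chrom": r["chrom"], "pos": int(r["pos"]), "ref": r["ref"], "alt": r["alt"],
            "depth": len(over), "alt_depth": len(sup), "alt_fwd": fwd, "alt_rev": rev,
            "offsets": offsets, "flank5": r.get("flank5", "N"), "flank3": r.get("flank3", "N"),
            "truth_class": r.get("truth_class", ""),
        })
    return pd.DataFrame(out_rows, columns=VARIANT_COLUMNS)


def _extract_snv(variants: pd.DataFrame) -> pd.DataFrame:
    ref = variants["ref"].astype(str)
    alt = variants["alt"].astype(str)
    ok = (ref.str.len() == 1) & (alt.str.len() == 1) & (ref != alt) \
        & ref.isin(list("ACGT")) & alt.isin(list("ACGT"))
    return variants[ok]


def apply_panel_and_germline_filter(
    variants: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    germline_sets: list[pd.DataFrame] | None = None,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SNV extraction, blacklist, panel, and germline-site removal.

    Site sets are keyed by (chrom, pos, ref, alt); the blacklist is a
    table of 0-based half-open (chrom, start, end) intervals.  A variant
    survives iff it is an SNV, its position lies inside no blacklist
    interval, and its site is in neither the panel nor any germline set.
    """
    out = _extract_snv(variants)
    out = _apply_blacklist(out, blacklist)
    out = _remove_sites(out, panel)
    for g in germline_sets or []:
        out = _remove_sites(out, g)
    return out


def _apply_blacklist(variants: pd.DataFrame, blacklist: pd.DataFrame | None) -> pd.DataFrame:
    if blacklist is None or len(blacklist) == 0 or len(variants) == 0:
        return variants
    if (blacklist["start"] >= blacklist["end"]).any():
        raise InvalidInputError("malformed blacklist interval (start >= end)")
    drop = np.zeros(len(variants), dtype=bool)
    pos0 = variants["pos"].to_numpy() - 1  # VCF 1-based -> 0-based
    chrom = variants["chrom"].to_numpy(object)
    for c, grp in blacklist.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = grp["end"].to_numpy()[np.argsort(grp["start"].to_numpy())]
        # intervals may overlap; use running max of ends for containment
        run_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, pos0[m], side="right") - 1
        inside = (idx >= 0) & (pos0[m] < run_end[np.clip(idx, 0, None)])
        drop[m] = inside
    return variants[~drop]


def _remove_sites(variants: pd.DataFrame, sites: pd.DataFrame | None) -> pd.DataFrame:
    if sites is None or len(sites) == 0 or len(variants) == 0:
        return variants
    key = pd.MultiIndex.from_frame(variants[_SITE_KEY])
    bad = pd.MultiIndex.from_frame(sites[_SITE_KEY].drop_duplicates())
    return variants[~key.isin(bad)]


def apply_artifact_filters(variants: pd.DataFrame, read_end_bp: int = 10) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Apply the four evidence-level artifact rules in order.

    Returns (survivors, per-rule removed records).  Rules: VAF=1.0,
    single-strand alt support, adjacent-position MNVs (both removed),
    and all-supporting-reads-at-read-end.
    """
    if read_end_bp < 0:
        raise InvalidInputError("read_end_bp must be >= 0")
    removed: dict[str, pd.DataFrame] = {}
    cur = variants

    is_vaf1 = _round_vaf(cur) == 1.0 if len(cur) else np.zeros(0, bool)
    removed["vaf"], cur = cur[is_vaf1], cur[~is_vaf1]

    if len(cur):
        single = (cur["alt_depth"].to_numpy() > 0) & (
            np.minimum(cur["alt_fwd"].to_numpy(), cur["alt_rev"].to_numpy()) == 0)
    else:
        single = np.zeros(0, bool)
    removed["strand"], cur = cur[single], cur[~single]

    if len(cur):
        mnv = np.zeros(len(cur), dtype=bool)
        pos = cur["pos"].to_numpy()
        chrom = cur["chrom"].to_numpy(object)
        order = np.lexsort((pos, chrom.astype(str)))
        sp, sc = pos[order], chrom[order]
        adj = (np.diff(sp) == 1) & (sc[:-1] == sc[1:])
        flag = np.zeros(len(cur), dtype=bool)
        flag[:-1] |= adj
        flag[1:] |= adj
        mnv[order] = flag
    else:
        mnv = np.zeros(0, bool)
    removed["mnv"], cur = cur[mnv], cur[~mnv]

    if len(cur):
        def all_at_ends(offs) -> bool:
            if not offs:
                return False  # no read evidence: nothing to judge
            return all(min(o5, o3) < read_end_bp for o5, o3 in offs)
        at_end = cur["offsets"].map(all_at_ends).to_numpy(bool)
    else:
        at_end = np.zeros(0, bool)
    removed["read_end"], cur = cur[at_end], cur[~at_end]
    return cur, removed


def run_filter_cascade(
    variants: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    germline_sets: list[pd.DataFrame] | None = None,
    blacklist: pd.DataFrame | None = None,
    read_end_bp: int = 10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade; returns (survivors, per-stage report)."""
    report = FilterReport(stages=list(STAGES), input_count=len(variants))
    cur = _extract_snv(variants)
    report.removed_sites["snv"] = variants[~variants.index.isin(cur.index)]
    report.surviving["snv"] = len(cur)

    try:
        nxt = _apply_blacklist(cur, blacklist)
    except InvalidInputError as e:
        raise InvalidInputError(f"stage blacklist: {e}") from e
    report.removed_sites["blacklist"] = cur[~cur.index.isin(nxt.index)]
    report.surviving["blacklist"] = len(nxt)
    cur = nxt

    for stage, sites in (("panel", panel), ("germline", None)):
        if stage == "panel":
            nxt = _remove_sites(cur, sites)
        else:
            nxt = cur
            for g in germline_sets or []:
                nxt = _remove_sites(nxt, g)
        report.removed_sites[stage] = cur[~cur.index.isin(nxt.index)]
        report.surviving[stage] = len(nxt)
        cur = nxt

    try:
        cur, removed = apply_artifact_filters(cur, read_end_bp=read_end_bp)
    except InvalidInputError as e:
        raise InvalidInputError(f"stage artifact: {e}") from e
    n = report.surviving["germline"]
    for stage in ("vaf", "strand", "mnv", "read_end"):
        report.removed_sites[stage] = removed[stage]
        n -= len(removed[stage])
        report.surviving[stage] = n
    report.check()
    cur = cur.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return cur, report
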