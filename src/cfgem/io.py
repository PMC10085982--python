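"""Readers and writers for the pipeline's on-disk formats.

Variants travel as VCF 4.2 with the evidence the filter cascade needs
(DP, strand-split alt depths SAF/SAR, an RO read-offset list and F5/F3
flanking bases as INFO fields, so a fragment/BAM file is not required
to re-annotate); fragments as BED3+; tumor mutation tables as
MAF-style TSV with the standard PCAWG export column names; panels as
site lists; peaks as narrowPeak/BED; V-plot tensors as ``.npz`` with a
JSON sidecar carrying axis metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cfgem.simulate import VARIANT_COLUMNS
from cfgem.vplot import VPlotTensor

_VCF_INFO_LINES = """##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt-supporting forward reads">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt-supporting reverse reads">
##INFO=<ID=RO,Number=.,Type=String,Description="Alt read offsets as from5:from3 pairs">
##INFO=<ID=F5,Number=1,Type=String,Description="5' flanking reference base">
##INFO=<ID=F3,Number=1,Type=String,Description="3' flanking reference base">
##INFO=<ID=TC,Number=1,Type=String,Description="Simulation truth class (diagnostic only)">
"""


def _contig_lines(chroms) -> str:
    return "".join(f"##contig=<ID={c}>\n" for c in dict.fromkeys(chroms))


def write_variants_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n" + _VCF_INFO_LINES)
        fh.write(_contig_lines(variants["chrom"]))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples(index=False):
            ro = ",".join(f"{o5}:{o3}" for o5, o3 in r.offsets) or "."
            info = (f"DP={r.depth};SAF={r.alt_fwd};SAR={r.alt_rev};RO={ro};"
                    f"F5={r.flank5};F3={r.flank3};TC={r.truth_class or '.'}")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            ro = info.get("RO", ())
            offsets = [tuple(int(v) for v in pair.split(":")) for pair in ro]
            saf, sar = int(info.get("SAF", 0)), int(info.get("SAR", 0))
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
                "depth": int(info.get("DP", 0)), "alt_depth": saf + sar,
                "alt_fwd": saf, "alt_rev": sar, "offsets": offsets,
                "flank5": info.get("F5", "N"), "flank3": info.get("F3", "N"),
                "truth_class": "" if info.get("TC", ".") == "." else info["TC"],
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_sites_vcf(sites: pd.DataFrame, path: str | Path) -> None:
    """Sites-only VCF (panel of normals / germline site lists)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_contig_lines(sites["chrom"]))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sites.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        rows = [(rec.chrom, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".")
                for rec in vf]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path, sample: str = ".") -> None:
    out = fragments[["chrom", "start", "end"]].copy()
    out["sample"] = sample
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


_MAF_COLS = {"sample": "Tumor_Sample_Barcode", "cancer_type": "Project_Code",
             "chrom": "Chromosome", "pos": "Start_position",
             "ref": "Reference_Allele", "alt": "Tumor_Seq_Allele2"}


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    out = maf.rename(columns=_MAF_COLS)
    out["Variant_Type"] = "SNP"
    out.to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    inv = {v: k for k, v in _MAF_COLS.items()}
    return df.rename(columns=inv)[list(_MAF_COLS)]


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read narrowPeak (10 cols, score = signalValue) or BED (score col 5)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = {0: "chrom", 1: "start", 2: "end"}
    df = df.rename(columns=cols)
    df["score"] = df[6] if df.shape[1] >= 10 else (df[4] if df.shape[1] >= 5 else 1.0)
    return df[["chrom", "start", "end", "score"]]


def write_bed(intervals: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_tensor(tensor: VPlotTensor, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=tensor.data)
    meta = {"tissue_order": list(tensor.tissue_order), "halfspan": tensor.halfspan,
            "normalized": tensor.normalized, "size_range": [100, 200]}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_tensor(path: str | Path) -> VPlotTensor:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return VPlotTensor(data=data, tissue_order=tuple(meta["tissue_order"]),
                       halfspan=meta["halfspan"], normalized=meta["normalized"])
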