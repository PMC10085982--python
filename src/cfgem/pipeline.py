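"""End-to-end synthetic pipeline orchestration.

``run_pipeline`` ties the stages together in topological order:

    simulate -> panel -> filter -> lmd-ref -> featurize-genome
             -> featurize-epigenome -> train -> evaluate -> attribute

Each stage reads earlier artifacts from an in-memory store; asking for
a stage whose prerequisites are neither cached nor scheduled raises an
error naming the stage.  Every run writes a manifest (config hash,
seed, package version) next to its outputs, and a fixed config hash
reproduces identical tabular outputs.

Two budget profiles exist purely as configuration: ``paper`` (30
restarts, patience 50, 250 conv kernels, 200 search trials) mirrors
the published training protocol; ``desk`` (the default) scales the
budgets to single-CPU minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cfgem
from cfgem import attribution as attr_mod
from cfgem import genome_features as gf
from cfgem import lmd, models, variants as vf, vplot
from cfgem.errors import InvalidInputError
from cfgem.rng import substream
from cfgem.simulate import (Cohort, default_config, demo_layout, germline_catalog,
                            plant_ndr_catalog, simulate_cohort, simulate_panel,
                            simulate_tumor_maf)

STAGE_ORDER = ["simulate", "panel", "filter", "lmd-ref", "featurize-genome",
               "featurize-epigenome", "train", "evaluate", "attribute"]

_DEPS = {
    "simulate": [],
    "panel": ["simulate"],
    "filter": ["simulate", "panel"],
    "lmd-ref": ["simulate"],
    "featurize-genome": ["filter"],
    "featurize-epigenome": ["simulate"],
    "train": ["featurize-genome", "featurize-epigenome"],
    "evaluate": ["train"],
    "attribute": ["train", "featurize-genome"],
}


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the documented constants."""

    seed: int = 0
    profile: str = "desk"                     # "desk" | "paper"
    # cohort scale
    cancer_types: tuple[str, ...] = ("breast", "liver", "lung")
    n_cancer_per_type: int = 34
    n_normal: int = 100
    n_windows: int = 40
    window_size: int = 1_000_000
    ndrs_per_tissue: int = 80
    maf_samples_per_type: int = 20
    # documented constants
    panel_recurrence: int = 2
    read_end_bp: int = 10
    max_zero_fraction: float = 0.5
    lmd_fdr: float = 0.05
    lmd_top_k: int = 25
    min_peaks: int = 30_000
    ndr_selection_size: int = 10_000
    vplot_halfspan: int = 500
    folds: int = 5
    n_boot: int = 1000
    spec_levels: tuple[float, ...] = (0.95, 0.98, 0.99)
    ig_steps: int = 50
    #: free-form overrides for SimulationConfig fields
    simulation: dict = field(default_factory=dict)
    #: ModelSpec overrides applied on top of the active profile
    genome_model: dict = field(default_factory=dict)
    epigenome_model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("cancer_types", "spec_levels"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def model_budgets(self) -> tuple[dict, dict]:
        g = {} if self.profile == "paper" else dict(models.DESK_GENOME)
        e = {} if self.profile == "paper" else dict(models.DESK_EPIGENOME)
        g.update(self.genome_model)
        e.update(self.epigenome_model)
        return g, e


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    outdir: str | Path | None = None,
    artifacts: dict | None = None,
) -> dict:
    """Execute the requested stages (default: all) and return artifacts.

    ``artifacts`` may carry results of earlier invocations; a stage
    whose prerequisites are missing from it raises
    :class:`InvalidInputError` naming the stage and the missing
    dependency.
    """
    stages = list(STAGE_ORDER) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise InvalidInputError(f"unknown stage(s): {unknown}")
    stages.sort(key=STAGE_ORDER.index)
    art: dict = dict(artifacts or {})
    done: list[str] = list(art.get("completed", []))
    for stage in stages:
        missing = [d for d in _DEPS[stage] if d not in done]
        if missing:
            raise InvalidInputError(f"stage {stage!r} requires {missing[0]!r} first")
        _STAGE_FUNCS[stage](config, art)
        done.append(stage)
        art["completed"] = done
    if outdir is not None:
        _persist(config, art, Path(outdir))
    return art


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, art: dict) -> None:
    layout = demo_layout(cfg.n_windows, cfg.window_size)
    sim = default_config(layout, seed=cfg.seed, cancer_types=cfg.cancer_types, **cfg.simulation)
    catalog = plant_ndr_catalog(layout, list(cfg.cancer_types), per_tissue=cfg.ndrs_per_tissue)
    cohort = simulate_cohort(layout, catalog, sim, cfg.n_cancer_per_type, cfg.n_normal)
    art.update(layout=layout, sim_config=sim, ndr_catalog=catalog, cohort=cohort)


def _stage_panel(cfg: PipelineConfig, art: dict) -> None:
    cohort: Cohort = art["cohort"]
    normals = [cohort.variants[s] for s in cohort.samples.loc[cohort.samples["label"] == "normal", "sample"]]
    art["panel"] = simulate_panel(normals, recurrence_threshold=cfg.panel_recurrence)
    art["germline_sites"] = germline_catalog(art["layout"], art["sim_config"])[["chrom", "pos", "ref", "alt"]]


def _stage_filter(cfg: PipelineConfig, art: dict) -> None:
    cohort: Cohort = art["cohort"]
    filtered, reports = {}, {}
    for s, tab in cohort.variants.items():
        out, rep = vf.run_filter_cascade(tab, panel=art["panel"],
                                         germline_sets=[art["germline_sites"]],
                                         read_end_bp=cfg.read_end_bp)
        filtered[s], reports[s] = out, rep
    art["filtered"], art["filter_reports"] = filtered, reports


def _stage_lmd_ref(cfg: PipelineConfig, art: dict) -> None:
    maf = simulate_tumor_maf(art["layout"], art["sim_config"], cfg.maf_samples_per_type)
    matrix = lmd.compute_lmd_matrix(maf, art["layout"])
    art["maf"] = maf
    art["lmd_ref"] = lmd.select_lmd_regions(matrix, fdr=cfg.lmd_fdr, top_k=cfg.lmd_top_k)


def _stage_featurize_genome(cfg: PipelineConfig, art: dict) -> None:
    counts = gf.cohort_window_counts(art["filtered"], art["layout"])
    retained = gf.retained_windows(counts, max_zero_fraction=cfg.max_zero_fraction)
    art["retained_windows"] = retained
    art["genome_features"] = gf.cohort_feature_matrix(art["filtered"], art["layout"], retained)


def _stage_featurize_epigenome(cfg: PipelineConfig, art: dict) -> None:
    cohort: Cohort = art["cohort"]
    tissue_ndrs = art["ndr_catalog"].tissue_lists()
    order = tuple(cfg.cancer_types)
    tensors = {s: vplot.sample_vplot_tensor(fr, tissue_ndrs, order, halfspan=cfg.vplot_halfspan)
               for s, fr in cohort.fragments.items()}
    art["vplot_order"] = order
    art["vplots"] = tensors


def _stage_train(cfg: PipelineConfig, art: dict) -> None:
    cohort: Cohort = art["cohort"]
    desk_g, desk_e = cfg.model_budgets()
    samples = cohort.samples["sample"].tolist()
    y_det = (cohort.samples["label"] != "normal").to_numpy().astype(int)
    xg = art["genome_features"].loc[samples].to_numpy(dtype=np.float32)
    xe = np.stack([art["vplots"][s].data for s in samples]).astype(np.float32)

    g_spec = models.ModelSpec(family="genome-dnn", task="detection", seed=cfg.seed, **desk_g)
    e_spec = models.ModelSpec(family="epigenome-cnn", task="detection", seed=cfg.seed, **desk_e)
    det_g = models.crossvalidate(xg, y_det, g_spec, k=cfg.folds, sample_ids=samples)
    det_e = models.crossvalidate(xe, y_det, e_spec, k=cfg.folds, sample_ids=samples)

    is_cancer = y_det == 1
    classes = tuple(cfg.cancer_types)
    y_loc = cohort.samples.loc[is_cancer, "label"].map({c: i for i, c in enumerate(classes)}).to_numpy()
    loc_samples = [s for s, c in zip(samples, is_cancer) if c]
    gl_spec = dataclasses.replace(g_spec, task="localization", n_classes=len(classes))
    el_spec = dataclasses.replace(e_spec, task="localization", n_classes=len(classes))
    loc_g = models.crossvalidate(xg[is_cancer], y_loc, gl_spec, k=cfg.folds,
                                 sample_ids=loc_samples, class_names=classes)
    loc_e = models.crossvalidate(xe[is_cancer], y_loc, el_spec, k=cfg.folds,
                                 sample_ids=loc_samples, class_names=classes)
    art["scores"] = {
        "detection": {"genome": det_g, "epigenome": det_e,
                      "combined": models.combine_scores(det_g, det_e)},
        "localization": {"genome": loc_g, "epigenome": loc_e,
                         "combined": models.combine_scores(loc_g, loc_e)},
    }
    art["feature_arrays"] = {"genome": xg, "epigenome": xe, "y_det": y_det}


def _stage_evaluate(cfg: PipelineConfig, art: dict) -> None:
    out = {}
    for task, d in art["scores"].items():
        out[task] = {}
        for name, sc in d.items():
            m = models.evaluate(sc, spec_levels=cfg.spec_levels, n_boot=cfg.n_boot, seed=cfg.seed)
            if task == "localization":
                m = {"accuracy": m["accuracy"]}
            else:
                m = {"auc": m["auc"],
                     "sensitivity": {str(k): v for k, v in m["sensitivity"].items()}}
            out[task][name] = m
    art["metrics"] = out


def _stage_attribute(cfg: PipelineConfig, art: dict) -> None:
    """Genome-model integrated gradients on confidently-scored samples."""
    xg = art["feature_arrays"]["genome"]
    y = art["feature_arrays"]["y_det"]
    desk_g, _ = cfg.model_budgets()
    spec = models.ModelSpec(family="genome-dnn", task="detection",
                            seed=cfg.seed + 7, **desk_g)
    rng = substream(cfg.seed, "attribution-split")
    idx = rng.permutation(len(y))
    cut = max(1, len(y) // 4)
    va, tr = idx[:cut], idx[cut:]
    net, _ = models.train_with_restarts(spec, xg[tr], y[tr], xg[va], y[va])
    sel = attr_mod.select_interpretation_samples(art["scores"]["detection"]["combined"])
    ig = {grp: attr_mod.integrated_gradients(net, xg[ix], steps=cfg.ig_steps)
          for grp, ix in sel.items() if len(ix)}
    n_lvd = len(art["retained_windows"])
    tops = {}
    if "cancer" in ig and "normal" in ig:
        tops = attr_mod.top_attribution_regions(
            ig["cancer"][:, :n_lvd], ig["normal"][:, :n_lvd], art["retained_windows"])
    art["attribution"] = {"selected": {k: v.tolist() for k, v in sel.items()},
                          "top_regions": tops}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "panel": _stage_panel,
    "filter": _stage_filter,
    "lmd-ref": _stage_lmd_ref,
    "featurize-genome": _stage_featurize_genome,
    "featurize-epigenome": _stage_featurize_epigenome,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "attribute": _stage_attribute,
}


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _persist(cfg: PipelineConfig, art: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.hash(), "seed": cfg.seed, "version": cfgem.__version__,
                "stages": art.get("completed", []),
                "config": dataclasses.asdict(cfg)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if "cohort" in art:
        art["cohort"].samples.to_csv(outdir / "samples.tsv", sep="\t", index=False,
                                     float_format="%.6g")
    if "filter_reports" in art:
        rows = []
        for s, rep in art["filter_reports"].items():
            t = rep.to_frame()
            t.insert(0, "sample", s)
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    if "lmd_ref" in art:
        ref = art["lmd_ref"]
        payload = {side: {t: d.to_dict(orient="list") for t, d in getattr(ref, side).items()}
                   for side in ("high", "low")}
        (outdir / "lmd_ref.json").write_text(json.dumps(payload, indent=1, default=float))
    if "genome_features" in art:
        art["genome_features"].to_csv(outdir / "genome_features.tsv", sep="\t", float_format="%.8g")
    if "scores" in art:
        for task, d in art["scores"].items():
            for name, sc in d.items():
                sc.table.to_csv(outdir / f"scores_{task}_{name}.tsv", sep="\t",
                                index=False, float_format="%.8g")
    if "metrics" in art:
        (outdir / "metrics.json").write_text(json.dumps(art["metrics"], indent=1, default=str))
    if "attribution" in art:
        (outdir / "attribution.json").write_text(
            json.dumps(art["attribution"], indent=1, default=str))
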