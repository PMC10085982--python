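"""Train and evaluate the full synthetic pipeline (small cohort).

Runs simulate -> panel -> filter -> featurize -> stratified 5-fold CV
for the genome net and epigenome CNN -> score averaging -> metrics.
Prints ROC-AUCs, bootstrap sensitivity at fixed specificity, and
localization accuracy.  Desk budgets keep this to a couple of minutes;
see PipelineConfig(profile="paper") for the reference protocol.
"""

from cfgem.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=0, n_cancer_per_type=7, n_normal=21, n_boot=200,
                        simulation=dict(fragments_per_sample=5000))
art = run_pipeline(config, stages=["simulate", "panel", "filter",
                                   "featurize-genome", "featurize-epigenome",
                                   "train", "evaluate"])

metrics = art["metrics"]
for model in ("genome", "epigenome", "combined"):
    det = metrics["detection"][model]
    sens95 = det["sensitivity"]["0.95"]
    print(f"{model:10s} detection AUC {det['auc']:.3f}  "
          f"sens@95%spec {sens95['estimate']:.2f} "
          f"(95% CI {sens95['ci95'][0]:.2f}-{sens95['ci95'][1]:.2f})")
    print(f"{model:10s} localization accuracy "
          f"{metrics['localization'][model]['accuracy']:.3f}")
# the combined model averages the two out-of-fold score vectors
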