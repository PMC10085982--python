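"""Genome-model features: local variant density + 150 variant contexts.

The LVD block is the per-window share of a sample's filtered variants
(windows retained when at most half the training cohort has zero
variants there); the context block holds 6 substitution, 48
dinucleotide and 96 trinucleotide frequencies under the
pyrimidine-reference convention.
"""

from cfgem.genome_features import (cohort_window_counts, genome_feature_vector,
                                   retained_windows)
from cfgem.simulate import (default_config, demo_layout, plant_ndr_catalog,
                            simulate_cfdna_sample)
from cfgem.variants import run_filter_cascade

layout = demo_layout()
config = default_config(layout, seed=7)
catalog = plant_ndr_catalog(layout, list(config.cancer_types))

filtered = {}
for i in range(6):
    _, raw = simulate_cfdna_sample(layout, catalog, config, "liver", f"s{i}")
    filtered[f"s{i}"], _ = run_filter_cascade(raw)

counts = cohort_window_counts(filtered, layout)
retained = retained_windows(counts, max_zero_fraction=0.5)
print(f"retained {len(retained)} of {layout.n_windows} windows")

vec = genome_feature_vector("s0", filtered["s0"], layout, retained)
print(f"feature vector length: {len(vec.concat())} (= {len(retained)} LVD + 150 contexts)")
print("liver high-LMD windows", config.high_windows["liver"],
      "carry LVD", vec.lvd.loc[list(config.high_windows['liver'])].round(3).tolist())
print("top contexts:", vec.variant_types.nlargest(3).round(3).to_dict())
# tumor variants concentrate LVD mass in the label's planted windows
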