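"""Simulate a seeded synthetic plasma cohort.

Builds a small multi-chromosome genome, plants cancer-type-specific
high/low mutation-density windows and tissue-specific NDRs, and draws
cancer and normal samples.  Prints the cohort sheet and the planted
fragment-length shift: cancer cfDNA mixes in shorter tumor-derived
fragments in proportion to tumor fraction.
"""

from cfgem.simulate import default_config, demo_layout, plant_ndr_catalog, simulate_cohort

layout = demo_layout()                       # 4 chromosomes, 40 x 1 Mb windows
config = default_config(layout, seed=7)
catalog = plant_ndr_catalog(layout, list(config.cancer_types))
cohort = simulate_cohort(layout, catalog, config, n_cancer_per_type=3, n_normal=5)

print(cohort.samples.to_string(index=False))
for sid in ["breast_000", "normal_000"]:
    fr = cohort.fragments[sid]
    n_var = len(cohort.variants[sid])
    mean_len = (fr["end"] - fr["start"]).mean()
    print(f"{sid}: {len(fr)} fragments, mean length {mean_len:.1f} bp, {n_var} raw variants")
# cancer mean length sits below the normal ~166 bp in proportion to tumor fraction
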