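"""The three comparison feature sets: cnv, fragpattern, fragsize.

cnv: z-scored coverage in 5-Mb windows.  fragpattern: GC-corrected
(LOWESS, span 0.75) short/long fragment coverage.  fragsize: 125
two-bp fragment-length bins over [0, 250), z-scored.
"""

import numpy as np

from cfgem.baselines import cnv_features, fragpattern_features, fragsize_features
from cfgem.layout import make_layout
from cfgem.simulate import default_config, demo_layout, plant_ndr_catalog, simulate_cfdna_sample

layout1mb = demo_layout()
config = default_config(layout1mb, seed=7)
catalog = plant_ndr_catalog(layout1mb, list(config.cancer_types))
fragments, _ = simulate_cfdna_sample(layout1mb, catalog, config, "lung", "b1",
                                     tumor_fraction=0.3)

layout5mb = make_layout(layout1mb.chrom_lengths, 5_000_000)
cnv = cnv_features(fragments, layout5mb)
print(f"cnv: {len(cnv)} windows, mean {cnv.mean():.1e}, sd {cnv.std():.3f}")

rng = np.random.default_rng(0)
gc = rng.uniform(0.35, 0.6, size=layout5mb.n_windows)
fp = fragpattern_features(fragments, layout5mb, gc)
print(f"fragpattern: {len(fp)} features (corrected total + short blocks)")

fs = fragsize_features(fragments)
print(f"fragsize: {len(fs)} bins; modal length {2 * fs.argmax()}-{2 * fs.argmax() + 1} bp")
# the cancer sample's mode sits below the ~166 bp of healthy cfDNA
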