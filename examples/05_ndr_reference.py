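"""Tissue-specific NDR selection from an accessibility count matrix.

Per-sample ATAC peak sets are merged into non-overlapping meta-peaks
(strongest peak wins among overlaps); short fragments (< 150 bp)
covering each midpoint are counted; and per tissue the 10,000 peaks
(here desk-scaled to 1,000) with the smallest one-vs-rest moderated-t
p-value on TMM-normalized log2-CPM become that tissue's NDR list.
"""

import numpy as np

from cfgem.ndr import filter_peak_samples, merge_meta_peaks, select_tissue_ndrs
from cfgem.simulate import demo_layout, simulate_ndr_count_matrix, simulate_peak_sets

layout = demo_layout()
peak_sets = simulate_peak_sets(layout, ["liver", "lung"], samples_per_tissue=3, seed=0)
kept = filter_peak_samples(peak_sets, min_peaks=100)   # desk-scaled threshold
meta = merge_meta_peaks(kept)
print(f"{sum(len(p) for p in kept)} peaks from {len(kept)} samples "
      f"-> {len(meta)} non-overlapping meta-peaks")

counts, labels, truth = simulate_ndr_count_matrix(
    n_peaks=6000, tissues=["a", "b", "c"], samples_per_tissue=8,
    seed=1, specific_per_tissue=1500)
lists, factors = select_tissue_ndrs(counts, labels, selection_size=1000)
for tissue in lists:
    precision = np.isin(lists[tissue]["peak_id"], truth[tissue]).mean()
    print(f"tissue {tissue}: {len(lists[tissue])} NDRs selected, "
          f"planted-truth precision {precision:.2f}")
# precision ~1.0: the selection recovers the planted tissue-specific peaks
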