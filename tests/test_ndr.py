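"""NDR reference: merging, counting, and tissue-specific selection."""

import numpy as np
import pandas as pd
import pytest

from cfgem.ndr import (count_ndr_fragments, filter_peak_samples,
                       merge_meta_peaks, select_tissue_ndrs)
from cfgem.simulate import simulate_ndr_count_matrix


def peaks(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


class TestSampleFilter:
    def test_strict_less_than_boundary(self):
        small = pd.DataFrame({"chrom": "chr1", "start": range(29_999),
                              "end": range(1, 30_000), "score": 1.0})
        big = pd.DataFrame({"chrom": "chr1", "start": range(30_000),
                            "end": range(1, 30_001), "score": 1.0})
        kept = filter_peak_samples([small, big], min_peaks=30_000)
        assert len(kept) == 1 and len(kept[0]) == 30_000

    def test_zero_threshold_is_identity(self):
        sets = [peaks(("chr1", 0, 10, 1.0))]
        assert filter_peak_samples(sets, min_peaks=0) == sets

    def test_all_excluded_warns(self):
        with pytest.warns(UserWarning):
            out = filter_peak_samples([peaks(("chr1", 0, 10, 1.0))], min_peaks=5)
        assert out == []


class TestMerge:
    def test_strongest_of_overlapping_pair_kept(self):
        out = merge_meta_peaks([peaks(("chr1", 0, 100, 5.0)), peaks(("chr1", 50, 150, 9.0))])
        assert out[["start", "end"]].to_numpy().tolist() == [[50, 150]]

    def test_chain_resolved_iteratively(self):
        # A-B-C where only B overlaps both and B is strongest:
        # B wins, A and C survive because they are disjoint from B
        out = merge_meta_peaks([peaks(
            ("chr1", 0, 100, 5.0), ("chr1", 90, 210, 9.0), ("chr1", 200, 300, 4.0))])
        assert len(out) == 1 and out.iloc[0]["start"] == 90
        out2 = merge_meta_peaks([peaks(
            ("chr1", 0, 80, 5.0), ("chr1", 90, 190, 9.0), ("chr1", 200, 300, 4.0))])
        assert len(out2) == 3

    def test_disjoint_all_kept_and_sorted(self):
        out = merge_meta_peaks([peaks(("chr1", 200, 300, 1.0), ("chr1", 0, 100, 2.0))])
        assert out["start"].tolist() == [0, 200]

    def test_score_tie_keeps_leftmost(self):
        out = merge_meta_peaks([peaks(("chr1", 50, 150, 5.0), ("chr1", 0, 100, 5.0))])
        assert out["start"].tolist() == [0]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        sets = []
        for _ in range(4):
            start = rng.integers(0, 5000, size=30)
            sets.append(pd.DataFrame({"chrom": "chr1", "start": start,
                                      "end": start + rng.integers(50, 300, size=30),
                                      "score": rng.gamma(3, 2, size=30)}))
        a = merge_meta_peaks(sets)
        b = merge_meta_peaks(sets[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestCounting:
    def _meta(self, *mids):
        return pd.DataFrame({"chrom": "chr1", "start": [m - 50 for m in mids],
                             "end": [m + 50 for m in mids], "midpoint": list(mids)})

    def test_midpoint_containment(self):
        frags = {"s": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                    "start": [95, 101], "end": [145, 140]})}
        counts = count_ndr_fragments(frags, self._meta(100))
        assert counts["s"].tolist() == [1]  # [101,140) misses midpoint 100

    def test_length_150_is_excluded(self):
        frags = {"s": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                    "start": [50, 50], "end": [200, 199]})}
        counts = count_ndr_fragments(frags, self._meta(100), max_fragment_len=150)
        assert counts["s"].tolist() == [1]

    def test_no_fragments_zero_matrix(self):
        frags = {"s": pd.DataFrame(columns=["chrom", "start", "end"])}
        assert count_ndr_fragments(frags, self._meta(100, 500))["s"].tolist() == [0, 0]

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(9)
        frags = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=600),
            "start": rng.integers(0, 50_000, size=600)})
        frags["end"] = frags["start"] + rng.integers(60, 220, size=600)
        mids = rng.integers(0, 50_000, size=40)
        meta = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], size=40),
                             "start": mids - 100, "end": mids + 100, "midpoint": mids})
        counts = count_ndr_fragments({"s": frags}, meta)["s"].to_numpy()
        brute = np.zeros(40, dtype=int)
        for i, (pc, pm) in enumerate(zip(meta["chrom"], meta["midpoint"])):
            for fc, fs, fe in frags.itertuples(index=False):
                if fc == pc and fe - fs < 150 and fs <= pm < fe:
                    brute[i] += 1
        assert (counts == brute).all()


class TestTissueSelection:
    def test_selection_size_honored_with_high_precision(self):
        counts, labels, truth = simulate_ndr_count_matrix(
            6000, ["a", "b", "c"], 8, seed=2, specific_per_tissue=1500)
        lists, factors = select_tissue_ndrs(counts, labels, selection_size=1000)
        for t in ("a", "b", "c"):
            assert len(lists[t]) == 1000
            precision = np.isin(lists[t]["peak_id"], truth[t]).mean()
            assert precision >= 0.9

    def test_label_permutation_collapses_precision(self):
        counts, labels, truth = simulate_ndr_count_matrix(
            6000, ["a", "b", "c"], 8, seed=3, specific_per_tissue=1500)
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        lists, _ = select_tissue_ndrs(counts, perm, selection_size=1000)
        precision = np.isin(lists["a"]["peak_id"], truth["a"]).mean()
        assert precision < 0.5  # near the 25% planted-fraction baseline

    def test_selection_size_beyond_peaks_returns_all(self):
        counts, labels, _ = simulate_ndr_count_matrix(100, ["a", "b"], 4, seed=4,
                                                      specific_per_tissue=20)
        lists, _ = select_tissue_ndrs(counts, labels, selection_size=10_000)
        assert len(lists["a"]) == 100

    def test_single_sample_tissue_excluded_with_warning(self):
        counts, labels, _ = simulate_ndr_count_matrix(200, ["a", "b"], 3, seed=5,
                                                      specific_per_tissue=30)
        labels = labels.copy()
        labels.iloc[0] = "solo"
        with pytest.warns(UserWarning):
            lists, _ = select_tissue_ndrs(counts, labels, selection_size=50)
        assert "solo" not in lists

    def test_deterministic_given_matrix(self):
        counts, labels, _ = simulate_ndr_count_matrix(500, ["a", "b"], 4, seed=6,
                                                      specific_per_tissue=100)
        l1, _ = select_tissue_ndrs(counts, labels, selection_size=80)
        l2, _ = select_tissue_ndrs(counts, labels, selection_size=80)
        for t in l1:
            pd.testing.assert_frame_equal(l1[t], l2[t])
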