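"""LMD reference: counting, TMM oracles, and differential selection."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cfgem.errors import InvalidInputError
from cfgem.layout import make_layout
from cfgem.lmd import LMDMatrix, compute_lmd_matrix, select_lmd_regions, tmm_factors
from cfgem.simulate import SimulationConfig, demo_layout, simulate_tumor_maf


def _maf(rows):
    return pd.DataFrame(rows, columns=["sample", "cancer_type", "chrom", "pos", "ref", "alt"])


class TestLmdMatrix:
    def test_counts_land_in_their_window(self):
        lay = make_layout({"chr1": 3_000_000}, 1_000_000)
        maf = _maf([("s1", "A", "chr1", p, "C", "T") for p in (10, 20, 30)])
        m = compute_lmd_matrix(maf, lay)
        assert m.counts["s1"].tolist() == [3, 0, 0]

    def test_window_start_position_is_inclusive(self):
        lay = make_layout({"chr1": 3_000_000}, 1_000_000)
        # 1-based pos 1_000_001 -> 0-based 1_000_000 -> second window
        maf = _maf([("s1", "A", "chr1", 1_000_001, "C", "T"),
                    ("s1", "A", "chr1", 1_000_000, "C", "T")])
        m = compute_lmd_matrix(maf, lay)
        assert m.counts["s1"].tolist() == [1, 1, 0]

    def test_empty_maf_zero_matrix(self):
        lay = make_layout({"chr1": 2_000_000}, 1_000_000)
        m = compute_lmd_matrix(_maf([]), lay)
        assert m.counts.to_numpy().sum() == 0


def brute_force_tmm(counts, ref, j, trim_m=0.30, trim_a=0.05):
    """Independent TMM oracle coded straight from the definition."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    obs, refc = counts[:, j], counts[:, ref]
    keep = (obs > 0) & (refc > 0)
    obs, refc = obs[keep], refc[keep]
    m = np.log2((obs / lib[j]) / (refc / lib[ref]))
    a = 0.5 * np.log2((obs / lib[j]) * (refc / lib[ref]))
    w = 1.0 / ((lib[j] - obs) / (lib[j] * obs) + (lib[ref] - refc) / (lib[ref] * refc))
    n = len(m)
    keep_idx = []
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    for i in range(n):
        if (np.floor(n * trim_m) + 1 <= rm[i] <= n - np.floor(n * trim_m)
                and np.floor(n * trim_a) + 1 <= ra[i] <= n - np.floor(n * trim_a)):
            keep_idx.append(i)
    keep_idx = np.array(keep_idx)
    return 2 ** (np.sum(m[keep_idx] * w[keep_idx]) / np.sum(w[keep_idx]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = np.tile(np.array([[5], [9], [2], [7]]), (1, 2))
        assert np.allclose(tmm_factors(m), [1.0, 1.0])

    def test_pure_depth_scaling_gives_unit_factors(self):
        col = np.array([5, 9, 2, 7])
        m = np.column_stack([col, 2 * col])
        assert np.allclose(tmm_factors(m), [1.0, 1.0])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(4)
        m = rng.poisson(40, size=(40, 2)) + 1
        m[:8, 0] *= 5  # composition shift
        factors = tmm_factors(m)
        lib = m.sum(axis=0) / np.quantile(m, 0.75, axis=0)  # determine ref as in impl
        f75 = np.array([np.quantile(m[:, j], 0.75) / m[:, j].sum() for j in range(2)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        other = 1 - ref
        raw = brute_force_tmm(m, ref, other)
        expected = np.ones(2)
        expected[other] = raw
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(factors, expected, rtol=1e-12)

    def test_matches_edger(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.poisson(50, size=(200, 4)) * np.array([1, 2, 1, 5])
        m[:30, 0] *= 8
        np.savetxt(tmp_path / "m.tsv", m, fmt="%d", delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            m <- as.matrix(read.table('{tmp_path / "m.tsv"}'))
            cat(format(calcNormFactors(DGEList(counts=m))$samples$norm.factors, digits=12))
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        expected = np.array([float(x) for x in res.stdout.split()])
        assert np.allclose(tmm_factors(pd.DataFrame(m)), expected, rtol=1e-6)

    def test_zero_library_rejected(self):
        with pytest.raises(InvalidInputError):
            tmm_factors(np.array([[0, 5], [0, 5]]))


def test_bh_adjustment_matches_sort_threshold_oracle():
    rng = np.random.default_rng(8)
    p = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(0, 1e-4, 10)])
    adj = multipletests(p, method="fdr_bh")[1]
    # oracle: adjusted p_i = min over j with p_j >= p_i of p_j * n / rank_j
    n = len(p)
    order = np.argsort(p)
    stepup = p[order] * n / (np.arange(n) + 1)
    cummin = np.minimum.accumulate(stepup[::-1])[::-1]
    oracle = np.empty(n)
    oracle[order] = np.minimum(cummin, 1.0)
    assert np.allclose(adj, oracle)


class TestSelection:
    def test_planted_enrichment_recovered(self):
        lay = demo_layout(n_windows=200, n_chroms=4)
        cfg = SimulationConfig(seed=1, cancer_types=("A", "B", "C"),
                               high_windows={"A": tuple(range(40))}, low_windows={})
        maf = simulate_tumor_maf(lay, cfg, 20)
        ref = select_lmd_regions(compute_lmd_matrix(maf, lay))
        high = ref.high["A"]
        assert len(high) == 25
        assert high["window_id"].isin(range(40)).all()
        assert (high["fdr"] <= 0.05).all()

    def test_no_effect_controls_type_one_error(self):
        lay = demo_layout(n_windows=200, n_chroms=4)
        cfg = SimulationConfig(seed=2, cancer_types=("A", "B"),
                               high_windows={}, low_windows={})
        maf = simulate_tumor_maf(lay, cfg, 15)
        ref = select_lmd_regions(compute_lmd_matrix(maf, lay))
        n_called = sum(len(v) for v in ref.high.values()) + sum(len(v) for v in ref.low.values())
        assert n_called <= 2  # ~FDR-level false positives in 200 windows

    def test_returns_fewer_than_top_k_when_fewer_pass(self):
        lay = demo_layout(n_windows=60, n_chroms=4, window_size=1_000_000)
        cfg = SimulationConfig(seed=3, cancer_types=("A", "B"),
                               high_windows={"A": (5,)}, low_windows={},
                               maf_fold=12.0)
        maf = simulate_tumor_maf(lay, cfg, 20)
        ref = select_lmd_regions(compute_lmd_matrix(maf, lay))
        assert ref.high["A"]["window_id"].tolist() == [5]

    def test_invariant_to_sample_order_and_count_scaling(self):
        lay = demo_layout(n_windows=80, n_chroms=4)
        cfg = SimulationConfig(seed=4, cancer_types=("A", "B"),
                               high_windows={"A": (0, 1, 2, 3)}, low_windows={})
        maf = simulate_tumor_maf(lay, cfg, 10)
        m = compute_lmd_matrix(maf, lay)
        ref1 = select_lmd_regions(m)
        perm = m.counts.sample(frac=1.0, axis=1, random_state=5)
        ref2 = select_lmd_regions(LMDMatrix(counts=perm, sample_types=m.sample_types))
        scaled = m.counts.copy()
        scaled.iloc[:, 0] *= 3  # depth scaling of one sample
        ref3 = select_lmd_regions(LMDMatrix(counts=scaled, sample_types=m.sample_types))
        ids1 = ref1.high["A"]["window_id"].tolist()
        assert ref2.high["A"]["window_id"].tolist() == ids1
        assert set(ref3.high["A"]["window_id"]) == set(ids1)

    def test_preconditions(self):
        lay = demo_layout(n_windows=40)
        counts = pd.DataFrame(np.ones((40, 3), dtype=int), columns=["a", "b", "c"])
        with pytest.raises(InvalidInputError):
            select_lmd_regions(LMDMatrix(counts=counts,
                                         sample_types=pd.Series({"a": "A", "b": "A", "c": "A"})))
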