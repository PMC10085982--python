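"""Filter-cascade unit behavior, invariants, and planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfgem.errors import InvalidInputError
from cfgem.simulate import (default_config, demo_layout, germline_catalog,
                            plant_ndr_catalog, simulate_cfdna_sample,
                            simulate_panel)
from cfgem.variants import (annotate_variants, apply_artifact_filters,
                            apply_panel_and_germline_filter, run_filter_cascade)
from tests.conftest import make_variant, variant_frame


class TestAnnotate:
    def _reads(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "alt_pos", "alt_base"])

    def test_strand_counting(self):
        reads = self._reads(
            [("chr1", 950, 1050, "+", 1000, "A")] * 3
            + [("chr1", 980, 1080, "-", 1000, "A")] * 2
            + [("chr1", 990, 1090, "+", np.nan, "")] * 4)
        rec = pd.DataFrame([{"chrom": "chr1", "pos": 1000, "ref": "C", "alt": "A"}])
        out = annotate_variants(rec, reads)
        assert out.iloc[0]["alt_fwd"] == 3 and out.iloc[0]["alt_rev"] == 2
        assert out.iloc[0]["alt_depth"] == 5 and out.iloc[0]["depth"] == 9

    def test_offset_pair_from_five_prime(self):
        # alt base at offset 4 from the 5' start of a 100 bp forward read
        reads = self._reads([("chr1", 995, 1095, "+", 1000, "T")])
        rec = pd.DataFrame([{"chrom": "chr1", "pos": 1000, "ref": "C", "alt": "T"}])
        out = annotate_variants(rec, reads)
        assert out.iloc[0]["offsets"] == [(4, 95)]  # (4, readlen - 5)

    def test_no_support_gives_empty_offsets(self):
        reads = self._reads([("chr1", 900, 1000, "+", np.nan, "")])
        rec = pd.DataFrame([{"chrom": "chr1", "pos": 5000, "ref": "C", "alt": "T"}])
        out = annotate_variants(rec, reads)
        assert out.iloc[0]["alt_depth"] == 0 and out.iloc[0]["offsets"] == []

    def test_position_outside_chromosome_rejected(self):
        reads = self._reads([])
        rec = pd.DataFrame([{"chrom": "chr1", "pos": 10_000, "ref": "C", "alt": "T"}])
        with pytest.raises(InvalidInputError):
            annotate_variants(rec, reads, chrom_lengths={"chr1": 5000})


class TestSiteFilters:
    def test_panel_site_removed(self):
        v = variant_frame(make_variant(pos=100))
        panel = pd.DataFrame([{"chrom": "chr1", "pos": 100, "ref": "C", "alt": "A"}])
        assert len(apply_panel_and_germline_filter(v, panel=panel)) == 0

    def test_blacklist_boundary_is_half_open(self):
        # interval [100, 200) in 0-based coords; VCF pos 100 -> 0-based 99
        bl = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])
        kept = variant_frame(make_variant(pos=100))     # 0-based 99, 1 bp left
        dropped = variant_frame(make_variant(pos=101))  # 0-based 100, first inside
        assert len(apply_panel_and_germline_filter(kept, blacklist=bl)) == 1
        assert len(apply_panel_and_germline_filter(dropped, blacklist=bl)) == 0

    def test_empty_resources_identity_on_snvs(self):
        v = variant_frame(make_variant(pos=1), make_variant(pos=2, ref="CT", alt="A"))
        out = apply_panel_and_germline_filter(v, panel=None, germline_sets=[])
        assert len(out) == 1  # the non-SNV record is extracted away

    def test_malformed_interval_rejected(self):
        bl = pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 200}])
        with pytest.raises(InvalidInputError):
            apply_panel_and_germline_filter(variant_frame(make_variant()), blacklist=bl)


class TestArtifactRules:
    def test_vaf_one_removed(self):
        v = variant_frame(make_variant(depth=8, alt_depth=8))
        out, removed = apply_artifact_filters(v)
        assert len(out) == 0 and len(removed["vaf"]) == 1

    @pytest.mark.parametrize("fwd,rev,survives", [(4, 0, False), (0, 4, False), (4, 1, True)])
    def test_strand_discordance_truth_table(self, fwd, rev, survives):
        v = variant_frame(make_variant(alt_depth=fwd + rev, alt_fwd=fwd, alt_rev=rev))
        out, _ = apply_artifact_filters(v)
        assert (len(out) == 1) is survives

    def test_adjacent_positions_removed_as_mnv(self):
        v = variant_frame(make_variant(pos=100), make_variant(pos=101, ref="T", alt="G"),
                          make_variant(pos=500))
        out, removed = apply_artifact_filters(v)
        assert len(removed["mnv"]) == 2
        assert out["pos"].tolist() == [500]

    def test_read_end_rule_requires_all_supporting_reads_at_ends(self):
        at_ends = make_variant(pos=10, offsets=[(3, 96), (98, 1)], alt_depth=2)
        rescued = make_variant(pos=900, offsets=[(3, 96), (50, 49)], alt_depth=2)
        out, removed = apply_artifact_filters(variant_frame(at_ends, rescued))
        assert removed["read_end"]["pos"].tolist() == [10]
        assert out["pos"].tolist() == [900]

    def test_negative_read_end_rejected(self):
        with pytest.raises(InvalidInputError):
            apply_artifact_filters(variant_frame(make_variant()), read_end_bp=-1)


@pytest.fixture(scope="module")
def planted():
    layout = demo_layout()
    cfg = default_config(layout, seed=23)
    catalog = plant_ndr_catalog(layout, list(cfg.cancer_types))
    normals = [simulate_cfdna_sample(layout, catalog, cfg, "normal", f"n{i}")[1]
               for i in range(4)]
    panel = simulate_panel(normals, 2)
    germ = germline_catalog(layout, cfg)[["chrom", "pos", "ref", "alt"]]
    return layout, catalog, cfg, panel, germ


class TestCascade:
    def test_planted_contaminants_fully_removed_and_tumor_recalled(self, planted):
        layout, catalog, cfg, panel, germ = planted
        total = {"tumor_in": 0, "tumor_out": 0, "leak": 0}
        for i in range(6):
            _, va = simulate_cfdna_sample(layout, catalog, cfg, "breast", f"c{i}")
            out, rep = run_filter_cascade(va, panel=panel, germline_sets=[germ])
            rep.check()
            surv = out["truth_class"].value_counts()
            for bad in ("germline", "vaf1", "single_strand", "mnv", "read_end"):
                assert surv.get(bad, 0) == 0, f"{bad} leaked"
            total["tumor_in"] += (va["truth_class"] == "tumor").sum()
            total["tumor_out"] += surv.get("tumor", 0)
            total["leak"] += len(out) - surv.get("tumor", 0) - surv.get("background", 0)
        assert total["tumor_out"] / total["tumor_in"] >= 0.95
        assert total["leak"] == 0

    def test_order_invariance(self, planted):
        layout, catalog, cfg, panel, germ = planted
        _, va = simulate_cfdna_sample(layout, catalog, cfg, "liver", "perm")
        shuffled = va.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a, _ = run_filter_cascade(va, panel=panel, germline_sets=[germ])
        b, _ = run_filter_cascade(shuffled, panel=panel, germline_sets=[germ])
        pd.testing.assert_frame_equal(a, b)

    def test_idempotence(self, planted):
        layout, catalog, cfg, panel, germ = planted
        _, va = simulate_cfdna_sample(layout, catalog, cfg, "lung", "idem")
        once, _ = run_filter_cascade(va, panel=panel, germline_sets=[germ])
        twice, _ = run_filter_cascade(once, panel=panel, germline_sets=[germ])
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        empty = variant_frame(make_variant()).iloc[:0]
        out, rep = run_filter_cascade(empty)
        assert len(out) == 0 and rep.input_count == 0

    def test_all_contaminant_sample_reconciles(self):
        v = variant_frame(
            make_variant(pos=10, depth=8, alt_depth=8),
            make_variant(pos=50, alt_depth=4, alt_fwd=4, alt_rev=0),
            make_variant(pos=100), make_variant(pos=101, ref="T", alt="G"),
        )
        out, rep = run_filter_cascade(v)
        assert len(out) == 0
        frame = rep.to_frame()
        assert frame["removed"].sum() == rep.input_count


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(
    st.tuples(st.integers(1, 2000), st.integers(1, 20), st.integers(0, 20),
              st.integers(0, 99)),
    min_size=0, max_size=25))
def test_cascade_counts_always_reconcile(records):
    """Property: per-stage counts are monotone and sum to the input."""
    rows = []
    for pos, depth, alt, off in records:
        alt = min(alt, depth)
        rows.append(make_variant(pos=pos, depth=depth, alt_depth=alt,
                                 alt_fwd=alt // 2, alt_rev=alt - alt // 2,
                                 offsets=[(off, 99 - off)] * alt))
    v = pd.DataFrame(rows, columns=list(make_variant().keys()))
    out, rep = run_filter_cascade(v)
    rep.check()
    assert rep.to_frame()["removed"].sum() + len(out) == rep.input_count
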