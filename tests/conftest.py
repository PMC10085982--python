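import pandas as pd
import pytest

from cfgem.simulate import default_config, demo_layout, plant_ndr_catalog


@pytest.fixture(scope="session")
def layout():
    return demo_layout()


@pytest.fixture(scope="session")
def sim_config(layout):
    return default_config(layout, seed=11)


@pytest.fixture(scope="session")
def ndr_catalog(layout, sim_config):
    return plant_ndr_catalog(layout, list(sim_config.cancer_types))


def make_variant(chrom="chr1", pos=1000, ref="C", alt="A", depth=40, alt_depth=8,
                 alt_fwd=None, alt_rev=None, offsets=None, flank5="A", flank3="T",
                 truth_class=""):
    """One fully-annotated SNV record with sensible defaults."""
    if alt_fwd is None:
        alt_fwd = alt_depth // 2
    if alt_rev is None:
        alt_rev = alt_depth - alt_fwd
    if offsets is None:
        offsets = [(40, 59)] * alt_depth
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "depth": depth,
        "alt_depth": alt_depth, "alt_fwd": alt_fwd, "alt_rev": alt_rev,
        "offsets": offsets, "flank5": flank5, "flank3": flank3,
        "truth_class": truth_class,
    }


def variant_frame(*records):
    return pd.DataFrame(list(records))
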