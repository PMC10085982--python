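"""Genome-model features: local variant density and mutation contexts.

A filtered cfDNA variant set becomes (a) a local variant density (LVD)
block — per retained 1-Mb window, the fraction of the sample's variants
falling in it — and (b) 150 variant-type frequencies: 6 single-base
substitutions (pyrimidine-reference), 48 dinucleotide contexts (each
substitution with either the 5' or the 3' flanking base) and 96
trinucleotide contexts (both flanks).

Denominator convention: frequencies divide by the sample's *total*
variant count, including variants in windows later dropped; the LVD
block therefore sums to at most 1.  Each variant increments one
substitution, one 5'-dinucleotide, one 3'-dinucleotide and one
trinucleotide, so the dinucleotide block sums to 2 per fully-annotated
sample (two flanks per variant).

Window retention is fitted on a training cohort (a window is kept
unless more than ``max_zero_fraction`` of samples have zero variants in
it) and frozen for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfgem.errors import InvalidInputError
from cfgem.layout import GenomeLayout
from cfgem.simulate import SUBSTITUTIONS

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = ("A", "C", "G", "T")


def variant_type_names() -> list[str]:
    """The fixed, ordered 150 variant-type feature names.

    Order: 6 substitutions, 24 five-prime dinucleotides ("A[C>A]"),
    24 three-prime dinucleotides ("[C>A]A"), 96 trinucleotides
    ("A[C>A]A"); each block enumerated substitution-major.
    """
    names = list(SUBSTITUTIONS)
    names += [f"{b}[{s}]" for s in SUBSTITUTIONS for b in _BASES]
    names += [f"[{s}]{b}" for s in SUBSTITUTIONS for b in _BASES]
    names += [f"{b5}[{s}]{b3}" for s in SUBSTITUTIONS for b5 in _BASES for b3 in _BASES]
    assert len(names) == 150
    return names


_TYPE_NAMES = variant_type_names()
_TYPE_INDEX = {n: i for i, n in enumerate(_TYPE_NAMES)}


def _collapse(ref: str, alt: str, f5: str, f3: str) -> tuple[str, str, str, str]:
    """Map a substitution to the pyrimidine-reference strand."""
    if ref in ("A", "G"):
        ref, alt = _COMP[ref], _COMP[alt]
        f5, f3 = _COMP.get(f3, "N"), _COMP.get(f5, "N")
    return ref, alt, f5, f3


@dataclass
class GenomeFeatureVector:
    """LVD block plus 150 variant-type frequencies for one sample."""

    sample: str
    lvd: pd.Series          # indexed by retained window id
    variant_types: pd.Series  # indexed by the 150 type names
    n_variants: int
    empty: bool             # True when the sample had zero variants

    def concat(self) -> pd.Series:
        lvd = self.lvd.copy()
        lvd.index = [f"lvd_{w}" for w in lvd.index]
        return pd.concat([lvd, self.variant_types])


def cohort_window_counts(variant_tables: dict[str, pd.DataFrame], layout: GenomeLayout) -> pd.DataFrame:
    """Per-(window, sample) filtered-variant counts for a cohort."""
    out = pd.DataFrame(0, index=np.arange(layout.n_windows), columns=list(variant_tables), dtype=np.int64)
    for s, tab in variant_tables.items():
        if len(tab) == 0:
            continue
        wid = layout.window_of(tab["chrom"].to_numpy(object), tab["pos"].to_numpy() - 1)
        vc = pd.Series(wid[wid >= 0]).value_counts()
        out.loc[vc.index, s] = vc.to_numpy()
    return out


def retained_windows(cohort_counts: pd.DataFrame, max_zero_fraction: float = 0.5) -> list[int]:
    """Windows with zero count in at most ``max_zero_fraction`` of samples.

    "More than 50% zero" drops a window, so equality retains it.  Fitted
    on the training cohort only and persisted for prediction.
    """
    if cohort_counts.shape[1] == 0:
        raise InvalidInputError("empty cohort")
    zero_frac = (cohort_counts == 0).mean(axis=1)
    return [int(w) for w in cohort_counts.index[zero_frac <= max_zero_fraction]]


def compute_lvd(variants: pd.DataFrame, layout: GenomeLayout, retained: list[int]) -> tuple[pd.Series, bool]:
    """LVD block: per retained window, count / total sample variants.

    Returns ``(values, empty)`` where ``empty`` flags a zero-variant
    sample (all-zero vector).
    """
    values = pd.Series(0.0, index=list(retained))
    if len(variants) == 0:
        return values, True
    wid = layout.window_of(variants["chrom"].to_numpy(object), variants["pos"].to_numpy() - 1)
    total = len(variants)
    vc = pd.Series(wid[wid >= 0]).value_counts()
    common = vc.index.intersection(values.index)
    values.loc[common] = vc.loc[common].to_numpy() / total
    return values, False


def variant_type_frequencies(variants: pd.DataFrame) -> pd.Series:
    """The 150 variant-type frequencies for one sample.

    Variants with an undefined flank (chromosome edge, recorded as "N")
    count toward the substitution block only.
    """
    counts = np.zeros(150)
    n = len(variants)
    if n:
        for ref, alt, f5, f3 in zip(variants["ref"], variants["alt"], variants["flank5"], variants["flank3"]):
            ref, alt, f5, f3 = _collapse(ref, alt, f5, f3)
            sub = f"{ref}>{alt}"
            counts[_TYPE_INDEX[sub]] += 1
            if f5 in _BASES:
                counts[_TYPE_INDEX[f"{f5}[{sub}]"]] += 1
            if f3 in _BASES:
                counts[_TYPE_INDEX[f"[{sub}]{f3}"]] += 1
            if f5 in _BASES and f3 in _BASES:
                counts[_TYPE_INDEX[f"{f5}[{sub}]{f3}"]] += 1
        counts /= n
    return pd.Series(counts, index=_TYPE_NAMES)


def genome_feature_vector(
    sample: str,
    variants: pd.DataFrame,
    layout: GenomeLayout,
    retained: list[int],
) -> GenomeFeatureVector:
    lvd, empty = compute_lvd(variants, layout, retained)
    vt = variant_type_frequencies(variants)
    return GenomeFeatureVector(sample=sample, lvd=lvd, variant_types=vt,
                               n_variants=len(variants), empty=empty)


def cohort_feature_matrix(
    variant_tables: dict[str, pd.DataFrame],
    layout: GenomeLayout,
    retained: list[int],
) -> pd.DataFrame:
    """Samples x features matrix (LVD block then variant-type block)."""
    rows = {s: genome_feature_vector(s, tab, layout, retained).concat()
            for s, tab in variant_tables.items()}
    return pd.DataFrame(rows).T
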