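"""Integrated-gradients interpretation of the trained models.

Integrated gradients attribute a model's output to its inputs by
integrating the gradient along the straight path from a baseline (a
zero array here) to the input:

    IG_i(x) = (x_i - b_i) * mean_k  dF/dx_i (b + a_k (x - b))

with a midpoint grid a_k = (k + 1/2)/steps, k = 0..steps-1 (50 steps
by default).  The midpoint rule keeps the completeness residual,
|sum(IG) - (F(x) - F(b))|, well under 1% at 50 steps (checked in tests
against a 5000-step reference); a plain left-Riemann average of the
same gradients carries an O(1/steps) bias that would not.

Downstream aggregations mirror the published analyses: selection of
confidently-scored samples, the top-100 positive/negative LVD regions
for the genome model, and V-plot attribution profiles (image, fragment
size, matched/unmatched NDR distance) for the epigenome model.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from cfgem.errors import InvalidInputError
from cfgem.models import CohortScores


def integrated_gradients(model, x: np.ndarray, baseline: np.ndarray | None = None, steps: int = 50,
                         class_idx: int | None = None) -> np.ndarray:
    """Integrated gradients for a batch of inputs.

    ``model`` must expose ``input_gradient(x, class_idx)`` returning
    d(score)/d(input) per sample (as the package's networks do).
    Returns attributions congruent with ``x``.
    """
    if steps < 1:
        raise InvalidInputError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    b = np.zeros_like(x) if baseline is None else np.broadcast_to(baseline, x.shape).astype(np.float64)
    total = np.zeros_like(x)
    diff = x - b
    for k in range(steps):
        alpha = (k + 0.5) / steps  # midpoint grid
        total += model.input_gradient(b + alpha * diff, class_idx=class_idx) if class_idx is not None \
            else model.input_gradient(b + alpha * diff)
    return diff * total / steps


def select_interpretation_samples(scores: CohortScores, task: str | None = None) -> dict[str, np.ndarray]:
    """Confidently-scored sample indices for attribution analysis.

    Detection: cancer samples with out-of-fold score strictly > 0.8 and
    controls with score strictly < 0.2.  Localization: samples whose
    argmax class is correct with that class's score strictly > 0.6.
    """
    task = task or scores.task
    y = scores.table["label"].to_numpy().astype(int)
    if task == "detection":
        s = scores.table["score"].to_numpy()
        return {
            "cancer": np.flatnonzero((y == 1) & (s > 0.8)),
            "normal": np.flatnonzero((y == 0) & (s < 0.2)),
        }
    s = scores.scores
    pred = s.argmax(axis=1)
    conf = s[np.arange(len(y)), pred]
    return {"correct": np.flatnonzero((pred == y) & (conf > 0.6))}


def top_attribution_regions(
    cancer_attr: np.ndarray,
    normal_attr: np.ndarray,
    lvd_feature_ids: list,
    k: int = 100,
) -> dict[str, list]:
    """Top-k consistently signed LVD regions.

    ``cancer_attr``/``normal_attr`` are (samples x features) attribution
    matrices restricted to the LVD block.  The positive set is the k
    regions with the largest cancer-mean attribution among regions
    positive in cancers and negative in normals; the negative set is
    symmetric.  Fewer are returned when fewer qualify.
    """
    mc = np.asarray(cancer_attr).mean(axis=0)
    mn = np.asarray(normal_attr).mean(axis=0)
    ids = np.asarray(lvd_feature_ids, dtype=object)
    pos_mask = (mc > 0) & (mn < 0)
    neg_mask = (mc < 0) & (mn > 0)
    pos_order = np.argsort(-mc[pos_mask])
    neg_order = np.argsort(mc[neg_mask])
    return {
        "positive": list(ids[pos_mask][pos_order][:k]),
        "negative": list(ids[neg_mask][neg_order][:k]),
    }


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def aggregate_vplot_attributions(
    attributions: np.ndarray,
    mode: str,
    matched_channel: np.ndarray | None = None,
    smooth: bool = False,
) -> np.ndarray | dict[str, np.ndarray]:
    """Aggregate (samples, 100, 250, T) V-plot attributions.

    * ``"image"``: mean |attribution| over samples and channels ->
      100 x 250 map.
    * ``"size"``: additionally averaged over positions, min-max
      normalized -> 100-vector.
    * ``"distance"``: channels split per sample into the class-matched
      channel and the rest, averaged over samples and sizes -> dict with
      two 250-vectors (requires ``matched_channel``, one channel index
      per sample).  Optional LOWESS smoothing for display.
    """
    a = np.asarray(attributions, dtype=np.float64)
    if a.ndim != 4:
        raise InvalidInputError("expected (samples, size, position, tissue) attributions")
    if mode == "image":
        return np.abs(a).mean(axis=(0, 3))
    if mode == "size":
        return _minmax(np.abs(a).mean(axis=(0, 2, 3)))
    if mode == "distance":
        if matched_channel is None:
            raise InvalidInputError("matched_channel required for distance mode")
        matched_channel = np.asarray(matched_channel, dtype=int)
        n, _, _, t = a.shape
        matched = np.stack([a[i][:, :, matched_channel[i]] for i in range(n)])
        prof_m = matched.mean(axis=(0, 1))
        if t > 1:
            others = np.stack([a[i][:, :, [c for c in range(t) if c != matched_channel[i]]] for i in range(n)])
            prof_u = others.mean(axis=(0, 1, 3))
        else:
            prof_u = np.zeros_like(prof_m)
        if smooth:
            xs = np.arange(len(prof_m), dtype=float)
            prof_m = lowess(prof_m, xs, frac=0.1, return_sorted=False)
            prof_u = lowess(prof_u, xs, frac=0.1, return_sorted=False)
        return {"matched": prof_m, "unmatched": prof_u}
    raise InvalidInputError(f"unknown mode {mode!r}")


def attribution_zscore_matrix(attributions: np.ndarray) -> np.ndarray:
    """Per-feature z-scored attribution matrix (clustering input)."""
    a = np.asarray(attributions, dtype=np.float64)
    flat = a.reshape(len(a), -1)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    return (flat - mu) / sd
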