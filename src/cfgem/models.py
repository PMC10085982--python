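"""Detection and localization predictors and the evaluation protocol.

The genome model is a dense network (batch norm, ReLU, dropout) over
the LVD + variant-type vector; the epigenome model is a small CNN over
the (100, 250, T) V-plot tensor (3x3 convolutions: first with
``conv1_kernels`` kernels, then a single-kernel convolution, each
followed by batch norm, ReLU and dropout, then a dense head).  Both
use AdamW, class-weighted cross-entropy, a log-prior output-bias
initialization, early stopping, and selection of the best of
``n_restarts`` random restarts by validation loss.

Reference training profile (as published): 30 restarts, patience 50,
250 first-layer kernels, 200 hyperparameter-search trials.  The desk
profile used by the bundled examples and tests scales these down
(restarts 3, smaller kernel counts) purely for single-CPU turnaround;
both profiles are plain configuration.

Evaluation: stratified 5-fold cross-validation in which the four
non-test folds are split 3:1 into train/validation; every sample gets
exactly one out-of-fold score.  Metrics: rank-statistic ROC-AUC,
bootstrap sensitivity CIs at fixed specificities, localization
accuracy and a row-normalized confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from cfgem.errors import InvalidInputError
from cfgem import nn
from cfgem.rng import substream


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + training hyperparameters for one model family."""

    family: str                      # "genome-dnn" | "epigenome-cnn" | "gbdt"
    task: str = "detection"          # "detection" | "localization"
    n_classes: int = 1
    dense_widths: tuple[int, ...] = (256, 64, 16)
    dropout: float = 0.3
    conv1_kernels: int = 250
    fc_width: int = 16
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 50
    n_restarts: int = 30
    seed: int = 0


#: desk-scale training budgets for interactive / CI-sized runs
DESK_GENOME = dict(n_restarts=3, patience=20, max_epochs=150)
DESK_EPIGENOME = dict(n_restarts=1, patience=3, max_epochs=15, conv1_kernels=4,
                      lr=3e-3, batch_size=64)


def build_genome_net(spec: ModelSpec, n_features: int, rng: np.random.Generator) -> nn.Network:
    """Dense net: [Dense -> BN -> ReLU -> Dropout] x L -> head."""
    layers: list[nn.Layer] = []
    d = n_features
    for w in spec.dense_widths:
        layers += [nn.Dense(d, w, rng), nn.BatchNorm(w), nn.ReLU(), nn.Dropout(spec.dropout, rng)]
        d = w
    out_dim = 1 if spec.task == "detection" else spec.n_classes
    layers.append(nn.Dense(d, out_dim, rng))
    return nn.Network(layers=layers, task=spec.task, n_classes=spec.n_classes)


def build_epigenome_net(spec: ModelSpec, input_shape: tuple[int, int, int], rng: np.random.Generator) -> nn.Network:
    """CNN: conv(k kernels) -> BN -> ReLU -> drop -> conv(1) -> BN ->
    ReLU -> drop -> flatten -> dense -> head."""
    h, w, c = input_shape
    layers: list[nn.Layer] = [
        nn.Conv3x3(c, spec.conv1_kernels, rng), nn.BatchNorm(spec.conv1_kernels),
        nn.ReLU(), nn.Dropout(spec.dropout, rng),
        nn.Conv3x3(spec.conv1_kernels, 1, rng), nn.BatchNorm(1),
        nn.ReLU(), nn.Dropout(spec.dropout, rng),
        nn.Flatten(), nn.Dense(h * w, spec.fc_width, rng), nn.ReLU(),
    ]
    out_dim = 1 if spec.task == "detection" else spec.n_classes
    layers.append(nn.Dense(spec.fc_width, out_dim, rng))
    return nn.Network(layers=layers, task=spec.task, n_classes=spec.n_classes)


def _make_net(spec: ModelSpec, x: np.ndarray, rng: np.random.Generator) -> nn.Network:
    if spec.family == "genome-dnn":
        return build_genome_net(spec, x.shape[1], rng)
    if spec.family == "epigenome-cnn":
        return build_epigenome_net(spec, x.shape[1:], rng)
    raise InvalidInputError(f"unknown family {spec.family!r}")


def train_with_restarts(
    spec: ModelSpec,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    n_restarts: int | None = None,
) -> tuple[nn.Network, list[float]]:
    """Train ``n_restarts`` times from scratch; keep lowest val loss.

    Restart ``r`` derives its own init/shuffle/dropout substream from
    the spec seed, so selection is reproducible.  Returns (best model,
    all restart validation losses).
    """
    n_restarts = spec.n_restarts if n_restarts is None else n_restarts
    if n_restarts < 1:
        raise InvalidInputError("n_restarts must be >= 1")
    if len(x_val) == 0:
        raise InvalidInputError("empty validation set")
    n_classes = 2 if spec.task == "detection" else spec.n_classes
    cw = nn.class_weight_map(y_train, n_classes)
    best_net, best_loss, losses = None, np.inf, []
    for r in range(n_restarts):
        rng = substream(spec.seed, "restart", spec.family, spec.task, r)
        net = _make_net(spec, x_train, rng)
        net.class_weights = cw
        nn.init_output_bias(net, y_train)
        res = nn.train_network(net, x_train, y_train, x_val, y_val, rng,
                               lr=spec.lr, weight_decay=spec.weight_decay,
                               batch_size=spec.batch_size, max_epochs=spec.max_epochs,
                               patience=spec.patience)
        losses.append(res.val_loss)
        if res.val_loss < best_loss:
            best_net, best_loss = net, res.val_loss
    return best_net, losses


@dataclass
class CohortScores:
    """Out-of-fold prediction scores with labels and fold assignment."""

    table: pd.DataFrame   # sample, label(int), fold, score (or score_<c> columns)
    task: str
    class_names: tuple[str, ...] = ()

    @property
    def scores(self) -> np.ndarray:
        if self.task == "detection":
            return self.table["score"].to_numpy()
        return self.table[[f"score_{c}" for c in self.class_names]].to_numpy()


def crossvalidate(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    k: int = 5,
    sample_ids: list[str] | None = None,
    class_names: tuple[str, ...] = (),
    n_restarts: int | None = None,
) -> CohortScores:
    """Stratified k-fold out-of-fold scoring.

    Per fold, the remaining folds are split 3:1 (stratified) into train
    and validation sets for early stopping and restart selection; the
    held-out fold is scored by the selected model.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    low = counts[counts < k]
    if len(low):
        raise InvalidInputError(f"class(es) with < {k} samples: {list(low.index)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed & 0x7FFFFFFF)
    n = len(labels)
    fold_of = np.full(n, -1)
    if spec.task == "detection":
        score_cols = {"score": np.full(n, np.nan)}
    else:
        score_cols = {f"score_{c}": np.full(n, np.nan) for c in class_names}
    for fold, (rest, test) in enumerate(skf.split(features, labels)):
        val_frac = 0.25 if k > 2 else 0.5  # k=2 degenerate: single fold split in half
        tr, va = train_test_split(rest, test_size=val_frac, stratify=labels[rest],
                                  random_state=(spec.seed + fold) & 0x7FFFFFFF)
        fold_spec = replace(spec, seed=spec.seed + 1000 * (fold + 1))
        net, _ = train_with_restarts(fold_spec, features[tr], labels[tr],
                                     features[va], labels[va], n_restarts=n_restarts)
        proba = net.predict_proba(features[test])
        fold_of[test] = fold
        if spec.task == "detection":
            score_cols["score"][test] = proba
        else:
            for ci, c in enumerate(class_names):
                score_cols[f"score_{c}"][test] = proba[:, ci]
    table = pd.DataFrame({
        "sample": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
        "label": labels, "fold": fold_of, **score_cols,
    })
    assert (fold_of >= 0).all()
    return CohortScores(table=table, task=spec.task, class_names=tuple(class_names))


def fit_gbdt_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    search_budget: int = 10,
    task: str = "detection",
    seed: int = 0,
):
    """Gradient-boosted trees with random hyperparameter search.

    Searches n_estimators, learning_rate, max_depth, min_child_weight
    and colsample_bytree by random search with 3-fold CV on log-loss,
    then refits the best configuration on the full training data.
    """
    if search_budget < 1:
        raise InvalidInputError("search_budget must be >= 1")
    from sklearn.model_selection import RandomizedSearchCV
    from xgboost import XGBClassifier

    objective = "binary:logistic" if task == "detection" else "multi:softprob"
    base = XGBClassifier(objective=objective, random_state=seed & 0x7FFFFFFF,
                         n_jobs=1, verbosity=0, eval_metric="logloss")
    space = {
        "n_estimators": [50, 100, 200, 400],
        "learning_rate": [0.01, 0.03, 0.1, 0.3],
        "max_depth": [2, 3, 4, 6],
        "min_child_weight": [1, 3, 5],
        "colsample_bytree": [0.5, 0.7, 1.0],
    }
    search = RandomizedSearchCV(base, space, n_iter=search_budget, cv=3,
                                scoring="neg_log_loss", random_state=seed & 0x7FFFFFFF,
                                n_jobs=1, refit=True)
    search.fit(features, labels)
    return search.best_estimator_


def combine_scores(a: CohortScores, b: CohortScores) -> CohortScores:
    """Elementwise mean of two models' scores over identical samples."""
    if a.task != b.task:
        raise InvalidInputError("tasks differ")
    if list(a.table["sample"]) != list(b.table["sample"]):
        raise InvalidInputError("sample sets differ")
    out = a.table.copy()
    cols = ["score"] if a.task == "detection" else [f"score_{c}" for c in a.class_names]
    for c in cols:
        out[c] = (a.table[c].to_numpy() + b.table[c].to_numpy()) / 2.0
    return CohortScores(table=out, task=a.task, class_names=a.class_names)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC via the Mann-Whitney rank statistic (ties shared)."""
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("need both classes for AUC")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sensitivity_at_specificity(labels: np.ndarray, scores: np.ndarray, level: float) -> float:
    """Sensitivity at the most permissive threshold with specificity >= level.

    Positive calls are scores >= threshold; among thresholds achieving
    control specificity of at least ``level``, the smallest (hence most
    sensitive) is used.
    """
    labels = np.asarray(labels).astype(int)
    controls = np.sort(scores[labels == 0])
    cases = scores[labels == 1]
    if len(controls) == 0 or len(cases) == 0:
        raise InvalidInputError("need both classes")
    cand = np.unique(np.concatenate([scores, [np.inf]]))
    spec = 1.0 - (len(controls) - np.searchsorted(controls, cand, side="left")) / len(controls)
    ok = cand[spec >= level]
    thr = ok.min()
    return float(np.mean(cases >= thr))


def evaluate(
    scores: CohortScores,
    spec_levels: tuple[float, ...] = (0.95, 0.98, 0.99),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Cohort metrics from out-of-fold scores.

    Detection: ROC-AUC plus sensitivity at each specificity level with
    a stratified percentile bootstrap 95% CI (``n_boot`` resamples).
    Localization: argmax accuracy plus a row-normalized confusion
    matrix.
    """
    y = scores.table["label"].to_numpy().astype(int)
    if scores.task == "detection":
        s = scores.table["score"].to_numpy()
        if len(np.unique(y)) < 2:
            raise InvalidInputError("one-class input")
        rng = substream(seed, "bootstrap")
        idx1 = np.flatnonzero(y == 1)
        idx0 = np.flatnonzero(y == 0)
        out = {"auc": roc_auc(y, s), "sensitivity": {}}
        for level in spec_levels:
            point = sensitivity_at_specificity(y, s, level)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                b1 = rng.choice(idx1, size=len(idx1), replace=True)
                b0 = rng.choice(idx0, size=len(idx0), replace=True)
                bi = np.concatenate([b1, b0])
                boots[b] = sensitivity_at_specificity(y[bi], s[bi], level)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            out["sensitivity"][level] = {"estimate": point, "ci95": (float(lo), float(hi))}
        return out
    s = scores.scores
    pred = s.argmax(axis=1)
    acc = float(np.mean(pred == y))
    k = s.shape[1]
    cm = np.zeros((k, k))
    for yi, pi in zip(y, pred):
        cm[yi, pi] += 1
    row = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)
    return {"accuracy": acc, "confusion": cm_norm,
            "class_names": scores.class_names}
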