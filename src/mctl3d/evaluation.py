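"""Evaluation protocol: LOOCV, repeated grid search, metrics, triage, transfer comparison.

Leave-one-out cross-validation holds out one sample per fold and refits
*everything* — brightness normalizer, augmentation draws and model weights —
on the remaining samples only (intensity windows are per-image, so they never
leak across samples).  The hyperparameter grid pairs convolution depth with a
filter count (1 layer/16 filters, 2/32, 3/64) and crosses it with fully
connected widths {16, 32, 64}; each configuration is evaluated by repeated
LOOCV (default 15 repeats) with freshly derived seeds, reported as min-max
ranges and means.  Confidence triage ranks held-out predictions by |2p - 1|
and scores the most confident fraction.  The transfer comparison runs paired
LOOCVs — identical folds, splits and augmentations — differing only in
whether the convolution stack starts from pretrained encoder weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, augment_sample
from .autoencoder import EncoderWeights
from .classifier import (
    ClassifierConfig,
    build_classifier,
    initialize_from_encoder,
    predict,
    stratified_split,
    train_classifier,
)
from .preprocessing import apply_normalizer, apply_window, compute_window, fit_normalizer
from .types import LabeledVolume, Prediction

__all__ = [
    "Metrics",
    "CVResult",
    "GridSearchResult",
    "TriageCurve",
    "confusion_metrics",
    "run_loocv",
    "default_grid",
    "run_grid_search",
    "triage_curve",
    "compare_initializations",
]


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived rates; undefined rates are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class CVResult:
    """One complete LOOCV: per-fold predictions and aggregate metrics."""

    predictions: List[Prediction]
    labels: List[int]
    metrics: Metrics
    config: ClassifierConfig
    init_mode: str
    seed: int
    inner_val_accuracies: List[float] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.predictions)


@dataclass
class GridSearchResult:
    """Repeated LOOCVs per configuration plus the summary table."""

    results: Dict[int, List[CVResult]]  # grid index -> one CVResult per repeat
    configs: List[ClassifierConfig]
    summary: pd.DataFrame
    best_index: int

    @property
    def best_config(self) -> ClassifierConfig:
        return self.configs[self.best_index]


@dataclass
class TriageCurve:
    """Accuracy among the top-confidence fraction, per coverage level."""

    coverages: List[float]
    accuracies: List[float]
    n_included: List[int]


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(labels: Sequence[int], predictions: Sequence[Prediction]) -> Metrics:
    """Accuracy, sensitivity (recall on class 1) and specificity (on class 0)."""
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    if len(labels) == 0:
        raise ValueError("need at least one prediction")
    y = np.asarray(labels, dtype=int)
    yhat = np.array([p.label for p in predictions], dtype=int)
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    return Metrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_rate(tp + tn, tp + fp + tn + fn),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
    )


def _fold_seed(master: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def prepare_fold(
    dataset: Sequence[LabeledVolume],
    train_idx: Sequence[int],
    coverage: float = 0.95,
) -> Tuple[List[LabeledVolume], "object"]:
    """Window every volume on itself; fit the normalizer on the training fold only."""
    windowed = [
        LabeledVolume(volume=apply_window(s.volume, compute_window(s.volume, coverage)), label=s.label)
        for s in dataset
    ]
    norm = fit_normalizer([windowed[i].volume for i in train_idx])
    return windowed, norm


def run_loocv(
    dataset: Sequence[LabeledVolume],
    config: ClassifierConfig,
    aug: Optional[AugmentationConfig] = None,
    init: Union[None, EncoderWeights] = None,
    seed: int = 0,
    coverage: float = 0.95,
) -> CVResult:
    """One fold per sample; all preprocessing and training fitted without it.

    Pipeline per fold: per-image windows (leakage-free by construction) ->
    stratified inner train/validation split of the training fold -> rigid
    augmentation of the inner-training portion (windowed volumes, background
    fill) -> normalization of everything with the fold's training statistics
    -> seeded training with checkpointing -> prediction on the held-out
    sample.  ``init`` switches the convolution stack to transfer
    initialization; fold seeds do not depend on it, so the random and
    transfer arms of a comparison are exactly paired.
    """
    n = len(dataset)
    if n < 4:
        raise ValueError(f"LOOCV needs at least 4 samples, got {n}")
    labels_all = [s.label for s in dataset]
    if len(set(labels_all)) < 2:
        raise ValueError("dataset must contain both classes")
    shape = dataset[0].volume.shape

    predictions: List[Prediction] = []
    inner_accs: List[float] = []
    for fold in range(n):
        train_idx = [i for i in range(n) if i != fold]
        windowed, norm = prepare_fold(dataset, train_idx, coverage)
        fold_seed = _fold_seed(seed, fold)
        rng = np.random.default_rng(np.random.SeedSequence([fold_seed, 0x5917]))
        train_labels = [windowed[i].label for i in train_idx]
        tr_rel, va_rel = stratified_split(train_labels, config.validation_fraction, rng)
        inner_train = [windowed[train_idx[i]] for i in tr_rel]
        inner_val = [windowed[train_idx[i]] for i in va_rel]

        augmented: List[LabeledVolume] = []
        if aug is not None and aug.k > 0:
            for j, s in enumerate(inner_train):
                aug_j = replace(aug, seed=_fold_seed(fold_seed, 10, j))
                augmented.extend(augment_sample(s, aug_j))

        def norm_s(s: LabeledVolume) -> LabeledVolume:
            return LabeledVolume(volume=apply_normalizer(s.volume, norm), label=s.label)

        fold_config = replace(config, seed=_fold_seed(fold_seed, 20))
        model = build_classifier(fold_config, shape)
        if init is not None:
            model = initialize_from_encoder(model, init)
        trained = train_classifier(
            model,
            [norm_s(s) for s in inner_train],
            fold_config,
            augmented=[norm_s(s) for s in augmented],
            val_samples=[norm_s(s) for s in inner_val],
        )
        inner_accs.append(trained.checkpoint_val_accuracy)
        heldout = apply_normalizer(windowed[fold].volume, norm)
        predictions.append(predict(trained.model, heldout))

    metrics = confusion_metrics(labels_all, predictions)
    return CVResult(
        predictions=predictions,
        labels=list(labels_all),
        metrics=metrics,
        config=config,
        init_mode="transfer" if init is not None else "random",
        seed=int(seed),
        inner_val_accuracies=inner_accs,
    )


def default_grid(
    base: Optional[ClassifierConfig] = None, full: bool = False
) -> List[ClassifierConfig]:
    """The search grid: depth/filter pairs (1/16, 2/32, 3/64) x fc {16,32,64}.

    ``full=True`` expands to the complete 27-configuration product of depths
    {1,2,3} x filters {16,32,64} x fc {16,32,64}.
    """
    base = base or ClassifierConfig()
    rows = (
        [(l, f) for l in (1, 2, 3) for f in (16, 32, 64)]
        if full
        else [(1, 16), (2, 32), (3, 64)]
    )
    return [
        replace(base, n_conv_layers=l, filters_per_layer=f, fc_nodes=fc)
        for (l, f) in rows
        for fc in (16, 32, 64)
    ]


def _config_n_params(config: ClassifierConfig, shape: Tuple[int, int, int]) -> int:
    return build_classifier(replace(config, seed=0), shape).n_params()


def run_grid_search(
    dataset: Sequence[LabeledVolume],
    grid: Optional[Sequence[ClassifierConfig]] = None,
    repeats: int = 15,
    aug: Optional[AugmentationConfig] = None,
    init: Union[None, EncoderWeights] = None,
    seed: int = 0,
    coverage: float = 0.95,
) -> GridSearchResult:
    """Repeated LOOCV per configuration; ranges, means and the best config.

    Every configuration gets the same number of repeats, each with a distinct
    derived seed.  Best configuration = highest mean accuracy; ties prefer
    fewer trainable parameters, then the lower grid index.
    """
    configs = list(grid) if grid is not None else default_grid()
    if not configs:
        raise ValueError("grid must be nonempty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    shape = dataset[0].volume.shape
    results: Dict[int, List[CVResult]] = {}
    rows = []
    for gi, cfg in enumerate(configs):
        runs = [
            run_loocv(dataset, cfg, aug=aug, init=init, seed=_fold_seed(seed, gi, rep), coverage=coverage)
            for rep in range(repeats)
        ]
        results[gi] = runs
        row: Dict = {
            "grid_index": gi,
            "n_conv_layers": cfg.n_conv_layers,
            "filters": cfg.filters_per_layer,
            "fc_nodes": cfg.fc_nodes,
            "n_params": _config_n_params(cfg, shape),
        }
        for metric in ("accuracy", "sensitivity", "specificity"):
            vals = np.array([getattr(r.metrics, metric) for r in runs], dtype=float)
            row[f"{metric}_min"] = float(np.nanmin(vals))
            row[f"{metric}_mean"] = float(np.nanmean(vals))
            row[f"{metric}_max"] = float(np.nanmax(vals))
        rows.append(row)
    summary = pd.DataFrame(rows)
    order = summary.sort_values(
        by=["accuracy_mean", "n_params", "grid_index"], ascending=[False, True, True], kind="stable"
    )
    best_index = int(order.iloc[0]["grid_index"])
    return GridSearchResult(results=results, configs=configs, summary=summary, best_index=best_index)


def triage_curve(
    cv: CVResult, coverages: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0)
) -> TriageCurve:
    """Accuracy over the ceil(c*N) most confident predictions per coverage c.

    Ties in confidence are broken by sample order; coverage 1.0 reproduces the
    overall accuracy exactly.
    """
    if cv.n_folds < 1:
        raise ValueError("need at least one prediction")
    conf = np.array([p.confidence for p in cv.predictions])
    correct = np.array([p.label == y for p, y in zip(cv.predictions, cv.labels)], dtype=float)
    rank = np.argsort(-conf, kind="stable")  # most confident first, ties by sample order
    accs, ns = [], []
    for c in coverages:
        if not 0.0 < c <= 1.0:
            raise ValueError(f"coverage must lie in (0, 1], got {c}")
        k = int(np.ceil(c * cv.n_folds - 1e-12))
        accs.append(float(np.mean(correct[rank[:k]])))
        ns.append(k)
    return TriageCurve(coverages=list(map(float, coverages)), accuracies=accs, n_included=ns)


def compare_initializations(
    dataset: Sequence[LabeledVolume],
    config: ClassifierConfig,
    aug: Optional[AugmentationConfig],
    weights: EncoderWeights,
    n_seeds: int = 10,
    seed: int = 0,
    coverage: float = 0.95,
) -> Dict:
    """Paired transfer-vs-random LOOCVs; improvement in percentage points.

    Both arms of each pair share one derived seed, hence identical folds,
    inner splits and augmentations; only the convolution initialization
    differs.  Reports per-seed accuracies and the mean accuracy improvement
    (transfer minus random) in percentage points.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    random_acc, transfer_acc = [], []
    per_seed = []
    for i in range(n_seeds):
        pair_seed = _fold_seed(seed, 0xC3, i)
        r = run_loocv(dataset, config, aug=aug, init=None, seed=pair_seed, coverage=coverage)
        t = run_loocv(dataset, config, aug=aug, init=weights, seed=pair_seed, coverage=coverage)
        random_acc.append(r.metrics.accuracy)
        transfer_acc.append(t.metrics.accuracy)
        per_seed.append({"seed": pair_seed, "random": r.metrics.accuracy, "transfer": t.metrics.accuracy})
    random_acc = np.array(random_acc)
    transfer_acc = np.array(transfer_acc)
    return {
        "per_seed": per_seed,
        "mean_random_accuracy": float(random_acc.mean()),
        "mean_transfer_accuracy": float(transfer_acc.mean()),
        "per_seed_improvement_pp": [float(d) for d in 100.0 * (transfer_acc - random_acc)],
        "mean_improvement_pp": float(100.0 * (transfer_acc - random_acc).mean()),
        "n_seeds": int(n_seeds),
    }
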