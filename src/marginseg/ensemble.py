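"""Fusion of multiple models' probability maps into one prediction.

Four strategies: unweighted averaging, weighted averaging, voting on
binarized maps, and a learned pixel-level combiner (logistic regression on
the per-model probabilities). Fusion parameters — model weights, vote
count, output threshold — are optimized on the *validation* split only,
for the Dice score, the top-margin error, or a balanced combination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .image import DEFAULT_ROW_SPACING_MM
from .metrics import dice_coefficient, tumor_margin_error
from .postprocess import postprocess_mask

__all__ = [
    "EnsembleConfig",
    "fuse_average",
    "fuse_vote",
    "fit_fusion_classifier",
    "apply_classifier",
    "optimize_fusion",
]

STRATEGIES = ("unweighted_avg", "weighted_avg", "vote", "classifier")


@dataclass
class EnsembleConfig:
    """A fitted/selected fusion rule, serializable to JSON."""

    strategy: str
    model_weights: list[float] | None = None
    vote_count: int | None = None
    per_model_thresholds: list[float] | None = None
    prob_threshold: float = 0.5
    classifier_coef: list[float] | None = None
    classifier_intercept: float | None = None
    criterion: str | None = None
    score: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.model_weights is not None:
            w = np.asarray(self.model_weights, dtype=float)
            if (w < 0).any():
                raise ValueError("model weights must be non-negative")
            if w.sum() <= 0:
                raise ValueError("model weights must not all be zero")
            self.model_weights = list(w / w.sum())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stack(maps: list[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    if arr.ndim != 3:
        raise ValueError("probability maps must be 2-D and share a shape")
    return arr


def fuse_average(maps: list[np.ndarray], weights: list[float] | None = None) -> np.ndarray:
    """Pixel-wise (weighted) mean of probability maps; output stays in [0, 1]."""
    arr = _stack(maps)
    if len(maps) < 2:
        raise ValueError("averaging needs at least 2 maps")
    if weights is None:
        return arr.mean(axis=0)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (arr.shape[0],):
        raise ValueError("one weight per model required")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    w = w / w.sum()
    return np.tensordot(w, arr, axes=1)


def fuse_vote(
    maps: list[np.ndarray],
    per_model_thresholds: list[float] | float = 0.5,
    vote_count: int = 1,
) -> np.ndarray:
    """Label a pixel tumor iff at least ``vote_count`` binarized maps do.

    vote_count 1 is the union of the binarized maps; vote_count = number of
    models is their intersection.
    """
    arr = _stack(maps)
    m = arr.shape[0]
    if not 1 <= vote_count <= m:
        raise ValueError(f"vote_count must be in [1, {m}]")
    thr = np.broadcast_to(np.asarray(per_model_thresholds, dtype=np.float64), (m,))
    votes = (arr >= thr[:, None, None]).sum(axis=0)
    return (votes >= vote_count).astype(np.uint8)


def fit_fusion_classifier(
    maps_train: list[list[np.ndarray]],
    truths_train: list[np.ndarray],
    classifier_kind: str = "logistic",
    max_pixels: int = 200_000,
    seed: int = 0,
) -> EnsembleConfig:
    """Train a per-pixel combiner on pooled validation pixels.

    ``maps_train[i]`` holds the M models' maps for validation image ``i``;
    each pixel is a sample with M probability features. Logistic regression
    is the default combiner — five coefficients plus an intercept, fast to
    apply per pixel and easy to audit. Fit only on validation data, never
    on the test split.
    """
    feats, labels = [], []
    for per_model, truth in zip(maps_train, truths_train):
        arr = _stack(per_model)  # (M, H, W)
        feats.append(arr.reshape(arr.shape[0], -1).T)
        labels.append((np.asarray(truth) > 0).ravel())
    x = np.concatenate(feats)
    y = np.concatenate(labels)
    if y.all() or not y.any():
        raise ValueError("single-class training pool; cannot fit a combiner")
    if x.shape[0] > max_pixels:
        idx = np.random.default_rng(seed).choice(x.shape[0], max_pixels, replace=False)
        x, y = x[idx], y[idx]
    if classifier_kind != "logistic":
        raise ValueError("only the logistic combiner is built in")
    clf = LogisticRegression(max_iter=500)
    clf.fit(x, y)
    return EnsembleConfig(
        strategy="classifier",
        classifier_coef=clf.coef_[0].tolist(),
        classifier_intercept=float(clf.intercept_[0]),
    )


def apply_classifier(config: EnsembleConfig, maps: list[np.ndarray]) -> np.ndarray:
    """Fused probability map from a fitted pixel combiner."""
    if config.classifier_coef is None:
        raise ValueError("config carries no fitted classifier")
    arr = _stack(maps)
    coef = np.asarray(config.classifier_coef)
    logit = np.tensordot(coef, arr, axes=1) + config.classifier_intercept
    return 1.0 / (1.0 + np.exp(-logit))


def fuse(config: EnsembleConfig, maps: list[np.ndarray]) -> np.ndarray:
    """Binary fused prediction for any strategy (threshold + post-rules applied by caller)."""
    if config.strategy == "unweighted_avg":
        return (fuse_average(maps) >= config.prob_threshold).astype(np.uint8)
    if config.strategy == "weighted_avg":
        return (fuse_average(maps, config.model_weights) >= config.prob_threshold).astype(np.uint8)
    if config.strategy == "vote":
        return fuse_vote(maps, config.per_model_thresholds or 0.5, config.vote_count or 1)
    return (apply_classifier(config, maps) >= config.prob_threshold).astype(np.uint8)


# -- validation-split optimization ------------------------------------------


def _score(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    criterion: str,
    row_spacing_mm: float,
    margin_ref_mm: float,
    lam: float,
    postprocess: bool,
) -> float:
    """Higher is better for every criterion."""
    if postprocess:
        preds = [postprocess_mask(p) for p in preds]
    dice = np.mean([dice_coefficient(t, p) for t, p in zip(truths, preds)])
    margin = np.mean(
        [tumor_margin_error(t, p, row_spacing_mm).error_mm for t, p in zip(truths, preds)]
    )
    if criterion == "dice":
        return float(dice)
    if criterion == "margin":
        return float(-margin)
    if criterion == "balanced":
        return float(dice - lam * margin / margin_ref_mm)
    raise ValueError("criterion must be 'dice', 'margin' or 'balanced'")


def _simplex_grid(m: int, step: float = 0.1):
    """Non-negative weight vectors of length m summing to 1, on a step grid."""
    n = round(1.0 / step)
    for combo in combinations_with_replacement(range(m), n):
        w = np.bincount(combo, minlength=m) / n
        yield w


def optimize_fusion(
    maps_val: list[list[np.ndarray]],
    truths_val: list[np.ndarray],
    strategy: str,
    criterion: str = "balanced",
    row_spacing_mm: float = DEFAULT_ROW_SPACING_MM,
    margin_ref_mm: float = 1.0,
    lam: float = 1.0,
    weight_step: float = 0.1,
    threshold_step: float = 0.01,
    postprocess: bool = True,
    seed: int = 0,
) -> EnsembleConfig:
    """Grid-search fusion parameters on the validation split.

    Searched per strategy: output threshold (0..1, step ``threshold_step``)
    for the averaging and classifier strategies; a step-0.1 simplex of
    model weights for weighted averaging; vote count 1..M (and a shared
    per-model threshold grid) for voting. The "balanced" criterion
    maximizes mean Dice minus ``lam`` times the mean margin error scaled by
    ``margin_ref_mm`` — the 1 mm default reflects the resection margin used
    clinically, putting both terms on comparable scales. Ties keep the
    earliest (most uniform / lowest-threshold) candidate, deterministically.
    """
    if not maps_val or not truths_val:
        raise ValueError("empty validation set")
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    m = len(maps_val[0])
    thresholds = np.round(np.arange(threshold_step, 1.0, threshold_step), 10)

    def evaluate(make_pred) -> float:
        preds = [make_pred(per_model) for per_model in maps_val]
        return _score(preds, truths_val, criterion, row_spacing_mm, margin_ref_mm, lam, postprocess)

    best: tuple[float, EnsembleConfig] | None = None

    def consider(score: float, config: EnsembleConfig) -> None:
        nonlocal best
        if best is None or score > best[0] + 1e-12:
            config.criterion, config.score = criterion, float(score)
            best = (score, config)

    if strategy == "unweighted_avg":
        fused = [fuse_average(per_model) for per_model in maps_val]
        for thr in thresholds:
            s = _score(
                [(f >= thr).astype(np.uint8) for f in fused],
                truths_val, criterion, row_spacing_mm, margin_ref_mm, lam, postprocess,
            )
            consider(s, EnsembleConfig("unweighted_avg", prob_threshold=float(thr)))
    elif strategy == "weighted_avg":
        # Uniform weights first so the tie-break lands on them.
        grid = [np.full(m, 1.0 / m)] + [w for w in _simplex_grid(m, weight_step)]
        for w in grid:
            fused = [fuse_average(per_model, w) for per_model in maps_val]
            for thr in thresholds[:: max(1, len(thresholds) // 20)]:
                s = _score(
                    [(f >= thr).astype(np.uint8) for f in fused],
                    truths_val, criterion, row_spacing_mm, margin_ref_mm, lam, postprocess,
                )
                consider(
                    s,
                    EnsembleConfig(
                        "weighted_avg", model_weights=w.tolist(), prob_threshold=float(thr)
                    ),
                )
    elif strategy == "vote":
        for per_thr in np.round(np.arange(0.3, 0.75, 0.1), 10):
            for count in range(1, m + 1):
                s = evaluate(lambda mm, t=per_thr, c=count: fuse_vote(mm, t, c))
                consider(
                    s,
                    EnsembleConfig(
                        "vote", vote_count=count, per_model_thresholds=[float(per_thr)] * m
                    ),
                )
    else:  # classifier
        fitted = fit_fusion_classifier(maps_val, truths_val, seed=seed)
        fused = [apply_classifier(fitted, per_model) for per_model in maps_val]
        for thr in thresholds:
            s = _score(
                [(f >= thr).astype(np.uint8) for f in fused],
                truths_val, criterion, row_spacing_mm, margin_ref_mm, lam, postprocess,
            )
            consider(
                s,
                EnsembleConfig(
                    "classifier",
                    classifier_coef=fitted.classifier_coef,
                    classifier_intercept=fitted.classifier_intercept,
                    prob_threshold=float(thr),
                ),
            )
    assert best is not None
    return best[1]
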