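"""Desk-scale study protocols: transfer, loss, ensemble and generator checks.

These functions reproduce, at laptop scale, the qualitative comparisons the
pipeline exists for: fine-tuning versus scratch training, depth-weighted
versus plain generalized Dice, and single models versus ensemble fusion.
They are used both by the test suite and by the results-reproduction
script, so every experiment takes an explicit seed and returns plain
dictionaries / DataFrames.

Problem sizes are deliberately small — 64 x 64 phantoms, tens of images,
minute-scale training — chosen so a full comparison runs on one CPU core
while leaving the compared conditions (matched budgets, shared datasets,
patient-wise splits) faithful to the full-scale protocol.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import fuse, optimize_fusion
from .losses import gen_dice_loss, gradient_weight_mask, gw_dice_loss
from .metrics import dice_coefficient, roc_auc, threshold_sweep, tumor_margin_error
from .nn import save_checkpoint
from .phantom import PhantomSpec, generate_dataset, generate_phantom, tradeoff_probability_maps
from .postprocess import postprocess_mask
from .train import MODEL_VARIANTS, TrainConfig, train

# 64 px desk-scale geometry: same 15 x 37.5 mm field of view as the 128 px
# default, at half resolution.
DESK_ROW_SPACING_MM = 0.1172 * 2
DESK_COL_SPACING_MM = 0.293 * 2


def desk_spec(domain: str, n_patients: int, seed: int, **overrides) -> PhantomSpec:
    kw = dict(
        n_patients=n_patients,
        domain=domain,
        image_shape=(64, 64),
        row_spacing_mm=DESK_ROW_SPACING_MM,
        col_spacing_mm=DESK_COL_SPACING_MM,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def split_samples(spec: PhantomSpec) -> dict[str, list]:
    samples, manifest = generate_dataset(spec)
    splits: dict[str, list] = {"train": [], "val": [], "test": []}
    for (img, mask), (_, row) in zip(samples, manifest.iterrows()):
        splits[row.split].append((img, mask))
    return splits


def _test_metrics(net, test_set, row_spacing_mm: float, threshold: float = 0.5) -> tuple[float, float]:
    dices, margins = [], []
    for img, mask in test_set:
        pred = postprocess_mask(net.predict(img.pixels) >= threshold)
        dices.append(dice_coefficient(mask, pred))
        margins.append(tumor_margin_error(mask, pred, row_spacing_mm).error_mm)
    return float(np.mean(dices)), float(np.mean(margins))


def _balanced_threshold(net, val_set, row_spacing_mm: float,
                        margin_ref_mm: float = 1.0) -> float:
    """Validation-optimal operating threshold for the Dice/margin balance.

    Mirrors the full-scale protocol: reported operating points come from a
    validation sweep maximizing mean Dice minus the mean margin error
    scaled by the 1 mm clinical reference, not from a fixed 0.5.
    """
    truths = [m for _, m in val_set]
    maps = [net.predict(img.pixels) for img, _ in val_set]
    sweep = threshold_sweep(
        truths, maps, np.round(np.arange(0.1, 1.0, 0.05), 10),
        row_spacing_mm=row_spacing_mm, postprocess=True,
    )
    score = sweep.mean_dice - sweep.mean_margin_error_mm / margin_ref_mm
    return float(sweep.thresholds[int(np.argmax(score))])


def pretrain_source(variant: str, out_path: str | Path, seed: int, epochs: int = 20,
                    n_patients: int = 20) -> float:
    """Pre-train one variant on source-domain phantoms; returns val Dice."""
    splits = split_samples(desk_spec("source", n_patients, seed=1000 + seed))
    result = train(
        TrainConfig(variant=variant, loss="gen_dice", epochs=epochs, batch_size=2, seed=seed),
        splits["train"], splits["val"],
    )
    save_checkpoint(out_path, result.net)
    return result.best_val_dice


def heldout_eval_set(seed: int, n_images: int = 30) -> list[tuple]:
    """Fresh target-domain phantoms never seen by any training or optimizer.

    The per-dataset test splits at desk scale hold only a handful of
    images, so chance composition (all-shallow vs some deep lesions)
    dominates comparisons; a common 30-image held-out set keeps the
    hard deep-margin cases represented.
    """
    spec = desk_spec("target", max(3, n_images // 2), seed=seed, images_per_patient=(2, 2))
    samples, _ = generate_dataset(spec)
    return samples[:n_images]


def run_transfer_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    epochs: int = 12,
    n_patients: int = 10,
    source_checkpoint: str | Path | None = None,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """Scratch training vs fine-tuning at a matched, scarce epoch budget.

    Both arms train the same variant on the same target-domain phantoms for
    the same number of epochs; the fine-tuned arm starts from a
    source-domain checkpoint (a plentiful source dataset, well trained) and
    uses the 10x-smaller learning rate with no frozen layers. The target
    set is deliberately small and the budget deliberately scarce — transfer
    learning is a data/compute-scarcity technique, and with a large target
    set or a long budget scratch training catches up. Both arms are scored
    on a common 30-image held-out set.
    """
    workdir = Path(workdir or tempfile.mkdtemp(prefix="marginseg_"))
    if source_checkpoint is None:
        source_checkpoint = workdir / "source_ed8.npz"
        pretrain_source("ed8", source_checkpoint, seed=seed + 1, epochs=30, n_patients=40)
    splits = split_samples(desk_spec("target", n_patients, seed=2000 + seed))
    eval_set = heldout_eval_set(seed=6000 + seed)
    rows = []
    for rep in range(n_seeds):
        for mode in ("scratch", "finetune"):
            cfg = TrainConfig(
                variant="ed8", loss="gw_dice", epochs=epochs, batch_size=2, seed=seed * 100 + rep,
                fine_tune=(mode == "finetune"),
                source_checkpoint=str(source_checkpoint) if mode == "finetune" else None,
            )
            result = train(cfg, splits["train"], splits["val"])
            dice, margin = _test_metrics(result.net, eval_set, DESK_ROW_SPACING_MM)
            rows.append({"mode": mode, "rep": rep, "test_dice": dice, "test_margin_mm": margin})
    return pd.DataFrame(rows)


def run_loss_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    epochs: int = 40,
    n_patients: int = 20,
) -> pd.DataFrame:
    """GWDice vs GenDice training, identical variants/data/budget.

    Trains to convergence at desk scale and scores test Dice and top-margin
    error per loss and replicate on a common 30-image held-out set.
    """
    splits = split_samples(desk_spec("target", n_patients, seed=3000 + seed))
    eval_set = heldout_eval_set(seed=7000 + seed)
    rows = []
    for rep in range(n_seeds):
        for loss in ("gen_dice", "gw_dice"):
            cfg = TrainConfig(
                variant="ed8", loss=loss, epochs=epochs, batch_size=2, seed=seed * 100 + rep
            )
            result = train(cfg, splits["train"], splits["val"])
            thr = _balanced_threshold(result.net, splits["val"], DESK_ROW_SPACING_MM)
            dice, margin = _test_metrics(result.net, eval_set, DESK_ROW_SPACING_MM, threshold=thr)
            rows.append(
                {"loss": loss, "rep": rep, "test_dice": dice, "test_margin_mm": margin,
                 "threshold": thr}
            )
    return pd.DataFrame(rows)


def train_variant_suite(
    seed: int = 0,
    epochs_pretrain: int = 20,
    epochs_finetune: int = 15,
    n_patients: int = 30,
    workdir: str | Path | None = None,
    checkpoints: dict[str, Path] | None = None,
) -> tuple[dict[str, object], dict[str, list]]:
    """Pre-train + fine-tune all five variants; returns nets and target splits.

    ``checkpoints`` may carry already pre-trained source checkpoints per
    variant (as written by :func:`pretrain_source`), in which case only the
    fine-tuning stage runs — replicate studies share one pre-training.
    """
    workdir = Path(workdir or tempfile.mkdtemp(prefix="marginseg_"))
    splits = split_samples(desk_spec("target", n_patients, seed=4000 + seed))
    nets = {}
    for variant in MODEL_VARIANTS:
        if checkpoints and variant in checkpoints:
            ckpt = Path(checkpoints[variant])
        else:
            ckpt = workdir / f"source_{variant}.npz"
            pretrain_source(variant, ckpt, seed=seed + 1, epochs=epochs_pretrain)
        result = train(
            TrainConfig(
                variant=variant, loss="gw_dice", epochs=epochs_finetune, batch_size=2,
                seed=seed, fine_tune=True, source_checkpoint=str(ckpt),
            ),
            splits["train"], splits["val"],
        )
        nets[variant] = result.net
    return nets, splits


def run_ensemble_experiment(
    nets: dict[str, object],
    splits: dict[str, list],
    seed: int = 0,
    n_eval_images: int = 30,
    weight_step: float = 0.2,
) -> pd.DataFrame:
    """Individual models vs the four fusion strategies on a held-out set.

    Fusion parameters are optimized on the validation split twice per
    strategy — once for the Dice score and once for the balanced
    Dice/margin criterion — and evaluated on ``n_eval_images`` fresh
    phantoms never seen by any model or optimizer. Returns one row per
    method with mean Dice, mean margin error and pooled AUC.
    """
    eval_spec = desk_spec(
        "target", n_eval_images // 2, seed=5000 + seed, images_per_patient=(2, 2)
    )
    eval_samples, _ = generate_dataset(eval_spec)
    eval_samples = eval_samples[:n_eval_images]

    val_truths = [m for _, m in splits["val"]]
    val_maps = [[nets[v].predict(img.pixels) for v in nets] for img, _ in splits["val"]]
    ev_truths = [m for _, m in eval_samples]
    ev_maps = [[nets[v].predict(img.pixels) for v in nets] for img, _ in eval_samples]

    rows = []
    for j, variant in enumerate(nets):
        maps_j = [mm[j] for mm in ev_maps]
        preds = [postprocess_mask(m >= 0.5) for m in maps_j]
        rows.append(
            {
                "method": f"individual:{variant}",
                "kind": "individual",
                "criterion": "none",
                "mean_dice": float(np.mean([dice_coefficient(t, p) for t, p in zip(ev_truths, preds)])),
                "mean_margin_mm": float(
                    np.mean(
                        [tumor_margin_error(t, p, DESK_ROW_SPACING_MM).error_mm
                         for t, p in zip(ev_truths, preds)]
                    )
                ),
                "auc": roc_auc(ev_truths, maps_j)[0],
            }
        )
    for strategy in ("unweighted_avg", "weighted_avg", "vote", "classifier"):
        for criterion in ("dice", "balanced"):
            cfg = optimize_fusion(
                val_maps, val_truths, strategy, criterion=criterion,
                row_spacing_mm=DESK_ROW_SPACING_MM, weight_step=weight_step, seed=seed,
            )
            preds = [postprocess_mask(fuse(cfg, mm)) for mm in ev_maps]
            fused_prob = None
            if strategy in ("unweighted_avg", "weighted_avg"):
                from .ensemble import fuse_average

                fused_prob = [fuse_average(mm, cfg.model_weights) for mm in ev_maps]
            elif strategy == "classifier":
                from .ensemble import apply_classifier

                fused_prob = [apply_classifier(cfg, mm) for mm in ev_maps]
            rows.append(
                {
                    "method": strategy,
                    "kind": "ensemble",
                    "criterion": criterion,
                    "mean_dice": float(
                        np.mean([dice_coefficient(t, p) for t, p in zip(ev_truths, preds)])
                    ),
                    "mean_margin_mm": float(
                        np.mean(
                            [tumor_margin_error(t, p, DESK_ROW_SPACING_MM).error_mm
                             for t, p in zip(ev_truths, preds)]
                        )
                    ),
                    "auc": roc_auc(ev_truths, fused_prob)[0] if fused_prob else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_ensemble_study(seed: int = 0, n_reps: int = 3, **suite_kw) -> pd.DataFrame:
    """Replicated individual-vs-ensemble comparison.

    Pre-trains the five source checkpoints once, then repeats the
    fine-tune + fuse + evaluate cycle ``n_reps`` times with fresh target
    datasets and fine-tuning seeds. Returns the concatenated per-rep
    tables with a ``rep`` column.
    """
    workdir = Path(tempfile.mkdtemp(prefix="marginseg_ens_"))
    epochs_pretrain = suite_kw.pop("epochs_pretrain", 20)
    checkpoints = {}
    for variant in MODEL_VARIANTS:
        ckpt = workdir / f"source_{variant}.npz"
        pretrain_source(variant, ckpt, seed=seed + 1, epochs=epochs_pretrain)
        checkpoints[variant] = ckpt
    tables = []
    for rep in range(n_reps):
        nets, splits = train_variant_suite(
            seed=seed * 10 + rep, checkpoints=checkpoints, **suite_kw
        )
        table = run_ensemble_experiment(nets, splits, seed=seed * 10 + rep)
        table["rep"] = rep
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


# -- loss-geometry and generator studies (no training involved) --------------


def margin_sensitivity_study(n_phantoms: int = 100, seed: int = 0) -> pd.DataFrame:
    """Erase equal tumor areas at the top vs the bottom; compare loss changes.

    For each phantom the prediction starts as a perfect binary copy of the
    mask; one variant erases the foreground pixels of the top 10% of tumor
    rows, the other erases an equal *pixel count* from the bottom upward.
    GWDice should penalize the top erasure more in every instance, while
    GenDice cannot tell the two apart.
    """
    master = np.random.default_rng(seed)
    spec = desk_spec("target", 1, seed=seed)
    rows = []
    for _ in range(n_phantoms):
        _, mask = generate_phantom(spec, patient_seed=int(master.integers(0, 2**31 - 1)))
        t_rows = np.nonzero(mask.any(axis=1))[0]
        n_top_rows = max(1, int(np.ceil(0.1 * t_rows.size)))
        top_rows = t_rows[:n_top_rows]
        area = int(mask[top_rows].sum())

        top_pred = mask.astype(float).copy()
        top_pred[top_rows] = 0.0

        fg = np.argwhere(mask > 0)
        order = np.lexsort((fg[:, 1], -fg[:, 0]))  # bottom-most first
        bottom_pred = mask.astype(float).copy()
        for r, c in fg[order][:area]:
            bottom_pred[r, c] = 0.0

        gwm = gradient_weight_mask(mask)
        base_gw = gw_dice_loss(mask, gwm, mask.astype(float))
        base_gen = gen_dice_loss(mask, mask.astype(float))
        rows.append(
            {
                "erased_px": area,
                "gw_top": gw_dice_loss(mask, gwm, top_pred) - base_gw,
                "gw_bottom": gw_dice_loss(mask, gwm, bottom_pred) - base_gw,
                "gen_top": gen_dice_loss(mask, top_pred) - base_gen,
                "gen_bottom": gen_dice_loss(mask, bottom_pred) - base_gen,
            }
        )
    return pd.DataFrame(rows)


def generator_margin_recovery(n_phantoms: int = 500, seed: int = 0) -> dict:
    """Empirical mean/sd of the realized lesion margin over many phantoms."""
    master = np.random.default_rng(seed)
    spec = desk_spec("target", 1, seed=seed)
    tops = []
    for _ in range(n_phantoms):
        _, mask = generate_phantom(spec, patient_seed=int(master.integers(0, 2**31 - 1)))
        top = int(np.nonzero(mask.any(axis=1))[0][0])
        tops.append(top * spec.row_spacing_mm)
    return {
        "mean_mm": float(np.mean(tops)),
        "sd_mm": float(np.std(tops)),
        "spec_mean_mm": spec.margin_mean_mm,
        "spec_sd_mm": spec.margin_sd_mm,
        "n": n_phantoms,
    }


def tradeoff_sweep_study(seed: int = 0, n_images: int = 8):
    """Threshold sweep on the constructed Dice/margin trade-off maps."""
    truths, maps = tradeoff_probability_maps(n_images=n_images, seed=seed)
    thresholds = np.round(np.arange(0.05, 1.0, 0.05), 10)
    return threshold_sweep(truths, maps, thresholds, row_spacing_mm=DESK_ROW_SPACING_MM)
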