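"""End-to-end training of the particle detector.

Optimization follows the detection-transformer recipe: AdamW with a
lower learning rate on the convolutional backbone (1e-5) than on the
transformer and heads (1e-4), weight decay 1e-4, Xavier-initialized
weights, dropout 0.1, and a step schedule that divides both learning
rates by 10 after a fixed epoch (200 of 300 at full scale).  Loss
components (classification NLL, L1, generalized IoU) are recorded
separately per epoch so denoised-vs-raw and backbone-depth comparisons
can be read off the histories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

from cryopick.losses import annotations_to_boxes, batch_hungarian_loss, hungarian_loss
from cryopick.model import (
    ParticleTransformer,
    ModelConfig,
    backbone_forward,
    head_forward,
    init_params,
    model_forward,
    pad_batch,
    save_checkpoint,
)
from cryopick.nn.optim import (
    AdamW,
    clip_grad_norm,
    flatten_params,
    unflatten_params,
)
from cryopick.preprocess import DenoiseConfig, denoise

__all__ = [
    "TrainConfig",
    "initialize_model",
    "train",
    "prepare_dataset",
    "train_valid_test_split",
    "ablation_table",
]


@dataclass
class TrainConfig:
    transformer_lr: float = 1e-4
    backbone_lr: float = 1e-5
    weight_decay: float = 1e-4
    epochs: int = 300
    lr_drop_epoch: int = 200
    lr_drop_factor: float = 10.0
    batch_size: int = 4
    dropout: float = 0.1
    seed: int = 0
    use_denoised_input: bool = True
    backbone_depth: int = 152
    lambda_iou: float = 2.0
    lambda_l1: float = 5.0
    empty_weight: float = 0.1
    clip_grad: float = 0.1
    freeze_backbone_early: bool = False
    freeze_backbone: bool = False  # hold backbone fixed; cache its features
    aux_loss: bool = False  # supervise intermediate decoder layers too
    augment: bool = False  # random dihedral (flip/transpose) augmentation
    input_upscale: int = 1  # bilinear upsampling factor before the backbone

    def __post_init__(self):
        if self.lr_drop_epoch >= self.epochs and self.epochs > 0:
            # a drop scheduled at/after the end simply never fires
            pass
        for name in ("transformer_lr", "backbone_lr", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def initialize_model(model_config: ModelConfig, seed: int = 0) -> ParticleTransformer:
    """Build a model with Xavier-initialized weights (seed-deterministic)."""
    return ParticleTransformer(config=model_config, params=init_params(model_config, seed))


def upscale_pixels(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear upsampling of a micrograph before the backbone.

    Small particles occupy few cells of the 1/32-resolution activation
    map; upsampling the input is the standard detection remedy.  The
    normalized box targets are unaffected.
    """
    if factor == 1:
        return pixels
    from skimage.transform import rescale

    return rescale(pixels.astype(np.float64), factor, order=1,
                   anti_aliasing=False).astype(np.float32)


def prepare_dataset(scenes, denoise_config: DenoiseConfig | None = None,
                    use_denoised: bool = True, input_upscale: int = 1):
    """Turn (Micrograph, annotations) pairs into training samples.

    Samples are ``(pixels, gt_boxes)`` with boxes normalized to the image
    extent.  With ``use_denoised=False`` the denoising chain is skipped
    and only z-score standardization is applied (inputs must still be on
    a sane numeric scale for optimization).
    """
    if use_denoised:
        cfg = denoise_config or DenoiseConfig()
    else:
        cfg = replace(DenoiseConfig.raw(), use_normalize=True)
    samples = []
    for mic, anns in scenes:
        den = denoise(mic, cfg)
        pixels = upscale_pixels(den.pixels, input_upscale)
        samples.append((pixels, annotations_to_boxes(anns, mic.shape)))
    return samples


def train_valid_test_split(items, seed: int = 0,
                           fractions=(0.8, 0.1, 0.1)):
    """Shuffled 80/10/10 (by default) split of a sample or scene list."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    idx = np.random.default_rng(seed).permutation(len(items))
    n_train = int(round(fractions[0] * len(items)))
    n_valid = int(round(fractions[1] * len(items)))
    pick = lambda ids: [items[i] for i in ids]
    return (
        pick(idx[:n_train]),
        pick(idx[n_train : n_train + n_valid]),
        pick(idx[n_train + n_valid :]),
    )


def ablation_table(histories: dict):
    """Comparable final-loss table for ablation runs.

    ``histories`` maps a variant label (e.g. ``"resnet18/denoised"``) to a
    training history; the result has one row per variant with the final
    loss components side by side.
    """
    import pandas as pd

    rows = []
    for label, hist in histories.items():
        last = hist[-1]
        rows.append({
            "variant": label,
            "epochs": len(hist),
            "loss": last["loss"],
            "class_loss": last["class_loss"],
            "l1_loss": last["l1_loss"],
            "giou_loss": last["giou_loss"],
        })
    return pd.DataFrame(rows).set_index("variant")


def _epoch_lr(base: float, epoch: int, cfg: TrainConfig) -> float:
    return base / cfg.lr_drop_factor if epoch >= cfg.lr_drop_epoch else base


def apply_dihedral(pixels: np.ndarray, k: int) -> np.ndarray:
    """One of the 8 axis flips/transposes of a 2-D image (k in 0..7)."""
    if k & 1:
        pixels = pixels[:, ::-1]
    if k & 2:
        pixels = pixels[::-1, :]
    if k & 4:
        pixels = pixels.T
    return np.ascontiguousarray(pixels)


def apply_dihedral_boxes(boxes: np.ndarray, k: int) -> np.ndarray:
    """Matching transform of normalized (cx, cy, w, h) ground truth."""
    b = np.array(boxes, copy=True)
    if b.size == 0:
        return b
    if k & 1:
        b[:, 0] = 1.0 - b[:, 0]
    if k & 2:
        b[:, 1] = 1.0 - b[:, 1]
    if k & 4:
        b = b[:, [1, 0, 3, 2]]
    return b


def _batch_objective(cfg: TrainConfig, model_cfg: ModelConfig, layouts,
                     parts_sink):
    """Objective over the two packed parameter vectors.

    The batch loss is the sum of per-image Hungarian losses normalized by
    the total number of true particles in the batch, which keeps the
    gradient scale independent of batch size and particle density.
    """
    bb_layout, rest_layout = layouts

    def score(out, gt_list):
        total, parts, n_boxes = batch_hungarian_loss(
            gt_list, out["class_logits"], out["boxes"],
            lambda_iou=cfg.lambda_iou, lambda_l1=cfg.lambda_l1,
            empty_weight=cfg.empty_weight)
        for aux_out in out.get("aux", []):
            aux_total, _, _ = batch_hungarian_loss(
                gt_list, aux_out["class_logits"], aux_out["boxes"],
                lambda_iou=cfg.lambda_iou, lambda_l1=cfg.lambda_l1,
                empty_weight=cfg.empty_weight)
            total = total + aux_total
        parts_sink.append(parts / len(gt_list))
        return total / max(n_boxes, 1)

    def objective(vec_backbone, vec_rest, images, sizes, gt_list, dropout_rng,
                  train_mode):
        params = {
            "backbone": unflatten_params(vec_backbone, bb_layout)["backbone"],
            **unflatten_params(vec_rest, rest_layout),
        }
        out = model_forward(params, model_cfg, images, sizes,
                            train=train_mode, dropout_rng=dropout_rng,
                            return_aux=cfg.aux_loss)
        return score(out, gt_list)

    def feature_objective(vec_rest, backbone_params, feats, fsizes, gt_list,
                          dropout_rng, train_mode):
        params = {"backbone": backbone_params,
                  **unflatten_params(vec_rest, rest_layout)}
        out = head_forward(params, model_cfg, feats, fsizes,
                           train=train_mode, dropout_rng=dropout_rng,
                           return_aux=cfg.aux_loss)
        return score(out, gt_list)

    return objective, feature_objective


def evaluate_loss(model: ParticleTransformer, samples, cfg: TrainConfig,
                  batch_size: int | None = None) -> float:
    """Mean per-image Hungarian loss over a dataset in evaluation mode."""
    total, count = 0.0, 0
    bs = batch_size or cfg.batch_size
    for start in range(0, len(samples), bs):
        chunk = samples[start : start + bs]
        images, sizes, _ = pad_batch([s[0] for s in chunk])
        out = model_forward(model.params, model.config, images, sizes)
        for i, (_, gt) in enumerate(chunk):
            lb = hungarian_loss(
                gt, out["class_logits"][i], out["boxes"][i],
                lambda_iou=cfg.lambda_iou, lambda_l1=cfg.lambda_l1,
                empty_weight=cfg.empty_weight,
            )
            total += float(getval(lb.total))
            count += 1
    return total / max(count, 1)


def train(model: ParticleTransformer, samples, config: TrainConfig,
          valid_samples=None, out_dir=None):
    """Optimize the model; returns (model, history).

    ``history`` is one dict per epoch with mean training-loss components
    (and validation loss when a validation set is given).  When
    ``out_dir`` is set, the loss history is written as ``history.csv``,
    the final weights as ``checkpoint.npz`` and — with validation — the
    best-validation weights as ``best.npz``.
    """
    if not samples:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    sink: list = []

    # the training config owns the dropout rate actually applied
    run_model_cfg = replace(model.config, dropout=config.dropout)

    vec_bb, bb_layout = flatten_params({"backbone": model.params["backbone"]})
    rest0 = {k: v for k, v in model.params.items() if k != "backbone"}
    vec_rest, rest_layout = flatten_params(rest0)
    objective, feature_objective = _batch_objective(
        config, run_model_cfg, (bb_layout, rest_layout), sink)
    square = all(s[0].shape[0] == s[0].shape[1] for s in samples)
    n_var = (8 if square else 4) if config.augment else 1

    if config.freeze_backbone:
        vag_feat = value_and_grad(feature_objective, argnum=0)
        # backbone held fixed: run it once per sample (and augmentation
        # variant) and cache the features
        feat_cache: dict = {}
        for k in range(n_var):
            variant = [apply_dihedral(s[0], k) for s in samples]
            for start in range(0, len(samples), config.batch_size):
                chunk = variant[start : start + config.batch_size]
                images, sizes, _ = pad_batch(chunk)
                feats, fsizes = backbone_forward(model.params, images, sizes,
                                                 model.config)
                for j in range(len(chunk)):
                    feat_cache[(start + j, k)] = (feats[j], fsizes[j])
        fshape = {f.shape for f, _ in feat_cache.values()}
        if len(fshape) != 1:
            raise ValueError(
                "freeze_backbone feature caching requires equally sized "
                f"micrographs; saw feature shapes {sorted(fshape)}"
            )
    else:
        vag = value_and_grad(objective, argnum=(0, 1))

    frozen_slices = []
    if config.freeze_backbone_early:
        for name, offset, shape in bb_layout:
            if name.startswith(("backbone.stem", "backbone.layer1")):
                frozen_slices.append((offset, offset + int(np.prod(shape))))

    opt_backbone = AdamW(vec_bb, lr=config.backbone_lr,
                         weight_decay=config.weight_decay)
    opt_rest = AdamW(vec_rest, lr=config.transformer_lr,
                     weight_decay=config.weight_decay)

    def rebuild_params():
        return {
            "backbone": unflatten_params(vec_bb, bb_layout)["backbone"],
            **unflatten_params(vec_rest, rest_layout),
        }

    history: list[dict] = []
    best_val = np.inf
    for epoch in range(config.epochs):
        opt_backbone.lr = _epoch_lr(config.backbone_lr, epoch, config)
        opt_rest.lr = _epoch_lr(config.transformer_lr, epoch, config)
        order = rng.permutation(len(samples))
        epoch_losses = []
        sink.clear()
        variants = (rng.integers(n_var, size=len(samples)) if n_var > 1
                    else np.zeros(len(samples), dtype=int))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            gt_list = [apply_dihedral_boxes(samples[i][1], variants[i])
                       for i in idx]
            drop_rng = np.random.default_rng(rng.integers(2**31))
            if config.freeze_backbone:
                feats = np.stack(
                    [feat_cache[(i, variants[i])][0] for i in idx])
                fsizes = [feat_cache[(i, variants[i])][1] for i in idx]
                loss_val, g_rest = vag_feat(vec_rest, model.params["backbone"],
                                            feats, fsizes, gt_list, drop_rng,
                                            True)
                g_bb = np.zeros_like(vec_bb)
            else:
                pixels = [apply_dihedral(samples[i][0], variants[i])
                          for i in idx]
                images, sizes, _ = pad_batch(pixels)
                loss_val, (g_bb, g_rest) = vag(vec_bb, vec_rest, images, sizes,
                                               gt_list, drop_rng, True)
            loss_val = float(loss_val)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss_val}"
                )
            for lo, hi in frozen_slices:
                g_bb[lo:hi] = 0.0
            if config.clip_grad:
                (g_bb, g_rest), _ = clip_grad_norm([g_bb, g_rest],
                                                   config.clip_grad)
            if not config.freeze_backbone:
                vec_bb = opt_backbone.step(vec_bb, g_bb)
            vec_rest = opt_rest.step(vec_rest, g_rest)
            epoch_losses.append(loss_val)
        model.params = rebuild_params()
        parts = np.mean(sink, axis=0)
        rec = {
            "epoch": epoch,
            "loss": float(np.mean(epoch_losses)),
            "class_loss": float(parts[0]),
            "l1_loss": float(parts[1]),
            "giou_loss": float(parts[2]),
            "lr_transformer": opt_rest.lr,
            "lr_backbone": opt_backbone.lr,
        }
        if valid_samples:
            rec["val_loss"] = evaluate_loss(model, valid_samples, config)
            if out_dir and rec["val_loss"] < best_val:
                best_val = rec["val_loss"]
                save_checkpoint(Path(out_dir) / "best.npz", model,
                                extra={"epoch": epoch, "val_loss": best_val})
        history.append(rec)

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "checkpoint.npz", model,
                        extra={"epoch": config.epochs - 1})
        if history:
            with open(out / "history.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(history[0]))
                writer.writeheader()
                writer.writerows(history)
    return model, history
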