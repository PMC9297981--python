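"""Training: runtime augmentation, MAE/Adam optimization, transfer protocols.

Two training patterns are supported.  ``noFT`` trains a fresh network in a
single stage on the target dataset.  ``FTx`` first trains end-to-end on the
synthetic dataset (the "Synth" model), then freezes everything except the
``x`` deepest symmetric block pairs and retrains on the target data.  The
leave-one-out cross-validation harness fine-tunes the Synth model once per
held-out volume pair.

Checkpoints follow the validation-SSIM-maximum rule: the returned weights are
those of the epoch with the highest validation SSIM, not the last epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import MetricsReport, psnr, ssim, volume_metrics
from .model import NetworkSpec, UNet, set_finetune_scope
from .nn import Adam, mae_loss
from .preprocess import DatasetSplit, SlicePair, build_dataset, denormalize_hu
from .volume import Volume


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 30
    pretrain_epochs: int = 50
    finetune_epochs: int = 30
    patch_size: int = 128
    seed: int = 0
    max_val_slices: int | None = None  # cap validation cost on large splits
    steps_per_epoch: int | None = None  # None: one pass over the training slices
    grad_clip: float | None = 1.0  # global-norm gradient clipping (stability)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must be in (0, 1)")


@dataclass
class TrainingHistory:
    stage: str = "single"  # pretrain | finetune | single
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        if not self.val_ssim:
            return -1
        return int(np.argmax(self.val_ssim))


def augment(pair: SlicePair, seed: int | np.random.Generator, patch_size: int = 128) -> SlicePair:
    """Random crop / 90-degree rotation / horizontal flip, shared across the pair.

    The identical transform is applied to input and label so the pair keeps
    representing the same anatomy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = pair.input_slice.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch {patch_size} larger than slice {pair.input_slice.shape}")
    top = int(rng.integers(0, h - patch_size + 1))
    left = int(rng.integers(0, w - patch_size + 1))
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    out = []
    for s in (pair.input_slice, pair.label_slice):
        p = s[top : top + patch_size, left : left + patch_size]
        p = np.rot90(p, k)
        if flip:
            p = p[:, ::-1]
        out.append(np.ascontiguousarray(p))
    return SlicePair(out[0], out[1], pair.phantom_id, pair.slice_index)


def _clip_gradients(net: UNet, max_norm: float) -> None:
    """Scale all trainable gradients so their global L2 norm <= max_norm."""
    sq = 0.0
    for layer in net.layers:
        if not layer.trainable:
            continue
        for g in layer.grads.values():
            sq += float((g.astype(np.float64) ** 2).sum())
    norm = np.sqrt(sq)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for layer in net.layers:
            if not layer.trainable:
                continue
            for k in layer.grads:
                layer.grads[k] = layer.grads[k] * scale


def _validate(net: UNet, pairs: list[SlicePair], cap: int | None) -> tuple[float, float, float]:
    """MAE / SSIM / PSNR of the network on full un-augmented slices."""
    if not pairs:
        return float("nan"), float("nan"), float("nan")
    use = pairs if cap is None else pairs[:cap]
    losses, ssims, psnrs = [], [], []
    for p in use:
        pred = net.predict(p.input_slice)
        losses.append(float(np.abs(pred - p.label_slice).mean()))
        ssims.append(ssim(p.label_slice, pred))
        psnrs.append(psnr(p.label_slice, pred))
    finite = [v for v in psnrs if np.isfinite(v)] or [float("inf")]
    return float(np.mean(losses)), float(np.mean(ssims)), float(np.mean(finite))


def train_model(
    spec_or_net: NetworkSpec | UNet,
    data: DatasetSplit,
    cfg: TrainConfig,
    epochs: int | None = None,
    stage: str = "single",
) -> tuple[UNet, TrainingHistory]:
    """Minimize MAE on augmented patches with Adam; checkpoint on val SSIM.

    Accepts either a spec (fresh weights) or an existing network (e.g. the
    pretrained Synth model with a fine-tune scope applied).  Fresh
    augmentation is drawn every epoch from a per-epoch seed stream, so the
    network never sees the same patch twice.
    """
    if not data.train:
        raise ValueError("empty training set")
    net = spec_or_net if isinstance(spec_or_net, UNet) else UNet(spec_or_net, seed=cfg.seed)
    n_epochs = cfg.epochs if epochs is None else epochs
    opt = Adam(net.layers, cfg.learning_rate, cfg.beta1, cfg.beta2)
    master = np.random.default_rng(cfg.seed)
    history = TrainingHistory(stage=stage)
    best_state = net.get_state()
    best_ssim = -np.inf
    n_steps = cfg.steps_per_epoch
    if n_steps is None:
        n_steps = int(np.ceil(len(data.train) / cfg.batch_size))
    for epoch in range(n_epochs):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        net.set_dropout_rng(rng)
        losses = []
        for _ in range(n_steps):
            idx = rng.integers(0, len(data.train), cfg.batch_size)
            patches = [augment(data.train[i], rng, cfg.patch_size) for i in idx]
            x = np.stack([p.input_slice for p in patches])
            t = np.stack([p.label_slice for p in patches])[:, None]
            pred = net.forward(x, training=True)
            loss, dy = mae_loss(pred, t)
            net.backward(dy.astype(np.float32))
            if cfg.grad_clip is not None:
                _clip_gradients(net, cfg.grad_clip)
            opt.step()
            losses.append(loss)
        vloss, vssim, vpsnr = _validate(net, data.validation, cfg.max_val_slices)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(vloss)
        history.val_ssim.append(vssim)
        history.val_psnr.append(vpsnr)
        if np.isnan(vssim) or vssim > best_ssim:
            best_ssim = vssim if not np.isnan(vssim) else best_ssim
            best_state = net.get_state()
    net.set_state(best_state)
    return net, history


def run_protocol(
    protocol: str,
    ds_synth: DatasetSplit | None,
    ds_target: DatasetSplit,
    x: int = 2,
    cfg: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
) -> tuple[UNet, list[TrainingHistory]]:
    """Run the ``noFT`` single-stage or ``FTx`` two-stage training pattern.

    ``noFT``: one stage on the target data only.  ``FTx``: end-to-end
    pretraining on the synthetic data, then retraining of the ``x`` deepest
    symmetric block pairs on the target data.
    """
    cfg = cfg or TrainConfig()
    spec = spec or NetworkSpec()
    protocol = protocol.lower()
    if protocol == "noft":
        net, hist = train_model(spec, ds_target, cfg, epochs=cfg.epochs, stage="single")
        return net, [hist]
    if protocol.startswith("ft"):
        if ds_synth is None or not ds_synth.train:
            raise ValueError("FTx requires a non-empty synthetic dataset")
        x = int(protocol[2:]) if protocol[2:].isdigit() else x
        if not (1 <= x <= spec.n_blocks):
            raise ValueError(f"fine-tune scope {x} out of range")
        net, h_pre = train_model(spec, ds_synth, cfg, epochs=cfg.pretrain_epochs, stage="pretrain")
        net.set_finetune_scope(x)
        net, h_ft = train_model(net, ds_target, cfg, epochs=cfg.finetune_epochs, stage="finetune")
        return net, [h_pre, h_ft]
    raise ValueError(f"unknown protocol {protocol!r}")


def _apply_volume(net: UNet, cbct: Volume, pad: int = 256) -> np.ndarray:
    """Run the network over every axial slice of a CBCT volume; returns HU."""
    from .preprocess import crop_slice, normalize_hu, pad_slice

    out = np.empty_like(cbct.values)
    size = cbct.shape[1]
    for k in range(cbct.shape[0]):
        inp = pad_slice(normalize_hu(cbct.values[k]).astype(np.float32), pad)
        pred = net.predict(inp)
        out[k] = denormalize_hu(np.clip(crop_slice(pred, size), 0.0, 1.0))
    return out


def run_loocv(
    pairs: list[tuple[Volume, Volume]],
    base: UNet | dict | None,
    cfg: TrainConfig | None = None,
    x: int = 2,
    spec: NetworkSpec | None = None,
    widths: list[float] | None = None,
    train_fn=None,
    split_seed: int = 0,
) -> list[MetricsReport]:
    """Leave-one-out cross-validation over (CBCT, CT) volume pairs.

    Fold ``i`` fine-tunes the pretrained Synth model (and trains a noFT
    baseline) on every pair except ``i`` and evaluates on pair ``i``.  Per
    fold, median PSNR/SSIM/MAE are reported for the ``Base`` (input CBCT),
    ``noFT`` and ``FTx`` outputs.

    ``train_fn(tag, fold_pairs)`` may replace the actual training (e.g. for
    structural tests); it must return an object with a
    ``predict(slice) -> slice`` method or None to reuse the Base volume.
    """
    if len(pairs) < 2:
        raise ValueError("LOO-CV needs at least 2 pairs")
    cfg = cfg or TrainConfig()
    spec = spec or NetworkSpec()
    reports: list[MetricsReport] = []
    for i, (cbct_i, ct_i) in enumerate(pairs):
        width = widths[i] if widths is not None else None
        train_pairs = [p for j, p in enumerate(pairs) if j != i]
        outputs: dict[str, np.ndarray] = {"Base": cbct_i.values}
        for tag, scope in (("noFT", None), (f"FT{x}", x)):
            if train_fn is not None:
                net = train_fn(tag, train_pairs)
            else:
                ds = build_dataset(train_pairs, seed=split_seed, split_level="volume")
                if scope is None:
                    net, _ = train_model(spec, ds, cfg, epochs=cfg.epochs, stage="single")
                else:
                    if base is None:
                        raise ValueError("FTx folds require the pretrained Synth model")
                    net = UNet(base.spec if isinstance(base, UNet) else spec, seed=cfg.seed)
                    net.set_state(base.get_state() if isinstance(base, UNet) else base)
                    net.set_finetune_scope(scope)
                    net, _ = train_model(net, ds, cfg, epochs=cfg.finetune_epochs, stage="finetune")
            outputs[tag] = cbct_i.values if net is None else _apply_volume(net, cbct_i)
        for tag, vol in outputs.items():
            reports.append(
                volume_metrics(ct_i.values, vol, tag, fold_id=i, phantom_width=width)
            )
    return reports
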