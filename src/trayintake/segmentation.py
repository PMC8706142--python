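"""Joint food/plate segmentation networks and their training loop.

Three architectures are provided behind one interface, all consuming a
single RGB image and emitting one 8-channel food head (background, six food
categories, plate) and — when the plate module is enabled — a parallel
5-channel plate head (background + four container types):

* ``encoder_pspnet`` — a plain five-stack convolutional encoder (stride-2
  stacks down to 1/16 resolution) followed by a pyramid scene-parsing
  module: the feature map is average-pooled to four grids, reduced by 1x1
  convolutions, upsampled and concatenated back onto the feature map before
  decoding to full resolution.
* ``resnet_pspnet`` — the same pyramid module on a residual backbone
  (stride-2 residual blocks with projection skips), randomly initialised.
* ``deeplabv3`` — the residual backbone with atrous spatial pyramid
  pooling: a 1x1 convolution, three 3x3 convolutions at increasing dilation
  rates, and a global image-pooling branch, concatenated and fused by 1x1
  convolution before upsampling.

Networks here are deliberately narrow (default width 8) so that training on
small synthetic scenes runs in minutes on one CPU core; widths, pyramid
grids and input sizes all scale through the config.  Training uses
unweighted per-pixel cross-entropy summed over the active heads and the
Adadelta optimiser, and is bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .labels import N_FOOD_CLASSES, N_PLATE_CLASSES, SegMaskPair
from .nn import Var

__all__ = [
    "SegMaskPair",
    "SegModelConfig",
    "SegModel",
    "build_model",
    "train_model",
    "predict_masks",
    "evaluate_model",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("encoder_pspnet", "resnet_pspnet", "deeplabv3")

#: Pyramid grids for a 30 x 40 feature map (1/16 of a 480 x 640 input);
#: they are rescaled proportionally for other input sizes.
REFERENCE_PYRAMID = ((1, 1), (2, 2), (3, 4), (6, 8))
REFERENCE_FEATURE_HW = (30, 40)


@dataclass
class SegModelConfig:
    architecture: str = "encoder_pspnet"
    with_plate_head: bool = True
    input_hw: tuple[int, int] = (480, 640)
    pyramid_scales: "tuple[tuple[int, int], ...] | None" = None
    optimizer: str = "adadelta"
    batch_size: int = 8
    epochs: int = 100
    pretrain_epochs: int = 20
    seed: int = 0
    width: int = 8
    detach_plate_head: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.epochs > 100:
            raise ValueError("epochs capped at 100")
        if self.input_hw[0] % 16 or self.input_hw[1] % 16:
            raise ValueError("input size must be divisible by 16")

    def feature_hw(self) -> tuple[int, int]:
        return (self.input_hw[0] // 16, self.input_hw[1] // 16)

    def scaled_pyramid(self) -> tuple[tuple[int, int], ...]:
        """Pyramid pooled sizes scaled proportionally to the feature map."""
        if self.pyramid_scales is not None:
            return tuple(self.pyramid_scales)
        fh, fw = self.feature_hw()
        rh, rw = REFERENCE_FEATURE_HW
        out = []
        for ph, pw in REFERENCE_PYRAMID:
            sh = max(1, min(fh, int(round(ph * fh / rh))))
            sw = max(1, min(fw, int(round(pw * fw / rw))))
            out.append((sh, sw))
        # keep the coarse-to-fine ladder strictly increasing where possible
        dedup = []
        for s in out:
            if s not in dedup:
                dedup.append(s)
        return tuple(dedup)


class SegModel:
    """A parameterised segmentation network (weights + forward graph)."""

    def __init__(self, cfg: SegModelConfig):
        self.cfg = cfg
        self.params: dict[str, Var] = {}
        self._rng = np.random.default_rng(cfg.seed)
        w = cfg.width
        arch = cfg.architecture

        if arch == "encoder_pspnet":
            # five stacks of convolutions; stride-2 from the second stack
            chans = [(3, w, 1), (w, 2 * w, 2), (2 * w, 2 * w, 2), (2 * w, 4 * w, 2), (4 * w, 4 * w, 2)]
            for i, (ci, co, s) in enumerate(chans):
                self._add_conv(f"enc{i}", ci, co, 3)
            self._enc_strides = [s for _, _, s in chans]
            feat_c = 4 * w
        else:
            self._add_conv("stem", 3, w, 3)
            blocks = [(w, w, 2), (w, 2 * w, 2), (2 * w, 4 * w, 2), (4 * w, 4 * w, 1)]
            for i, (ci, co, s) in enumerate(blocks):
                self._add_conv(f"res{i}_a", ci, co, 3)
                self._add_conv(f"res{i}_b", co, co, 3)
                self._add_conv(f"res{i}_proj", ci, co, 1)
            self._res_blocks = blocks
            feat_c = 4 * w
        self.feat_c = feat_c

        if arch in ("encoder_pspnet", "resnet_pspnet"):
            scales = cfg.scaled_pyramid()
            for i, _ in enumerate(scales):
                self._add_conv(f"pyr{i}", feat_c, w, 1)
            fused_c = feat_c + w * len(scales)
            self._build_decoder("food", fused_c, N_FOOD_CLASSES)
            if cfg.with_plate_head:
                self._build_decoder("plate", fused_c, N_PLATE_CLASSES)
        else:  # deeplabv3: atrous spatial pyramid pooling
            self._add_conv("aspp_1x1", feat_c, w, 1)
            for i, d in enumerate((1, 2, 3)):
                self._add_conv(f"aspp_d{i}", feat_c, w, 3)
            self._aspp_dilations = (1, 2, 3)
            self._add_conv("aspp_pool", feat_c, w, 1)
            fused_c = 5 * w
            self._add_conv("aspp_fuse", fused_c, 2 * w, 1)
            self._build_decoder("food", 2 * w, N_FOOD_CLASSES)
            if cfg.with_plate_head:
                self._build_decoder("plate", 2 * w, N_PLATE_CLASSES)

    # -- construction helpers ------------------------------------------------

    def _add_conv(self, name: str, cin: int, cout: int, k: int) -> None:
        fan_in = cin * k * k
        self.params[f"{name}.w"] = Var(nn.he_init(self._rng, (cout, cin, k, k), fan_in))
        self.params[f"{name}.b"] = Var(np.zeros(cout, dtype=np.float32))

    def _build_decoder(self, head: str, cin: int, cout: int) -> None:
        w = self.cfg.width
        self._add_conv(f"{head}_dec0", cin, 2 * w, 3)
        self._add_conv(f"{head}_dec1", 2 * w, w, 3)
        self._add_conv(f"{head}_out", w, cout, 1)

    def _conv(self, name: str, x: Var, stride: int = 1, dilation: int = 1) -> Var:
        return nn.conv2d(
            x, self.params[f"{name}.w"], self.params[f"{name}.b"], stride, dilation
        )

    # -- forward -------------------------------------------------------------

    def _backbone(self, x: Var) -> Var:
        if self.cfg.architecture == "encoder_pspnet":
            for i, s in enumerate(self._enc_strides):
                x = nn.relu(self._conv(f"enc{i}", x, stride=s))
            return x
        x = nn.relu(self._conv("stem", x, stride=2))
        for i, (ci, co, s) in enumerate(self._res_blocks):
            y = nn.relu(self._conv(f"res{i}_a", x, stride=s))
            y = self._conv(f"res{i}_b", y)
            skip = self._conv(f"res{i}_proj", x, stride=s)
            x = nn.relu(nn.add(y, skip))
        return x

    def _psp_module(self, feat: Var) -> Var:
        fh, fw = feat.value.shape[2:]
        branches = [feat]
        for i, (ph, pw) in enumerate(self.cfg.scaled_pyramid()):
            p = nn.adaptive_avg_pool(feat, (ph, pw))
            p = nn.relu(self._conv(f"pyr{i}", p))
            branches.append(nn.upsample_nearest(p, (fh, fw)))
        return nn.concat(branches)

    def _aspp_module(self, feat: Var) -> Var:
        fh, fw = feat.value.shape[2:]
        branches = [nn.relu(self._conv("aspp_1x1", feat))]
        for i, d in enumerate(self._aspp_dilations):
            branches.append(nn.relu(self._conv(f"aspp_d{i}", feat, dilation=d)))
        pooled = nn.adaptive_avg_pool(feat, (1, 1))
        pooled = nn.relu(self._conv("aspp_pool", pooled))
        branches.append(nn.upsample_nearest(pooled, (fh, fw)))
        fused = nn.concat(branches)
        return nn.relu(self._conv("aspp_fuse", fused))

    def _decode(self, head: str, fused: Var) -> Var:
        # staged resize-convolution decoder: 3x3 refinement at 1/16 and 1/4,
        # final 1x1 classifier at full resolution
        h, w_ = self.cfg.input_hw
        x = nn.relu(self._conv(f"{head}_dec0", fused))
        x = nn.upsample_bilinear(x, (h // 4, w_ // 4))
        x = nn.relu(self._conv(f"{head}_dec1", x))
        x = nn.upsample_bilinear(x, (h, w_))
        return self._conv(f"{head}_out", x)

    def forward(self, images: np.ndarray) -> tuple[Var, "Var | None"]:
        """images: N x 3 x H x W float32 in [-0.5, 0.5]; returns head logits."""
        if images.shape[2:] != tuple(self.cfg.input_hw):
            raise ValueError(
                f"input size {images.shape[2:]} does not match config {self.cfg.input_hw}"
            )
        x = Var(images, requires_grad=False)
        feat = self._backbone(x)
        fused = self._psp_module(feat) if self.cfg.architecture != "deeplabv3" else self._aspp_module(feat)
        food = self._decode("food", fused)
        plate = None
        if self.cfg.with_plate_head:
            plate_in = nn.detach(fused) if self.cfg.detach_plate_head else fused
            plate = self._decode("plate", plate_in)
        return food, plate

    def param_list(self) -> list[Var]:
        return [self.params[k] for k in sorted(self.params)]


def build_model(cfg: SegModelConfig) -> SegModel:
    """Construct a randomly initialised network from its config."""
    return SegModel(cfg)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    arr = np.stack([im.astype(np.float32) / 255.0 - 0.5 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train_model(
    model: SegModel,
    train_set: list[tuple[np.ndarray, SegMaskPair]],
    cfg: "SegModelConfig | None" = None,
    pretrain_set: "list[tuple[np.ndarray, SegMaskPair]] | None" = None,
) -> dict:
    """Train with per-pixel cross-entropy (summed over heads) and Adadelta.

    With a ``pretrain_set``, the model first trains ``cfg.pretrain_epochs``
    epochs on it, then fine-tunes ``cfg.epochs`` epochs on ``train_set``.
    Returns the loss history; deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    if not train_set:
        raise ValueError("empty training set")
    for rgb, masks in train_set:
        if rgb.shape[:2] != masks.food_mask.shape:
            raise ValueError("mask shape does not match frame")
    if cfg.optimizer != "adadelta":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")

    opt = nn.Adadelta(model.param_list())
    rng = np.random.default_rng(cfg.seed + 1)
    history: dict = {"loss": [], "phase": [], "pixel_accuracy": []}

    phases = []
    if pretrain_set:
        phases.append(("pretrain", pretrain_set, cfg.pretrain_epochs))
    phases.append(("train", train_set, cfg.epochs))

    for phase_name, data, n_epochs in phases:
        images = _to_batch([rgb for rgb, _ in data])
        foods = np.stack([m.food_mask for _, m in data]).astype(np.int64)
        plates = np.stack([m.plate_mask for _, m in data]).astype(np.int64)
        n = len(data)
        for _ in range(n_epochs):
            order = rng.permutation(n)
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                opt.zero_grad()
                food_logits, plate_logits = model.forward(images[sel])
                loss, acc = nn.softmax_cross_entropy(food_logits, foods[sel])
                if plate_logits is not None:
                    ploss, _ = nn.softmax_cross_entropy(plate_logits, plates[sel])
                    loss = nn.add(loss, ploss)
                nn.backward(loss)
                opt.step()
                ep_loss += float(loss.value)
                ep_acc += acc
                n_batches += 1
            history["loss"].append(ep_loss / n_batches)
            history["pixel_accuracy"].append(ep_acc / n_batches)
            history["phase"].append(phase_name)
    return history


def predict_masks(model: SegModel, frame) -> SegMaskPair:
    """Argmax over each head's channels (ties resolve to the lowest class)."""
    rgb = frame.rgb if hasattr(frame, "rgb") else np.asarray(frame)
    if rgb.shape[:2] != tuple(model.cfg.input_hw):
        raise ValueError(
            f"frame size {rgb.shape[:2]} does not match config {model.cfg.input_hw}"
        )
    food_logits, plate_logits = model.forward(_to_batch([rgb]))
    food = food_logits.value[0].argmax(axis=0).astype(np.uint8)
    if plate_logits is not None:
        plate = plate_logits.value[0].argmax(axis=0).astype(np.uint8)
    else:
        plate = np.zeros_like(food)
    return SegMaskPair(food_mask=food, plate_mask=plate)


def evaluate_model(
    model: SegModel,
    data: list[tuple[np.ndarray, SegMaskPair]],
    include_background: bool = False,
) -> dict:
    """Mean IoU / accuracy of the food head (and plate head) over a dataset."""
    from .seg_metrics import mean_accuracy, mean_iou

    food_iou, food_acc, plate_iou = [], [], []
    for rgb, gt in data:
        pred = predict_masks(model, rgb)
        food_iou.append(mean_iou(gt.food_mask, pred.food_mask, include_background=include_background))
        food_acc.append(mean_accuracy(gt.food_mask, pred.food_mask, include_background=include_background))
        if model.cfg.with_plate_head:
            plate_iou.append(mean_iou(gt.plate_mask, pred.plate_mask, include_background=include_background))
    out = {
        "food_mean_iou": float(np.mean(food_iou)),
        "food_mean_accuracy": float(np.mean(food_acc)),
    }
    if plate_iou:
        out["plate_mean_iou"] = float(np.mean(plate_iou))
    return out


def save_model(model: SegModel, path: str | Path) -> None:
    payload = {
        "config": asdict(model.cfg),
        "weights": {k: v.value for k, v in model.params.items()},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> SegModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg_d = payload["config"]
    cfg_d["input_hw"] = tuple(cfg_d["input_hw"])
    if cfg_d.get("pyramid_scales") is not None:
        cfg_d["pyramid_scales"] = tuple(map(tuple, cfg_d["pyramid_scales"]))
    model = SegModel(SegModelConfig(**cfg_d))
    for k, v in payload["weights"].items():
        model.params[k].value = v.astype(np.float32)
    return model
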