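"""Training loop, augmentation and bookkeeping for both U-nets.

Training samples random square patches from the image pairs, augments
each sample with a random element of the dihedral group (flips and
rotations by multiples of 90 degrees, identical transform for input and
target), and runs Adam minibatch steps.  At full scale the enhancement
network uses learning rate 1e-4, batch 16, lambda_tv 0.03; the
segmentation network uses 1e-5, batch 20 and class weights (1, 2, 1).
Full-scale iteration counts (604k / 80k) are far beyond a desktop CPU;
the reduced configs used in tests exercise the identical code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import losses
from .layers import Adam
from .unet import UNet, UNetConfig, build_unet


@dataclass(frozen=True)
class TrainConfig:
    task: str = "enhance"  # enhance | segment
    learning_rate: float = 1e-4
    batch_size: int = 16
    iterations: int = 604_000
    lambda_tv: float = 0.03
    class_weights: tuple[float, float, float] = losses.DEFAULT_CLASS_WEIGHTS
    patch: int = 128
    seed: int = 0
    log_every: int = 10

    def __post_init__(self):
        if self.task not in ("enhance", "segment"):
            raise ValueError("task must be 'enhance' or 'segment'")
        if self.learning_rate <= 0 or self.lambda_tv < 0:
            raise ValueError("invalid TrainConfig")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


# Full-scale configurations matching the published training recipes.
ENHANCE_FULL = TrainConfig(task="enhance", learning_rate=1e-4, batch_size=16,
                           iterations=604_000, lambda_tv=0.03, patch=128)
SEGMENT_FULL = TrainConfig(task="segment", learning_rate=1e-5, batch_size=20,
                           iterations=80_000, patch=128)


@dataclass
class TrainLog:
    iterations: int
    losses: list = field(default_factory=list)  # (iteration, loss)
    epoch_equivalent: float = 0.0

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.losses, columns=["iteration", "loss"]).assign(
            epoch_equivalent=self.epoch_equivalent
        ).to_csv(path, index=False)


def epoch_equivalent(iterations: int, batch_size: int,
                     n_images: int | None = None,
                     image_side: float | None = None,
                     patch_side: float | None = None,
                     n_patches: int | None = None) -> float:
    """Epochs implied by iteration count and dataset size.

    For whole-image datasets an image counts as ``(image_side /
    patch_side)**2`` fractional patches; for pre-cut patch datasets pass
    ``n_patches`` directly.
    """
    if iterations < 0 or batch_size <= 0:
        raise ValueError("iterations >= 0 and batch_size > 0 required")
    if n_patches is not None:
        denom = n_patches
    else:
        if not (n_images and image_side and patch_side):
            raise ValueError("need n_images, image_side, patch_side or n_patches")
        denom = n_images * (image_side / patch_side) ** 2
    return iterations * batch_size / denom


def _dihedral(arr: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(arr, k, axes=(0, 1))
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(batch, rng: np.random.Generator):
    """Random flip/rot90 augmentation of a list of (input, target) pairs.

    Both members of a pair receive the identical transform; patches must
    be square.
    """
    out = []
    for x, t in batch:
        if x.shape[0] != x.shape[1]:
            raise ValueError("augmentation requires square patches")
        k = int(rng.integers(4))
        flip = bool(rng.integers(2))
        out.append((_dihedral(x, k, flip), _dihedral(t, k, flip)))
    return out


def _sample_patch(img, target, patch, rng):
    h, w = img.shape[:2]
    if h < patch or w < patch:
        raise ValueError("image smaller than the training patch")
    r = int(rng.integers(0, h - patch + 1))
    c = int(rng.integers(0, w - patch + 1))
    return img[r:r + patch, c:c + patch], target[r:r + patch, c:c + patch]


def _to_nchw(stack):
    return np.stack([np.moveaxis(a, -1, 0) for a in stack])


def train(net: UNet, dataset, cfg: TrainConfig):
    """Run ``cfg.iterations`` Adam steps on random augmented crops.

    ``dataset`` is a list of (input HWC, target) pairs; for the
    segmentation task targets are integer label masks (HW).  Returns the
    trained network and a :class:`TrainLog`; raises if the loss becomes
    non-finite.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), cfg.learning_rate)
    side = dataset[0][0].shape[0]
    log = TrainLog(iterations=cfg.iterations)
    log.epoch_equivalent = epoch_equivalent(
        cfg.iterations, cfg.batch_size, n_images=len(dataset),
        image_side=side, patch_side=cfg.patch)

    for it in range(cfg.iterations):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        batch = [_sample_patch(*dataset[i], cfg.patch, rng) for i in idx]
        batch = augment(batch, rng)
        x = _to_nchw([b[0] for b in batch])
        out = net.forward(x)

        if cfg.task == "enhance":
            z = _to_nchw([b[1] for b in batch])
            loss = 0.0
            gout = np.empty_like(out)
            for n in range(out.shape[0]):
                g_hwc = np.moveaxis(out[n], 0, -1)
                z_hwc = np.moveaxis(z[n], 0, -1)
                loss += losses.enhancement_loss(z_hwc, g_hwc, cfg.lambda_tv)
                gout[n] = np.moveaxis(
                    losses.enhancement_loss_grad(z_hwc, g_hwc, cfg.lambda_tv),
                    -1, 0)
            loss /= out.shape[0]
            gout /= out.shape[0]
        else:
            loss = 0.0
            gout = np.empty_like(out)
            for n in range(out.shape[0]):
                y_hwc = np.moveaxis(out[n], 0, -1)
                a = losses.one_hot(batch[n][1], out.shape[1])
                loss += losses.weighted_ce_from_logits(a, y_hwc, cfg.class_weights)
                gout[n] = np.moveaxis(
                    losses.weighted_ce_logits_grad(a, y_hwc, cfg.class_weights),
                    -1, 0)
            loss /= out.shape[0]
            gout /= out.shape[0]

        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}")
        if it % cfg.log_every == 0 or it == cfg.iterations - 1:
            log.losses.append((it, float(loss)))
        net.backward(gout)
        opt.step()
    return net, log


def predict(net: UNet, image: np.ndarray) -> np.ndarray:
    """Apply the network to one HWC image of arbitrary valid size."""
    x = np.moveaxis(image, -1, 0)[None]
    out = net.forward(x)[0]
    return np.moveaxis(out, 0, -1)


def save_checkpoint(net: UNet, path, train_cfg: TrainConfig | None = None):
    """Weights as npz plus a JSON sidecar with the configs."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(net.parameters())}
    np.savez(path, **arrays)
    sidecar = {"unet": asdict(net.cfg)}
    if train_cfg is not None:
        sidecar["train"] = asdict(train_cfg)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    unet_cfg = sidecar["unet"]
    unet_cfg.pop("class_weights", None)  # tolerate older sidecars
    net = build_unet(UNetConfig(**unet_cfg))
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        for i, p in enumerate(net.parameters()):
            p.value[...] = data[f"p{i}"]
    return net
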