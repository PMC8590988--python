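"""Dual-view MIP localizer: existence classification + 3-D box regression.

The network consumes the anterior and lateral 224x224 MIP images of a
whole-body scan.  Both views pass through one shared convolutional
backbone; the two feature vectors are concatenated, pass through a
fully connected layer, and feed two heads: a sigmoid existence
probability ``p`` (does the scan contain the entire brain?) and a
6-vector of normalized box coordinates ``(min_x, min_y, min_z, size_x,
size_y, size_z)``.

Training minimizes the composite loss

    L = alpha * BCE(Y, p) + beta * Y * sum_j (y_j - yhat_j)^2

so the box term is gated off for scans whose whole-brain label ``Y``
is 0 (they have no box to regress).  Defaults alpha=10, beta=1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import boxes, nn, projection
from .volume import Volume

EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    fc_dim: int = 4096
    channels: tuple[int, ...] = (8, 16, 32, 32)
    input_pool: int = 4

    def __post_init__(self):
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.fc_dim < 16:
            raise ValueError("fc_dim must be >= 16")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale preset: narrow fully connected layer."""
        return cls(fc_dim=256)


@dataclass(frozen=True)
class TrainConfig:
    alpha: float = 10.0
    beta: float = 1.0
    learning_rate: float = 1e-5
    epochs: int = 150
    batch_size: int = 8
    seed: int = 0
    validation_fraction: float = 0.1
    restore_best: bool = True  # return the best-validation-loss checkpoint
    augment: bool = True
    augment_params: projection.AugmentParams = field(default_factory=projection.AugmentParams)

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 120) -> "TrainConfig":
        """Profile for training the small backbone from scratch on CPU.

        The documented defaults mirror fine-tuning a large pretrained
        backbone (lr 1e-5, 150 epochs, augmentation on).  Training the
        compact backbone from random init needs a larger step size, and
        on a fully randomized synthetic cohort the geometric/intensity
        augmentations are redundant regularization that slows
        convergence, so this profile uses lr 1e-3, 120 epochs and no
        augmentation.  See docs/methods.md.
        """
        return cls(learning_rate=1e-3, epochs=epochs, augment=False, seed=seed)

    @classmethod
    def overfit(cls, seed: int = 0, epochs: int = 150) -> "TrainConfig":
        """Memorization regime: final weights kept, no best-val restore."""
        return cls(learning_rate=1e-3, epochs=epochs, augment=False, seed=seed,
                   restore_best=False)


@dataclass
class ModelOutput:
    p_exist: float
    box_vector: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.p_exist <= 1.0):
            raise ValueError("p_exist must lie in [0, 1]")


@dataclass
class Sample:
    """One training/evaluation record: preprocessed MIP pair + labels."""

    anterior: projection.MIPImage
    lateral: projection.MIPImage
    exists: bool
    box_vector: np.ndarray | None  # normalized 6-vector, None when absent
    grid_shape: tuple[int, int, int]
    truth_box: boxes.Box3D | None = None


def make_sample(volume: Volume, truth) -> Sample:
    ant = projection.preprocess(projection.mip(volume, projection.ANTERIOR))
    lat = projection.preprocess(projection.mip(volume, projection.LATERAL))
    vec = None
    if truth.whole_brain_present:
        vec = boxes.encode(truth.brain_box, volume.shape)
    return Sample(ant, lat, truth.whole_brain_present, vec, volume.shape,
                  truth.brain_box if truth.whole_brain_present else None)


def make_dataset(cohort) -> list[Sample]:
    return [make_sample(vol, truth) for vol, truth in cohort]


class DualViewModel:
    """Shared-backbone dual-view CNN with existence and box heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        blocks: list[nn.Layer] = [nn.AvgPool(config.input_pool)]
        side = projection.TARGET_SIZE // config.input_pool
        cin = 1
        for i, cout in enumerate(config.channels):
            blocks += [nn.Conv3x3(cin, cout, rng), nn.ReLU()]
            if i < len(config.channels) - 1:
                blocks.append(nn.MaxPool2())
                side //= 2
            cin = cout
        blocks.append(nn.Flatten())
        self.backbone = nn.Sequential(*blocks)
        feat = cin * side * side
        self.fc = nn.Linear(2 * feat, config.fc_dim, rng)
        self.fc_relu = nn.ReLU()
        self.head_exist = nn.Linear(config.fc_dim, 1, rng)
        self.head_box = nn.Linear(config.fc_dim, 6, rng)
        self._heads = [self.fc, self.head_exist, self.head_box]
        self.params = self.backbone.params + [p for l in self._heads for p in l.params]
        self.grads = self.backbone.grads + [g for l in self._heads for g in l.grads]

    # -- forward / backward ------------------------------------------
    def forward(self, ant: np.ndarray, lat: np.ndarray, train: bool = False):
        """ant/lat: (N, 224, 224) in [0, 255].  Returns (p, box) arrays."""
        n = ant.shape[0]
        x = np.concatenate([ant, lat], axis=0)[:, None, :, :].astype(np.float32) / 255.0
        f = self.backbone.forward(x, train=train)
        feat = np.concatenate([f[:n], f[n:]], axis=1)
        h = self.fc_relu.forward(self.fc.forward(feat, train=train), train=train)
        ze = self.head_exist.forward(h, train=train)
        zb = self.head_box.forward(h, train=train)
        p = nn.sigmoid(ze[:, 0])
        b = nn.sigmoid(zb)
        return p, b

    def backward(self, gze: np.ndarray, gzb: np.ndarray) -> None:
        """Backprop from gradients w.r.t. the two head pre-activations."""
        gh = self.head_exist.backward(gze) + self.head_box.backward(gzb)
        gfeat = self.fc.backward(self.fc_relu.backward(gh))
        half = gfeat.shape[1] // 2
        gf = np.concatenate([gfeat[:, :half], gfeat[:, half:]], axis=0)
        self.backbone.backward(gf)

    # -- persistence -------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "DualViewModel":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            cfg_dict["channels"] = tuple(cfg_dict["channels"])
            model = cls(ModelConfig(**cfg_dict))
            for i, p in enumerate(model.params):
                p[...] = data[f"p{i}"]
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> DualViewModel:
    return DualViewModel(config or ModelConfig(), seed=seed)


# -- loss -------------------------------------------------------------

def loss_total(p_exist, box_pred, y_true, box_true, alpha: float = 10.0,
               beta: float = 1.0) -> float:
    """Composite loss, averaged over the batch.

    ``box_true`` rows for absent-brain samples are ignored (gated by
    ``y_true``); pass zeros there.  Probabilities are clamped to
    [eps, 1-eps] before the log.
    """
    p = np.clip(np.atleast_1d(np.asarray(p_exist, dtype=np.float64)), EPS, 1.0 - EPS)
    y = np.atleast_1d(np.asarray(y_true, dtype=np.float64))
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    bp = np.atleast_2d(np.asarray(box_pred, dtype=np.float64))
    bt = np.atleast_2d(np.asarray(box_true, dtype=np.float64))
    sq = y * np.sum((bt - bp) ** 2, axis=1)
    return float(np.mean(alpha * bce + beta * sq))


def _augmented_batch(samples, cfg: TrainConfig, rng: np.random.Generator):
    """Assemble one batch, applying shared-geometry augmentation."""
    ants, lats, ys, bvecs = [], [], [], []
    ap = cfg.augment_params
    for s in samples:
        if cfg.augment:
            sc = rng.uniform(*ap.scale)
            t_row = rng.uniform(-ap.translate_px, ap.translate_px)
            t_ca = rng.uniform(-ap.translate_px, ap.translate_px)
            t_cl = rng.uniform(-ap.translate_px, ap.translate_px)
            seed_a = int(rng.integers(2**31 - 1))
            seed_l = int(rng.integers(2**31 - 1))
            ant = projection.augment(s.anterior, seed_a, ap, geometry=(sc, t_row, t_ca))
            lat = projection.augment(s.lateral, seed_l, ap, geometry=(sc, t_row, t_cl))
            vec = None
            if s.box_vector is not None:
                vec = transform_box_vector(
                    s.anterior, s.lateral, s.box_vector, sc, t_row, t_ca, t_cl
                )
            ants.append(ant.pixels)
            lats.append(lat.pixels)
            bvecs.append(np.zeros(6) if vec is None else vec)
        else:
            ants.append(s.anterior.pixels)
            lats.append(s.lateral.pixels)
            bvecs.append(np.zeros(6) if s.box_vector is None else s.box_vector)
        ys.append(float(s.exists))
    return (np.stack(ants), np.stack(lats), np.asarray(ys, dtype=np.float64),
            np.stack(bvecs).astype(np.float64))


def transform_box_vector(ant, lat, vec, s, t_row, t_col_ant, t_col_lat) -> np.ndarray:
    """Map a normalized 6-vector through the scale+translate augmentation.

    The augmentation acts in preprocessed-pixel space; the box is
    carried endpoint-wise through voxel -> pixel -> augmented pixel ->
    voxel for each axis (x via the anterior columns, y via the lateral
    columns, z via the shared rows, which flip superior-side-up).
    """
    vec = np.asarray(vec, dtype=float)
    nx, ny, nz = ant.volume_shape
    out = np.empty(6)

    def _axis(mip_img, ax_idx, n, extent_idx, t_col):
        pad = mip_img.pad_before[1]
        k = mip_img.scale[1]
        e0 = vec[ax_idx] * n
        e1 = (vec[ax_idx] + vec[extent_idx]) * n
        p0 = projection._src_to_px(e0, pad, k)
        p1 = projection._src_to_px(e1, pad, k)
        q0 = projection.transform_point((0.0, p0), s, (0.0, t_col))[1]
        q1 = projection.transform_point((0.0, p1), s, (0.0, t_col))[1]
        v0 = projection._px_to_src(q0, pad, k)
        v1 = projection._px_to_src(q1, pad, k)
        return v0 / n, (v1 - v0) / n

    out[0], out[3] = _axis(ant, 0, nx, 3, t_col_ant)
    out[1], out[4] = _axis(lat, 1, ny, 4, t_col_lat)

    # z runs through the flipped row axis, shared between views
    pad = ant.pad_before[0]
    k = ant.scale[0]
    z0 = vec[2] * nz
    z1 = (vec[2] + vec[5]) * nz
    r0 = projection._src_to_px(nz - 1 - z1, pad, k)
    r1 = projection._src_to_px(nz - 1 - z0, pad, k)
    q0 = projection.transform_point((r0, 0.0), s, (t_row, 0.0))[0]
    q1 = projection.transform_point((r1, 0.0), s, (t_row, 0.0))[0]
    w1 = nz - 1 - projection._px_to_src(q0, pad, k)
    w0 = nz - 1 - projection._px_to_src(q1, pad, k)
    out[2], out[5] = w0 / nz, (w1 - w0) / nz
    return np.clip(out, 0.0, 1.0)


def train(dataset: list[Sample], model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None):
    """Train the dual-view model; returns (model, history DataFrame).

    A seeded ``validation_fraction`` of the data is held out; the
    checkpoint with the best validation loss is restored at the end.
    """
    import logging

    log = logging.getLogger(__name__)
    cfg = train_config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    labels = {s.exists for s in dataset}
    if len(labels) < 2:
        log.warning("training data contains a single existence class: %s", labels)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(cfg.validation_fraction * len(dataset)))) \
        if len(dataset) > 1 else 0
    val = [dataset[i] for i in order[:n_val]]
    tr = [dataset[i] for i in order[n_val:]]

    model = DualViewModel(model_config or ModelConfig(), seed=int(rng.integers(2**31 - 1)))
    opt = nn.Adam(model.params, model.grads, lr=cfg.learning_rate)

    best = (np.inf, None)
    rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(tr), cfg.batch_size):
            batch = [tr[i] for i in perm[start : start + cfg.batch_size]]
            ant, lat, y, bt = _augmented_batch(batch, cfg, rng)
            p, b = model.forward(ant, lat, train=True)
            losses.append(loss_total(p, b, y, bt, cfg.alpha, cfg.beta))
            m = len(batch)
            gze = (cfg.alpha * (p - y) / m)[:, None]
            gzb = cfg.beta * y[:, None] * 2.0 * (b - bt) * b * (1.0 - b) / m
            model.backward(gze.astype(np.float32), gzb.astype(np.float32))
            opt.step()
        row = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val:
            vm = evaluate(model, val, alpha=cfg.alpha, beta=cfg.beta)
            row.update(
                val_loss=vm["loss"], val_accuracy=vm["accuracy"],
                val_iou_mean=vm["iou_mean"],
            )
            if vm["loss"] < best[0]:
                best = (vm["loss"], [p.copy() for p in model.params])
        rows.append(row)
    if cfg.restore_best and best[1] is not None:
        for p, bp in zip(model.params, best[1]):
            p[...] = bp
    return model, pd.DataFrame(rows)


def predict(model: DualViewModel, volume: Volume, threshold: float = 0.5):
    """Run the full per-scan inference: MIPs -> network -> decision+box.

    Returns ``(ModelOutput, Box3D or None)``; the box (in voxel indices
    of the volume's own grid) is emitted only when ``p >= threshold``.
    """
    sample_ant = projection.preprocess(projection.mip(volume, projection.ANTERIOR))
    sample_lat = projection.preprocess(projection.mip(volume, projection.LATERAL))
    p, b = model.forward(sample_ant.pixels[None], sample_lat.pixels[None], train=False)
    out = ModelOutput(float(p[0]), b[0])
    if out.p_exist < threshold:
        return out, None
    return out, boxes.decode(b[0], volume.shape)


def evaluate(model: DualViewModel, dataset: list[Sample], threshold: float = 0.5,
             alpha: float = 10.0, beta: float = 1.0) -> dict:
    """Existence accuracy plus IOU statistics over true-positive boxes.

    IOU is computed for samples whose label and prediction both say the
    whole brain is present.  Returns a dict with a per-sample report
    DataFrame under ``"report"``.
    """
    ants = np.stack([s.anterior.pixels for s in dataset])
    lats = np.stack([s.lateral.pixels for s in dataset])
    y = np.array([float(s.exists) for s in dataset])
    bt = np.stack([
        np.zeros(6) if s.box_vector is None else s.box_vector for s in dataset
    ])
    p, b = model.forward(ants, lats, train=False)
    pred_exist = p >= threshold
    correct = pred_exist == (y > 0.5)
    ious, rows = [], []
    for i, s in enumerate(dataset):
        iou = np.nan
        if s.exists and pred_exist[i]:
            iou = boxes.iou3d(boxes.decode(b[i], s.grid_shape), s.truth_box)
            ious.append(iou)
        rows.append({
            "index": i, "y_true": int(s.exists), "p_exist": float(p[i]),
            "y_pred": int(pred_exist[i]), "iou": iou,
        })
    return {
        "loss": loss_total(p, b, y, bt, alpha, beta),
        "accuracy": float(np.mean(correct)),
        "iou_mean": float(np.mean(ious)) if ious else np.nan,
        "iou_sd": float(np.std(ious, ddof=1)) if len(ious) > 1 else 0.0,
        "n": len(dataset),
        "report": pd.DataFrame(rows),
    }
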