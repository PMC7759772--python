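"""Configuration-driven training and the end-to-end two-step monitor.

``train`` fits any of the three models on a written phantom (or user)
dataset with the published recipes: classification uses batch 32,
categorical cross-entropy, momentum SGD (lr 1e-4, momentum 0.9), the
table4 augmentation preset and minority-class oversampling; segmentation
uses batch 16, per-pixel MSE on sigmoid outputs, AdaBound (lr 1e-3) and
the table6 preset. Both run for at most 300 epochs with best-validation
checkpointing and early stopping.

``monitor`` composes the trained pieces over one video: per-second
phase/problem probabilities, the moving-average risk trace D_t, the first
threshold crossing as the alert time, and — inside the detected important
phase — segmentation with circumscribed-circle annotations and certainty
overlays. Every second's outputs depend only on frames up to that second.

The ``small`` profile shrinks network widths (width 1/8, growth 8) and
input sizes (151x85 classification, 64x32 segmentation) so the full
pipeline trains on a single CPU in minutes; the full-size architectures
remain the default ``describe`` target.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import augment as aug
from . import nets, nn, phantom, risk as risk_mod, segeval

TASKS = ("phase", "problem", "segmentation")

SMALL_CLS_INPUT = (151, 85, 3)
SMALL_SEG_INPUT = (64, 32, 3)
SMALL_WIDTH_MULT = 0.125
SMALL_GROWTH = 8


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (defaults follow the recipes)."""

    task: str
    batch_size: int = 32
    loss: str = "categorical-cross-entropy"
    optimizer: str = "momentum-sgd"
    lr: float = 1e-4
    momentum: float = 0.9
    max_epochs: int = 300
    patience: int = 10
    augment_preset: str = "table4"
    seed: int = 0
    small: bool = False
    problem_frame_scope: str = "all"     # or "important": train only on critical-phase frames
    frame_stride: int = 1                # temporal subsampling of training frames
    oversample: bool = True
    target_metric: float | None = None   # stop once the validation metric reaches this

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.max_epochs > 300:
            raise ValueError("the recipe caps training at 300 epochs")

    @classmethod
    def for_task(cls, task: str, small: bool = False, **overrides) -> "TrainConfig":
        if task == "segmentation":
            base = dict(task=task, batch_size=16, loss="mean-squared-error",
                        optimizer="adabound", lr=1e-3, oversample=False,
                        augment_preset="table6-small" if small else "table6",
                        frame_stride=4 if small else 1)
        else:
            # The published recipe assumes ImageNet-pretrained weights and a
            # six-figure frame count; the from-scratch reduced profile needs a
            # larger step and quarter-strength augmentation to converge.
            base = dict(task=task, frame_stride=2 if small else 1,
                        lr=1e-2 if small else 1e-4,
                        augment_preset="table4-small" if small else "table4")
        base["small"] = small
        base.update(overrides)
        return cls(**base)

    def hyperparameters(self) -> dict:
        d = asdict(self)
        if self.optimizer != "momentum-sgd":
            d.pop("momentum")
        return d


def _build_model(task: str, small: bool, seed: int, n_classes: int = 2):
    if task == "segmentation":
        shape = SMALL_SEG_INPUT if small else nets.SEG_INPUT_SHAPE
        params = nets.DenseBlockParams(growth=SMALL_GROWTH if small else nets.DEFAULT_GROWTH)
        return nets.build_scse_fc_densenet40(3, shape, params, seed), shape
    shape = SMALL_CLS_INPUT if small else nets.CLS_INPUT_SHAPE
    mult = SMALL_WIDTH_MULT if small else 1.0
    return nets.build_classifier(n_classes, shape, mult, seed), shape


def _resize_frames(frames: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    h, w, _ = shape
    if frames.shape[1:3] == (h, w):
        return frames
    out = np.empty((len(frames), h, w, 3), dtype=np.uint8)
    for i, f in enumerate(frames):
        r = resize(f, (h, w), order=1, preserve_range=True, anti_aliasing=True)
        out[i] = np.clip(r, 0, 255).round().astype(np.uint8)
    return out


def _resize_mask(mask: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    if mask.shape == hw:
        return mask
    r = resize(mask.astype(float), hw, order=0, preserve_range=True)
    return (r >= 0.5).astype(np.uint8)


def save_checkpoint(net, meta: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"arr_{i:05d}": a for i, a in enumerate(nets.state_arrays(net))}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path):
    try:
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            keys = sorted(k for k in z.files if k.startswith("arr_"))
            arrays = [z[k] for k in keys]
    except Exception as exc:  # noqa: BLE001 - any unreadable file is a load error
        raise TrainingError(f"cannot load checkpoint {path}: {exc}") from exc
    net, _ = _build_model(meta["task"], meta["small"], seed=0,
                          n_classes=meta.get("n_classes", 2))
    nets.load_state_arrays(net, arrays)
    return net, meta


@dataclass
class TrainResult:
    checkpoint_path: Path
    log: list[dict]
    best_val_loss: float
    best_val_metric: float
    config: TrainConfig


def _classification_items(seqs, splits, task: str, scope: str, stride: int):
    """(video index, frame index, label) triples per split."""
    by_id = {s.video_id: s for s in seqs}
    items = {}
    for split, vids in splits.items():
        lst = []
        for vid in vids:
            seq = by_id[vid]
            for t in range(0, seq.n_frames, stride):
                if task == "phase":
                    label = int(seq.phase[t] == "important")
                else:
                    if scope == "important" and seq.phase[t] != "important":
                        continue
                    label = int(seq.problem[t])
                lst.append((vid, t, label))
        items[split] = lst
    return items


def train(manifest_path: str | Path, config: TrainConfig,
          out_dir: str | Path | None = None) -> TrainResult:
    """Train one model on a written dataset; returns the best checkpoint.

    Raises TrainingError on a non-finite loss and a ValueError when the
    manifest lacks the required train/val splits.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir) if out_dir else manifest_path.parent / "runs"
    seqs, splits = phantom.load_dataset(manifest_path,
                                        with_masks=config.task == "segmentation")
    for needed in ("train", "val"):
        if not splits.get(needed):
            raise ValueError(f"manifest must provide a nonempty {needed!r} split")
    rng = np.random.default_rng(config.seed)
    preset = aug.PRESETS[config.augment_preset]
    net, in_shape = _build_model(config.task, config.small, config.seed)
    params = net.params()
    if config.optimizer == "momentum-sgd":
        opt = nn.SGDMomentum(params, lr=config.lr, momentum=config.momentum)
    elif config.optimizer == "adabound":
        opt = nn.AdaBound(params, lr=config.lr)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    by_id = {s.video_id: s for s in seqs}
    cache: dict[str, np.ndarray] = {}
    log: list[dict] = []

    if config.task == "segmentation":
        items = {}
        for split, vids in splits.items():
            lst = []
            for vid in vids:
                seq = by_id[vid]
                if seq.masks is None:
                    continue
                if seq.problem_onset is not None:
                    continue  # instrument tracking is trained on problem-free surgeries
                for t in range(0, seq.n_frames, config.frame_stride):
                    if seq.phase[t] == "important":
                        lst.append((vid, t))
            items[split] = lst
        for needed in ("train", "val"):
            if not items.get(needed):
                raise ValueError(
                    f"the {needed!r} split has no important-phase frames from "
                    "problem-free videos with masks; segmentation needs them")
        for vid in {v for lst in items.values() for v, _ in lst}:
            cache[vid] = _resize_frames(by_id[vid].seg_frames, in_shape)

        def batch_arrays(batch, train_mode):
            xs, ys = [], []
            for vid, t in batch:
                img = cache[vid][t]
                mset = by_id[vid].masks[t]
                masks = phantom.MaskSet(*[_resize_mask(getattr(mset, c), in_shape[:2])
                                          for c in phantom.MaskSet.CLASSES])
                if train_mode:
                    img, masks = aug.augment_segmentation(img, masks, preset, rng)
                xs.append(aug.normalize(img))
                ys.append(masks.stacked().astype(np.float32))
            return np.stack(xs), np.stack(ys)

        def eval_split(batch_items):
            losses, ious = [], []
            for i in range(0, len(batch_items), config.batch_size):
                x, y = batch_arrays(batch_items[i: i + config.batch_size], False)
                pred = net.forward(x)
                losses.append(nn.mse_loss(pred, y)[0])
                for b in range(len(x)):
                    ious.append(segeval.iou(segeval.binarize(pred[b, ..., 0]), y[b, ..., 0]))
            return float(np.mean(losses)), float(np.mean(ious))
    else:
        items = _classification_items(seqs, splits, config.task,
                                      config.problem_frame_scope, config.frame_stride)
        if not items["train"] or not items["val"]:
            raise ValueError("train/val splits produced no frames for this task")
        for vid in {v for lst in items.values() for v, _, _ in lst}:
            cache[vid] = _resize_frames(by_id[vid].frames, in_shape)

        def batch_arrays(batch, train_mode):
            xs, ys = [], []
            for vid, t, label in batch:
                img = cache[vid][t]
                if train_mode:
                    img = aug.augment_classification(img, preset, rng)
                xs.append(aug.normalize(img))
                ys.append(label)
            return np.stack(xs), np.asarray(ys)

        def eval_split(batch_items):
            losses, correct = [], 0
            for i in range(0, len(batch_items), config.batch_size):
                x, y = batch_arrays(batch_items[i: i + config.batch_size], False)
                logits = net.forward(x)
                losses.append(nn.cross_entropy_loss(logits, y)[0])
                correct += int((logits.argmax(axis=1) == y).sum())
            return float(np.mean(losses)), correct / len(batch_items)

    best_val = np.inf
    best_metric = 0.0
    best_state = None
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        t0 = time.time()
        train_items = items["train"]
        if config.task != "segmentation" and config.oversample:
            per_class: dict[int, list] = {}
            for it in train_items:
                per_class.setdefault(it[2], []).append(it)
            if len(per_class) > 1:
                train_items = aug.oversample_epoch(
                    {str(k): v for k, v in per_class.items()}, rng)
            else:
                train_items = [train_items[i] for i in rng.permutation(len(train_items))]
        else:
            train_items = [train_items[i] for i in rng.permutation(len(train_items))]

        epoch_losses = []
        for i in range(0, len(train_items), config.batch_size):
            batch = train_items[i: i + config.batch_size]
            x, y = batch_arrays(batch, True)
            opt.zero_grad()
            if config.task == "segmentation":
                pred = net.forward(x, train=True)
                loss, d = nn.mse_loss(pred, y)
            else:
                logits = net.forward(x, train=True)
                loss, d = nn.cross_entropy_loss(logits, y)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward(d)
            opt.step()
            epoch_losses.append(loss)
        val_loss, val_metric = eval_split(items["val"])
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss, "val_metric": val_metric,
                    "seconds": round(time.time() - t0, 2),
                    "hyperparameters": config.hyperparameters() if epoch == 0 else None})
        if val_loss < best_val:
            best_val, best_metric = val_loss, val_metric
            best_state = [a.copy() for a in nets.state_arrays(net)]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
        if config.target_metric is not None and val_metric >= config.target_metric:
            best_val, best_metric = val_loss, val_metric
            best_state = [a.copy() for a in nets.state_arrays(net)]
            break
    if best_state is not None:
        nets.load_state_arrays(net, best_state)
    meta = {"task": config.task, "small": config.small,
            "n_classes": 3 if config.task == "segmentation" else 2,
            "input_shape": list(in_shape),
            "hyperparameters": config.hyperparameters()}
    ckpt = save_checkpoint(net, meta, Path(out_dir) / f"{config.task}.npz")
    (Path(out_dir) / f"{config.task}_log.jsonl").write_text(
        "\n".join(json.dumps(e) for e in log) + "\n")
    return TrainResult(ckpt, log, best_val, best_metric, config)


# ---------------------------------------------------------------------------
# monitoring
# ---------------------------------------------------------------------------

@dataclass
class MonitorOutput:
    """Everything the two-step monitor derives from one video."""

    video_id: str
    phase_probs: np.ndarray        # (T, 2)
    problem_probs: np.ndarray      # (T, 2)
    risk: risk_mod.RiskSeries
    alert_time: int | None
    segmented_seconds: list[int]
    circles: dict[int, list[segeval.CircleAnnotation]]
    certainty_maps: dict[int, np.ndarray]
    overlays: dict[int, np.ndarray]


def _predict_probs(net, frames_u8: np.ndarray, batch: int = 32) -> np.ndarray:
    out = []
    for i in range(0, len(frames_u8), batch):
        out.append(net.predict_proba(aug.normalize(frames_u8[i: i + batch])))
    return np.concatenate(out, axis=0)


def monitor(source: str | Path | phantom.FrameSequence,
            phase_ckpt: str | Path, problem_ckpt: str | Path,
            seg_ckpt: str | Path | None = None, threshold: float = 0.5,
            window: int = risk_mod.DEFAULT_WINDOW,
            overlay_stride: int = 10) -> MonitorOutput:
    """Run the full two-step monitor over one video.

    Step one scores every second with both classifiers and fuses them into
    the risk trace; step two segments the frames whose smoothed
    important-phase probability exceeds 0.5 and annotates each detected
    object with its circumscribed circle. All operations are trailing, so
    outputs at second t depend only on frames up to t.
    """
    seq = source if isinstance(source, phantom.FrameSequence) else phantom.load_video(source)
    phase_net, phase_meta = load_checkpoint(phase_ckpt)
    problem_net, problem_meta = load_checkpoint(problem_ckpt)
    cls_shape = tuple(phase_meta["input_shape"])
    frames = _resize_frames(seq.frames, cls_shape)
    phase_probs = _predict_probs(phase_net, frames)
    problem_probs = _predict_probs(problem_net, _resize_frames(seq.frames,
                                   tuple(problem_meta["input_shape"])))
    rs = risk_mod.compute_risk(
        risk_mod.ProbabilitySeries(seq.video_id, phase_probs),
        risk_mod.ProbabilitySeries(seq.video_id, problem_probs),
        threshold=threshold, window=window)

    circles: dict[int, list] = {}
    cert: dict[int, np.ndarray] = {}
    overlays: dict[int, np.ndarray] = {}
    segmented: list[int] = []
    if seg_ckpt is not None:
        seg_net, seg_meta = load_checkpoint(seg_ckpt)
        seg_shape = tuple(seg_meta["input_shape"])
        src = seq.seg_frames if seq.seg_frames is not None else seq.frames
        seg_frames = _resize_frames(src, seg_shape)
        in_phase = np.nan_to_num(rs.phase_avg, nan=0.0) > 0.5
        segmented = [int(t) for t in np.flatnonzero(in_phase)]
        for i in range(0, len(segmented), 16):
            chunk = segmented[i: i + 16]
            maps = seg_net.predict(aug.normalize(seg_frames[chunk]))
            for j, t in enumerate(chunk):
                cert[t] = maps[j]
                anns = []
                for ci, cls in enumerate(phantom.MaskSet.CLASSES):
                    anns.extend(segeval.circumscribed_circles(
                        segeval.binarize(maps[j][..., ci]), cls))
                circles[t] = anns
                if t % overlay_stride == 0:
                    overlays[t] = segeval.gradation_overlay(seg_frames[t],
                                                            maps[j][..., 0])
    return MonitorOutput(seq.video_id, phase_probs, problem_probs, rs,
                         rs.estimated_time, segmented, circles, cert, overlays)


def describe_model(checkpoint: str | Path) -> list[dict]:
    """Layer/shape/parameter table of a trained checkpoint."""
    net, _ = load_checkpoint(checkpoint)
    return nets.describe(net)
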