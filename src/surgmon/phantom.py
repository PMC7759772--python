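"""Synthetic phantom cataract-surgery video generator.

Real surgical recordings cannot be shared, so every downstream stage is
exercised on a parametric phantom: each video is a sequence of 1-FPS
frames showing an elliptical "cornea" on a dark background. During the
important phase (capsulorrhexis through nuclear extraction) a bright
instrument shaft with a distinct tip sweeps over the cornea and a short
incision arc appears on the corneal rim; from a problem's onset the
corneal interior acquires a visually distinct speckle perturbation.
Per-frame phase labels, problem flags and exact per-class masks (cornea,
forceps tips, incisional site) are emitted alongside the frames.

The default timeline mirrors the clinical class balance: the important
phase spans ~37% of the video (mean 376 s important vs 642 s other in
the source data), and half of the videos contain a problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse, ellipse_perimeter, line


class ConfigurationError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Parameters of one phantom dataset.

    frames_per_video is in seconds (videos are 1 FPS); phase_boundaries
    are fractional positions of the important-phase start/end within the
    video; problem_onset is the fractional position of the problem within
    the important phase; noise_level is a pixel-noise std on the 0-1
    intensity scale.
    """

    n_videos: int = 20
    frames_per_video: int = 120
    cls_resolution: tuple[int, int] = (299, 168)   # (width, height)
    seg_resolution: tuple[int, int] = (256, 128)
    phase_boundaries: tuple[float, float] = (0.35, 0.72)
    problem_fraction: float = 0.5
    problem_onset: float = 0.4
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.phase_boundaries
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("phase boundaries must be strictly ordered inside (0,1)")
        if not (0.0 <= self.problem_onset <= 1.0):
            raise ConfigurationError("problem_onset must lie inside the important phase [0,1]")
        if not (0.0 <= self.problem_fraction <= 1.0):
            raise ConfigurationError("problem_fraction must be a fraction")
        if min(self.n_videos, self.frames_per_video) < 1:
            raise ConfigurationError("n_videos and frames_per_video must be positive")
        if min(*self.cls_resolution, *self.seg_resolution) < 8:
            raise ConfigurationError("resolutions must be positive (>= 8 px)")
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be >= 0")


@dataclass
class MaskSet:
    """Binary masks for one frame: cornea, forceps tips, incisional site."""

    cornea: np.ndarray
    tips: np.ndarray
    incision: np.ndarray

    CLASSES = ("cornea", "tips", "incision")

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cornea, self.tips, self.incision)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        for name in self.CLASSES:
            m = getattr(self, name)
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} mask must be binary")

    def stacked(self) -> np.ndarray:
        """(H, W, 3) stack in class order."""
        return np.stack([self.cornea, self.tips, self.incision], axis=-1)


@dataclass
class FrameSequence:
    """One phantom surgery: frames plus per-frame labels and masks.

    ``frames`` are classification-resolution RGB uint8 images;
    ``seg_frames``/``masks`` are the segmentation-resolution renderings of
    the same scene (masks match the rendered geometry exactly).
    """

    video_id: str
    frames: np.ndarray                  # (T, H, W, 3) uint8
    phase: np.ndarray                   # (T,) of {"important", "other"}
    problem: np.ndarray                 # (T,) of {0, 1}
    seg_frames: np.ndarray | None = None
    masks: list[MaskSet] | None = None
    problem_onset: int | None = None    # second of onset, None if no problem

    def __post_init__(self) -> None:
        t = len(self.frames)
        if len(self.phase) != t or len(self.problem) != t:
            raise ValueError("exactly one label per frame required")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def important_span(config: PhantomConfig) -> tuple[int, int]:
    """[start, end) frame indices of the important phase."""
    lo, hi = config.phase_boundaries
    t = config.frames_per_video
    return int(np.floor(lo * t)), int(np.floor(hi * t))


def _problem_videos(config: PhantomConfig) -> np.ndarray:
    """Deterministic choice of which video indices carry a problem."""
    k = int(round(config.problem_fraction * config.n_videos))
    order = np.random.default_rng([config.seed, 9743]).permutation(config.n_videos)
    flag = np.zeros(config.n_videos, dtype=bool)
    flag[order[:k]] = True
    return flag


def _render_frame(shape_hw: tuple[int, int], geom: dict, t: int, start: int, end: int,
                  problem_active: bool, rng: np.random.Generator,
                  noise_level: float) -> tuple[np.ndarray, MaskSet]:
    """Render one frame and its exact masks at the given resolution."""
    h, w = shape_hw
    img = np.full((h, w, 3), 0.08, dtype=np.float64)
    cy, cx = geom["center"][0] * h, geom["center"][1] * w
    ry, rx = geom["radii"][0] * h, geom["radii"][1] * w

    cornea = np.zeros((h, w), dtype=np.uint8)
    rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
    cornea[rr, cc] = 1
    img[rr, cc] = (0.42, 0.38, 0.46)
    # iris-like inner ring for texture
    rr2, cc2 = ellipse(cy, cx, 0.55 * ry, 0.55 * rx, shape=(h, w))
    img[rr2, cc2] = (0.30, 0.26, 0.34)

    tips = np.zeros((h, w), dtype=np.uint8)
    incision = np.zeros((h, w), dtype=np.uint8)
    in_phase = start <= t < end
    if in_phase:
        # instrument shaft entering from the top-left, tip orbiting the center
        u = (t - start) / max(end - start - 1, 1)
        ang = geom["tip_phase"] + 2.2 * np.pi * u
        ty = cy + 0.45 * ry * np.sin(ang)
        tx = cx + 0.45 * rx * np.cos(ang)
        r0, c0 = 1, int(0.1 * w)
        rr, cc = line(r0, c0, int(round(ty)), int(round(tx)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] = (0.95, 0.95, 0.9)
        rr, cc = disk((ty, tx), max(2.0, 0.02 * h), shape=(h, w))
        img[rr, cc] = (1.0, 1.0, 0.85)
        tips[rr, cc] = 1
        # incision arc on the corneal rim (fixed angular sector)
        rr, cc = ellipse_perimeter(int(round(cy)), int(round(cx)),
                                   int(round(ry)), int(round(rx)), shape=(h, w))
        theta = np.arctan2(rr - cy, cc - cx)
        a0 = geom["incision_angle"]
        sector = np.abs(np.angle(np.exp(1j * (theta - a0)))) < 0.25
        incision[rr[sector], cc[sector]] = 1
        # thicken the arc by one dilation step
        ys, xs = np.nonzero(incision)
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = np.clip(ys + dy, 0, h - 1), np.clip(xs + dx, 0, w - 1)
            incision[yy, xx] = 1
        img[incision.astype(bool)] = (0.85, 0.3, 0.3)

    if problem_active:
        # speckled reddening inside the cornea, deterministic per video
        sy, sx = np.nonzero(cornea & geom["speckle"][:h, :w])
        img[sy, sx, 0] = np.minimum(img[sy, sx, 0] + 0.35, 1.0)
        img[sy, sx, 2] *= 0.5

    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    frame = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return frame, MaskSet(cornea, tips, incision)


def generate_video(config: PhantomConfig, index: int) -> FrameSequence:
    """Deterministically render phantom video ``index``.

    Identical (config, seed, index) always yields bit-identical frames,
    labels and masks.
    """
    if not 0 <= index < config.n_videos:
        raise ConfigurationError(f"index {index} out of range for {config.n_videos} videos")
    start, end = important_span(config)
    has_problem = bool(_problem_videos(config)[index])
    onset = None
    if has_problem:
        onset = start + int(round(config.problem_onset * max(end - start - 1, 0)))

    rng = np.random.default_rng([config.seed, index])
    geom_rng = np.random.default_rng([config.seed, index, 17])
    hmax = max(config.cls_resolution[1], config.seg_resolution[1])
    wmax = max(config.cls_resolution[0], config.seg_resolution[0])
    geom = {
        "center": (0.5 + 0.05 * geom_rng.uniform(-1, 1), 0.5 + 0.05 * geom_rng.uniform(-1, 1)),
        "radii": (geom_rng.uniform(0.28, 0.34), geom_rng.uniform(0.26, 0.32)),
        "tip_phase": geom_rng.uniform(0, 2 * np.pi),
        "incision_angle": geom_rng.uniform(-np.pi, np.pi),
        "speckle": geom_rng.random((hmax, wmax)) < 0.25,
    }

    t_total = config.frames_per_video
    wc, hc = config.cls_resolution
    ws, hs = config.seg_resolution
    frames = np.empty((t_total, hc, wc, 3), dtype=np.uint8)
    seg_frames = np.empty((t_total, hs, ws, 3), dtype=np.uint8)
    masks: list[MaskSet] = []
    phase = np.empty(t_total, dtype=object)
    problem = np.zeros(t_total, dtype=np.int64)
    for t in range(t_total):
        active = onset is not None and t >= onset
        frames[t], _ = _render_frame((hc, wc), geom, t, start, end, active,
                                     np.random.default_rng([config.seed, index, t, 0]),
                                     config.noise_level)
        seg_frames[t], mset = _render_frame((hs, ws), geom, t, start, end, active,
                                            np.random.default_rng([config.seed, index, t, 1]),
                                            config.noise_level)
        masks.append(mset)
        phase[t] = "important" if start <= t < end else "other"
        problem[t] = 1 if active else 0
    return FrameSequence(f"video_{index:03d}", frames, phase, problem,
                         seg_frames, masks, onset)


def generate_dataset(config: PhantomConfig) -> list[FrameSequence]:
    return [generate_video(config, i) for i in range(config.n_videos)]


def make_splits(n_videos: int, fractions=(0.6, 0.2, 0.2)) -> dict[str, list[int]]:
    """Deterministic contiguous train/val/test partition of video indices."""
    n_train = max(1, int(round(fractions[0] * n_videos)))
    n_val = max(1, int(round(fractions[1] * n_videos))) if n_videos > 2 else 0
    idx = list(range(n_videos))
    return {"train": idx[:n_train],
            "val": idx[n_train:n_train + n_val],
            "test": idx[n_train + n_val:]}


def write_dataset(sequences: list[FrameSequence], out_dir: str | Path,
                  splits: dict[str, list[int]] | None = None) -> Path:
    """Write frames (PNG), per-video label CSVs, per-class mask PNGs and a
    JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if splits is None:
        splits = make_splits(len(sequences))
    entries = []
    for seq in sequences:
        vdir = out_dir / seq.video_id
        (vdir / "frames").mkdir(parents=True, exist_ok=True)
        rows = []
        for t in range(seq.n_frames):
            iio.imwrite(vdir / "frames" / f"frame_{t:05d}.png", seq.frames[t])
            rows.append({"frame_index": t, "phase": seq.phase[t],
                         "problem": int(seq.problem[t])})
        pd.DataFrame(rows).to_csv(vdir / "labels.csv", index=False)
        if seq.seg_frames is not None:
            (vdir / "seg_frames").mkdir(exist_ok=True)
            (vdir / "masks").mkdir(exist_ok=True)
            for t in range(seq.n_frames):
                iio.imwrite(vdir / "seg_frames" / f"frame_{t:05d}.png", seq.seg_frames[t])
                for cls in MaskSet.CLASSES:
                    arr = (getattr(seq.masks[t], cls) * 255).astype(np.uint8)
                    iio.imwrite(vdir / "masks" / f"frame_{t:05d}_{cls}.png", arr)
        entries.append({"video_id": seq.video_id, "n_frames": seq.n_frames,
                        "problem_onset": seq.problem_onset,
                        "has_masks": seq.seg_frames is not None})
    manifest = {"videos": entries,
                "splits": {k: [sequences[i].video_id for i in v]
                           for k, v in splits.items()}}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_video(video_dir: str | Path, with_masks: bool = True) -> FrameSequence:
    """Read one written phantom video back into memory."""
    vdir = Path(video_dir)
    labels = pd.read_csv(vdir / "labels.csv")
    t_total = len(labels)
    frames = np.stack([iio.imread(vdir / "frames" / f"frame_{t:05d}.png")
                       for t in range(t_total)])
    seg_frames = None
    masks = None
    if with_masks and (vdir / "masks").exists():
        seg_frames = np.stack([iio.imread(vdir / "seg_frames" / f"frame_{t:05d}.png")
                               for t in range(t_total)])
        masks = []
        for t in range(t_total):
            parts = {cls: (iio.imread(vdir / "masks" / f"frame_{t:05d}_{cls}.png") > 127)
                     .astype(np.uint8) for cls in MaskSet.CLASSES}
            masks.append(MaskSet(**parts))
    problem = labels["problem"].to_numpy()
    onset = int(np.argmax(problem)) if problem.any() else None
    return FrameSequence(vdir.name, frames, labels["phase"].to_numpy(object),
                         problem, seg_frames, masks, onset)


def load_dataset(manifest_path: str | Path, with_masks: bool = True
                 ) -> tuple[list[FrameSequence], dict[str, list[str]]]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    seqs = [load_video(manifest_path.parent / e["video_id"], with_masks)
            for e in manifest["videos"]]
    return seqs, manifest["splits"]
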