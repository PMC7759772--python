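"""Architecture construction for the two monitoring networks.

Two networks drive the monitor:

* an InceptionV3-style classifier (299x168x3 in, softmax out) used twice —
  once for surgical-phase recognition (important phase vs other) and once
  for problem detection (with/without problem);
* an scSE-FC-DenseNet40 segmenter (256x128x3 in, per-pixel sigmoid out,
  three classes: cornea, forceps tips, incisional site) built from dense
  blocks of growth 16 with a concurrent squeeze-and-excitation gate after
  each block and U-Net style skip connections.

Both are described declaratively as :class:`NetSpec` layer tables so shape
propagation and parameter counting can be checked against the printed
architecture tables without instantiating weights, and both can be
realized as trainable NumPy networks (optionally width-scaled for CPU
training).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn

# Classifier input per the architecture table; the dataset description
# mentions 256x168 downsampling, but the table (and the conv arithmetic
# that follows from it) uses 299x168 and is adopted as the default.
CLS_INPUT_SHAPE = (299, 168, 3)
SEG_INPUT_SHAPE = (256, 128, 3)
DEFAULT_GROWTH = 16  # forced by the table's channel arithmetic (48->80->144->272)


class ShapeTriple(NamedTuple):
    """(height, width, channels) of a feature tensor."""

    h: int
    w: int
    c: int


class ShapeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter / computation counting
# ---------------------------------------------------------------------------

def conv_param_count(kh: int, kw: int, cin: int, cout: int) -> int:
    """Trainable parameters of a conv layer: kh*kw*cin*cout weights + cout biases."""
    if min(kh, kw, cin, cout) < 1:
        raise ValueError("all arguments must be >= 1")
    return kh * kw * cin * cout + cout

def conv_flop_count(kh: int, kw: int, h: int, w: int, cin: int, cout: int) -> int:
    """Multiply count of a (stride-1, same-size-output) conv layer: kh*kw*h*w*cin*cout."""
    if min(kh, kw, h, w, cin, cout) < 1:
        raise ValueError("all arguments must be >= 1")
    return kh * kw * h * w * cin * cout

def factorization_ratio(n: int, c: int) -> float:
    """Parameter ratio of one n x n conv vs a (1 x n + n x 1) pair at c channels.

    Approaches n/2 for large channel counts — the saving that motivates
    the factorized modules.
    """
    full = conv_param_count(n, n, c, c)
    split = conv_param_count(1, n, c, c) + conv_param_count(n, 1, c, c)
    return full / split


# ---------------------------------------------------------------------------
# declarative layer tables
# ---------------------------------------------------------------------------

#: layer kinds accepted by :func:`propagate_shape`
LAYER_KINDS = frozenset({
    "conv", "conv-padded", "transposed-conv", "max-pool", "avg-pool",
    "global-avg-pool", "dense-block-scse", "inception-A", "inception-B",
    "inception-C", "inception-D", "inception-E", "fully-connected",
    "softmax", "sigmoid", "concat",
})


@dataclass
class LayerSpec:
    """One row of an architecture table."""

    kind: str
    patch: tuple[int, int] = (1, 1)
    stride: int = 1
    out_channels: int | None = None   # cout; for dense stages: growth rate
    repeat: int = 1                   # dense blocks per stage / inception repeats
    emit: str = "all"                 # dense stage output: "all" maps or "new" only
    skip_out: int | None = None       # tag this row's output as skip source x
    concat_in: int | None = None      # concat skip x onto this row's input

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if min(*self.patch, self.stride) < 1:
            raise ValueError("patch size and stride must be >= 1")


@dataclass
class NetSpec:
    """Ordered layer table plus the input shape and class count."""

    layers: list[LayerSpec]
    input_shape: ShapeTriple
    n_classes: int

    def propagate(self) -> list[ShapeTriple]:
        """Input shape seen by every row (mirrors the tables' Input Shape column)."""
        shapes: list[ShapeTriple] = []
        skips: dict[int, ShapeTriple] = {}
        shape = ShapeTriple(*self.input_shape)
        for spec in self.layers:
            if spec.concat_in is not None:
                skip = skips[spec.concat_in]
                if skip[:2] != shape[:2]:
                    raise ShapeError("skip connection spatial dims do not match")
                shape = ShapeTriple(shape.h, shape.w, shape.c + skip.c)
            shapes.append(shape)
            shape = propagate_shape(spec, shape)
            if spec.skip_out is not None:
                skips[spec.skip_out] = shape
        return shapes

    def to_dict(self) -> dict:
        rows = []
        for s in self.layers:
            rows.append({k: v for k, v in vars(s).items()
                         if v not in (None,) and not (k == "repeat" and v == 1)
                         and not (k == "emit" and v == "all")
                         and not (k == "patch" and v == (1, 1))
                         and not (k == "stride" and v == 1)})
            rows[-1]["kind"] = s.kind
            if "patch" in rows[-1]:
                rows[-1]["patch"] = list(s.patch)
        return {"input_shape": list(self.input_shape),
                "n_classes": self.n_classes, "layers": rows}

    @classmethod
    def from_dict(cls, d: dict) -> "NetSpec":
        layers = []
        for row in d["layers"]:
            row = dict(row)
            if "patch" in row:
                row["patch"] = tuple(row["patch"])
            layers.append(LayerSpec(**row))
        return cls(layers, ShapeTriple(*d["input_shape"]), d["n_classes"])

    def to_yaml(self, path=None) -> str:
        import yaml
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "NetSpec":
        import yaml
        from pathlib import Path
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def _valid_out(size: int, k: int, stride: int) -> int:
    out = (size - k) // stride + 1
    if out < 1:
        raise ShapeError(f"output dimension {out} < 1")
    return out


def propagate_shape(layer: LayerSpec, in_shape: ShapeTriple) -> ShapeTriple:
    """Output shape of one table row given its input shape.

    Valid (unpadded) conv/pool: out = floor((in - k)/stride) + 1 per axis.
    Padded conv preserves spatial dims; the stride-2 transposed conv
    doubles them; a dense stage of m blocks with growth k adds m*k
    channels (or emits only the m*k new ones).
    """
    h, w, c = in_shape
    kind = layer.kind
    kh, kw = layer.patch
    if kind == "conv":
        return ShapeTriple(_valid_out(h, kh, layer.stride),
                           _valid_out(w, kw, layer.stride), layer.out_channels)
    if kind == "conv-padded":
        return ShapeTriple(h, w, layer.out_channels)
    if kind == "transposed-conv":
        cout = layer.out_channels if layer.out_channels is not None else c
        return ShapeTriple(h * layer.stride, w * layer.stride, cout)
    if kind in ("max-pool", "avg-pool"):
        return ShapeTriple(_valid_out(h, kh, layer.stride),
                           _valid_out(w, kw, layer.stride), c)
    if kind == "global-avg-pool":
        return ShapeTriple(1, 1, c)
    if kind == "dense-block-scse":
        new = layer.repeat * layer.out_channels
        return ShapeTriple(h, w, new if layer.emit == "new" else c + new)
    if kind.startswith("inception-"):
        letter = kind[-1]
        if letter in ("B", "D"):   # grid-reducing: valid 3x3 stride 2 on every branch
            return ShapeTriple(_valid_out(h, 3, 2), _valid_out(w, 3, 2), layer.out_channels)
        return ShapeTriple(h, w, layer.out_channels)
    if kind == "fully-connected":
        return ShapeTriple(1, 1, layer.out_channels)
    if kind in ("softmax", "sigmoid"):
        return in_shape
    if kind == "concat":
        return in_shape  # channels handled by NetSpec.propagate via concat_in
    raise ValueError(f"unknown layer kind {kind!r}")


def classifier_spec(n_classes: int = 2,
                    input_shape: tuple[int, int, int] = CLS_INPUT_SHAPE) -> NetSpec:
    """Layer table of the phase/problem classifier (the InceptionV3 variant)."""
    L = LayerSpec
    layers = [
        L("conv", (3, 3), 2, 32),
        L("conv", (3, 3), 1, 32),
        L("conv-padded", (3, 3), 1, 64),
        L("max-pool", (3, 3), 2),
        L("conv", (1, 1), 1, 80),
        L("conv", (3, 3), 1, 192),
        L("max-pool", (3, 3), 2),
        L("inception-A", out_channels=256),
        L("inception-A", out_channels=288),
        L("inception-A", out_channels=288),
        L("inception-B", out_channels=768),
        L("inception-C", out_channels=768, repeat=4),
        L("inception-D", out_channels=1280),
        L("inception-E", out_channels=2048),
        L("inception-E", out_channels=2048),
        L("global-avg-pool"),
        L("fully-connected", out_channels=1024),
        L("fully-connected", out_channels=n_classes),
        L("softmax"),
    ]
    return NetSpec(layers, ShapeTriple(*input_shape), n_classes)


@dataclass
class DenseBlockParams:
    """Dense-stage hyperparameters of the segmenter."""

    growth: int = DEFAULT_GROWTH
    scse_reduction: int = 2
    scse_fusion: str = "max"

    def __post_init__(self) -> None:
        if self.growth < 1:
            raise ValueError("growth rate must be >= 1")


def segmenter_spec(n_classes: int = 3,
                   input_shape: tuple[int, int, int] = SEG_INPUT_SHAPE,
                   growth: int = DEFAULT_GROWTH) -> NetSpec:
    """Layer table of the scSE-FC-DenseNet40 segmenter (2/4/8 encoder stages,
    6-block bottleneck, 8/4/2 decoder stages, growth ``growth``)."""
    k = growth
    L = LayerSpec
    layers = [
        L("conv-padded", (3, 3), 1, 3 * k),
        L("dense-block-scse", out_channels=k, repeat=2, skip_out=1),
        L("conv", (1, 1), 2, 3 * k + 2 * k),
        L("dense-block-scse", out_channels=k, repeat=4, skip_out=2),
        L("conv", (1, 1), 2, 3 * k + 6 * k),
        L("dense-block-scse", out_channels=k, repeat=8, skip_out=3),
        L("conv", (1, 1), 2, 3 * k + 14 * k),
        L("dense-block-scse", out_channels=k, repeat=6, emit="new"),
        L("transposed-conv", (3, 3), 2),
        L("dense-block-scse", out_channels=k, repeat=8, emit="new", concat_in=3),
        L("transposed-conv", (3, 3), 2),
        L("dense-block-scse", out_channels=k, repeat=4, emit="new", concat_in=2),
        L("transposed-conv", (3, 3), 2),
        L("dense-block-scse", out_channels=k, repeat=2, concat_in=1),
        L("conv", (1, 1), 1, n_classes),
        L("sigmoid"),
    ]
    return NetSpec(layers, ShapeTriple(*input_shape), n_classes)


# ---------------------------------------------------------------------------
# realized networks
# ---------------------------------------------------------------------------

def _cbr(kh, kw, cin, cout, stride, padding, rng, name):
    """conv -> batch-norm -> relu, the composite conv used throughout."""
    return nn.Sequential([
        nn.Conv2D(kh, kw, cin, cout, stride, padding, rng, name),
        nn.BatchNorm2D(cout, name=f"{name}.bn"),
        nn.ReLU(),
    ])


def _scale(c: int, mult: float) -> int:
    return max(1, round(c * mult))


def build_inception_module(kind: str, cin: int, *, pool_features: int = 32,
                           c7: int = 128, width_mult: float = 1.0,
                           rng: np.random.Generator | None = None) -> nn.Parallel:
    """One Inception module of the given kind on ``cin`` input channels.

    Branch widths follow the canonical factorized-convolution design and
    are chosen so the stage output channels match the architecture table;
    ``width_mult`` scales every width for the reduced CPU profile.

    * A — 5x5 branch partially replaced by stacked 3x3s (non-reducing)
    * B — grid reduction via stride-2 3x3 branches plus max-pool
    * C — 7x7 factorized into 1x7/7x1 pairs (non-reducing)
    * D — grid reduction with factorized 7s
    * E — 3x3 split into parallel 1x3 and 3x1 (non-reducing)
    """
    rng = rng or np.random.default_rng(0)
    s = lambda c: _scale(c, width_mult)
    if kind == "A":
        branches = [
            _cbr(1, 1, cin, s(64), 1, "valid", rng, "a.b1"),
            nn.Sequential([_cbr(1, 1, cin, s(48), 1, "valid", rng, "a.b2a"),
                           _cbr(5, 5, s(48), s(64), 1, "same", rng, "a.b2b")]),
            nn.Sequential([_cbr(1, 1, cin, s(64), 1, "valid", rng, "a.b3a"),
                           _cbr(3, 3, s(64), s(96), 1, "same", rng, "a.b3b"),
                           _cbr(3, 3, s(96), s(96), 1, "same", rng, "a.b3c")]),
            nn.Sequential([nn.AvgPool2D(3),
                           _cbr(1, 1, cin, s(pool_features), 1, "valid", rng, "a.b4")]),
        ]
    elif kind == "B":
        branches = [
            _cbr(3, 3, cin, s(384), 2, "valid", rng, "b.b1"),
            nn.Sequential([_cbr(1, 1, cin, s(64), 1, "valid", rng, "b.b2a"),
                           _cbr(3, 3, s(64), s(96), 1, "same", rng, "b.b2b"),
                           _cbr(3, 3, s(96), s(96), 2, "valid", rng, "b.b2c")]),
            nn.MaxPool2D(3, 2),
        ]
    elif kind == "C":
        c7s = s(c7)
        branches = [
            _cbr(1, 1, cin, s(192), 1, "valid", rng, "c.b1"),
            nn.Sequential([_cbr(1, 1, cin, c7s, 1, "valid", rng, "c.b2a"),
                           _cbr(1, 7, c7s, c7s, 1, "same", rng, "c.b2b"),
                           _cbr(7, 1, c7s, s(192), 1, "same", rng, "c.b2c")]),
            nn.Sequential([_cbr(1, 1, cin, c7s, 1, "valid", rng, "c.b3a"),
                           _cbr(7, 1, c7s, c7s, 1, "same", rng, "c.b3b"),
                           _cbr(1, 7, c7s, c7s, 1, "same", rng, "c.b3c"),
                           _cbr(7, 1, c7s, c7s, 1, "same", rng, "c.b3d"),
                           _cbr(1, 7, c7s, s(192), 1, "same", rng, "c.b3e")]),
            nn.Sequential([nn.AvgPool2D(3),
                           _cbr(1, 1, cin, s(192), 1, "valid", rng, "c.b4")]),
        ]
    elif kind == "D":
        branches = [
            nn.Sequential([_cbr(1, 1, cin, s(192), 1, "valid", rng, "d.b1a"),
                           _cbr(3, 3, s(192), s(320), 2, "valid", rng, "d.b1b")]),
            nn.Sequential([_cbr(1, 1, cin, s(192), 1, "valid", rng, "d.b2a"),
                           _cbr(1, 7, s(192), s(192), 1, "same", rng, "d.b2b"),
                           _cbr(7, 1, s(192), s(192), 1, "same", rng, "d.b2c"),
                           _cbr(3, 3, s(192), s(192), 2, "valid", rng, "d.b2d")]),
            nn.MaxPool2D(3, 2),
        ]
    elif kind == "E":
        branches = [
            _cbr(1, 1, cin, s(320), 1, "valid", rng, "e.b1"),
            nn.Sequential([_cbr(1, 1, cin, s(384), 1, "valid", rng, "e.b2a"),
                           nn.Parallel([_cbr(1, 3, s(384), s(384), 1, "same", rng, "e.b2b"),
                                        _cbr(3, 1, s(384), s(384), 1, "same", rng, "e.b2c")])]),
            nn.Sequential([_cbr(1, 1, cin, s(448), 1, "valid", rng, "e.b3a"),
                           _cbr(3, 3, s(448), s(384), 1, "same", rng, "e.b3b"),
                           nn.Parallel([_cbr(1, 3, s(384), s(384), 1, "same", rng, "e.b3c"),
                                        _cbr(3, 1, s(384), s(384), 1, "same", rng, "e.b3d")])]),
            nn.Sequential([nn.AvgPool2D(3),
                           _cbr(1, 1, cin, s(192), 1, "valid", rng, "e.b4")]),
        ]
    else:
        raise ValueError(f"unknown Inception module kind {kind!r}")
    return nn.Parallel(branches)


build_scse_module = nn.SCSEModule


class InceptionClassifier(nn.Layer):
    """Realized phase/problem classifier: stem, Inception stages A-E,
    global average pooling and a two-layer softmax head.

    ``width_mult`` scales every channel count (1.0 = the full printed
    architecture); the layer list mirrors the table row-for-row, and
    ``forward`` can record the input shape of every row for auditing.
    """

    def __init__(self, n_classes: int = 2,
                 input_shape: tuple[int, int, int] = CLS_INPUT_SHAPE,
                 width_mult: float = 1.0, seed: int = 0) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(seed)
        s = lambda c: _scale(c, width_mult)
        m = width_mult
        self.n_classes = n_classes
        self.input_shape = tuple(input_shape)
        self.width_mult = width_mult
        pool_a = [32, 64, 64]   # per-stage pool-branch widths forced by 256/288/288
        rows: list[tuple[str, nn.Layer]] = [
            ("conv 3x3/2", _cbr(3, 3, 3, s(32), 2, "valid", rng, "stem1")),
            ("conv 3x3/1", _cbr(3, 3, s(32), s(32), 1, "valid", rng, "stem2")),
            ("conv-padded 3x3/1", _cbr(3, 3, s(32), s(64), 1, "same", rng, "stem3")),
            ("max-pool 3x3/2", nn.MaxPool2D(3, 2)),
            ("conv 1x1/1", _cbr(1, 1, s(64), s(80), 1, "valid", rng, "stem4")),
            ("conv 3x3/1", _cbr(3, 3, s(80), s(192), 1, "valid", rng, "stem5")),
            ("max-pool 3x3/2", nn.MaxPool2D(3, 2)),
        ]
        cin = s(192)
        for i, pf in enumerate(pool_a):
            mod = build_inception_module("A", cin, pool_features=pf, width_mult=m, rng=rng)
            rows.append((f"inception-A.{i + 1}", mod))
            cin = s(64) + s(64) + s(96) + s(pf)
        rows.append(("inception-B", build_inception_module("B", cin, width_mult=m, rng=rng)))
        cin = s(384) + s(96) + cin
        for i, c7 in enumerate([128, 160, 160, 192]):
            mod = build_inception_module("C", cin, c7=c7, width_mult=m, rng=rng)
            rows.append((f"inception-C.{i + 1}", mod))
            cin = 3 * s(192) + s(192)
        rows.append(("inception-D", build_inception_module("D", cin, width_mult=m, rng=rng)))
        cin = s(320) + s(192) + cin
        for i in range(2):
            mod = build_inception_module("E", cin, width_mult=m, rng=rng)
            rows.append((f"inception-E.{i + 1}", mod))
            cin = s(320) + 2 * s(384) + 2 * s(384) + s(192)
        rows.append(("global-avg-pool", nn.GlobalAvgPool()))
        rows.append(("fully-connected", nn.Dense(cin, s(1024), rng, "head1")))
        rows.append(("relu", nn.ReLU()))
        rows.append(("fully-connected", nn.Dense(s(1024), n_classes, rng, "head2")))
        self.rows = rows
        self.feature_channels = cin

    def children(self) -> list[nn.Layer]:
        return [layer for _, layer in self.rows]

    def forward(self, x: np.ndarray, train: bool = False,
                trace: list | None = None) -> np.ndarray:
        """Logits for a batch of NHWC images; appends (row name, input shape)
        tuples to ``trace`` when given."""
        for name, layer in self.rows:
            if trace is not None:
                trace.append((name, tuple(x.shape[1:])))
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.rows):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for _, layer in self.rows:
            out.extend(layer.params())
        return out

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-class probabilities (rows sum to 1) for NHWC images in [0, 1]."""
        return nn.softmax(self.forward(np.asarray(images, dtype=np.float32)))


class _DenseStage(nn.Layer):
    """m x (dense block + scSE) with optional emission of only the new maps."""

    def __init__(self, cin: int, m: int, params: DenseBlockParams,
                 rng: np.random.Generator, name: str) -> None:
        self.units: list[tuple[nn.DenseUnit, nn.SCSEModule]] = []
        c = cin
        for i in range(m):
            du = nn.DenseUnit(c, params.growth, rng, f"{name}.u{i}")
            c += params.growth
            se = nn.SCSEModule(c, params.scse_reduction, params.scse_fusion,
                               rng, f"{name}.se{i}")
            self.units.append((du, se))
        self.cin, self.cout = cin, c
        self.new_channels = m * params.growth

    def children(self) -> list[nn.Layer]:
        return [l for pair in self.units for l in pair]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for du, se in self.units:
            x = se.forward(du.forward(x, train=train), train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for du, se in reversed(self.units):
            dy = du.backward(se.backward(dy))
        return dy

    def params(self) -> list[nn.Param]:
        return [p for l in self.children() for p in l.params()]


class SCSEFCDenseNet(nn.Layer):
    """Realized scSE-FC-DenseNet40 segmenter.

    Encoder dense stages of 2/4/8 blocks with stride-2 1x1 transitions,
    a 6-block bottleneck, and decoder stages of 8/4/2 blocks; each
    transition-up transposes only the preceding stage's newly produced
    feature maps and concatenates them with the matching encoder output.
    The head is a 1x1 conv to ``n_classes`` certainty maps in [0, 1].
    """

    def __init__(self, n_classes: int = 3,
                 input_shape: tuple[int, int, int] = SEG_INPUT_SHAPE,
                 params: DenseBlockParams | None = None, seed: int = 0) -> None:
        h, w, _ = input_shape
        if h % 8 or w % 8:
            raise ShapeError("segmenter input spatial dims must be divisible by 8")
        params = params or DenseBlockParams()
        rng = np.random.default_rng(seed)
        k = params.growth
        self.n_classes = n_classes
        self.input_shape = tuple(input_shape)
        self.block_params = params
        self.stem = _cbr(3, 3, 3, 3 * k, 1, "same", rng, "stem")
        self.enc1 = _DenseStage(3 * k, 2, params, rng, "enc1")
        self.td1 = nn.Conv2D(1, 1, self.enc1.cout, self.enc1.cout, 2, "valid", rng, "td1")
        self.enc2 = _DenseStage(self.enc1.cout, 4, params, rng, "enc2")
        self.td2 = nn.Conv2D(1, 1, self.enc2.cout, self.enc2.cout, 2, "valid", rng, "td2")
        self.enc3 = _DenseStage(self.enc2.cout, 8, params, rng, "enc3")
        self.td3 = nn.Conv2D(1, 1, self.enc3.cout, self.enc3.cout, 2, "valid", rng, "td3")
        self.mid = _DenseStage(self.enc3.cout, 6, params, rng, "mid")
        self.tu3 = nn.ConvTranspose2D(3, self.mid.new_channels, self.mid.new_channels,
                                      2, rng, "tu3")
        self.dec3 = _DenseStage(self.mid.new_channels + self.enc3.cout, 8, params, rng, "dec3")
        self.tu2 = nn.ConvTranspose2D(3, self.dec3.new_channels, self.dec3.new_channels,
                                      2, rng, "tu2")
        self.dec2 = _DenseStage(self.dec3.new_channels + self.enc2.cout, 4, params, rng, "dec2")
        self.tu1 = nn.ConvTranspose2D(3, self.dec2.new_channels, self.dec2.new_channels,
                                      2, rng, "tu1")
        self.dec1 = _DenseStage(self.dec2.new_channels + self.enc1.cout, 2, params, rng, "dec1")
        self.head = nn.Conv2D(1, 1, self.dec1.cout, n_classes, 1, "valid", rng, "head")
        self.out_act = nn.Sigmoid()

    def children(self) -> list[nn.Layer]:
        return [self.stem, self.enc1, self.td1, self.enc2, self.td2, self.enc3,
                self.td3, self.mid, self.tu3, self.dec3, self.tu2, self.dec2,
                self.tu1, self.dec1, self.head, self.out_act]

    def forward(self, x: np.ndarray, train: bool = False,
                trace: list | None = None) -> np.ndarray:
        t = trace
        def rec(name, t_in):
            if t is not None:
                t.append((name, tuple(t_in.shape[1:])))
        rec("conv 3x3/1", x); x = self.stem.forward(x, train=train)
        rec("enc1 2x(dense+scSE)", x); s1 = self.enc1.forward(x, train=train)
        rec("td1 conv 1x1/2", s1); x = self.td1.forward(s1, train=train)
        rec("enc2 4x(dense+scSE)", x); s2 = self.enc2.forward(x, train=train)
        rec("td2 conv 1x1/2", s2); x = self.td2.forward(s2, train=train)
        rec("enc3 8x(dense+scSE)", x); s3 = self.enc3.forward(x, train=train)
        rec("td3 conv 1x1/2", s3); x = self.td3.forward(s3, train=train)
        rec("mid 6x(dense+scSE) -> new maps", x)
        x = self.mid.forward(x, train=train)
        x = x[..., self.enc3.cout:]                       # newly produced maps only
        rec("tu3 tconv 3x3/2", x); x = self.tu3.forward(x, train=train)
        x = np.concatenate([x, s3], axis=-1)
        rec("dec3 8x(dense+scSE) [concat 3]", x)
        x = self.dec3.forward(x, train=train)[..., self.dec3.cin:]
        rec("tu2 tconv 3x3/2", x); x = self.tu2.forward(x, train=train)
        x = np.concatenate([x, s2], axis=-1)
        rec("dec2 4x(dense+scSE) [concat 2]", x)
        x = self.dec2.forward(x, train=train)[..., self.dec2.cin:]
        rec("tu1 tconv 3x3/2", x); x = self.tu1.forward(x, train=train)
        x = np.concatenate([x, s1], axis=-1)
        rec("dec1 2x(dense+scSE) [concat 1]", x)
        x = self.dec1.forward(x, train=train)
        rec("conv 1x1/1", x); x = self.head.forward(x, train=train)
        rec("sigmoid", x)
        return self.out_act.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(self.out_act.backward(dy))
        dy = self.dec1.backward(dy)
        d_up, d_s1 = dy[..., : self.dec2.new_channels], dy[..., self.dec2.new_channels:]
        dy = self.tu1.backward(d_up)
        full = np.zeros(dy.shape[:-1] + (self.dec2.cout,), dtype=dy.dtype)
        full[..., self.dec2.cin:] = dy
        dy = self.dec2.backward(full)
        d_up, d_s2 = dy[..., : self.dec3.new_channels], dy[..., self.dec3.new_channels:]
        dy = self.tu2.backward(d_up)
        full = np.zeros(dy.shape[:-1] + (self.dec3.cout,), dtype=dy.dtype)
        full[..., self.dec3.cin:] = dy
        dy = self.dec3.backward(full)
        d_up, d_s3 = dy[..., : self.mid.new_channels], dy[..., self.mid.new_channels:]
        dy = self.tu3.backward(d_up)
        full = np.zeros(dy.shape[:-1] + (self.mid.cout,), dtype=dy.dtype)
        full[..., self.enc3.cout:] = dy
        dy = self.mid.backward(full)
        dy = self.enc3.backward(self.td3.backward(dy) + d_s3)
        dy = self.enc2.backward(self.td2.backward(dy) + d_s2)
        dy = self.enc1.backward(self.td1.backward(dy) + d_s1)
        return self.stem.backward(dy)

    def params(self) -> list[nn.Param]:
        return [p for l in self.children() for p in l.params()]

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel, per-class certainty maps in [0, 1] (NHWC in [0, 1] in)."""
        return self.forward(np.asarray(images, dtype=np.float32))


def build_classifier(n_classes: int = 2,
                     input_shape: tuple[int, int, int] = CLS_INPUT_SHAPE,
                     width_mult: float = 1.0, seed: int = 0) -> InceptionClassifier:
    return InceptionClassifier(n_classes, input_shape, width_mult, seed)


def build_scse_fc_densenet40(n_classes: int = 3,
                             input_shape: tuple[int, int, int] = SEG_INPUT_SHAPE,
                             params: DenseBlockParams | None = None,
                             seed: int = 0) -> SCSEFCDenseNet:
    return SCSEFCDenseNet(n_classes, input_shape, params, seed)


# ---------------------------------------------------------------------------
# checkpoint state I/O
# ---------------------------------------------------------------------------

def _leaf_arrays(layer: nn.Layer) -> list[np.ndarray]:
    kids = layer.children() if hasattr(layer, "children") else []
    if isinstance(layer, nn.BatchNorm2D):
        return [layer.gamma.value, layer.beta.value,
                layer.running_mean, layer.running_var]
    if isinstance(layer, nn.Sequential):
        kids = layer.layers
    elif isinstance(layer, nn.Parallel):
        kids = layer.branches
    elif isinstance(layer, nn.SCSEModule):
        kids = [layer.fc1, layer.fc2, layer.conv]
    elif isinstance(layer, nn.DenseUnit):
        kids = [layer.f]
    if kids:
        return [a for k in kids for a in _leaf_arrays(k)]
    return [p.value for p in layer.params()]


def _set_leaf_arrays(layer: nn.Layer, arrays: list[np.ndarray], pos: int = 0) -> int:
    kids = layer.children() if hasattr(layer, "children") else []
    if isinstance(layer, nn.BatchNorm2D):
        layer.gamma.value[...] = arrays[pos]
        layer.beta.value[...] = arrays[pos + 1]
        layer.running_mean[...] = arrays[pos + 2]
        layer.running_var[...] = arrays[pos + 3]
        return pos + 4
    if isinstance(layer, nn.Sequential):
        kids = layer.layers
    elif isinstance(layer, nn.Parallel):
        kids = layer.branches
    elif isinstance(layer, nn.SCSEModule):
        kids = [layer.fc1, layer.fc2, layer.conv]
    elif isinstance(layer, nn.DenseUnit):
        kids = [layer.f]
    if kids:
        for k in kids:
            pos = _set_leaf_arrays(k, arrays, pos)
        return pos
    for p in layer.params():
        p.value[...] = arrays[pos]
        pos += 1
    return pos


def state_arrays(net: nn.Layer) -> list[np.ndarray]:
    """All weight and normalization-statistic arrays in traversal order."""
    return _leaf_arrays(net)


def load_state_arrays(net: nn.Layer, arrays: list[np.ndarray]) -> None:
    used = _set_leaf_arrays(net, list(arrays))
    if used != len(arrays):
        raise ValueError("checkpoint array count does not match the network")


def describe(net, input_shape: tuple[int, int, int] | None = None) -> list[dict]:
    """Per-row table (name, input shape, parameter count) of a realized net.

    Runs one tracing forward pass on a zero image to read off each row's
    actual input shape, the audit mirror of the printed tables.
    """
    shape = tuple(input_shape or net.input_shape)
    x = np.zeros((1, *shape), dtype=np.float32)
    trace: list = []
    net.forward(x, trace=trace)
    rows = []
    if isinstance(net, InceptionClassifier):
        blocks = [layer for _, layer in net.rows]
    else:
        blocks = [net.stem, net.enc1, net.td1, net.enc2, net.td2, net.enc3, net.td3,
                  net.mid, net.tu3, net.dec3, net.tu2, net.dec2, net.tu1, net.dec1,
                  net.head, net.out_act]
    for (name, in_shape), layer in zip(trace, blocks):
        rows.append({"type": name, "input_shape": in_shape,
                     "n_params": nn.count_params(layer)})
    return rows
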