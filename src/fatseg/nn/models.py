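"""The three encoder-decoder segmentation architectures.

All three share the same macro-structure: ``depth`` encoder levels with
2x2 max pooling, a bottleneck, and a mirrored decoder, ending in a 1x1
convolution to 3 class scores at input resolution. They differ in how
features are combined:

* **UNet** — plain double-convolution blocks; decoder upsamples with
  transposed convolutions and concatenates the encoder skip.
* **DenseUNet** — densely connected blocks: each thin convolution
  (``growth_rate`` channels) sees the concatenation of all previous
  features; a 1x1 transition restores the level width.
* **CDFNet** — competitive dense fusion: concatenation is replaced by an
  element-wise maximum (maxout) within blocks, and the decoder uses
  max-unpooling with index transfer from the paired encoder pool, fusing
  with the skip by maximum. Channel counts never grow by fusion, which is
  why the dense variants use markedly fewer parameters than the UNet at
  matched depth and width.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .layers import (
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    MaxUnpool2d,
    Maximum,
    Param,
    ReLU,
    softmax,
)

ARCH_NAMES = ("unet", "denseunet", "cdfnet")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Configuration of a segmentation network.

    ``depth`` is the number of pooling steps; level widths double from
    ``base_channels``. ``growth_rate`` and ``layers_per_block`` apply to
    the dense variants.
    """

    name: str = "cdfnet"
    depth: int = 4
    base_channels: int = 64
    growth_rate: int = 16
    layers_per_block: int = 4
    n_classes: int = 3
    input_size: int = 256

    def __post_init__(self) -> None:
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; expected one of {ARCH_NAMES}")
        for f in ("depth", "base_channels", "growth_rate", "layers_per_block", "input_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive, got {getattr(self, f)}")
        if self.n_classes != 3:
            raise ValueError(f"n_classes must be 3 (background/SAT/VAT), got {self.n_classes}")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )


# ---------------------------------------------------------------------------
# blocks

class _Block(Layer):
    """A unit with one input and one output feature map."""

    out_channels: int

    def forward(self, x): ...
    def backward(self, gy): ...


class ConvBlock(_Block):
    """conv3x3 -> ReLU -> conv3x3 -> ReLU (classic UNet block)."""

    def __init__(self, cin: int, cout: int, rng):
        self.c1, self.r1 = Conv2d(cin, cout, 3, rng), ReLU()
        self.c2, self.r2 = Conv2d(cout, cout, 3, rng), ReLU()
        self.out_channels = cout

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, gy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(gy))))


class DenseBlock(_Block):
    """Densely connected block: L thin convolutions on the running
    concatenation, then a 1x1 transition to the level width."""

    def __init__(self, cin: int, cout: int, growth: int, n_layers: int, rng):
        self.convs = [Conv2d(cin + i * growth, growth, 3, rng) for i in range(n_layers)]
        self.relus = [ReLU() for _ in range(n_layers)]
        self.trans = Conv2d(cin + n_layers * growth, cout, 1, rng)
        self.trelu = ReLU()
        self.cin, self.growth = cin, growth
        self.out_channels = cout

    def params(self):
        ps = []
        for c in self.convs:
            ps += c.params()
        return ps + self.trans.params()

    def forward(self, x):
        feats = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(feats))
            feats = np.concatenate([feats, h], axis=-1)
        return self.trelu.forward(self.trans.forward(feats))

    def backward(self, gy):
        g = self.trans.backward(self.trelu.backward(gy))
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            gfeats, gh = g[..., : -self.growth], g[..., -self.growth:]
            g = gfeats + conv.backward(relu.backward(gh))
        return g


class CompetitiveBlock(_Block):
    """Competitive fusion block: thin (``growth``-wide) candidate features
    fused into a running map by element-wise maximum instead of
    concatenation, then a 1x1 transition to the level width. Fusing by
    maximum keeps the channel count constant, which is where the
    parameter saving over concatenative blocks comes from."""

    def __init__(self, cin: int, cout: int, growth: int, n_layers: int, rng):
        self.first, self.frelu = Conv2d(cin, growth, 3, rng), ReLU()
        self.convs = [Conv2d(growth, growth, 3, rng) for _ in range(max(n_layers - 1, 0))]
        self.relus = [ReLU() for _ in self.convs]
        self.maxes = [Maximum() for _ in self.convs]
        self.trans = Conv2d(growth, cout, 1, rng)
        self.trelu = ReLU()
        self.out_channels = cout

    def params(self):
        ps = self.first.params()
        for c in self.convs:
            ps += c.params()
        return ps + self.trans.params()

    def forward(self, x):
        f = self.frelu.forward(self.first.forward(x))
        for conv, relu, mx in zip(self.convs, self.relus, self.maxes):
            f = mx.forward(f, relu.forward(conv.forward(f)))
        return self.trelu.forward(self.trans.forward(f))

    def backward(self, gy):
        g = self.trans.backward(self.trelu.backward(gy))
        for conv, relu, mx in zip(reversed(self.convs), reversed(self.relus), reversed(self.maxes)):
            ga, gb = mx.backward(g)
            g = ga + conv.backward(relu.backward(gb))
        return self.first.backward(self.frelu.backward(g))


# ---------------------------------------------------------------------------
# networks

class _EncoderDecoder:
    """Shared machinery: encoder blocks + pools, bottleneck, decoder."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        widths = [spec.base_channels * 2**i for i in range(spec.depth + 1)]
        self.widths = widths
        self.enc: list[_Block] = []
        self.pools: list[MaxPool2d] = []
        cin = 1
        for i in range(spec.depth):
            self.enc.append(self._make_block(cin, widths[i], rng))
            self.pools.append(MaxPool2d())
            cin = widths[i]
        self.bottleneck = self._make_block(cin, widths[spec.depth], rng)
        self._build_decoder(rng)
        self.head = Conv2d(widths[0], spec.n_classes, 1, rng)

    def _make_block(self, cin, cout, rng) -> _Block:
        raise NotImplementedError

    def _build_decoder(self, rng) -> None:
        # UNet/DenseUNet style: transposed conv + skip concatenation
        self.ups: list[ConvTranspose2d] = []
        self.dec: list[_Block] = []
        for i in reversed(range(self.spec.depth)):
            self.ups.append(ConvTranspose2d(self.widths[i + 1], self.widths[i], rng))
            self.dec.append(self._make_block(2 * self.widths[i], self.widths[i], rng))

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for u in self.ups:
            ps += u.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            s = block.forward(x)
            skips.append(s)
            x = pool.forward(s)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            u = up.forward(x)
            self._skip_channels.append(skip.shape[-1])
            x = block.forward(np.concatenate([skip, u], axis=-1))
        return self.head.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.head.backward(gy)
        gskips = []
        for up, block, cs in zip(reversed(self.ups), reversed(self.dec),
                                 reversed(self._skip_channels)):
            gcat = block.backward(g)
            gskips.append(gcat[..., :cs])
            g = up.backward(gcat[..., cs:])
        g = self.bottleneck.backward(g)
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools), reversed(gskips)):
            g = block.backward(pool.backward(g) + gskip)
        return g


class UNet(_EncoderDecoder):
    def _make_block(self, cin, cout, rng):
        return ConvBlock(cin, cout, rng)


class DenseUNet(_EncoderDecoder):
    def _make_block(self, cin, cout, rng):
        return DenseBlock(cin, cout, self.spec.growth_rate, self.spec.layers_per_block, rng)


class CDFNet(_EncoderDecoder):
    """Competitive dense fusion network: maxout blocks, max-unpooling with
    encoder index transfer, and max skip fusion (no concatenation)."""

    def _make_block(self, cin, cout, rng):
        return CompetitiveBlock(cin, cout, self.spec.growth_rate, self.spec.layers_per_block, rng)

    def _build_decoder(self, rng) -> None:
        self.proj: list[Conv2d] = []       # channel reduction before unpooling
        self.unpools: list[MaxUnpool2d] = []
        self.fuses: list[Maximum] = []
        self.dec: list[_Block] = []
        for i in reversed(range(self.spec.depth)):
            self.proj.append(Conv2d(self.widths[i + 1], self.widths[i], 1, rng))
            self.unpools.append(MaxUnpool2d(self.pools[i]))
            self.fuses.append(Maximum())
            self.dec.append(self._make_block(self.widths[i], self.widths[i], rng))

    def params(self):
        ps: list[Param] = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for p in self.proj:
            ps += p.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def forward(self, x):
        skips = []
        for block, pool in zip(self.enc, self.pools):
            s = block.forward(x)
            skips.append(s)
            x = pool.forward(s)
        x = self.bottleneck.forward(x)
        for proj, unpool, fuse, block, skip in zip(
            self.proj, self.unpools, self.fuses, self.dec, reversed(skips)
        ):
            u = unpool.forward(proj.forward(x))
            x = block.forward(fuse.forward(skip, u))
        return self.head.forward(x)

    def backward(self, gy):
        g = self.head.backward(gy)
        gskips = []
        for proj, unpool, fuse, block in zip(
            reversed(self.proj), reversed(self.unpools), reversed(self.fuses), reversed(self.dec)
        ):
            gf = block.backward(g)
            gskip, gu = fuse.backward(gf)
            gskips.append(gskip)
            g = proj.backward(unpool.backward(gu))
        g = self.bottleneck.backward(g)
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools), reversed(gskips)):
            g = block.backward(pool.backward(g) + gskip)
        return g


_ARCHS = {"unet": UNet, "denseunet": DenseUNet, "cdfnet": CDFNet}


class SegmentationModel:
    """A built network plus its spec; maps a normalised image grid to
    per-pixel class scores of the same spatial size."""

    def __init__(self, spec: ArchitectureSpec, net: _EncoderDecoder):
        self.spec = spec
        self.net = net

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.net.params()))

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 1) normalised images -> (N, H, W, n_classes) scores."""
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError(f"expected (N, H, W, 1) input, got {x.shape}")
        if x.shape[1] % 2**self.spec.depth or x.shape[2] % 2**self.spec.depth:
            raise ValueError(
                f"spatial dims {x.shape[1:3]} not divisible by 2^depth = {2**self.spec.depth}"
            )
        return self.net.forward(np.ascontiguousarray(x, dtype=np.float32))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)


def build_model(spec: ArchitectureSpec, init_seed: int = 0) -> SegmentationModel:
    """Construct a segmentation network with deterministic seeded weights."""
    rng = np.random.default_rng(init_seed)
    net = _ARCHS[spec.name](spec, rng)
    return SegmentationModel(spec, net)


def normalize_slice(image: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Per-slice robust intensity scaling to [0, 1] using the 1st-99th
    percentiles; constant images map to zero."""
    image = np.asarray(image, dtype=np.float32)
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def predict_slice(
    model: SegmentationModel,
    image: np.ndarray,
    normalization: bool = True,
    class_weight_correction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment one 2-D slice.

    The slice is normalised, resampled to the model's input size, scored,
    and the class probabilities are resampled back to the native grid.
    Returns ``(labels, probabilities)`` where labels are the per-pixel
    argmax (ties resolve to the lowest class index) and probabilities sum
    to 1 per pixel.

    ``class_weight_correction``: the class weights used in a weighted
    cross-entropy loss, if any. Training with weighted CE scales the
    learned posteriors by the weights, so dividing them out at decode
    time (plug-in correction) restores the calibrated decision rule.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {image.shape}")
    x = normalize_slice(image) if normalization else image
    native = x.shape
    size = model.spec.input_size
    if native != (size, size):
        x = resize(x, (size, size), order=1, preserve_range=True, anti_aliasing=True)
    logits = model.forward(x[None, ..., None].astype(np.float32))
    probs = softmax(logits)[0]  # (size, size, 3)
    if native != (size, size):
        probs = np.stack(
            [resize(probs[..., k], native, order=1, preserve_range=True, anti_aliasing=False)
             for k in range(probs.shape[-1])], axis=-1,
        )
        probs = np.clip(probs, 1e-12, None)
        probs /= probs.sum(axis=-1, keepdims=True)
    if class_weight_correction is not None:
        corrected = probs / np.asarray(class_weight_correction, dtype=np.float32)
        labels = corrected.argmax(axis=-1).astype(np.uint8)
    else:
        labels = probs.argmax(axis=-1).astype(np.uint8)
    return labels, probs


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Save spec + weights to a single ``.npz`` file."""
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(Path(path), spec=json.dumps(asdict(model.spec)), **arrays)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    with np.load(Path(path), allow_pickle=False) as data:
        spec = ArchitectureSpec(**json.loads(str(data["spec"])))
        model = build_model(spec, init_seed=0)
        params = model.params()
        for i, p in enumerate(params):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p.value[...] = stored
    return model
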