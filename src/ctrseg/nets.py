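"""Encoder–decoder segmentation networks.

The architecture is a symmetric, skip-free encoder–decoder built from a
single *convolutional block*: 3x3 convolution (stride 1, shape
preserving) → batch normalization → ReLU → CBAM attention.  The encoder
stacks ``blocks_per_stage`` such blocks per stage followed by a 2x2
max-pool, doubling the filter count each stage (16, 32, 64, 128, 256 at
the reference width).  The decoder mirrors it with stride-2 transposed
convolutions (each followed by batch normalization and ReLU), ends with a
3x3 convolution to one channel, batch normalization, and a sigmoid, and
emits a per-pixel foreground probability map.  Batch normalization ahead
of the output sigmoid is unusual but intentional — it is part of the
architecture contract this package implements.

For a 299-pixel input the encoder chain is 299→149→74→37→18→9 and the
decoder inverts it with the transposed-convolution padding pattern
same/valid/same/valid/valid.  For other input sizes the padding pattern
is recomputed automatically: an even size is recovered with ``same``
(out = 2·in), an odd one with ``valid`` (out = 2·in + 1).

In the semi-supervised configuration a model bundles the shared encoder,
the main decoder, and an auxiliary decoder of identical architecture that
consumes perturbed latent representations of unlabeled images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn


class ShapeError(ValueError):
    """Input size incompatible with the pooling/upsampling chain."""


def conv_block(cin: int, filters: int, rng=None, dtype=None,
               cbam: bool = True, reduction: int = 16,
               spatial_k: int = 7) -> nn.Sequential:
    """Conv 3x3 (same) → BatchNorm → ReLU → CBAM."""
    layers = [
        nn.Conv2d(cin, filters, k=3, rng=rng, dtype=dtype),
        nn.BatchNorm2d(filters, dtype=dtype),
        nn.ReLU(),
    ]
    if cbam:
        layers.append(nn.CBAM(filters, reduction=reduction,
                              spatial_k=spatial_k, rng=rng, dtype=dtype))
    return nn.Sequential(layers)


def encoder_size_chain(input_size: int, depth: int) -> list:
    """Spatial sizes before/after each pooling stage; rejects collapse."""
    sizes = [input_size]
    s = input_size
    for _ in range(depth):
        s = s // 2
        if s < 1:
            raise ShapeError(
                f"input size {input_size} collapses before depth {depth}"
            )
        sizes.append(s)
    return sizes


def stage_filters(base_filters: int, depth: int) -> list:
    return [base_filters * (2 ** i) for i in range(depth)]


def build_encoder(input_size: int, in_channels: int = 3,
                  base_filters: int = 16, depth: int = 5,
                  blocks_per_stage: int = 3, cbam: bool = True,
                  reduction: int = 16, spatial_k: int = 7,
                  rng=None, dtype=None) -> nn.Sequential:
    encoder_size_chain(input_size, depth)
    layers = []
    cin = in_channels
    for f in stage_filters(base_filters, depth):
        for _ in range(blocks_per_stage):
            layers.append(conv_block(cin, f, rng=rng, dtype=dtype, cbam=cbam,
                                     reduction=reduction, spatial_k=spatial_k))
            cin = f
        layers.append(nn.MaxPool2d(2))
    return nn.Sequential(layers)


def build_decoder(input_size: int, base_filters: int = 16, depth: int = 5,
                  blocks_per_stage: int = 3, cbam: bool = True,
                  reduction: int = 16, spatial_k: int = 7,
                  rng=None, dtype=None) -> nn.Sequential:
    """Decoder inverting the encoder's shape chain for ``input_size``."""
    sizes = encoder_size_chain(input_size, depth)
    filters = stage_filters(base_filters, depth)
    layers = []
    cin = filters[-1]
    for stage in range(depth - 1, -1, -1):
        f = filters[stage]
        for _ in range(blocks_per_stage):
            layers.append(conv_block(cin, f, rng=rng, dtype=dtype, cbam=cbam,
                                     reduction=reduction, spatial_k=spatial_k))
            cin = f
        cout = filters[stage - 1] if stage > 0 else 1
        cur, target = sizes[stage + 1], sizes[stage]
        if target == 2 * cur:
            pad = "same"
        elif target == 2 * cur + 1:
            pad = "valid"
        else:  # unreachable for floor-halving chains; guards bad chains
            raise ShapeError(f"cannot upsample {cur} -> {target}")
        layers.append(nn.ConvTranspose2d(cin, cout, k=3, stride=2,
                                         padding=pad, rng=rng, dtype=dtype))
        layers.append(nn.BatchNorm2d(cout, dtype=dtype))
        layers.append(nn.ReLU())
        cin = cout
    layers.append(nn.Conv2d(1, 1, k=3, rng=rng, dtype=dtype))
    layers.append(nn.BatchNorm2d(1, dtype=dtype))
    layers.append(nn.Sigmoid())
    return nn.Sequential(layers)


def decoder_padding_pattern(input_size: int, depth: int = 5) -> list:
    """The same/valid pattern the decoder uses for a given input size."""
    sizes = encoder_size_chain(input_size, depth)
    pattern = []
    for stage in range(depth - 1, -1, -1):
        cur, target = sizes[stage + 1], sizes[stage]
        pattern.append("same" if target == 2 * cur else "valid")
    return pattern


_ARCH_KEYS = ("input_size", "in_channels", "base_filters", "depth",
              "blocks_per_stage", "cbam", "reduction", "spatial_k")


class ModelBundle:
    """Shared encoder + main decoder (+ optional auxiliary decoder)."""

    def __init__(self, encoder, main_decoder, aux_decoder=None, meta=None):
        self.encoder = encoder
        self.main_decoder = main_decoder
        self.aux_decoder = aux_decoder
        self.meta = dict(meta or {})

    # -- construction ------------------------------------------------
    @classmethod
    def build(cls, input_size: int, in_channels: int = 3,
              base_filters: int = 16, depth: int = 5,
              blocks_per_stage: int = 3, cbam: bool = True,
              reduction: int = 16, spatial_k: int = 7,
              with_aux: bool = False, seed: int = 0, dtype=None,
              organ: str = "", mode: str = "") -> "ModelBundle":
        rng = np.random.default_rng(seed)
        kw = dict(base_filters=base_filters, depth=depth,
                  blocks_per_stage=blocks_per_stage, cbam=cbam,
                  reduction=reduction, spatial_k=spatial_k, dtype=dtype)
        enc = build_encoder(input_size, in_channels=in_channels, rng=rng, **kw)
        dec = build_decoder(input_size, rng=rng, **kw)
        aux = build_decoder(input_size, rng=rng, **kw) if with_aux else None
        meta = dict(input_size=input_size, in_channels=in_channels,
                    base_filters=base_filters, depth=depth,
                    blocks_per_stage=blocks_per_stage, cbam=cbam,
                    reduction=reduction, spatial_k=spatial_k,
                    with_aux=with_aux, seed=seed, organ=organ, mode=mode)
        return cls(enc, dec, aux, meta)

    # -- inference ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = self.encoder.forward(x, train)
        return self.main_decoder.forward(z, train)

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Eval-mode probability maps (N, H, W) for NCHW input images."""
        outs = []
        for i in range(0, len(images), batch_size):
            p = self.forward(images[i:i + batch_size], train=False)
            outs.append(p[:, 0])
        return np.concatenate(outs, axis=0)

    # -- parameter bookkeeping --------------------------------------
    def _nets(self):
        nets = [("enc", self.encoder), ("dec", self.main_decoder)]
        if self.aux_decoder is not None:
            nets.append(("aux", self.aux_decoder))
        return nets

    def all_params(self):
        out = []
        for _, net in self._nets():
            out.extend(net.params())
        return out

    # -- checkpoint I/O ----------------------------------------------
    def save(self, path) -> None:
        """Write parameters to ``<path>.npz`` and metadata to ``<path>.json``."""
        path = Path(path)
        arrays = {}
        for tag, net in self._nets():
            for i, p in enumerate(net.params()):
                arrays[f"{tag}_p{i}"] = p.value
            for j, mod in enumerate(net.iter_modules()):
                for name, buf in mod.buffers().items():
                    arrays[f"{tag}_b{j}_{name}"] = buf
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        bundle = cls.build(
            **{k: meta[k] for k in _ARCH_KEYS},
            with_aux=meta.get("with_aux", False), seed=meta.get("seed", 0),
            organ=meta.get("organ", ""), mode=meta.get("mode", ""),
        )
        bundle.meta = meta
        with np.load(path.with_suffix(".npz")) as data:
            for tag, net in bundle._nets():
                for i, p in enumerate(net.params()):
                    p.value = data[f"{tag}_p{i}"].copy()
                    p.grad = np.zeros_like(p.value)
                for j, mod in enumerate(net.iter_modules()):
                    bufs = {
                        name: data[f"{tag}_b{j}_{name}"].copy()
                        for name in mod.buffers()
                    }
                    if bufs:
                        mod.load_buffers(bufs)
        return bundle
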