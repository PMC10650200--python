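"""The dual-phase stacked UNet.

Two identically scheduled UNet encoder--decoders run in sequence.  The
first consumes the RGB image and emits a soft mask; the second consumes
the image concatenated with that mask (4 channels) and, after every one
of its encoder blocks, its bottleneck, and every decoder block, replaces
its features with the elementwise mean of its own features and the
corresponding features of the first UNet:

    F_i^e = (E_i^1 + E_i^2) / 2        F_i^d = (D_i^1 + D_i^2) / 2

Skip connections in the second UNet therefore carry fused encoder
features.  Both networks end in a 1x1 convolution with sigmoid
activation, so the model emits two soft masks per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DHuNeTConfig
from .exceptions import ValidationError
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv2d, ConvBlock, ConvTranspose2d, Module


def fuse(a, b):
    """Elementwise mean of two feature maps (arrays or graph tensors)."""
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return ag.mean_pair(ag.as_tensor(a), ag.as_tensor(b))
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"fuse shape mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


@dataclass
class FeaturePyramid:
    """Per-level feature maps of one UNet pass.

    ``encoder_features[i]`` / ``decoder_features[i]`` hold the level-(i+1)
    block outputs (index 0 = highest resolution); for the second UNet
    these are the post-fusion maps and the ``*_prefusion`` lists keep the
    maps as they were before averaging, which the fusion tests inspect.
    """

    encoder_features: list = field(default_factory=list)
    bottleneck: object = None
    decoder_features: list = field(default_factory=list)
    encoder_prefusion: list = field(default_factory=list)
    bottleneck_prefusion: object = None
    decoder_prefusion: list = field(default_factory=list)


class UNet(Module):
    """One symmetric encoder--decoder with skip connections."""

    def __init__(self, cfg: DHuNeTConfig, in_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ch = cfg.filters  # depth levels + bottleneck
        prev = in_channels
        for i in range(cfg.depth):
            setattr(self, f"enc{i}", ConvBlock(prev, ch[i], cfg.kernel_size,
                                               cfg.convs_per_block,
                                               cfg.use_batchnorm, rng))
            prev = ch[i]
        self.bottleneck_block = ConvBlock(ch[cfg.depth - 1], ch[cfg.depth],
                                          cfg.kernel_size, cfg.convs_per_block,
                                          cfg.use_batchnorm, rng)
        up_in = ch[cfg.depth]
        for i in range(cfg.depth - 1, -1, -1):
            if cfg.upsample_mode == "transposed":
                setattr(self, f"up{i}", ConvTranspose2d(up_in, ch[i], rng))
            else:
                setattr(self, f"up{i}", Conv2d(up_in, ch[i], cfg.kernel_size,
                                               rng, bias=True))
            setattr(self, f"dec{i}", ConvBlock(2 * ch[i], ch[i], cfg.kernel_size,
                                               cfg.convs_per_block,
                                               cfg.use_batchnorm, rng))
            up_in = ch[i]
        self.head = Conv2d(ch[0], cfg.out_channels, 1, rng, bias=True)

    def _upsample(self, x: Tensor, i: int) -> Tensor:
        up = getattr(self, f"up{i}")
        if self.cfg.upsample_mode == "transposed":
            return up(x)
        return up(ag.upsample_nearest2x(x))

    def forward(self, x: Tensor, fuse_with: FeaturePyramid | None = None
                ) -> tuple[Tensor, FeaturePyramid]:
        cfg = self.cfg
        pyr = FeaturePyramid()
        cur = x
        for i in range(cfg.depth):
            f = getattr(self, f"enc{i}")(cur)
            if fuse_with is not None:
                pyr.encoder_prefusion.append(f)
                f = ag.mean_pair(fuse_with.encoder_features[i], f)
            pyr.encoder_features.append(f)
            cur = ag.max_pool2x2(f)
        bott = self.bottleneck_block(cur)
        if fuse_with is not None:
            pyr.bottleneck_prefusion = bott
            bott = ag.mean_pair(fuse_with.bottleneck, bott)
        pyr.bottleneck = bott
        cur = bott
        dec_rev = []
        for i in range(cfg.depth - 1, -1, -1):
            cur = self._upsample(cur, i)
            cur = ag.concat_channels(pyr.encoder_features[i], cur)
            d = getattr(self, f"dec{i}")(cur)
            if fuse_with is not None:
                dec_rev.append(("pre", d))
                d = ag.mean_pair(fuse_with.decoder_features[i], d)
            dec_rev.append(("post", d))
            cur = d
        for tag, t in dec_rev:
            (pyr.decoder_prefusion if tag == "pre" else pyr.decoder_features).append(t)
        pyr.decoder_features.reverse()   # index 0 = highest resolution
        pyr.decoder_prefusion.reverse()
        mask = ag.sigmoid(self.head(cur))
        return mask, pyr


class DHuNeT(Module):
    """Model handle: both UNets plus the wiring between them."""

    def __init__(self, config: DHuNeTConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.unet1 = UNet(config, config.in_channels_unet1, rng)
        self.unet2 = UNet(config, config.in_channels_unet2, rng)

    @property
    def parameter_count(self) -> int:
        return count_parameters(self)

    def _check_batch(self, batch: np.ndarray | Tensor) -> Tensor:
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels_unet1:
            raise ValidationError(
                f"expected (N, {self.config.in_channels_unet1}, H, W) batch, "
                f"got {tuple(x.shape)}")
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.config.depth
        if h % div or w % div or h < div or w < div:
            raise ValidationError(
                f"spatial size {h}x{w} not divisible by 2^depth = {div}")
        return x

    def forward(self, batch, capture: bool = False):
        """Run both stages; returns (mask1, mask2[, (pyramid1, pyramid2)]).

        Masks are sigmoid outputs in (0, 1), shape (N, 1, H, W).  With
        ``capture=True`` the per-level feature pyramids of both UNets are
        returned for inspection.
        """
        x = self._check_batch(batch)
        mask1, pyr1 = self.unet1.forward(x)
        x2 = ag.concat_channels(x, mask1)
        mask2, pyr2 = self.unet2.forward(x2, fuse_with=pyr1)
        if capture:
            return mask1, mask2, (pyr1, pyr2)
        return mask1, mask2, None

    def __call__(self, batch, capture: bool = False):
        return self.forward(batch, capture)

    def predict_masks(self, batch) -> tuple[np.ndarray, np.ndarray]:
        """Inference helper: soft masks of both heads as (N, H, W) arrays."""
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                m1, m2, _ = self.forward(batch)
        finally:
            self.train(was_training)
        return m1.data[:, 0], m2.data[:, 0]


def build_dhunet(config: DHuNeTConfig | None = None, seed: int = 0) -> DHuNeT:
    """Construct the dual UNet with seeded He-uniform initialisation."""
    return DHuNeT(config or DHuNeTConfig(), seed=seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar weights across both UNets."""
    return int(sum(p.data.size for p in model.parameters()))
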