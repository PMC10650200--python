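"""Configuration records for the generator, preprocessor, network and trainer.

Every record validates its fields on construction and round-trips through a
flat YAML mapping, so a run is fully described by one config file plus the
seeds logged at startup.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic wound image/mask pair.

    The generator draws 1-3 irregular reddish lesions over a noisy
    skin-toned background; ``border_widths`` adds the all-black bands
    (left, right, top, bottom) that the preprocessing crop removes.
    """

    seed: int = 0
    size: int = 128
    n_lesions: int = 2
    lesion_radius_frac: tuple[float, float] = (0.08, 0.25)
    boundary_jitter: float = 0.3
    skin_tone: tuple[int, int, int] = (198, 144, 118)
    noise_sd: float = 8.0
    border_widths: tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self):
        if self.size < 32:
            raise ValidationError(f"size must be >= 32, got {self.size}")
        if not 0 <= self.n_lesions <= 3:
            raise ValidationError(f"n_lesions must be in [0, 3], got {self.n_lesions}")
        lo, hi = self.lesion_radius_frac
        if not (0 < lo <= hi < 0.5):
            raise ValidationError(f"bad lesion_radius_frac {self.lesion_radius_frac}")
        if self.boundary_jitter < 0:
            raise ValidationError("boundary_jitter must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if any(w < 0 for w in self.border_widths):
            raise ValidationError(f"border widths must be >= 0, got {self.border_widths}")
        if not all(0 <= v <= 255 for v in self.skin_tone):
            raise ValidationError(f"skin_tone must be 8-bit RGB, got {self.skin_tone}")


@dataclass(frozen=True)
class BlurConfig:
    """Blur-and-grayscale stage: median (default) or Gaussian smoothing."""

    mode: str = "median"
    kernel: int = 5
    sigma_x: float = 1.0
    sigma_y: float = 1.0

    def __post_init__(self):
        if self.mode not in ("median", "gaussian"):
            raise ValidationError(f"mode must be median|gaussian, got {self.mode!r}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValidationError(f"kernel must be odd and >= 1, got {self.kernel}")
        if self.mode == "gaussian" and (self.sigma_x <= 0 or self.sigma_y <= 0):
            raise ValidationError("gaussian sigmas must be > 0")


@dataclass(frozen=True)
class PreprocessConfig:
    """Full region-of-interest pipeline configuration.

    ``threshold`` separates near-black border bands from content (default
    10 of 255); ``dp_tolerance_frac`` is the polygon-simplification
    tolerance as a fraction of contour perimeter.
    """

    blur: BlurConfig = field(default_factory=BlurConfig)
    threshold: int = 10
    target_size: int = 128
    dp_tolerance_frac: float = 0.01

    def __post_init__(self):
        if not 0 <= self.threshold <= 255:
            raise ValidationError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.target_size < 8:
            raise ValidationError(f"target_size must be >= 8, got {self.target_size}")


@dataclass(frozen=True)
class DHuNeTConfig:
    """Architecture of the dual stacked UNet.

    The default schedule was fixed by an exhaustive constraint search
    (``scripts/search_default_config.py``) over depth 2-5, base filters
    4-32, batchnorm on/off and both upsampling modes, selecting the
    configuration whose trainable-parameter count comes closest to the
    published total; it lands at 1,081,978 parameters.
    """

    depth: int = 4
    base_filters: int = 8
    filter_growth: int = 2
    kernel_size: int = 3
    convs_per_block: int = 2
    use_batchnorm: bool = True
    upsample_mode: str = "interp+conv"  # or "transposed"
    in_channels_unet1: int = 3
    in_channels_unet2: int = 4  # RGB + first-stage soft mask
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 2:
            raise ValidationError(f"depth must be >= 2, got {self.depth}")
        if self.base_filters < 1:
            raise ValidationError("base_filters must be >= 1")
        if self.upsample_mode not in ("transposed", "interp+conv"):
            raise ValidationError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.kernel_size % 2 == 0:
            raise ValidationError("kernel_size must be odd")
        if self.convs_per_block < 1:
            raise ValidationError("convs_per_block must be >= 1")

    @property
    def filters(self) -> list[int]:
        """Channel schedule per encoder level, plus the bottleneck."""
        return [self.base_filters * self.filter_growth ** i for i in range(self.depth + 1)]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; learning rate, batch size and optimiser follow
    the published training setup (0.005, 32, Adam)."""

    strategy: str = "bce"  # or "dice"
    learning_rate: float = 0.005
    batch_size: int = 32
    optimizer: str = "adam"
    epochs: int = 50
    head_loss_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    checkpoint_dir: str | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.strategy not in ("bce", "dice"):
            raise ValidationError(f"strategy must be bce|dice, got {self.strategy!r}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        w1, w2 = self.head_loss_weights
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValidationError("head weights must be >= 0 and not both zero")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must be in (0, 1)")


# ---------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------

_SECTIONS = {
    "synthetic": SyntheticSpec,
    "preprocess": PreprocessConfig,
    "model": DHuNeTConfig,
    "train": TrainConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "blur" and isinstance(v, dict):
            v = BlurConfig(**v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(path: str | Path, **sections) -> None:
    """Write any of synthetic=, preprocess=, model=, train= to one YAML file."""
    doc = {name: _to_plain(cfg) for name, cfg in sections.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a dict of typed config records."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, payload in doc.items():
        if name not in _SECTIONS:
            raise ValidationError(f"unknown config section {name!r}")
        out[name] = _from_plain(_SECTIONS[name], payload or {})
    return out
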