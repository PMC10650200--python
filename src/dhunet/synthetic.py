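"""Seeded generator of wound-like image/mask pairs.

Real chronic-wound photographs show irregular reddish lesions on skin with
varying texture, plus occasional all-black bands where photographs were
padded or letterboxed — the artifact the preprocessing crop removes.  This
module emulates exactly those features with pixel-exact masks:

* a skin-toned background with Gaussian pixel noise and a smooth
  illumination field,
* 1-3 simply connected lesions, each an ellipse whose radius is modulated
  by a low-order sum of sinusoids (irregular but star-shaped, so the mask
  is exact by construction),
* optional all-black border bands on any edge.

All geometry is drawn in unit (fractional) coordinates, so the same seed
produces the same scene at any raster size and the foreground fraction is
scale-free up to rasterisation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .config import SyntheticSpec
from .exceptions import ValidationError

_MAX_SEED = 2**31 - 1


def _lesion_color(rng: np.random.Generator) -> np.ndarray:
    """A reddish wound tone, clearly distinct from skin."""
    r = rng.uniform(140, 200)
    g = rng.uniform(30, 70)
    b = rng.uniform(35, 75)
    return np.array([r, g, b])


def _render_lesion(rng: np.random.Generator, spec: SyntheticSpec,
                   yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Boolean support of one lesion on the pixel-centre grid (unit coords)."""
    lo, hi = spec.lesion_radius_frac
    r0 = rng.uniform(lo, hi)
    cx = rng.uniform(0.2, 0.8)
    cy = rng.uniform(0.2, 0.8)
    aspect = rng.uniform(0.6, 1.0)
    phi = rng.uniform(0, np.pi)
    # periodic smooth jitter: <= 4 sinusoids with random phase
    n_harm = 4
    amps = rng.uniform(0.3, 1.0, n_harm)
    amps *= spec.boundary_jitter / max(amps.sum(), 1e-12)
    phases = rng.uniform(0, 2 * np.pi, n_harm)

    dx, dy = xx - cx, yy - cy
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    a, b = r0, r0 * aspect
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    mod = np.zeros_like(theta)
    for k in range(n_harm):
        mod += amps[k] * np.sin((k + 2) * theta + phases[k])
    boundary = base * np.clip(1.0 + mod, 0.2, None)
    return rho <= boundary


def generate_sample(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one image/mask pair.

    Returns an 8-bit ``size x size x 3`` image and a ``size x size`` mask
    in {0, 1}.  The mask is exactly the union of the rendered lesion
    supports.  Identical specs give bit-identical output.
    """
    # geometry and texture use independent child streams so the scene
    # layout (and hence the foreground fraction) is raster-size invariant
    ss = np.random.SeedSequence(entropy=spec.seed)
    geom_rng, tex_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    size = spec.size
    coords = (np.arange(size) + 0.5) / size
    xx, yy = np.meshgrid(coords, coords)

    # background: skin tone + smooth illumination + pixel noise
    skin = np.array(spec.skin_tone, dtype=float)
    illum = 0.5 * spec.noise_sd * np.sin(
        2 * np.pi * (geom_rng.uniform(0.5, 1.5) * xx
                     + geom_rng.uniform(0.5, 1.5) * yy)
        + geom_rng.uniform(0, 2 * np.pi)
    )
    image = skin[None, None, :] + illum[:, :, None]
    image += tex_rng.normal(0.0, spec.noise_sd, size=(size, size, 3))

    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(spec.n_lesions):
        support = _render_lesion(geom_rng, spec, yy, xx)
        color = _lesion_color(geom_rng)
        shade = 0.75 + 0.25 * geom_rng.uniform()
        # darker core, lighter rim; lesion noise re-uses the background sd
        tex = tex_rng.normal(0.0, spec.noise_sd, size=(size, size, 3))
        lesion_px = color[None, None, :] * shade + tex
        image = np.where(support[:, :, None], lesion_px, image)
        mask[support] = 1

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    if any(spec.border_widths):
        image, mask = add_black_border(image, mask, spec.border_widths)
    return image, mask


def add_black_border(image: np.ndarray, mask: np.ndarray,
                     widths: tuple[int, int, int, int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Surround an image/mask pair with all-black bands.

    ``widths`` is (left, right, top, bottom); the output grows by those
    amounts and the interior is the unmodified input.
    """
    left, right, top, bottom = widths
    if min(widths) < 0:
        raise ValidationError(f"border widths must be >= 0, got {widths}")
    h, w = mask.shape
    if image.shape[:2] != (h, w):
        raise ValidationError(
            f"image/mask shape mismatch: {image.shape[:2]} vs {mask.shape}")
    if w == 0 or h == 0:
        raise ValidationError("empty interior")
    if left + right >= w or top + bottom >= h:
        raise ValidationError(
            f"band widths {widths} too large for a {h}x{w} interior")
    out_img = np.zeros((h + top + bottom, w + left + right, 3), dtype=image.dtype)
    out_mask = np.zeros((h + top + bottom, w + left + right), dtype=mask.dtype)
    out_img[top:top + h, left:left + w] = image
    out_mask[top:top + h, left:left + w] = mask
    return out_img, out_mask


def sample_seed(template_seed: int, index: int) -> int:
    """Counter-based per-sample seed: order-independent and collision-safe."""
    ss = np.random.SeedSequence(entropy=template_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0]) & _MAX_SEED


def generate_dataset(spec_template: SyntheticSpec, n: int, out_dir: str | Path,
                     train_frac: float | None = None) -> Path:
    """Write ``n`` image/mask PNG pairs plus a TSV manifest; returns its path.

    Per-sample specs differ from the template only in their seed, derived
    deterministically from ``spec_template.seed`` and the sample index.
    With ``train_frac`` set, the first ``round(n * train_frac)`` rows are
    tagged ``train`` and the rest ``test``; otherwise all rows are ``train``.
    """
    from . import io as dio  # local import to avoid a cycle at import time

    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = n if train_frac is None else int(round(n * train_frac))
    rows = []
    for i in range(n):
        spec_i = dataclasses.replace(spec_template, seed=sample_seed(spec_template.seed, i))
        image, mask = generate_sample(spec_i)
        img_name, mask_name = f"sample_{i:04d}.png", f"mask_{i:04d}.png"
        dio.save_image(out_dir / img_name, image)
        dio.save_mask(out_dir / mask_name, mask)
        rows.append(dio.ManifestRow(img_name, mask_name,
                                    "train" if i < n_train else "test"))
    manifest_path = out_dir / "manifest.tsv"
    dio.write_manifest(rows, manifest_path)
    return manifest_path
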