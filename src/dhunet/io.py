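"""Raster and manifest I/O.

Conventions: images travel as 8-bit RGB arrays; masks are stored on disk
as single-channel {0, 255} PNG (viewer friendly) and live in memory as
{0, 1} uint8.  Manifests are UTF-8 TSV files with the header
``image<TAB>mask<TAB>split``; paths are resolved relative to the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import ImageIOError, ManifestError

VALID_SPLITS = ("train", "val", "test")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG into an 8-bit H x W x 3 array (grayscale is promoted)."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError as e:
        raise ImageIOError(f"image not found: {path}") from e
    except UnidentifiedImageError as e:
        raise ImageIOError(f"not a raster file: {path}") from e


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; {0, 255} (or already-{0, 1}) storage becomes {0, 1}."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except FileNotFoundError as e:
        raise ImageIOError(f"mask not found: {path}") from e
    except UnidentifiedImageError as e:
        raise ImageIOError(f"not a raster file: {path}") from e
    return (arr > 127).astype(np.uint8) if arr.max(initial=0) > 1 else arr.astype(np.uint8)


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_sample(image_path: str | Path, mask_path: str | Path
                ) -> tuple[np.ndarray, np.ndarray]:
    """Load a paired image and mask, checking that their sizes agree."""
    image = load_image(image_path)
    mask = load_mask(mask_path)
    if image.shape[:2] != mask.shape:
        raise ImageIOError(
            f"image/mask size mismatch: {image.shape[:2]} ({image_path}) vs "
            f"{mask.shape} ({mask_path})")
    return image, mask


# ---------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRow:
    image: str
    mask: str
    split: str = "train"


def write_manifest(rows: list[ManifestRow], path: str | Path) -> Path:
    path = Path(path)
    lines = ["image\tmask\tsplit"]
    lines += [f"{r.image}\t{r.mask}\t{r.split}" for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_manifest(path: str | Path, split: str | None = None,
                  check_exists: bool = True) -> list[ManifestRow]:
    """Parse a manifest; optionally filter by split tag.

    Paths in the returned rows are made absolute against the manifest's
    directory so callers can load samples directly.
    """
    path = Path(path)
    if not path.is_file():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["image", "mask", "split"]:
        raise ManifestError(f"bad manifest header in {path}")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ManifestError(f"{path}:{ln}: expected 3 tab-separated fields")
        img, msk, tag = parts
        if tag not in VALID_SPLITS:
            raise ManifestError(f"{path}:{ln}: unknown split {tag!r}")
        img_p, msk_p = str(base / img), str(base / msk)
        if check_exists and not (Path(img_p).is_file() and Path(msk_p).is_file()):
            raise ManifestError(f"{path}:{ln}: referenced file missing")
        if split is None or tag == split:
            rows.append(ManifestRow(img_p, msk_p, tag))
    return rows


# ---------------------------------------------------------------------
# metric reports and run metadata
# ---------------------------------------------------------------------

REPORT_COLUMNS = ("strategy", "head", "recall", "precision", "f1", "dice",
                  "aggregation")


def write_report(reports, path: str | Path) -> Path:
    """Write metric reports as TSV, one row per head x strategy x aggregation."""
    if not reports:
        raise ValueError("write_report needs at least one report")
    path = Path(path)
    lines = ["\t".join(REPORT_COLUMNS)]
    for r in reports:
        lines.append("\t".join([
            r.strategy or "-", str(r.head),
            f"{r.recall:.4f}", f"{r.precision:.4f}",
            f"{r.f1:.4f}", f"{r.dice:.4f}", r.aggregation,
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_report_json(reports, path: str | Path) -> Path:
    payload = []
    for r in reports:
        d = dataclasses.asdict(r)
        d["counts"] = dataclasses.asdict(r.counts) if r.counts else None
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def write_run_metadata(path: str | Path, **fields) -> Path:
    """Record config, seeds and environment facts for a run as JSON."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(fields, indent=1, default=default))
    return Path(path)
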